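"""Cohort-construction rules: washout, same-month diagnosis, exclusions,
baseline covariates, attrition bookkeeping, and all-drugs deduplication."""

from __future__ import annotations

import pytest

from persistkit import (apply_inclusion_exclusion, build_all_drugs_cohort,
                        build_cohort, find_index_events)
from persistkit.drugs import default_catalog

from conftest import make_bundle, qualifying_fixture

DRUG = "rasagiline"


def bundle_with(config, fills_spec, extra_dx=(), patient_overrides=None,
                pid="p1", entry=400):
    """One qualifying patient plus index fills per ``fills_spec``
    [(day, supply), ...]; levodopa/G20 scaffolding included."""
    patients, fills, dx = qualifying_fixture(config, pid, entry, DRUG,
                                             n_refills=0)
    fills = [f for f in fills if f[1] != DRUG]
    fills += [(pid, DRUG, day, supply) for day, supply in fills_spec]
    dx += list(extra_dx)
    if patient_overrides:
        patients[0].update(patient_overrides)
    return make_bundle(config, patients, fills, dx)


# -- washout / index events ------------------------------------------------


@pytest.mark.parametrize("fill_days,expected_entry,washout_ok", [
    ([400], 400, True),          # clean first use
    ([300, 400], 400, False),    # prior use 100 days back: washout violated
    ([150, 400], 400, True),     # prior use 250 days back: outside washout
], ids=["first-use", "washout-violated", "old-use-ok"])
def test_washout_rule(config, fill_days, expected_entry, washout_ok):
    b = bundle_with(config, [(d, 30) for d in fill_days])
    events = find_index_events(b, DRUG, config)
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev["entry_day"] == expected_entry
    assert bool(ev["washout_ok"]) is washout_ok


def test_washout_from_extraction_start_is_stricter(config):
    cfg2 = config.model_copy(update={"washout_from_extraction_start": True})
    b = bundle_with(config, [(150, 30), (400, 30)])
    assert bool(find_index_events(b, DRUG, config).iloc[0]["washout_ok"])
    assert not bool(find_index_events(b, DRUG, cfg2).iloc[0]["washout_ok"])


def test_non_index_drug_rejected(config):
    b = bundle_with(config, [(400, 30)])
    with pytest.raises(ValueError):
        find_index_events(b, "levodopa_300", config)
    with pytest.raises(KeyError):
        find_index_events(b, "nonexistent", config)


# -- inclusion / exclusion -------------------------------------------------


def _cohort(bundle, config):
    return build_cohort(bundle, DRUG, config)


def test_qualifying_patient_is_retained(config):
    members, att = _cohort(bundle_with(config, [(400, 30)]), config)
    assert list(members["patient_id"]) == ["p1"]
    assert att.telescopes()
    assert att.rows[-1].n_after == 1


def test_pd_diagnosis_must_be_in_entry_month(config):
    entry_month = config.month_index_of_day(400)
    b = bundle_with(config, [(400, 30)])
    b.diagnoses = b.diagnoses.iloc[0:0]  # drop scaffold G20
    b2 = make_bundle(config, [{"patient_id": "p1"}],
                     b.fills.values.tolist(),
                     [("p1", "G20", entry_month - 1)])
    members, att = _cohort(b2, config)
    assert len(members) == 0
    assert "p1" in att.excluded_by("PD diagnosis (G20) in entry month")


def test_levodopa_needed_at_entry_and_in_lookback(config):
    b = bundle_with(config, [(400, 30)])
    # remove the entry-day levodopa fill only
    lev = set(default_catalog().query("`class` == 'levodopa'").index)
    f = b.fills
    b.fills = f[~(f["drug_code"].isin(lev) & (f["fill_date"] == 400))]
    members, att = _cohort(b, config)
    assert len(members) == 0
    assert "p1" in att.excluded_by("levodopa at entry and in look-back")


def test_exclusion_diagnosis_any_time_excludes(config):
    b = bundle_with(config, [(400, 30)],
                    extra_dx=[("p1", "G23.1", 2)])  # PSP long before entry
    members, att = _cohort(b, config)
    assert len(members) == 0
    assert "p1" in att.excluded_by("no differential-diagnosis codes")


def test_minimum_age_enforced(config):
    b = bundle_with(config, [(400, 30)],
                    patient_overrides={"birth_year": 1990})  # age 31 in 2021
    members, att = _cohort(b, config)
    assert len(members) == 0
    assert "p1" in att.excluded_by("age >= 40 at entry")


def test_enrollment_must_cover_lookback_and_followup(config):
    b = bundle_with(config, [(400, 30)],
                    patient_overrides={"last_observed": 500})
    members, att = _cohort(b, config)
    assert len(members) == 0
    assert "p1" in att.excluded_by(
        "continuous enrollment over look-back and follow-up")


def test_empty_cohort_is_valid(config):
    b = bundle_with(config, [(400, 30)])
    b.fills = b.fills[b.fills["drug_code"] != DRUG]
    events = find_index_events(b, DRUG, config)
    members, att = apply_inclusion_exclusion(events, b, config, DRUG)
    assert len(members) == 0 and att.telescopes()


# -- baseline covariates ---------------------------------------------------


def test_covariates_computed_at_entry(config):
    pid, entry = "p1", 400
    patients, fills, dx = qualifying_fixture(config, pid, entry, DRUG)
    # ongoing concomitants: two distinct ATC2 classes >= 14 days, one short
    fills += [(pid, "statin", entry - 30, 30), (pid, "statin", entry, 30),
              (pid, "ppi", entry, 30),
              (pid, "nsaid", entry, 7)]
    # a second anti-PD adjunct filled at entry
    fills += [(pid, "zonisamide", entry - 200, 30),
              (pid, "zonisamide", entry, 30)]
    dx += [(pid, "F32.9", config.month_index_of_day(entry) - 2)]
    b = make_bundle(config, patients, fills, dx)
    members, _ = _cohort(b, config)
    m = members.iloc[0]
    assert m["age"] == config.offset_date(entry).year - 1945
    assert m["n_anti_pd"] == 2          # index + zonisamide, levodopa apart
    assert m["n_concomitant"] == 2      # statin + ppi; nsaid under 14 days
    assert m["levodopa_dose"] == 300.0
    assert m["led_excl_index"] == pytest.approx(300.0 + 100.0)  # minus index
    assert m["co_depression"] == 1 and m["co_dementia"] == 0
    assert m["hosp_rx"] == 0


def test_covariates_ignore_post_entry_data_except_hospital_flag(config):
    pid, entry = "p1", 400
    patients, fills, dx = qualifying_fixture(config, pid, entry, DRUG)
    b1 = make_bundle(config, patients, list(fills), dx)
    # post-entry noise: new concomitant, extra adjunct, discharge fill
    fills2 = fills + [(pid, "statin", entry + 60, 30),
                      (pid, "zonisamide", entry + 90, 30),
                      (pid, DRUG, entry + 200, 1, True)]
    b2 = make_bundle(config, patients, fills2, dx)
    m1 = build_cohort(b1, DRUG, config)[0].iloc[0]
    m2 = build_cohort(b2, DRUG, config)[0].iloc[0]
    baseline = ["age", "sex", "n_anti_pd", "n_concomitant", "levodopa_dose",
                "led_excl_index"]
    assert m1[baseline].tolist() == m2[baseline].tolist()
    assert m1["hosp_rx"] == 0 and m2["hosp_rx"] == 1


# -- all-drugs deduplication -----------------------------------------------


def two_drug_bundle(config, day_a, day_b):
    pid = "p1"
    patients, fills, dx = qualifying_fixture(config, pid, min(day_a, day_b),
                                             DRUG, n_refills=0)
    fills = [f for f in fills if f[1] != DRUG]
    entry_b_month = config.month_index_of_day(max(day_a, day_b))
    dx += [(pid, "G20", entry_b_month)]
    for k in range(-6, 13):  # levodopa around both candidate entries
        fills.append((pid, "levodopa_300", max(day_a, day_b) + 30 * k, 30))
    fills += [(pid, DRUG, day_a, 30), (pid, "zonisamide", day_b, 30)]
    return make_bundle(config, patients, fills, dx)


def test_all_drugs_keeps_earliest_entry(config):
    b = two_drug_bundle(config, 400, 450)
    per_drug = {d: build_cohort(b, d, config)[0]
                for d in (DRUG, "zonisamide")}
    assert all(len(v) == 1 for v in per_drug.values())
    merged = build_all_drugs_cohort(per_drug, b.catalog)
    assert len(merged) == 1
    assert merged.iloc[0]["entry_day"] == 400
    assert merged.iloc[0]["index_drugs"] == (DRUG,)


def test_same_day_new_fills_merge_into_combination(config):
    b = two_drug_bundle(config, 400, 400)
    per_drug = {d: build_cohort(b, d, config)[0]
                for d in (DRUG, "zonisamide")}
    merged = build_all_drugs_cohort(per_drug, b.catalog)
    assert len(merged) == 1
    m = merged.iloc[0]
    assert m["index_drugs"] == (DRUG, "zonisamide")
    # combination LED exclusion removes both constituents
    assert m["led_excl_index"] == pytest.approx(
        m["led_n04_total"] - 100.0 - 100.0)


def test_single_cohort_patient_passes_through_unchanged(config):
    b = bundle_with(config, [(400, 30)])
    members, _ = _cohort(b, config)
    merged = build_all_drugs_cohort({DRUG: members}, b.catalog)
    assert merged.iloc[0].equals(members.iloc[0])


def test_all_drugs_size_bounded_by_sum(small_sim, config):
    _, bundle, _ = small_sim
    drugs = sorted(set(bundle.catalog.index[
        bundle.catalog["is_index_candidate"]])
        & set(bundle.fills["drug_code"]))
    per_drug = {d: build_cohort(bundle, d, config)[0] for d in drugs}
    merged = build_all_drugs_cohort(per_drug, bundle.catalog)
    assert len(merged) <= sum(len(v) for v in per_drug.values())
    ids = {pid for v in per_drug.values() for pid in v["patient_id"]}
    assert set(merged["patient_id"]) == ids
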