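"""Generator checks: determinism, demographic calibration, the closed-form
survival of the refill process, and generator/pipeline consistency."""

from __future__ import annotations

import math

import pytest

from persistkit import (SimParams, generate, inject_violations,
                        persistence_probability, run_primary, validate_bundle,
                        write_claims)
from persistkit.drugs import DrugSimSpec

from conftest import single_drug_params


def test_same_seed_means_byte_identical_output(tmp_path, config):
    params = SimParams(n_patients=100, seed=1)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        bundle, _ = generate(params, config)
        write_claims(bundle, d)
    for f in d1.iterdir():
        assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name


def test_different_seeds_differ(config):
    b1, _ = generate(SimParams(n_patients=50, seed=1), config)
    b2, _ = generate(SimParams(n_patients=50, seed=2), config)
    assert not b1.fills.equals(b2.fills)


def test_generated_bundle_is_valid(small_sim):
    _, bundle, _ = small_sim
    assert validate_bundle(bundle).ok


def test_lookback_levodopa_present_for_every_patient(small_sim, config):
    _, bundle, truth = small_sim
    lev = set(bundle.catalog.index[bundle.catalog["class"] == "levodopa"])
    fills = bundle.fills[bundle.fills["drug_code"].isin(lev)]
    for row in truth.patients.itertuples():
        mine = fills[fills["patient_id"] == row.patient_id]["fill_date"]
        assert (mine == row.entry_day).any()
        assert ((mine >= row.entry_day - config.lookback_days)
                & (mine < row.entry_day)).any()


def test_no_index_fills_after_true_discontinuation(small_sim):
    _, bundle, truth = small_sim
    for row in truth.patients.itertuples():
        if row.true_persistent:
            continue
        drugs = row.index_drugs.split("+")
        mine = bundle.fills[(bundle.fills["patient_id"] == row.patient_id)
                            & (bundle.fills["drug_code"].isin(drugs))]
        rel = mine["fill_date"] - row.entry_day
        # the true discontinuation day is the end of the last covered period
        assert (rel[rel <= 365] < row.true_disc_day).all()


def test_demographic_calibration():
    params = SimParams(n_patients=5000, seed=9)
    bundle, truth = generate(params)
    entry_year = truth.patients.set_index("patient_id")["entry_day"]
    pats = bundle.patients.set_index("patient_id")
    cfg = bundle.config
    ages = entry_year.map(lambda d: cfg.offset_date(d).year) \
        - pats.loc[entry_year.index, "birth_year"]
    se_age = params.age_sd / math.sqrt(params.n_patients)
    assert abs(ages.mean() - params.age_mean) < 3 * se_age + 0.5  # int rounding
    male = (pats["sex"] == "male").mean()
    se_male = math.sqrt(params.male_frac * (1 - params.male_frac)
                        / params.n_patients)
    assert abs(male - params.male_frac) < 3 * se_male


@pytest.mark.parametrize("h", [0.0, 0.05, 0.2])
def test_closed_form_survival_of_monthly_process(h):
    """With 30-day cycles the refill process survives 11 refill decisions,
    so 1-year persistence is (1-h)^11; the recursion must agree."""
    assert persistence_probability(h, {30: 1.0}) == pytest.approx(
        (1 - h) ** 11)


def test_closed_form_with_mixed_cycles_brackets_pure_cycles():
    # longer cycles mean fewer refill decisions, hence higher persistence
    h = 0.07
    mixed = persistence_probability(h, {30: 0.5, 90: 0.5})
    assert persistence_probability(h, {90: 1.0}) >= mixed \
        >= persistence_probability(h, {30: 1.0})


def test_zero_hazard_perfect_refills_give_full_persistence(config):
    params = single_drug_params(80, 21, hazard=0.0)
    bundle, truth = generate(params, config)
    assert truth.patients["true_persistent"].all()
    report = run_primary(bundle, config)
    row = report.persistence_table.set_index("cohort").loc["all_drugs"]
    assert row["pct_persistent"] == 100.0


def test_pipeline_recovers_true_discontinuation_days(config):
    """With zero jitter and no hospitalizations the pipeline's per-patient
    discontinuation day equals the generating truth exactly."""
    params = single_drug_params(150, 22, hazard=0.08)
    bundle, truth = generate(params, config)
    report = run_primary(bundle, config)
    oc = report.per_patient["all_drugs"].set_index("patient_id")
    tr = truth.patients.set_index("patient_id")
    assert len(oc) == len(tr)
    joined = oc.join(tr, rsuffix="_true")
    assert (joined["persistent_1yr"] == joined["true_persistent"]).all()
    assert (joined["persistent_period_days"]
            == joined["true_persistent_days"]).all()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(n_patients=10, male_frac=1.5)
    with pytest.raises(ValueError):
        SimParams(n_patients=10, drug_menu={
            "rasagiline": DrugSimSpec(weight=1.0, hazard=-0.1)})
    with pytest.raises(ValueError):
        SimParams(n_patients=0)


def test_injection_manifest_is_disjoint_and_sized(small_sim):
    _, bundle, truth = small_sim
    corrupted, manifest = inject_violations(
        bundle, truth,
        {"age_under_40": 4, "no_pd_diagnosis": 4, "exclusion_dx:G23.1": 4},
        seed=3)
    all_ids = [pid for ids in manifest.values() for pid in ids]
    assert len(all_ids) == len(set(all_ids)) == 12
    assert validate_bundle(corrupted).ok
    # original untouched
    assert len(bundle.patients) == len(corrupted.patients)


def test_unknown_defect_rejected(small_sim):
    _, bundle, truth = small_sim
    with pytest.raises(ValueError):
        inject_violations(bundle, truth, {"bogus_defect": 1})
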