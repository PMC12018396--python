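from __future__ import annotations

import pandas as pd
import pytest

from persistkit import ClaimsBundle, SimParams, StudyConfig, generate
from persistkit.drugs import default_catalog


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


def single_drug_params(n, seed, hazard, jitter=0.0, **kw):
    """Generator settings under which the refill process's closed-form
    survival is exact: one drug, 30-day cycles, no jitter, no
    hospitalizations, no covariate effects on the hazard."""
    from persistkit.drugs import DrugSimSpec
    return SimParams(
        n_patients=n, seed=seed,
        drug_menu={"rasagiline": DrugSimSpec(weight=1.0, hazard=hazard)},
        refill_jitter_sd=jitter, p_late_refiller=0.0,
        p_hospitalization=0.0, p_combo_index=0.0,
        extra_anti_pd_probs={0: 1.0},
        hazard_mult_per_extra_anti_pd=1.0, hazard_mult_depression=1.0,
        **kw)


@pytest.fixture(scope="session")
def small_sim(config):
    """A shared mid-size synthetic cohort (default study conditions)."""
    params = SimParams(n_patients=250, seed=11)
    bundle, truth = generate(params, config)
    return params, bundle, truth


def make_bundle(config: StudyConfig,
                patients: list[dict],
                fills: list[tuple],
                diagnoses: list[tuple] = (),
                hospitalizations: list[tuple] = ()) -> ClaimsBundle:
    """Hand-built bundle for rule-level tests.

    ``patients``: dicts with patient_id and optional sex/birth_year/
    first_observed/last_observed (defaults: female, born 1945, observed over
    the whole extraction window).  ``fills``: (patient_id, drug_code, day,
    days_supplied[, discharge_flag[, setting]]).  ``diagnoses``:
    (patient_id, icd10, month_index).  ``hospitalizations``:
    (patient_id, admit_day, discharge_day).
    """
    pat_rows = []
    for p in patients:
        pat_rows.append({
            "patient_id": p["patient_id"],
            "sex": p.get("sex", "female"),
            "birth_year": p.get("birth_year", 1945),
            "first_observed": p.get("first_observed", 0),
            "last_observed": p.get("last_observed", config.n_days - 1),
        })
    fill_rows = []
    for f in fills:
        pid, code, day, supply, *rest = f
        fill_rows.append({
            "patient_id": pid, "drug_code": code, "fill_date": day,
            "days_supplied": supply,
            "discharge_flag": rest[0] if rest else False,
            "setting": rest[1] if len(rest) > 1 else "outpatient",
        })
    return ClaimsBundle(
        patients=pd.DataFrame(pat_rows),
        fills=pd.DataFrame(fill_rows, columns=[
            "patient_id", "drug_code", "fill_date", "days_supplied",
            "discharge_flag", "setting"]),
        diagnoses=pd.DataFrame(list(diagnoses), columns=[
            "patient_id", "icd10", "year_month"]),
        hospitalizations=pd.DataFrame(list(hospitalizations), columns=[
            "patient_id", "admit_date", "discharge_date"]),
        catalog=default_catalog(),
        config=config,
    ).canonical()


def qualifying_fixture(config: StudyConfig, pid: str, entry: int,
                       drug: str = "rasagiline",
                       n_refills: int = 12) -> tuple[list, list, list]:
    """Patient rows that satisfy every inclusion criterion: G20 in the entry
    month, monthly levodopa through look-back and follow-up, and a monthly
    index-drug schedule from entry."""
    patients = [{"patient_id": pid}]
    fills = []
    for k in range(-6, 13):
        fills.append((pid, "levodopa_300", entry + 30 * k, 30))
    for k in range(n_refills + 1):
        fills.append((pid, drug, entry + 30 * k, 30))
    diagnoses = [(pid, "G20", config.month_index_of_day(entry))]
    return patients, fills, diagnoses
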