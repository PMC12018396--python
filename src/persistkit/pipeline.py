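"""End-to-end orchestration: cohorts -> exposure -> persistence ->
adherence -> statistics, with report tables, sensitivity variants and
subgroup stratification.

The primary analysis reports, per drug cohort and for the deduplicated
all-drugs cohort: the 1-year persistence rate with a five-number summary of
the persistent treatment period; the share of adherence-eligible patients
(>= 2 fills) with PDC >= 80% plus a five-number PDC summary; Kaplan-Meier
discontinuation curves; and, in the all-drugs cohort, modified-Poisson risk
ratios for persistence and for good adherence.

Sensitivity variants change exactly one element of the primary analysis:
``gap15`` (15-day gap threshold), ``full_washout`` (washout from the start
of data extraction), ``pdc_followup`` (PDC denominator anchored in the
follow-up window) and ``mpr`` (MPR in place of PDC).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adherence import AdherenceResult, assess_adherence
from .cohort import (AttritionTable, build_all_drugs_cohort, build_cohort)
from .config import StudyConfig
from .exposure import (assess_persistence, impute_discharge_days,
                       intersect_covered_periods, merge_periods,
                       fill_periods)
from .io_model import ClaimsBundle
from .stats import (KMCurve, RRModelFit, fit_modified_poisson,
                    kaplan_meier, summarize_quartiles)


class SensitivityVariant(str, enum.Enum):
    gap15 = "gap15"
    full_washout = "full_washout"
    pdc_followup = "pdc_followup"
    mpr = "mpr"


@dataclass
class AnalysisReport:
    """All tables and fits of one analysis run."""

    persistence_table: pd.DataFrame
    adherence_table: pd.DataFrame
    per_patient: dict[str, pd.DataFrame]
    km: dict[str, KMCurve]
    fits: dict[str, RRModelFit]
    attrition: dict[str, AttritionTable]
    config: StudyConfig
    adherence_measure: str = "pdc_persistent"
    metadata: dict = field(default_factory=dict)


def _patient_outcomes(bundle: ClaimsBundle, members: pd.DataFrame,
                      config: StudyConfig,
                      adherence_measure: str = "pdc_persistent"
                      ) -> pd.DataFrame:
    """Per-patient persistence and adherence for one cohort's members."""
    cfg = config
    fu = cfg.followup_days
    fills_by = {pid: grp for pid, grp
                in bundle.fills.groupby("patient_id", sort=False)}
    rows = []
    for m in members.itertuples():
        entry = m.entry_day
        drugs = m.index_drugs
        pf = fills_by[m.patient_id]
        mine = pf[pf["drug_code"].isin(drugs) & (pf["fill_date"] >= entry)]
        mine = impute_discharge_days(mine, cfg.discharge_impute_cap_days)

        per_drug_periods = []
        per_drug_dates: list[set[int]] = []
        supply_by_date: dict[int, int] = {}
        n_imputed = 0
        for drug in drugs:
            df = mine[mine["drug_code"] == drug]
            n_imputed += int(df["imputed"].sum())
            by_date = df.groupby("fill_date")["days_supplied"].max()
            rel = [int(d - entry) for d in by_date.index]
            supp = [int(s) for s in by_date.to_numpy()]
            per_drug_periods.append(fill_periods(rel, supp, fu))
            per_drug_dates.append(set(rel))
            for d, s in zip(rel, supp):
                supply_by_date[d] = min(supply_by_date.get(d, s), s)

        combined = intersect_covered_periods(per_drug_periods)
        pers = assess_persistence(merge_periods(combined), fu,
                                  cfg.gap_threshold_days)

        combo_dates = sorted(set.intersection(*per_drug_dates))
        combo_supplies = [supply_by_date[d] for d in combo_dates]
        adh: AdherenceResult = assess_adherence(
            combo_dates, combo_supplies, pers.persistent_period_days,
            fu, cfg.pdc_good_threshold,
            combo_periods=combined if len(drugs) > 1 else None)

        rows.append({
            "patient_id": m.patient_id,
            "index_drugs": drugs,
            "persistent_1yr": pers.persistent_1yr,
            "discontinuation_day": pers.discontinuation_day,
            "persistent_period_days": pers.persistent_period_days,
            "censored": pers.censored,
            "eligible": adh.eligible,
            "pdc_persistent": adh.pdc_persistent,
            "pdc_followup": adh.pdc_followup,
            "mpr_followup": adh.mpr_followup,
            "good_adherence": adh.good_adherence,
            "n_imputed_fills": n_imputed,
        })
    cols = ["patient_id", "index_drugs", "persistent_1yr",
            "discontinuation_day", "persistent_period_days", "censored",
            "eligible", "pdc_persistent", "pdc_followup", "mpr_followup",
            "good_adherence", "n_imputed_fills"]
    out = pd.DataFrame(rows, columns=cols)
    if adherence_measure != "pdc_persistent" and len(out):
        # re-derive the good-adherence classification from the variant
        # measure; eligibility and the >= threshold rule are unchanged
        alt = out[adherence_measure]
        out["good_adherence"] = alt.map(
            lambda v: None if pd.isna(v) else v >= cfg.pdc_good_threshold)
    return out


def _persistence_row(name: str, outcomes: pd.DataFrame) -> dict:
    n = len(outcomes)
    n_pers = int(outcomes["persistent_1yr"].sum()) if n else 0
    row = {"cohort": name, "n": n, "n_persistent": n_pers,
           "pct_persistent": round(100.0 * n_pers / n, 1) if n else np.nan}
    if n:
        s = summarize_quartiles(outcomes["persistent_period_days"])
        row.update(zip(("min", "q1", "median", "q3", "max"), s.as_tuple()))
    else:
        row.update({k: np.nan for k in ("min", "q1", "median", "q3", "max")})
    return row


def _adherence_row(name: str, outcomes: pd.DataFrame, measure: str) -> dict:
    vals = outcomes[measure].dropna() if len(outcomes) else pd.Series(dtype=float)
    n = len(vals)
    good = outcomes["good_adherence"].dropna() if len(outcomes) \
        else pd.Series(dtype=bool)
    n_good = int(good.astype(bool).sum())
    row = {"cohort": name, "n": n, "n_good": n_good,
           "pct_good": round(100.0 * n_good / n, 1) if n else np.nan}
    if n:
        s = summarize_quartiles(100.0 * vals)
        row.update(zip(("min", "q1", "median", "q3", "max"),
                       (round(v, 1) for v in s.as_tuple())))
    else:
        row.update({k: np.nan for k in ("min", "q1", "median", "q3", "max")})
    return row


_MODEL_COVARIATES = [
    "age", "male", "n_anti_pd", "n_concomitant", "levodopa_dose_100",
    "led_excl_index_100", "hosp_rx", "co_depression", "co_dementia",
    "co_liver_renal",
]


def _design_matrix(members: pd.DataFrame) -> pd.DataFrame:
    X = members.set_index("patient_id").copy()
    X["levodopa_dose_100"] = X["levodopa_dose"] / 100.0
    X["led_excl_index_100"] = X["led_excl_index"] / 100.0
    X["co_liver_renal"] = ((X.get("co_liver_failure", 0)
                            | X.get("co_renal_failure", 0))).astype(int)
    return X[[c for c in _MODEL_COVARIATES if c in X.columns]]


def _fit_models(members: pd.DataFrame, outcomes: pd.DataFrame
                ) -> dict[str, RRModelFit]:
    fits: dict[str, RRModelFit] = {}
    if len(members) < 50:
        return fits
    X = _design_matrix(members)
    oc = outcomes.set_index("patient_id")
    y_pers = oc.loc[X.index, "persistent_1yr"].astype(int)
    try:
        fits["persistence"] = fit_modified_poisson(X, y_pers)
    except ValueError:
        pass
    good = oc.loc[X.index, "good_adherence"]
    defined = good.notna()
    if defined.sum() >= 50 and good[defined].astype(bool).nunique() == 2:
        fits["adherence"] = fit_modified_poisson(
            X[defined], good[defined].astype(int))
    return fits


def run_primary(bundle: ClaimsBundle, config: StudyConfig | None = None,
                adherence_measure: str = "pdc_persistent",
                drugs: list[str] | None = None) -> AnalysisReport:
    """Run the full analysis on a claims bundle.

    ``adherence_measure`` selects the adherence column used for the good-
    adherence classification and summary: ``pdc_persistent`` (primary),
    ``pdc_followup`` or ``mpr_followup``.
    """
    cfg = config or bundle.config
    if drugs is None:
        candidates = set(bundle.catalog.index[
            bundle.catalog["is_index_candidate"]])
        drugs = sorted(candidates & set(bundle.fills["drug_code"]))

    per_drug_members: dict[str, pd.DataFrame] = {}
    attrition: dict[str, AttritionTable] = {}
    for drug in drugs:
        members, att = build_cohort(bundle, drug, cfg)
        per_drug_members[drug] = members
        attrition[drug] = att
    all_members = build_all_drugs_cohort(per_drug_members, bundle.catalog)

    cohorts = {"all_drugs": all_members, **per_drug_members}
    per_patient: dict[str, pd.DataFrame] = {}
    km: dict[str, KMCurve] = {}
    pers_rows, adh_rows = [], []
    for name, members in cohorts.items():
        outcomes = _patient_outcomes(bundle, members, cfg, adherence_measure)
        per_patient[name] = outcomes
        pers_rows.append(_persistence_row(name, outcomes))
        adh_rows.append(_adherence_row(name, outcomes, adherence_measure))
        if len(outcomes):
            km[name] = kaplan_meier(outcomes["persistent_period_days"],
                                    ~outcomes["persistent_1yr"])

    fits = _fit_models(all_members, per_patient["all_drugs"])

    from . import __version__
    return AnalysisReport(
        persistence_table=pd.DataFrame(pers_rows),
        adherence_table=pd.DataFrame(adh_rows),
        per_patient=per_patient,
        km=km,
        fits=fits,
        attrition=attrition,
        config=cfg,
        adherence_measure=adherence_measure,
        metadata={"config_hash": cfg.content_hash(),
                  "version": __version__,
                  "n_drug_cohorts": len(drugs)},
    )


def sensitivity_config(config: StudyConfig, variant: SensitivityVariant
                       ) -> tuple[StudyConfig, str]:
    """Resolved (config, adherence_measure) for a sensitivity variant.

    Exactly one element differs from the primary analysis.
    """
    cfg = config.model_copy()
    measure = "pdc_persistent"
    if variant is SensitivityVariant.gap15:
        cfg = config.model_copy(update={"gap_threshold_days": 15})
    elif variant is SensitivityVariant.full_washout:
        cfg = config.model_copy(update={"washout_from_extraction_start": True})
    elif variant is SensitivityVariant.pdc_followup:
        measure = "pdc_followup"
    elif variant is SensitivityVariant.mpr:
        measure = "mpr_followup"
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {variant!r}")
    n_deltas = sum(
        getattr(cfg, f) != getattr(config, f)
        for f in type(config).model_fields
    ) + (measure != "pdc_persistent")
    assert n_deltas == 1, "sensitivity variant must change exactly one thing"
    return cfg, measure


def run_sensitivity(bundle: ClaimsBundle, config: StudyConfig | None,
                    variant: SensitivityVariant | str,
                    drugs: list[str] | None = None) -> AnalysisReport:
    """Re-run the analysis with exactly one variant delta applied."""
    variant = SensitivityVariant(variant)
    cfg, measure = sensitivity_config(config or bundle.config, variant)
    report = run_primary(bundle, cfg, adherence_measure=measure, drugs=drugs)
    report.metadata["sensitivity"] = variant.value
    return report


#: Stratifiers for subgroup analyses: covariate -> labelling function.
_SUBGROUP_RULES = {
    "sex": lambda m: m["sex"],
    "age_band": lambda m: np.where(m["age"] >= 75, "age>=75", "age<75"),
    "levodopa_dose": lambda m: np.where(
        m["levodopa_dose"] >= 400, "levodopa>=400mg", "levodopa<400mg"),
    "n_anti_pd": lambda m: np.where(
        m["n_anti_pd"] >= 2, "anti_pd>=2", "anti_pd=1"),
    "hosp_rx": lambda m: np.where(
        m["hosp_rx"] == 1, "hospital_rx", "no_hospital_rx"),
    "co_depression": lambda m: np.where(
        m["co_depression"] == 1, "depression", "no_depression"),
    "co_dementia": lambda m: np.where(
        m["co_dementia"] == 1, "dementia", "no_dementia"),
}


def run_subgroups(bundle: ClaimsBundle, config: StudyConfig | None,
                  by: list[str]) -> dict[str, pd.DataFrame]:
    """Stratified persistence/adherence tables for the all-drugs cohort.

    For each requested covariate the strata partition the cohort; returns a
    {covariate: table} mapping with one persistence+adherence row per
    stratum.
    """
    cfg = config or bundle.config
    candidates = set(bundle.catalog.index[bundle.catalog["is_index_candidate"]])
    drugs = sorted(candidates & set(bundle.fills["drug_code"]))
    per_drug = {d: build_cohort(bundle, d, cfg)[0] for d in drugs}
    members = build_all_drugs_cohort(per_drug, bundle.catalog)

    out: dict[str, pd.DataFrame] = {}
    for cov in by:
        if cov not in _SUBGROUP_RULES:
            raise KeyError(f"unknown subgroup covariate {cov!r}")
        labels = pd.Series(_SUBGROUP_RULES[cov](members),
                           index=members.index, name="stratum")
        rows = []
        for stratum, idx in labels.groupby(labels).groups.items():
            sub = members.loc[idx]
            outcomes = _patient_outcomes(bundle, sub, cfg)
            prow = _persistence_row(str(stratum), outcomes)
            arow = _adherence_row(str(stratum), outcomes, "pdc_persistent")
            rows.append({**prow,
                         **{f"adh_{k}": v for k, v in arow.items()
                            if k != "cohort"}})
        out[cov] = pd.DataFrame(rows)
    return out


def write_report(report: AnalysisReport, out_dir) -> None:
    """Persist the report tables as CSV under ``out_dir``."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.persistence_table.to_csv(out / "persistence_table.csv",
                                    index=False)
    report.adherence_table.to_csv(out / "adherence_table.csv", index=False)
    for name, fit in report.fits.items():
        fit.table.to_csv(out / f"model_{name}.csv", index=False)
    for name, curve in report.km.items():
        curve.to_frame().to_csv(out / f"km_{name}.csv", index=False)
    for name, att in report.attrition.items():
        att.to_frame().to_csv(out / f"attrition_{name}.csv", index=False)
    import json
    (out / "run_metadata.json").write_text(
        json.dumps(report.metadata, indent=2, default=str))
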