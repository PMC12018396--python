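"""Synthetic claims generator with known ground truth.

Emulates an elderly Japanese claims population on a levodopa backbone who
newly add one (occasionally two) adjunct anti-parkinson drugs at a cohort
entry date: monthly-ish refill cycles with integer jitter, an absorbing
per-refill-cycle discontinuation hazard, look-back levodopa use, ICD-10
diagnoses (G20 in the entry month, comorbidities as independent Bernoulli
prevalences), ongoing concomitant drugs by ATC second level, hospitalization
episodes whose post-discharge fill may be registered as a 1-day supply, and
an independent severity-proxy flag.

The discontinuation process has a closed form: a patient refills at each
supply exhaustion (plus jitter) and at every refill decision stops for good
with probability ``hazard``.  With 30-day cycles, zero jitter and no
hospitalizations, 1-year persistence under the 30-day-gap rule equals
``(1 - hazard)**11`` — surviving the 11 refill decisions whose preceding
coverage ends on or before day 335; the general cycle-mix form is computed
by :func:`persistence_probability`.  Every patient's true discontinuation
day, intended schedule and adherence level are recorded so each downstream
stage can be checked against the generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import StudyConfig
from .drugs import (DEFAULT_LEVODOPA_MIX, DrugSimSpec, default_catalog,
                    default_drug_menu)
from .io_model import ClaimsBundle

DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "depression": 0.143,
    "dementia": 0.194,
    "liver_failure": 0.156,
    "renal_failure": 0.056,
}

_COMORBIDITY_CODES: dict[str, str] = {
    "depression": "F32.9",
    "dementia": "F03",
    "liver_failure": "K72.9",
    "renal_failure": "N18.9",
}


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions emulated.

    Demographics follow the published profile of elderly Japanese
    Parkinson's disease patients (age 77.2 +/- 7.0 truncated at 40, 43.6%
    male); the drug menu's weights and hazards span the observed range of
    adjunct persistence.  All probabilities must lie in [0, 1] and hazards
    must be nonnegative; the seed fully determines the output.
    """

    n_patients: int = 1000
    seed: int = 0
    age_mean: float = 77.2
    age_sd: float = 7.0
    age_min: float = 40.0
    male_frac: float = 0.436
    drug_menu: dict[str, DrugSimSpec] = field(default_factory=default_drug_menu)
    levodopa_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVODOPA_MIX))
    refill_jitter_sd: float = 3.0
    #: Fraction of patients with habitually late refills, and the range
    #: their mean per-cycle delay (days) is drawn from — the generator's
    #: model of heterogeneous adherence behavior.
    p_late_refiller: float = 0.08
    late_delay_range: tuple[float, float] = (4.0, 12.0)
    p_hospitalization: float = 0.15
    p_discharge_1day: float = 0.7
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES))
    n_concomitant_mean: float = 5.2
    #: Distribution of the number of *other* ongoing anti-PD adjuncts
    #: (besides levodopa and the new index drug); these have look-back use,
    #: so they are never new users of those drugs.
    extra_anti_pd_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.47, 1: 0.28, 2: 0.17, 3: 0.08})
    #: Multiplicative effect of each extra anti-PD drug (and of depression)
    #: on the per-cycle discontinuation hazard: polypharmacy and depression
    #: shorten persistence.
    hazard_mult_per_extra_anti_pd: float = 1.15
    hazard_mult_depression: float = 1.10
    p_combo_index: float = 0.03
    severity_flag_prev: float = 0.618
    lookback_levodopa: bool = True

    def __post_init__(self) -> None:
        probs = [self.male_frac, self.p_late_refiller,
                 self.p_hospitalization, self.p_discharge_1day,
                 self.p_combo_index, self.severity_flag_prev,
                 *self.comorbidity_prevalences.values(),
                 *self.extra_anti_pd_probs.values(),
                 *self.levodopa_mix.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        for code, spec in self.drug_menu.items():
            if spec.hazard < 0:
                raise ValueError(f"negative hazard for {code}")
            if any(not (0.0 <= p <= 1.0) for p in spec.cycle_probs.values()):
                raise ValueError(f"bad cycle probabilities for {code}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """Per-patient generating-process truth emitted alongside the bundle."""

    patients: pd.DataFrame
    params: SimParams

    def expected_persistence(self) -> float:
        """Mean closed-form 1-year persistence probability of the cohort."""
        return float(self.patients["persistence_prob"].mean())


def persistence_probability(hazard: float, cycle_probs: dict[int, float],
                            followup_days: int = 365,
                            gap_threshold_days: int = 30) -> float:
    """Closed-form 1-year persistence of the refill process.

    A refill decision occurs whenever coverage ends on or before
    ``followup - gap_threshold`` (a later end leaves a terminal gap shorter
    than the threshold); each decision continues with probability
    ``1 - hazard``.  Computed by recursion over the coverage end; for pure
    30-day cycles this reduces to ``(1 - hazard)**11`` under the defaults.
    """
    last_decision_day = followup_days - gap_threshold_days
    items = tuple(sorted(cycle_probs.items()))

    @lru_cache(maxsize=None)
    def persist_from(cov_end: int) -> float:
        if cov_end > last_decision_day:
            return 1.0
        return (1.0 - hazard) * sum(
            p * persist_from(cov_end + length) for length, p in items)

    return float(sum(p * persist_from(length) for length, p in items))


def _truth_outcomes(rel_dates: list[int], supplies: list[int],
                    followup: int = 365, gap: int = 30
                    ) -> tuple[bool, int, float]:
    """Day-vector scan of the true schedule: (persistent, persistent-period
    days, true PDC).  Coverage on day d comes from the most recent fill only
    (no stockpiling)."""
    covered = np.zeros(followup, dtype=bool)
    for i, (d, s) in enumerate(zip(rel_dates, supplies)):
        end = min(d + s, followup)
        if i + 1 < len(rel_dates):
            end = min(end, rel_dates[i + 1])
        covered[d:max(end, d)] = True
    # first uncovered run of >= gap days ends the persistent period
    disc_day = None
    run_start = None
    for day in range(followup + 1):
        if day < followup and not covered[day]:
            if run_start is None:
                run_start = day
        else:
            if run_start is not None and (day - run_start) >= gap:
                disc_day = run_start
                break
            if day < followup and covered[day]:
                run_start = None
    if run_start is not None and disc_day is None \
            and followup - run_start >= gap:
        disc_day = run_start
    persistent = disc_day is None
    period = followup if persistent else disc_day

    in_fu = [d for d in rel_dates if d < followup]
    pdc = math.nan
    if len(in_fu) >= 2 and in_fu[-1] > 0:
        last = in_fu[-1]
        pdc = float(covered[:last].sum()) / last
    return persistent, period, pdc


def generate(params: SimParams,
             config: StudyConfig | None = None
             ) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle plus ground truth; seed-deterministic."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(params.seed)
    catalog = default_catalog()
    entry_lo, entry_hi = cfg.entry_window
    n_days = cfg.n_days
    fu = cfg.followup_days
    menu_codes = list(params.drug_menu)
    menu_w = np.array([params.drug_menu[c].weight for c in menu_codes])
    menu_w = menu_w / menu_w.sum()
    lev_codes = list(params.levodopa_mix)
    lev_w = np.array(list(params.levodopa_mix.values()))
    lev_w = lev_w / lev_w.sum()
    from .drugs import CONCOMITANT_CODES
    extra_ks = list(params.extra_anti_pd_probs)
    extra_w = np.array(list(params.extra_anti_pd_probs.values()))
    extra_w = extra_w / extra_w.sum()

    a = (params.age_min - params.age_mean) / params.age_sd
    ages = truncnorm.rvs(a, np.inf, loc=params.age_mean,
                         scale=params.age_sd, size=params.n_patients,
                         random_state=rng)

    pat_rows, fill_rows, dx_rows, hosp_rows, truth_rows = [], [], [], [], []

    for i in range(params.n_patients):
        pid = f"P{i:06d}"
        entry = int(rng.integers(entry_lo, entry_hi + 1))
        entry_date = cfg.offset_date(entry)
        age = int(round(ages[i]))
        sex = "male" if rng.random() < params.male_frac else "female"
        pat_rows.append((pid, sex, entry_date.year - age, 0, n_days - 1))

        entry_month = cfg.month_index_of_day(entry)
        # PD diagnosis: entry month plus an earlier month on record
        dx_rows.append((pid, "G20", entry_month))
        dx_rows.append((pid, "G20",
                        max(0, entry_month - int(rng.integers(1, 7)))))

        comorbid: dict[str, bool] = {}
        for name, prev in params.comorbidity_prevalences.items():
            has = rng.random() < prev
            comorbid[name] = has
            if has:
                dx_rows.append((pid, _COMORBIDITY_CODES[name],
                                max(0, entry_month - int(rng.integers(0, 12)))))

        # levodopa backbone: monthly fills through look-back and follow-up
        lev_code = str(rng.choice(lev_codes, p=lev_w))
        k_start = -6 if params.lookback_levodopa else 0
        for k in range(k_start, 13):
            day = entry + 30 * k
            if 0 <= day < n_days:
                fill_rows.append((pid, lev_code, day, 30, False, "outpatient"))

        # ongoing extra anti-PD adjuncts (look-back use -> not new users)
        n_extra = int(rng.choice(extra_ks, p=extra_w))
        others = [c for c in menu_codes]
        index_code = str(rng.choice(menu_codes, p=menu_w))
        others.remove(index_code)
        extra_codes = list(rng.choice(others, size=min(n_extra, len(others)),
                                      replace=False))
        index_drugs = [index_code]
        if rng.random() < params.p_combo_index and extra_codes:
            # one "extra" drug is instead newly started at entry too
            index_drugs.append(str(extra_codes.pop()))
        # fills start a year before entry so a washout window anchored at
        # any in-window fill always finds prior use: genuinely ongoing drugs
        for code in extra_codes:
            for k in range(-12, 13):
                day = entry + 30 * k
                if 0 <= day < n_days:
                    fill_rows.append((pid, code, day, 30, False, "outpatient"))

        # concomitant non-anti-PD drugs, ongoing over look-back + entry
        n_con = min(int(rng.poisson(params.n_concomitant_mean)),
                    len(CONCOMITANT_CODES))
        con_codes = rng.choice(CONCOMITANT_CODES, size=n_con, replace=False)
        for code in con_codes:
            for k in (-2, -1, 0):
                day = entry + 30 * k
                if 0 <= day < n_days:
                    fill_rows.append((pid, str(code), day, 30, False,
                                      "outpatient"))
        if rng.random() < 0.1:
            # an occasional short course below the 14-day concomitance bar
            spare = [c for c in CONCOMITANT_CODES if c not in set(con_codes)]
            if spare:
                fill_rows.append((pid, str(rng.choice(spare)),
                                  int(entry - rng.integers(0, 90)), 7,
                                  False, "outpatient"))

        # index refill process (shared schedule for combination starts)
        spec = params.drug_menu[index_code]
        hazard = spec.hazard
        hazard *= params.hazard_mult_per_extra_anti_pd ** len(extra_codes)
        if comorbid.get("depression"):
            hazard *= params.hazard_mult_depression
        hazard = min(hazard, 0.95)
        delay_mean = 0.0
        late = rng.random() < params.p_late_refiller
        if late:
            delay_mean = float(rng.uniform(*params.late_delay_range))
        cyc_lens = list(spec.cycle_probs)
        cyc_w = np.array(list(spec.cycle_probs.values()))
        cyc_w = cyc_w / cyc_w.sum()

        dates: list[int] = []
        true_supplies: list[int] = []
        t = entry
        dropout_cycle = -1
        cycle = 0
        while t - entry <= fu and t < n_days:
            cycle += 1
            supply = int(rng.choice(cyc_lens, p=cyc_w))
            dates.append(t)
            true_supplies.append(supply)
            if rng.random() < hazard:
                dropout_cycle = cycle
                break
            jitter = int(round(rng.normal(delay_mean,
                                          params.refill_jitter_sd)))
            jitter = max(jitter, -min(7, supply - 1))
            t = t + supply + jitter

        # hospitalization: displace the in-stay refill to the discharge day
        recorded = list(true_supplies)
        discharge_idx = -1
        if rng.random() < params.p_hospitalization:
            admit = entry + int(rng.integers(30, 300))
            stay = int(rng.integers(5, 22))
            discharge = admit + stay
            hosp_rows.append((pid, admit, discharge))
            for j, d in enumerate(dates):
                if admit <= d < discharge:
                    delta = discharge - d
                    for k in range(j, len(dates)):
                        dates[k] += delta
                    discharge_idx = j
                    if rng.random() < params.p_discharge_1day:
                        recorded[j] = 1
                    break

        for j, (d, s) in enumerate(zip(dates, recorded)):
            if d >= n_days:
                continue
            flag = j == discharge_idx
            for code in index_drugs:
                fill_rows.append((pid, code, d, s, flag, "outpatient"))

        rel = [d - entry for d in dates]
        persistent, period, pdc = _truth_outcomes(rel, true_supplies, fu,
                                                  cfg.gap_threshold_days)
        truth_rows.append({
            "patient_id": pid,
            "index_drugs": "+".join(sorted(index_drugs)),
            "entry_day": entry,
            "hazard": hazard,
            "persistence_prob": persistence_probability(
                hazard, spec.cycle_probs, fu, cfg.gap_threshold_days),
            "n_index_fills": len(dates),
            "dropout_cycle": dropout_cycle,
            "true_persistent": persistent,
            "true_persistent_days": period,
            "true_disc_day": -1 if persistent else period,
            "true_pdc": pdc,
            "true_good_adherence": (pdc >= cfg.pdc_good_threshold)
            if not math.isnan(pdc) else None,
            "late_refiller": late,
            "severity_flag": bool(rng.random() < params.severity_flag_prev),
            **{f"true_{k}": v for k, v in comorbid.items()},
            "n_extra_anti_pd": len(extra_codes),
        })

    bundle = ClaimsBundle(
        patients=pd.DataFrame(pat_rows, columns=[
            "patient_id", "sex", "birth_year", "first_observed",
            "last_observed"]),
        fills=pd.DataFrame(fill_rows, columns=[
            "patient_id", "drug_code", "fill_date", "days_supplied",
            "discharge_flag", "setting"]),
        diagnoses=pd.DataFrame(dx_rows, columns=[
            "patient_id", "icd10", "year_month"]),
        hospitalizations=pd.DataFrame(hosp_rows, columns=[
            "patient_id", "admit_date", "discharge_date"]),
        catalog=catalog,
        config=cfg,
    ).canonical()
    truth = GroundTruth(patients=pd.DataFrame(truth_rows), params=params)
    return bundle, truth


# ---------------------------------------------------------------------------
# controlled defects for negative-control fixtures

_DEFECT_NAMES = (
    "age_under_40", "prior_index_use", "no_lookback_levodopa",
    "no_entry_levodopa", "no_pd_diagnosis", "short_enrollment",
)  # plus "exclusion_dx:<CODE>"


def inject_violations(bundle: ClaimsBundle, truth: GroundTruth,
                      defects: dict[str, int], seed: int = 0
                      ) -> tuple[ClaimsBundle, dict[str, frozenset]]:
    """Inject controlled eligibility defects into a copy of the bundle.

    ``defects`` maps a defect name to the number of patients to corrupt;
    patients are drawn without replacement across all defects, so each
    manifest entry fails exactly its own criterion.  Supported names:
    ``age_under_40``, ``prior_index_use``, ``no_lookback_levodopa``,
    ``no_entry_levodopa``, ``no_pd_diagnosis``, ``short_enrollment`` and
    ``exclusion_dx:<ICD-10 code>``.  Returns the corrupted copy and the
    manifest of patient ids per defect.
    """
    rng = np.random.default_rng(seed)
    out = bundle.copy()
    cfg = out.config
    tp = truth.patients.set_index("patient_id")
    lev_codes = set(out.catalog.index[out.catalog["class"] == "levodopa"])
    entry_lo, _ = cfg.entry_window

    available = list(tp.index)
    rng.shuffle(available)
    manifest: dict[str, frozenset] = {}

    def take(n: int, eligible=None) -> list[str]:
        pool = available if eligible is None else \
            [p for p in available if eligible(p)]
        if len(pool) < n:
            raise ValueError("not enough uncorrupted patients for defect")
        chosen = pool[:n]
        for p in chosen:
            available.remove(p)
        return chosen

    for name, n in defects.items():
        base = name.split(":")[0]
        if base not in _DEFECT_NAMES and base != "exclusion_dx":
            raise ValueError(f"unknown defect {name!r}")
        if base == "age_under_40":
            pids = take(n)
            for pid in pids:
                year = cfg.offset_date(int(tp.loc[pid, "entry_day"])).year
                out.patients.loc[
                    out.patients["patient_id"] == pid, "birth_year"] = year - 30
        elif base == "prior_index_use":
            # the injected fill must precede the entry window yet fall inside
            # the 180-day washout, so only early entrants are eligible
            pids = take(n, lambda p: int(tp.loc[p, "entry_day"]) - entry_lo
                        <= cfg.lookback_days - 20)
            extra = []
            for pid in pids:
                drug = tp.loc[pid, "index_drugs"].split("+")[0]
                extra.append((pid, drug, entry_lo - 10, 30, False,
                              "outpatient"))
            out.fills = pd.concat([out.fills, pd.DataFrame(
                extra, columns=out.fills.columns)], ignore_index=True)
        elif base == "exclusion_dx":
            code = name.split(":", 1)[1]
            pids = take(n)
            extra = [(pid, code, cfg.month_index_of_day(
                int(tp.loc[pid, "entry_day"]))) for pid in pids]
            out.diagnoses = pd.concat([out.diagnoses, pd.DataFrame(
                extra, columns=out.diagnoses.columns)], ignore_index=True)
        elif base == "no_lookback_levodopa":
            pids = take(n)
            for pid in pids:
                entry = int(tp.loc[pid, "entry_day"])
                f = out.fills
                drop = ((f["patient_id"] == pid)
                        & f["drug_code"].isin(lev_codes)
                        & (f["fill_date"] >= entry - cfg.lookback_days)
                        & (f["fill_date"] < entry))
                out.fills = f[~drop]
        elif base == "no_entry_levodopa":
            pids = take(n)
            for pid in pids:
                entry = int(tp.loc[pid, "entry_day"])
                f = out.fills
                drop = ((f["patient_id"] == pid)
                        & f["drug_code"].isin(lev_codes)
                        & (f["fill_date"] == entry))
                out.fills = f[~drop]
        elif base == "no_pd_diagnosis":
            pids = take(n)
            for pid in pids:
                month = cfg.month_index_of_day(int(tp.loc[pid, "entry_day"]))
                d = out.diagnoses
                drop = ((d["patient_id"] == pid) & (d["icd10"] == cfg.pd_code)
                        & (d["year_month"] == month))
                out.diagnoses = d[~drop]
        elif base == "short_enrollment":
            pids = take(n)
            for pid in pids:
                entry = int(tp.loc[pid, "entry_day"])
                cutoff = entry + 100
                out.patients.loc[
                    out.patients["patient_id"] == pid,
                    "last_observed"] = cutoff
                f = out.fills
                out.fills = f[~((f["patient_id"] == pid)
                                & (f["fill_date"] > cutoff))]
        manifest[name] = frozenset(pids)

    return out.canonical(), manifest
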