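"""New-user cohort construction with attrition accounting.

A patient enters a drug-specific cohort at the first fill of that index drug
inside the entry window, provided (in this order):

1. a definitive Parkinson's disease diagnosis (G20) in the same calendar
   month as the entry date;
2. oral levodopa filled both on the entry date and within the 180-day
   look-back window;
3. no fill of the index drug during the washout window (new-user design);
4. age >= 40 at entry;

and neither exclusion: (a) enrollment not covering the look-back plus the
365-day follow-up, (b) any diagnosis of a disease to be differentiated from
Parkinson's disease over the extraction window.

The washout window is the 180-day look-back by default; a sensitivity
variant extends it back to the start of data extraction.  The all-drugs
cohort deduplicates patients qualifying in several drug cohorts to the
earliest entry date; several index drugs newly filled on that same date form
a combination index drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import StudyConfig, comorbidity_flags, match_any_prefix
from .io_model import ClaimsBundle


def _by_patient(df: pd.DataFrame) -> dict:
    """{patient_id: sub-frame} for per-patient loops."""
    return {pid: grp for pid, grp in df.groupby("patient_id", sort=False)}

#: Shared baseline columns that must agree when drug-specific members of the
#: same patient are merged into the all-drugs cohort.
_SHARED_COVARIATES = [
    "entry_day", "age", "sex", "male", "n_anti_pd", "n_concomitant",
    "levodopa_dose", "led_n04_total", "hosp_rx",
]


@dataclass
class AttritionRow:
    label: str
    n_before: int
    n_excluded: int
    n_after: int
    excluded_ids: frozenset = field(default_factory=frozenset)


@dataclass
class AttritionTable:
    rows: list[AttritionRow] = field(default_factory=list)

    def add(self, label: str, before: set, excluded: set) -> set:
        after = before - excluded
        self.rows.append(AttritionRow(
            label, len(before), len(excluded), len(after),
            frozenset(excluded)))
        return after

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.n_before, r.n_excluded, r.n_after)
             for r in self.rows],
            columns=["criterion", "n_before", "n_excluded", "n_after"],
        )

    def excluded_by(self, label: str) -> frozenset:
        for r in self.rows:
            if r.label == label:
                return r.excluded_ids
        raise KeyError(label)

    def telescopes(self) -> bool:
        return all(
            r.n_after == r.n_before - r.n_excluded and
            (i == 0 or r.n_before == self.rows[i - 1].n_after)
            for i, r in enumerate(self.rows)
        )


def find_index_events(bundle: ClaimsBundle, drug_code: str,
                      config: StudyConfig) -> pd.DataFrame:
    """First-fill candidates of one index drug within the entry window.

    Returns a frame with one row per patient having any fill of the drug in
    the entry window: ``patient_id``, ``entry_day`` (first such fill) and
    ``washout_ok`` (no fill of the drug in the washout window before that
    day).  Downstream criteria are applied by
    :func:`apply_inclusion_exclusion`.
    """
    if drug_code not in bundle.catalog.index:
        raise KeyError(f"unknown drug_code {drug_code!r}")
    if not bool(bundle.catalog.loc[drug_code, "is_index_candidate"]):
        raise ValueError(f"{drug_code!r} is not an index-eligible drug")

    lo, hi = config.entry_window
    fills = bundle.fills[bundle.fills["drug_code"] == drug_code]
    in_window = fills[(fills["fill_date"] >= lo) & (fills["fill_date"] <= hi)]
    if in_window.empty:
        return pd.DataFrame(columns=["patient_id", "entry_day", "washout_ok"])
    entry = in_window.groupby("patient_id")["fill_date"].min()
    drug_fills = _by_patient(fills)

    rows = []
    for pid, day in entry.items():
        start = 0 if config.washout_from_extraction_start \
            else day - config.lookback_days
        dates = drug_fills[pid]["fill_date"]
        prior = ((dates >= start) & (dates < day)).any()
        rows.append((pid, int(day), not prior))
    return pd.DataFrame(rows, columns=["patient_id", "entry_day",
                                       "washout_ok"])


def _entry_age(birth_year: int, entry_day: int, config: StudyConfig) -> int:
    return config.offset_date(entry_day).year - int(birth_year)


def apply_inclusion_exclusion(
        events: pd.DataFrame, bundle: ClaimsBundle, config: StudyConfig,
        index_drug: str | None = None,
) -> tuple[pd.DataFrame, AttritionTable]:
    """Apply the inclusion and exclusion criteria in the study's order.

    ``events`` is the candidate frame from :func:`find_index_events` (the
    new-user washout verdict travels in its ``washout_ok`` column so that the
    attrition table can report it as criterion 3).  Returns the member frame
    with baseline covariates and the attrition table.  An empty cohort is a
    valid result.
    """
    cfg = config
    cat = bundle.catalog
    patients = bundle.patients.set_index("patient_id")
    entry_of = dict(zip(events["patient_id"], events["entry_day"]))
    washout_ok = dict(zip(events["patient_id"], events["washout_ok"]))
    current = set(entry_of)
    att = AttritionTable()
    att.add("index fill in entry window", current, set())

    levodopa_codes = set(cat.index[cat["class"] == "levodopa"])
    dx_by = _by_patient(bundle.diagnoses)
    empty_dx = bundle.diagnoses.iloc[0:0]

    # 1. PD diagnosis in the entry month
    fail = set()
    for pid in current:
        month = cfg.month_index_of_day(entry_of[pid])
        d = dx_by.get(pid, empty_dx)
        d = d[d["year_month"] == month]
        if not d["icd10"].map(
                lambda c: match_any_prefix(c, [cfg.pd_code])).any():
            fail.add(pid)
    current = att.add("PD diagnosis (G20) in entry month", current, fail)

    # 2. levodopa on the entry date and in the look-back window
    lev = bundle.fills[bundle.fills["drug_code"].isin(levodopa_codes)]
    lev_by = _by_patient(lev)
    empty_fills = bundle.fills.iloc[0:0]
    fail = set()
    for pid in current:
        day = entry_of[pid]
        dates = lev_by.get(pid, empty_fills)["fill_date"]
        at_entry = (dates == day).any()
        in_lookback = ((dates >= day - cfg.lookback_days)
                       & (dates < day)).any()
        if not (at_entry and in_lookback):
            fail.add(pid)
    current = att.add("levodopa at entry and in look-back", current, fail)

    # 3. new user: no index-drug fill in the washout window
    fail = {pid for pid in current if not washout_ok[pid]}
    current = att.add("no index-drug fill in washout (new user)",
                      current, fail)

    # 4. age >= 40 at entry
    birth = dict(zip(bundle.patients["patient_id"],
                     bundle.patients["birth_year"]))
    fail = {pid for pid in current
            if _entry_age(birth[pid], entry_of[pid], cfg) < cfg.min_age}
    current = att.add(f"age >= {cfg.min_age} at entry", current, fail)

    # exclusion 1: continuous data over look-back and follow-up
    fail = set()
    for pid in current:
        day = entry_of[pid]
        row = patients.loc[pid]
        if not (row["first_observed"] <= day - cfg.lookback_days
                and row["last_observed"] >= day + cfg.followup_days):
            fail.add(pid)
    current = att.add("continuous enrollment over look-back and follow-up",
                      current, fail)

    # exclusion 2: differential diagnoses anywhere in the extraction window
    fail = set()
    for pid in current:
        codes = dx_by.get(pid, empty_dx)["icd10"]
        if codes.map(lambda c: match_any_prefix(
                c, cfg.exclusion_codes)).any():
            fail.add(pid)
    current = att.add("no differential-diagnosis codes", current, fail)

    members = _baseline_covariates(
        sorted(current), entry_of, bundle, cfg, index_drug)
    return members, att


def _baseline_covariates(pids: list, entry_of: dict, bundle: ClaimsBundle,
                         cfg: StudyConfig,
                         index_drug: str | None) -> pd.DataFrame:
    cat = bundle.catalog
    patients = bundle.patients.set_index("patient_id")
    fills_by = _by_patient(bundle.fills)
    dx_by = _by_patient(bundle.diagnoses)
    empty_dx = bundle.diagnoses.iloc[0:0]
    atc2 = cat["atc2"].to_dict()
    led = cat["led_factor"].to_dict()
    drug_class = cat["class"].to_dict()

    rows = []
    for pid in pids:
        day = entry_of[pid]
        mine = fills_by[pid]
        at_entry = mine[mine["fill_date"] == day]
        entry_codes = set(at_entry["drug_code"])

        n04_entry = {c for c in entry_codes if atc2.get(c) == cfg.anti_pd_atc2}
        lev_entry = {c for c in n04_entry if drug_class[c] == "levodopa"}
        n_anti_pd = len(n04_entry - lev_entry)
        levodopa_dose = sum(led[c] for c in lev_entry)
        led_total = sum(led[c] for c in n04_entry)

        # concomitant drugs: distinct non-N04 ATC2 classes with >= 14 days
        # supplied over the entry date plus look-back
        window = mine[(mine["fill_date"] >= day - cfg.lookback_days)
                      & (mine["fill_date"] <= day)]
        non_n04 = window[window["drug_code"].map(
            lambda c: atc2.get(c) != cfg.anti_pd_atc2)]
        by_class = non_n04.groupby(
            non_n04["drug_code"].map(atc2))["days_supplied"].sum()
        n_concomitant = int((by_class >= cfg.concomitant_min_days).sum())

        # comorbidities from diagnoses up to and including the entry month
        month = cfg.month_index_of_day(day)
        d = dx_by.get(pid, empty_dx)
        codes = d.loc[d["year_month"] <= month, "icd10"].tolist()
        flags = comorbidity_flags(codes, cfg.comorbidity_code_map)

        # anti-PD prescription during hospitalization within follow-up
        fu = mine[(mine["fill_date"] >= day)
                  & (mine["fill_date"] <= day + cfg.followup_days)]
        fu_n04 = fu[fu["drug_code"].map(
            lambda c: atc2.get(c) == cfg.anti_pd_atc2)]
        hosp_rx = bool((fu_n04["discharge_flag"]
                        | (fu_n04["setting"] == "inpatient")).any())

        prow = patients.loc[pid]
        index_set = (index_drug,) if index_drug else ()
        rows.append({
            "patient_id": pid,
            "index_drugs": index_set,
            "entry_day": int(day),
            "age": _entry_age(patients.loc[pid, "birth_year"], day, cfg),
            "sex": prow["sex"],
            "male": int(prow["sex"] == "male"),
            "n_anti_pd": n_anti_pd,
            "n_concomitant": n_concomitant,
            "levodopa_dose": levodopa_dose,
            "led_n04_total": led_total,
            "led_excl_index": led_total - sum(
                led.get(c, 0.0) for c in index_set if c in n04_entry),
            "hosp_rx": int(hosp_rx),
            **{f"co_{k}": int(v) for k, v in flags.items()},
        })
    columns = ["patient_id", "index_drugs", "entry_day", "age", "sex",
               "male", "n_anti_pd", "n_concomitant", "levodopa_dose",
               "led_n04_total", "led_excl_index", "hosp_rx"] + [
               f"co_{k}" for k in cfg.comorbidity_code_map]
    return pd.DataFrame(rows, columns=columns)


def build_cohort(bundle: ClaimsBundle, drug_code: str, config: StudyConfig
                 ) -> tuple[pd.DataFrame, AttritionTable]:
    """Drug-specific cohort: index events plus inclusion/exclusion."""
    events = find_index_events(bundle, drug_code, config)
    return apply_inclusion_exclusion(events, bundle, config,
                                     index_drug=drug_code)


def build_all_drugs_cohort(per_drug: dict[str, pd.DataFrame],
                           catalog: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate drug-specific cohorts into the all-drugs cohort.

    A patient qualifying in several drug cohorts keeps only the earliest
    entry; ties on the entry date merge the drugs into a combination index
    drug.  Shared baseline covariates must agree across the merged rows.
    """
    frames = [df for df in per_drug.values() if len(df)]
    if not frames:
        return next(iter(per_drug.values())).iloc[0:0].copy()
    led = catalog["led_factor"].to_dict()
    stacked = pd.concat(frames, ignore_index=True)
    out_rows = []
    for pid, grp in stacked.groupby("patient_id"):
        earliest = grp["entry_day"].min()
        at_earliest = grp[grp["entry_day"] == earliest]
        for col in _SHARED_COVARIATES:
            if at_earliest[col].nunique() > 1:
                raise ValueError(
                    f"conflicting baseline covariate {col!r} for patient "
                    f"{pid} at entry day {earliest}")
        row = at_earliest.iloc[0].copy()
        drugs = tuple(sorted(
            {d for t in at_earliest["index_drugs"] for d in t}))
        row["index_drugs"] = drugs
        row["led_excl_index"] = row["led_n04_total"] - sum(
            led.get(d, 0.0) for d in drugs)
        out_rows.append(row)
    return pd.DataFrame(out_rows).sort_values("patient_id") \
        .reset_index(drop=True)
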