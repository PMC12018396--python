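"""Covered-period interval algebra and gap-based persistence.

All computations run on half-open integer-day intervals ``[start, end)``
relative to the cohort entry date (entry = day 0).  A fill's covered period
runs from its fill date to the earliest of supply exhaustion, the next fill
of the same drug (no stockpiling: overlapping supply is forfeited), and the
follow-up horizon.  The gap between consecutive covered periods is
``next.start - previous.end``; under this convention a refill on the exact
day supply runs out produces a gap of 0, and a 1-day supply never refilled
yields a persistent-period length of 1 day.

Persistence over follow-up: the first gap (including the terminal gap to the
follow-up horizon) of at least ``gap_threshold_days`` marks discontinuation
at the end of the preceding covered period; with no qualifying gap the
patient is persistent and the persistent treatment period equals the full
follow-up.  A gap exactly equal to the threshold counts as discontinuation
(persistence requires the gap to be strictly less than the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

Interval = tuple[int, int]


@dataclass(frozen=True)
class PersistenceResult:
    """Outcome of the gap scan over one patient's covered periods."""

    persistent_1yr: bool
    discontinuation_day: int | None
    persistent_period_days: int
    censored: bool  # reached follow-up end without a qualifying gap

    def __post_init__(self) -> None:
        assert self.persistent_1yr == self.censored
        assert self.persistent_period_days >= 1


def impute_discharge_days(fills: pd.DataFrame, cap_days: int = 30) -> pd.DataFrame:
    """Impute nominal 1-day discharge fills to their intended duration.

    Hospital-discharge dispensations are often registered as a single day's
    supply.  For each fill with ``discharge_flag`` and ``days_supplied == 1``
    the supply is replaced by the days until the next fill of the same drug
    for the same patient, capped at ``cap_days``; with no subsequent fill the
    cap is used.  Returns a copy with an added boolean ``imputed`` column.
    """
    out = fills.sort_values(["patient_id", "drug_code", "fill_date"]).copy()
    next_fill = out.groupby(["patient_id", "drug_code"])["fill_date"].shift(-1)
    target = out["discharge_flag"] & (out["days_supplied"] == 1)
    until_next = (next_fill - out["fill_date"]).fillna(cap_days)
    imputed_days = until_next.clip(lower=1, upper=cap_days).astype(int)
    out["imputed"] = target
    out.loc[target, "days_supplied"] = imputed_days[target]
    return out


def fill_periods(fill_dates: list[int], supplies: list[int],
                 followup_days: int) -> list[Interval]:
    """Per-fill covered periods, truncated but not merged.

    Each fill i yields ``[date_i, min(date_i + supply_i, date_{i+1},
    followup_days))``; zero-length periods (e.g. two fills on one day) are
    dropped.  Dates must be sorted ascending with the first at day 0.
    """
    if not fill_dates:
        raise ValueError("no fills")
    if fill_dates[0] < 0:
        raise ValueError("fill precedes the entry date")
    if list(fill_dates) != sorted(fill_dates):
        raise ValueError("fill dates must be sorted")
    periods: list[Interval] = []
    for i, (d, s) in enumerate(zip(fill_dates, supplies)):
        end = min(d + s, followup_days)
        if i + 1 < len(fill_dates):
            end = min(end, fill_dates[i + 1])
        if end > d:
            periods.append((d, end))
    return periods


def merge_periods(periods: list[Interval]) -> list[Interval]:
    """Normalize: sort and merge touching or overlapping intervals."""
    if not periods:
        return []
    periods = sorted(periods)
    merged = [periods[0]]
    for s, e in periods[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def build_covered_periods(fill_dates: list[int], supplies: list[int],
                          followup_days: int) -> list[Interval]:
    """Normalized (sorted, disjoint, merged) covered periods for one drug."""
    return merge_periods(fill_periods(fill_dates, supplies, followup_days))


def intersect_covered_periods(per_drug: list[list[Interval]]) -> list[Interval]:
    """Days on which *every* drug's covered-period union covers the patient.

    Used for combination index drugs: the combined covered period is the
    overlap of the constituent drugs' covered periods.
    """
    if not per_drug:
        raise ValueError("need at least one drug's period list")
    result = merge_periods(list(per_drug[0]))
    for periods in per_drug[1:]:
        other = merge_periods(list(periods))
        out: list[Interval] = []
        i = j = 0
        while i < len(result) and j < len(other):
            s = max(result[i][0], other[j][0])
            e = min(result[i][1], other[j][1])
            if s < e:
                out.append((s, e))
            if result[i][1] <= other[j][1]:
                i += 1
            else:
                j += 1
        result = out
    return result


def covered_days(periods: list[Interval], upto: int | None = None) -> int:
    """Total covered days, optionally clipped to ``[0, upto)``."""
    total = 0
    for s, e in merge_periods(list(periods)):
        if upto is not None:
            e = min(e, upto)
        if e > s:
            total += e - s
    return total


def assess_persistence(periods: list[Interval], followup_days: int = 365,
                       gap_threshold_days: int = 30) -> PersistenceResult:
    """Scan gaps between covered periods and classify 1-year persistence.

    ``periods`` must be normalized with the first starting at day 0 (the
    entry-date fill).  The terminal gap from the last covered day to the
    follow-up horizon counts like any other gap.
    """
    periods = merge_periods(list(periods))
    if not periods:
        raise ValueError("empty covered-period list")
    if periods[0][0] != 0:
        raise ValueError("first covered period must start at entry (day 0)")
    prev_end = periods[0][1]
    for s, e in periods[1:]:
        if s - prev_end >= gap_threshold_days:
            return PersistenceResult(False, prev_end, prev_end, False)
        prev_end = e
    if followup_days - prev_end >= gap_threshold_days:
        return PersistenceResult(False, prev_end, prev_end, False)
    return PersistenceResult(True, None, followup_days, True)
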