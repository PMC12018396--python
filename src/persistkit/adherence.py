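"""Adherence measures: proportion of days covered (PDC) and medication
possession ratio (MPR).

Both measures anchor on the *start of the last covered period* inside an
evaluation window (for a single index drug this is the last fill date, since
each fill opens a covered period):

* PDC = covered days strictly before that anchor / days from the first fill
  to the day before the anchor.  Covered days use the truncated
  (no-stockpiling) covered periods, so PDC is in [0, 1].
* MPR = total dispensed days-supplied of fills strictly before the anchor /
  the same denominator.  Overlapping fills are not truncated in the
  numerator, so MPR may exceed 1.

The primary evaluation window is the persistent treatment period; the
follow-up period is the window for the sensitivity variants.  Both measures
are computed only for patients with at least two fills in the window
("continuous users"); a one-fill patient, or a degenerate window (all fills
on one day), yields an undefined value, reported as missing — never as 0
or 1.  Good adherence is PDC >= 80% (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exposure import Interval, covered_days, fill_periods


@dataclass(frozen=True)
class AdherenceResult:
    eligible: bool            # >= 2 index-drug fills within follow-up
    pdc_persistent: float | None
    pdc_followup: float | None
    mpr_followup: float | None
    good_adherence: bool | None  # pdc_persistent >= threshold, when defined


def _collapse(fill_dates: list[int], supplies: list[int]
              ) -> tuple[list[int], list[int]]:
    """Collapse same-day fills of one drug into a single fill event
    (keeping the larger supply)."""
    by_date: dict[int, int] = {}
    for d, s in zip(fill_dates, supplies):
        by_date[d] = max(by_date.get(d, 0), s)
    dates = sorted(by_date)
    return dates, [by_date[d] for d in dates]


def pdc_from_periods(periods: list[Interval], anchor_starts: list[int],
                     window_days: int) -> float | None:
    """PDC given covered periods and the period-start anchors.

    ``anchor_starts`` are the starts of the individual (unmerged) covered
    periods — fill dates for a single drug, intersected-period starts for a
    drug combination.  Returns None when fewer than two anchors fall inside
    the window (ineligible) or the denominator is zero (undefined).
    """
    anchors = sorted(a for a in anchor_starts if 0 <= a < window_days)
    if len(anchors) < 2:
        return None
    last = anchors[-1]
    denom = last - anchors[0]
    if denom == 0:
        return None
    num = covered_days(periods, upto=last)
    pdc = num / denom
    assert 0.0 <= pdc <= 1.0 + 1e-12
    return min(pdc, 1.0)


def compute_pdc(fill_dates: list[int], supplies: list[int],
                window_days: int, followup_days: int = 365) -> float | None:
    """PDC of one drug's fills within ``[0, window_days)``.

    ``window_days`` is the persistent-treatment-period length for the primary
    measure or ``followup_days`` for the follow-up-window variant.
    """
    dates, supp = _collapse(fill_dates, supplies)
    periods = fill_periods(dates, supp, followup_days)
    return pdc_from_periods(periods, dates, window_days)


def compute_mpr(fill_dates: list[int], supplies: list[int],
                followup_days: int = 365) -> float | None:
    """MPR over the follow-up window: dispensed days before the last fill
    divided by the days up to that fill; may exceed 1 when fills overlap."""
    dates, supp = _collapse(fill_dates, supplies)
    in_window = [(d, s) for d, s in zip(dates, supp) if d < followup_days]
    if len(in_window) < 2:
        return None
    last = in_window[-1][0]
    denom = last - in_window[0][0]
    if denom == 0:
        return None
    num = sum(s for d, s in in_window if d < last)
    return num / denom


def classify_adherence(pdc: float, threshold: float = 0.80) -> bool:
    """Good adherence: PDC at or above the threshold."""
    if pdc is None or math.isnan(pdc):
        raise ValueError("adherence classification requires a defined PDC")
    return pdc >= threshold


def assess_adherence(fill_dates: list[int], supplies: list[int],
                     persistent_period_days: int,
                     followup_days: int = 365,
                     good_threshold: float = 0.80,
                     combo_periods: list[Interval] | None = None,
                     ) -> AdherenceResult:
    """All adherence measures for one patient.

    For a combination index drug pass the intersected covered periods as
    ``combo_periods`` and the combination fill dates (days on which every
    constituent drug was filled) as ``fill_dates``; supplies are then unused
    for PDC but still feed the MPR numerator.
    """
    dates, supp = _collapse(fill_dates, supplies)
    eligible = len([d for d in dates if d < followup_days]) >= 2

    if combo_periods is not None:
        anchors = [s for s, _ in combo_periods]
        periods = combo_periods
    else:
        anchors = dates
        periods = fill_periods(dates, supp, followup_days) if dates else []

    pdc_pp = pdc_from_periods(periods, anchors, persistent_period_days) \
        if dates else None
    pdc_fu = pdc_from_periods(periods, anchors, followup_days) \
        if dates else None
    mpr = compute_mpr(dates, supp, followup_days) if dates else None
    good = classify_adherence(pdc_pp, good_threshold) \
        if pdc_pp is not None else None
    return AdherenceResult(eligible, pdc_pp, pdc_fu, mpr, good)
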