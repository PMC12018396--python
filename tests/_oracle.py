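"""Brute-force day-vector oracle for the interval engine.

Everything here is computed by looping over the 365 follow-up days with the
most literal reading of the definitions: a day is covered when the most
recent fill on or before it still has supply left (no stockpiling);
persistence fails at the first run of >= gap uncovered days; PDC/MPR anchor
on the last fill date inside the window.  Deliberately independent of the
interval arithmetic in persistkit.exposure / persistkit.adherence.
"""

from __future__ import annotations


def day_vector(dates: list[int], supplies: list[int],
               followup: int = 365) -> list[bool]:
    covered = [False] * followup
    for day in range(followup):
        last = None
        for i, d in enumerate(dates):
            if d <= day:
                last = i
        if last is not None and day < dates[last] + supplies[last]:
            covered[day] = True
    return covered


def covered_total(dates, supplies, followup=365, upto=None) -> int:
    cov = day_vector(dates, supplies, followup)
    if upto is not None:
        cov = cov[:upto]
    return sum(cov)


def uncovered_runs(dates, supplies, followup=365) -> list[tuple[int, int]]:
    """(start, length) of each maximal uncovered run, terminal run included."""
    cov = day_vector(dates, supplies, followup)
    runs = []
    start = None
    for day in range(followup):
        if not cov[day]:
            if start is None:
                start = day
        else:
            if start is not None:
                runs.append((start, day - start))
                start = None
    if start is not None:
        runs.append((start, followup - start))
    return runs


def persistence(dates, supplies, followup=365, gap=30):
    """(persistent, discontinuation_day_or_None, persistent_period_days)."""
    for start, length in uncovered_runs(dates, supplies, followup):
        if length >= gap:
            return False, start, start
    return True, None, followup


def pdc(dates, supplies, window, followup=365):
    """(numerator, denominator) or None when ineligible/undefined."""
    in_window = sorted(set(d for d in dates if 0 <= d < window))
    if len(in_window) < 2:
        return None
    last = in_window[-1]
    denom = last - in_window[0]
    if denom == 0:
        return None
    num = covered_total(dates, supplies, followup, upto=last)
    return num, denom


def mpr(dates, supplies, followup=365):
    """(numerator, denominator) or None when ineligible/undefined."""
    pairs = sorted({(d, s) for d, s in zip(dates, supplies)})
    # collapse same-day duplicates to the larger supply, as the engine does
    by_date: dict[int, int] = {}
    for d, s in pairs:
        if d < followup:
            by_date[d] = max(by_date.get(d, 0), s)
    if len(by_date) < 2:
        return None
    last = max(by_date)
    denom = last - min(by_date)
    if denom == 0:
        return None
    num = sum(s for d, s in by_date.items() if d < last)
    return num, denom


def impute(fills: list[tuple[int, int, bool]], cap: int = 30
           ) -> list[tuple[int, int, bool]]:
    """Discharge 1-day imputation for one drug's (date, supply, flag) list."""
    fills = sorted(fills)
    out = []
    for i, (d, s, flag) in enumerate(fills):
        if flag and s == 1:
            if i + 1 < len(fills):
                s = min(max(fills[i + 1][0] - d, 1), cap)
            else:
                s = cap
        out.append((d, s, flag))
    return out
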