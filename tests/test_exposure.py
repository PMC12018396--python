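"""Interval-engine unit and property tests: covered periods, gap scanning,
discharge imputation — checked against hand-worked cases and the brute-force
day-vector oracle."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from persistkit.exposure import (assess_persistence, build_covered_periods,
                                 covered_days, fill_periods,
                                 impute_discharge_days,
                                 intersect_covered_periods)

from _oracle import persistence as oracle_persistence

# -- covered-period construction -------------------------------------------


@pytest.mark.parametrize("dates,supplies,expected", [
    # back-to-back refills merge into one period
    ([0, 30], [30, 30], [(0, 60)]),
    # early refill truncates the previous supply (no stockpiling)
    ([0, 20], [30, 30], [(0, 50)]),
    # late refill leaves the periods apart
    ([0, 40], [30, 30], [(0, 30), (40, 70)]),
    # follow-up horizon truncates the final supply
    ([0, 350], [30, 30], [(0, 30), (350, 365)]),
], ids=["contiguous-merge", "overlap-truncated", "gap", "horizon-clip"])
def test_covered_periods(dates, supplies, expected):
    assert build_covered_periods(dates, supplies, 365) == expected


def test_covered_periods_reject_pre_entry_fill():
    with pytest.raises(ValueError):
        fill_periods([-5, 0], [30, 30], 365)


@pytest.mark.parametrize("lists,expected", [
    ([[(0, 30)]], [(0, 30)]),                        # identity
    ([[(0, 30)], [(10, 40)]], [(10, 30)]),           # partial overlap
    ([[(0, 30)], [(30, 60)]], []),                   # disjoint -> empty
    ([[(0, 100)], [(10, 20), (50, 120)]], [(10, 20), (50, 100)]),
])
def test_intersection(lists, expected):
    assert intersect_covered_periods(lists) == expected


def test_intersection_requires_input():
    with pytest.raises(ValueError):
        intersect_covered_periods([])


# -- persistence gap rule --------------------------------------------------


@pytest.mark.parametrize("periods,persistent,disc,length", [
    ([(0, 365)], True, None, 365),                 # full coverage
    ([(0, 30)], False, 30, 30),                    # terminal gap 335
    ([(0, 30), (59, 89)], False, 89, 89),          # gap 29 < 30: survives it,
                                                   # then the terminal gap hits
    ([(0, 30), (60, 90)], False, 30, 30),          # gap exactly 30: discontinued
    ([(0, 1)], False, 1, 1),                       # 1-day supply -> 1-day period
    ([(0, 30), (59, 365)], True, None, 365),       # 29-day gap, covered to end
    ([(0, 340)], True, None, 365),                 # terminal gap 25 < 30
])
def test_gap_rule(periods, persistent, disc, length):
    res = assess_persistence(periods, 365, 30)
    assert res.persistent_1yr is persistent
    assert res.discontinuation_day == disc
    assert res.persistent_period_days == length
    assert res.censored is persistent


def test_persistence_requires_entry_day_coverage():
    with pytest.raises(ValueError):
        assess_persistence([(5, 40)], 365, 30)
    with pytest.raises(ValueError):
        assess_persistence([], 365, 30)


# -- discharge-day imputation ----------------------------------------------


def _fills_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_code",
                                       "fill_date", "days_supplied",
                                       "discharge_flag", "setting"])


@pytest.mark.parametrize("next_day,expected", [
    (120, 20),   # days until the next fill
    (145, 30),   # capped at 30
    (None, 30),  # no later fill: cap applies
], ids=["until-next", "capped", "no-next"])
def test_discharge_imputation(next_day, expected):
    rows = [("p", "a", 100, 1, True, "outpatient")]
    if next_day is not None:
        rows.append(("p", "a", next_day, 30, False, "outpatient"))
    out = impute_discharge_days(_fills_frame(rows))
    first = out[out["fill_date"] == 100].iloc[0]
    assert first["days_supplied"] == expected
    assert bool(first["imputed"])


def test_imputation_only_touches_1day_discharge_fills():
    rows = [
        ("p", "a", 0, 30, False, "outpatient"),   # plain fill
        ("p", "a", 40, 14, True, "outpatient"),   # discharge but 14 days
        ("p", "b", 60, 1, False, "outpatient"),   # 1 day but not discharge
    ]
    out = impute_discharge_days(_fills_frame(rows))
    assert out["days_supplied"].tolist() == [30, 14, 1]
    assert not out["imputed"].any()


def test_imputation_uses_next_fill_of_same_drug_only():
    rows = [
        ("p", "a", 100, 1, True, "outpatient"),
        ("p", "b", 110, 30, False, "outpatient"),  # other drug: ignored
        ("p", "a", 125, 30, False, "outpatient"),
    ]
    out = impute_discharge_days(_fills_frame(rows))
    assert out[(out["drug_code"] == "a")
               & (out["fill_date"] == 100)].iloc[0]["days_supplied"] == 25


# -- properties against the day-vector oracle ------------------------------

@st.composite
def random_fills(draw):
    n = draw(st.integers(0, 9))
    later = sorted({draw(st.integers(1, 364)) for _ in range(n)})
    dates = [0] + later
    supplies = [draw(st.integers(1, 90)) for _ in dates]
    return dates, supplies


@settings(max_examples=200, derandomize=True, deadline=None)
@given(random_fills())
def test_interval_engine_matches_oracle(fills):
    dates, supplies = fills
    periods = build_covered_periods(dates, supplies, 365)
    got = assess_persistence(periods, 365, 30)
    exp_pers, exp_disc, exp_len = oracle_persistence(dates, supplies)
    assert got.persistent_1yr == exp_pers
    assert got.discontinuation_day == exp_disc
    assert got.persistent_period_days == exp_len


@settings(max_examples=200, derandomize=True, deadline=None)
@given(random_fills(), st.integers(1, 364))
def test_adding_a_large_fill_never_hurts_persistence(fills, new_date):
    """Monotonicity: an extra fill whose supply is at least as long as any
    existing one can only extend coverage.  (A *shorter* inserted fill can
    legitimately shrink coverage, because the no-stockpiling rule truncates
    the previous supply at the new fill date.)"""
    dates, supplies = fills
    if new_date in dates:
        return
    base = assess_persistence(
        build_covered_periods(dates, supplies, 365), 365, 30)
    dates2, supplies2 = map(list, zip(*sorted(
        zip(dates + [new_date], supplies + [max(supplies)]))))
    aug = assess_persistence(
        build_covered_periods(dates2, supplies2, 365), 365, 30)
    if base.persistent_1yr:
        assert aug.persistent_1yr
    assert aug.persistent_period_days >= base.persistent_period_days


@settings(max_examples=200, derandomize=True, deadline=None)
@given(random_fills())
def test_gap_threshold_monotonicity(fills):
    """Persistence under a 15-day gap rule implies persistence under 30."""
    dates, supplies = fills
    periods = build_covered_periods(dates, supplies, 365)
    strict = assess_persistence(periods, 365, 15)
    lax = assess_persistence(periods, 365, 30)
    if strict.persistent_1yr:
        assert lax.persistent_1yr
    assert strict.persistent_period_days <= lax.persistent_period_days


@settings(max_examples=150, derandomize=True, deadline=None)
@given(random_fills())
def test_covered_days_match_oracle(fills):
    dates, supplies = fills
    periods = build_covered_periods(dates, supplies, 365)
    from _oracle import covered_total
    assert covered_days(periods) == covered_total(dates, supplies)
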