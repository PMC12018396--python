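"""Estimators for the study outcomes.

* Five-number summaries (min, Q1, median, Q3, max) with linearly
  interpolated quartiles.
* Kaplan-Meier product-limit curves for time to treatment discontinuation
  (via lifelines).
* Modified Poisson regression for binary outcomes: Poisson working
  likelihood with log link and a robust HC0 sandwich variance (Zou's
  estimator, via statsmodels), yielding risk ratios with 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

Z_95 = 1.96  # normal quantile for the 95% confidence level


@dataclass(frozen=True)
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.min, self.q1, self.median, self.q3, self.max)


def summarize_quartiles(values) -> FiveNumberSummary:
    """Min, quartiles and max of a nonempty sequence.

    Quartiles use linear interpolation between order statistics, the shared
    default of numpy, pandas and R's ``quantile(type = 7)``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return FiveNumberSummary(*q)


@dataclass
class KMCurve:
    """Product-limit estimate of the probability of remaining on treatment."""

    times: np.ndarray      # distinct event/censoring times, ascending
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray   # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """S(t): probability of persisting beyond time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.n_risk,
            "n_event": self.n_event, "n_censored": self.n_censored,
            "survival": self.survival,
        })


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier curve with discontinuation as the event.

    ``times`` are persistent-treatment-period lengths in days;
    ``events`` is True for discontinuation, False for censoring (reaching
    the end of follow-up still on treatment).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table[kmf.event_table.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    t = table.index.to_numpy(dtype=float)
    return KMCurve(
        times=t,
        n_risk=table["at_risk"].to_numpy(dtype=int),
        n_event=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        survival=surv.reindex(table.index).to_numpy(dtype=float),
    )


@dataclass
class RRModelFit:
    """Risk-ratio fit from a modified Poisson regression."""

    table: pd.DataFrame  # term, coef, robust_se, rr, ci_low, ci_high, p
    converged: bool
    n: int
    n_dropped: int       # complete-case row loss
    n_fitted_risk_gt1: int  # known modified-Poisson pathology, reported

    def rr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "rr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def fit_modified_poisson(design: pd.DataFrame, outcome,
                         add_intercept: bool = True) -> RRModelFit:
    """Fit a modified Poisson model for a binary outcome.

    Poisson GLM with log link on 0/1 outcomes; the misspecified Poisson
    variance is corrected with the HC0 sandwich estimator, giving valid
    standard errors for the risk ratios exp(coef).  Rows with missing
    covariates are dropped (complete case) and counted in ``n_dropped``.
    Fitted risks above 1 are reported, never clipped.
    """
    y = pd.Series(np.asarray(outcome), index=design.index, name="y")
    if not set(np.unique(y.dropna())) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    data = pd.concat([design, y], axis=1)
    n_total = len(data)
    data = data.dropna()
    n_dropped = n_total - len(data)
    y = data.pop("y").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all 0 or all 1")
    X = data.astype(float)
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
    if len(X) <= X.shape[1]:
        raise ValueError("more parameters than observations")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(cov_type="HC0", maxiter=100, tol=1e-8)
    coefs = res.params.to_numpy()
    ses = res.bse.to_numpy()
    fitted = res.fittedvalues.to_numpy()

    table = pd.DataFrame({
        "term": list(X.columns),
        "coef": coefs,
        "robust_se": ses,
        "rr": np.exp(coefs),
        "ci_low": np.exp(coefs - Z_95 * ses),
        "ci_high": np.exp(coefs + Z_95 * ses),
        "p": res.pvalues.to_numpy(),
    })
    return RRModelFit(
        table=table,
        converged=bool(res.converged),
        n=len(X),
        n_dropped=n_dropped,
        n_fitted_risk_gt1=int((fitted > 1.0).sum()),
    )
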