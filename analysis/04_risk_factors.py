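#!/usr/bin/env python
"""Factors associated with persistence and with good adherence.

Fits the modified Poisson (risk-ratio) models in the all-drugs cohort and
writes the coefficient tables under results/risk_factors/, printing the
covariates whose 95% CI excludes 1.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import CLAIMS_DIR, CONFIG, RESULTS

from persistkit import load_claims, run_primary


def main() -> None:
    bundle = load_claims(CLAIMS_DIR, CONFIG)
    report = run_primary(bundle, CONFIG)
    out = RESULTS / "risk_factors"
    out.mkdir(parents=True, exist_ok=True)

    for outcome, fit in report.fits.items():
        fit.table.to_csv(out / f"model_{outcome}.csv", index=False)
        print(f"\n{outcome} model (n={fit.n}, converged={fit.converged}, "
              f"fitted risks >1: {fit.n_fitted_risk_gt1})")
        for row in fit.table.itertuples():
            if row.term == "const":
                continue
            sig = "*" if row.ci_low > 1 or row.ci_high < 1 else " "
            print(f"  {row.term:22s} RR {row.rr:5.2f} "
                  f"({row.ci_low:.2f}-{row.ci_high:.2f}) p={row.p:.3f} {sig}")
    print(f"\ncoefficient tables in {out}")


if __name__ == "__main__":
    main()
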