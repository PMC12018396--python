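#!/usr/bin/env python
"""Build the 17 drug-specific new-user cohorts and the all-drugs cohort.

Loads the claims written by 01_simulate_claims.py, applies the inclusion/
exclusion cascade per drug, deduplicates into the all-drugs cohort, and
writes the member and attrition tables under results/cohorts/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import CLAIMS_DIR, CONFIG, RESULTS

from persistkit import build_all_drugs_cohort, build_cohort, load_claims


def main() -> None:
    bundle = load_claims(CLAIMS_DIR, CONFIG)
    out = RESULTS / "cohorts"
    out.mkdir(parents=True, exist_ok=True)

    candidates = sorted(
        set(bundle.catalog.index[bundle.catalog["is_index_candidate"]])
        & set(bundle.fills["drug_code"]))
    per_drug = {}
    att_frames = []
    for drug in candidates:
        members, att = build_cohort(bundle, drug, CONFIG)
        per_drug[drug] = members
        frame = att.to_frame()
        frame.insert(0, "cohort", drug)
        att_frames.append(frame)
        print(f"{drug:18s} candidates {att.rows[0].n_before:5d} "
              f"-> cohort {len(members):5d}")

    all_members = build_all_drugs_cohort(per_drug, bundle.catalog)
    combos = all_members["index_drugs"].map(len).gt(1).sum()
    print(f"{'all drugs':18s} deduplicated  -> cohort {len(all_members):5d} "
          f"({combos} combination index)")

    pd.concat(att_frames).to_csv(out / "attrition.csv", index=False)
    for name, df in {**per_drug, "all_drugs": all_members}.items():
        df2 = df.copy()
        df2["index_drugs"] = df2["index_drugs"].map("+".join)
        df2.to_csv(out / f"cohort_{name}.csv", index=False)
    print(f"wrote member and attrition tables to {out}")


if __name__ == "__main__":
    main()
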