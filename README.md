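# persistkit

Medication **persistence** and **adherence** analysis on pharmacy-claims
data, built around the levodopa-adjunct treatment landscape in elderly
Parkinson's disease (PD): new-user cohorts with a washout window,
covered-period interval algebra over prescription fills, gap-based 1-year
persistence, PDC/MPR adherence, Kaplan–Meier discontinuation curves, and
modified Poisson risk-ratio models. Because real claims databases of this
kind are licensed and not redistributable, the package ships a synthetic
claims generator with known ground truth, so every stage of the pipeline is
testable end to end.

It is written for pharmacoepidemiologists and biostatisticians who want an
auditable, reusable implementation of these standard outcome definitions
rather than one-off SQL.

## The outcome definitions

All computation runs on half-open integer-day intervals relative to the
cohort entry date (day 0 = first fill of the newly started *index drug*).

* **Covered period** of fill *i* with supply *sᵢ*:
  `[tᵢ, min(tᵢ + sᵢ, tᵢ₊₁, 365))` — supply left over at the next fill is
  forfeited (no stockpiling). Nominal 1-day discharge fills are imputed to
  `min(t_next − t, 30)` days first.
* **Persistence**: scan the gaps between covered periods (terminal gap to
  day 365 included). The first gap ≥ 30 days (gap = next start − previous
  end; "less than 30" is strict) marks discontinuation at the end of the
  preceding covered period; no qualifying gap ⇒ persistent, with a
  365-day persistent treatment period. For a combination index (several
  drugs newly started the same day) the covered period is the intersection
  of the constituents' covered periods.
* **PDC** (proportion of days covered, computed only for patients with ≥ 2
  fills): covered days strictly before the start of the last covered
  period inside the evaluation window, divided by the days from the first
  fill to that start. The primary window is the persistent treatment
  period; a sensitivity variant uses the full follow-up window. Good
  adherence is PDC ≥ 80 % (inclusive).
* **MPR** (medication possession ratio): total dispensed days over the
  same denominator; overlapping fills can push it above 1.
* **Modified Poisson regression** (Zou's method): Poisson GLM with log
  link on the binary outcome, HC0 sandwich variance, reported as risk
  ratios with 95 % CIs.

## Worked example

```python
from persistkit import SimParams, StudyConfig, generate, run_primary

config = StudyConfig()                       # 2019-12..2022-11 extraction,
                                             # 180-day look-back, 30-day gap
bundle, truth = generate(SimParams(n_patients=2000, seed=1), config)
report = run_primary(bundle, config)
print(report.persistence_table.set_index("cohort").loc["all_drugs"])
```

```
n                 2000.0
n_persistent       926.0
pct_persistent      46.3
min                 30.0
q1                 124.0
median             296.0
q3                 365.0
max                365.0
Name: all_drugs, dtype: float64
```

Read: of the 2,000 synthetic new users of a levodopa adjunct, 46.3 %
reached one year without a ≥ 30-day gap in index-drug coverage; the median
persistent treatment period was 296 days (the generator's hazards imply
45.6 % persistence in closed form, so the pipeline's estimate is on
target). `report.adherence_table` shows that among the 1,852 patients with
≥ 2 fills, 94.7 % had PDC ≥ 80 % (median PDC 96.0 %), and
`report.fits["persistence"]` gives, e.g., RR 0.79 (0.70–0.88) per
additional concomitant anti-PD drug — the polypharmacy penalty built into
the generator, recovered by the model.

The numbered scripts under `analysis/` run the same study as a narrative
sequence (simulate → cohorts → outcomes → risk factors → sensitivity and
subgroups), writing their tables and the Kaplan–Meier SVG panels under
`results/` (simulated claims go to `scratch/`):

```bash
python analysis/01_simulate_claims.py
python analysis/02_build_cohorts.py
python analysis/03_persistence_adherence.py
python analysis/04_risk_factors.py
python analysis/05_sensitivity_subgroups.py
```

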