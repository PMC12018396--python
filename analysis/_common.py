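"""Shared paths and study conditions for the numbered analysis scripts."""

from pathlib import Path

from persistkit import SimParams, StudyConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
# the simulated claims tables are bulky intermediates; keep them out of the
# versioned results
CLAIMS_DIR = ROOT / "scratch" / "claims"

SEED = 1
N_PATIENTS = 2000

CONFIG = StudyConfig()
PARAMS = SimParams(n_patients=N_PATIENTS, seed=SEED)
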