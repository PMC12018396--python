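"""Default drug catalog and simulation menu.

The catalog covers the 17 levodopa-adjunct index drugs (oral or transdermal,
ergot dopamine agonists excluded), strength-specific oral levodopa products,
and a menu of common non-antiparkinson concomitant drugs identified by their
ATC second-level class.

``led_factor`` is the levodopa-equivalent dose in mg/day contributed while a
patient is on the drug at a typical maintenance dose.  Claims fills carry no
strength, so dose enters the data model only through the catalog; the shipped
factors are plausible defaults for synthetic data, to be replaced by a
site-specific conversion table in any real analysis.  Anticholinergics,
amantadine-class drugs without an accepted conversion, and droxidopa carry 0.

Per-drug cohort weights and per-refill-cycle discontinuation hazards in
``DEFAULT_DRUG_MENU`` calibrate the synthetic generator to the observed
landscape of adjunct use in elderly Japanese Parkinson's disease care:
weights follow relative cohort sizes and hazards are back-solved so that the
implied 1-year persistence under monthly refills spans roughly 29-60% across
drugs (~45% pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# drug_code -> (name, class, led_factor, cohort weight, 1-yr persistence target)
_INDEX_DRUGS: list[tuple[str, str, str, float, int, float]] = [
    ("pramipexole_ir", "Pramipexole (immediate-release tablet)", "non_ergot_da", 150.0, 329, 0.389),
    ("pramipexole_sr", "Pramipexole (sustained-release tablet)", "non_ergot_da", 150.0, 345, 0.539),
    ("ropinirole_ir", "Ropinirole (immediate-release tablet)", "non_ergot_da", 120.0, 52, 0.327),
    ("ropinirole_sr", "Ropinirole (sustained-release tablet)", "non_ergot_da", 120.0, 429, 0.490),
    ("ropinirole_patch", "Ropinirole (transdermal patch)", "non_ergot_da", 160.0, 1358, 0.539),
    ("rotigotine", "Rotigotine (transdermal patch)", "non_ergot_da", 120.0, 867, 0.419),
    ("selegiline", "Selegiline", "maob_inhibitor", 100.0, 425, 0.494),
    ("rasagiline", "Rasagiline", "maob_inhibitor", 100.0, 932, 0.519),
    ("safinamide", "Safinamide", "maob_inhibitor", 100.0, 876, 0.558),
    ("entacapone", "Entacapone", "comt_inhibitor", 100.0, 635, 0.369),
    ("opicapone", "Opicapone", "comt_inhibitor", 50.0, 920, 0.527),
    ("trihexyphenidyl", "Trihexyphenidyl", "anticholinergic", 0.0, 200, 0.375),
    ("biperiden", "Biperiden", "anticholinergic", 0.0, 7, 0.286),
    ("droxidopa", "Droxidopa", "other", 0.0, 574, 0.556),
    ("amantadine", "Amantadine", "other", 100.0, 459, 0.510),
    ("istradefylline", "Istradefylline", "other", 20.0, 452, 0.493),
    ("zonisamide", "Zonisamide", "other", 100.0, 850, 0.595),
]

#: Strength-specific oral levodopa (carbidopa/benserazide combination)
#: products; led_factor doubles as the daily dose in mg.
_LEVODOPA_PRODUCTS: list[tuple[str, float]] = [
    ("levodopa_150", 150.0),
    ("levodopa_300", 300.0),
    ("levodopa_450", 450.0),
    ("levodopa_600", 600.0),
]

#: Concomitant (non-antiparkinson) drugs: code -> ATC second level.
_CONCOMITANT_DRUGS: list[tuple[str, str]] = [
    ("ppi", "A02"),
    ("laxative", "A06"),
    ("antidiabetic", "A10"),
    ("anticoagulant", "B01"),
    ("diuretic", "C03"),
    ("ccb", "C08"),
    ("ras_inhibitor", "C09"),
    ("statin", "C10"),
    ("thyroid_hormone", "H03"),
    ("nsaid", "M01"),
    ("hypnotic", "N05"),
    ("antidepressant", "N06"),
]


def default_catalog() -> pd.DataFrame:
    """Catalog table indexed by drug_code.

    Columns: name, class, atc2, led_factor, is_index_candidate.
    """
    rows = []
    for code, name, cls, led, _, _ in _INDEX_DRUGS:
        rows.append((code, name, cls, "N04", led, True))
    for code, dose in _LEVODOPA_PRODUCTS:
        rows.append((code, f"Levodopa {dose:.0f} mg/day", "levodopa", "N04", dose, False))
    # One ergot agonist for completeness: available but never index-eligible.
    rows.append(("cabergoline", "Cabergoline", "ergot", "N04", 200.0, False))
    for code, atc2 in _CONCOMITANT_DRUGS:
        rows.append((code, code.replace("_", " "), "other_non_pd", atc2, 0.0, False))
    df = pd.DataFrame(
        rows,
        columns=["drug_code", "name", "class", "atc2", "led_factor",
                 "is_index_candidate"],
    )
    return df.set_index("drug_code")


@dataclass(frozen=True)
class DrugSimSpec:
    """Per-drug generator settings: sampling weight, per-refill-cycle
    discontinuation hazard, and refill-cycle-length distribution
    (days -> probability)."""

    weight: float
    hazard: float
    cycle_probs: dict[int, float] = field(
        default_factory=lambda: {30: 1.0}
    )


def _hazard_for_persistence(p: float, n_refills: int = 11) -> float:
    """Per-cycle hazard whose monthly-refill process yields 1-year
    persistence ``p`` (persistence = surviving ``n_refills`` refill
    decisions)."""
    return 1.0 - p ** (1.0 / n_refills)


def default_drug_menu() -> dict[str, DrugSimSpec]:
    total = sum(n for *_, n, _ in _INDEX_DRUGS)
    return {
        code: DrugSimSpec(
            weight=n / total,
            hazard=round(_hazard_for_persistence(p), 6),
        )
        for code, _, _, _, n, p in _INDEX_DRUGS
    }


#: Daily-dose distribution for the levodopa backbone (drug_code -> prob).
DEFAULT_LEVODOPA_MIX: dict[str, float] = {
    "levodopa_150": 0.10,
    "levodopa_300": 0.45,
    "levodopa_450": 0.30,
    "levodopa_600": 0.15,
}

CONCOMITANT_CODES: tuple[str, ...] = tuple(c for c, _ in _CONCOMITANT_DRUGS)
INDEX_DRUG_CODES: tuple[str, ...] = tuple(c for c, *_ in _INDEX_DRUGS)
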