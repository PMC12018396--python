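"""Study configuration: windows, thresholds, and ICD-10 code lists.

All interval logic in the package runs on integer day offsets from
``extraction_start`` (day 0); files carry ISO-8601 dates.  Diagnoses are
recorded at calendar-month granularity, indexed as months since the
extraction-start month.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

#: Differential diagnoses that disqualify a Parkinson's disease cohort member:
#: secondary/atypical parkinsonism (multiple system atrophy, progressive
#: supranuclear palsy, basal-ganglia degeneration, vascular and drug-induced
#: parkinsonism), normal pressure hydrocephalus, and schizophrenia.  These are
#: standard ICD-10 prefixes for those disease names; site code lists should be
#: supplied via config where they differ.
DEFAULT_EXCLUSION_CODES: tuple[str, ...] = (
    "G21",    # secondary parkinsonism (incl. drug-induced G21.1, vascular G21.4)
    "G22",    # parkinsonism in diseases classified elsewhere
    "G23",    # other degenerative diseases of basal ganglia (incl. PSP G23.1)
    "G90.3",  # multi-system degeneration (multiple system atrophy)
    "G91.2",  # normal pressure hydrocephalus
    "F20",    # schizophrenia
)

DEFAULT_COMORBIDITY_MAP: dict[str, tuple[str, ...]] = {
    "depression": ("F32", "F33"),
    "dementia": ("F00", "F01", "F02", "F03", "G30"),
    "liver_failure": ("K72", "K74"),
    "renal_failure": ("N17", "N18", "N19"),
}


class StudyConfig(BaseModel):
    """Run configuration for cohort construction and outcome definitions."""

    extraction_start: dt.date = dt.date(2019, 12, 1)
    extraction_end: dt.date = dt.date(2022, 11, 30)
    entry_start: dt.date = dt.date(2020, 12, 1)
    entry_end: dt.date = dt.date(2021, 11, 30)

    lookback_days: int = Field(default=180, gt=0)
    followup_days: int = Field(default=365, gt=0)
    gap_threshold_days: int = Field(default=30, gt=0)
    pdc_good_threshold: float = Field(default=0.80, gt=0.0, le=1.0)
    min_age: int = Field(default=40, ge=0)
    pd_code: str = "G20"
    exclusion_codes: tuple[str, ...] = DEFAULT_EXCLUSION_CODES
    comorbidity_code_map: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_MAP)
    )
    concomitant_min_days: int = Field(default=14, gt=0)
    anti_pd_atc2: str = "N04"
    discharge_impute_cap_days: int = Field(default=30, gt=0)
    #: When true, the new-user washout extends from the start of data
    #: extraction to the day before entry instead of the fixed look-back
    #: window (sensitivity analysis on the washout window).
    washout_from_extraction_start: bool = False

    @model_validator(mode="after")
    def _check_windows(self) -> "StudyConfig":
        if not (self.extraction_start <= self.entry_start <= self.entry_end
                <= self.extraction_end):
            raise ValueError("entry window must lie inside the extraction window")
        return self

    # -- date arithmetic ---------------------------------------------------

    def day_offset(self, date: dt.date) -> int:
        """Integer day index of ``date`` (extraction start = day 0)."""
        return (date - self.extraction_start).days

    def offset_date(self, day: int) -> dt.date:
        return self.extraction_start + dt.timedelta(days=int(day))

    def month_index(self, year: int, month: int) -> int:
        """Months elapsed since the extraction-start month."""
        return (year - self.extraction_start.year) * 12 + (
            month - self.extraction_start.month
        )

    def month_index_of_day(self, day: int) -> int:
        d = self.offset_date(day)
        return self.month_index(d.year, d.month)

    @property
    def n_days(self) -> int:
        return self.day_offset(self.extraction_end) + 1

    @property
    def entry_window(self) -> tuple[int, int]:
        """Closed [start, end] entry window in day offsets."""
        return self.day_offset(self.entry_start), self.day_offset(self.entry_end)

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = json.loads(self.model_dump_json())
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


def match_any_prefix(code: str, prefixes: Sequence[str]) -> bool:
    """True if an ICD-10 ``code`` falls under any of the given prefixes.

    Matching is on the dotted representation: "G23" matches "G23", "G23.1";
    "G90.3" matches "G90.3" but not "G90.9".
    """
    code = code.strip().upper()
    for p in prefixes:
        p = p.strip().upper()
        if code == p or code.startswith(p + ".") or (
            "." not in p and code.startswith(p)
        ):
            return True
    return False


def comorbidity_flags(
    codes: Sequence[str], code_map: Mapping[str, Sequence[str]]
) -> dict[str, bool]:
    return {
        name: any(match_any_prefix(c, prefixes) for c in codes)
        for name, prefixes in code_map.items()
    }
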