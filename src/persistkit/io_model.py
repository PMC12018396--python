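"""Claims data model: loading, writing, and validating the five study tables.

A :class:`ClaimsBundle` holds the patients/enrollment, drug-fill, diagnosis,
hospitalization and drug-catalog tables as pandas DataFrames with all dates
normalized to integer day offsets from the extraction-window start (diagnoses
to month indices).  Files are RFC-4180 CSV with ISO-8601 dates; loading is
row-order insensitive because every table is canonically sorted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import StudyConfig

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_year", "first_observed",
                 "last_observed"],
    "fills": ["patient_id", "drug_code", "fill_date", "days_supplied",
              "discharge_flag", "setting"],
    "diagnoses": ["patient_id", "icd10", "year_month"],
    "hospitalizations": ["patient_id", "admit_date", "discharge_date"],
    "drug_catalog": ["drug_code", "name", "class", "atc2", "led_factor",
                     "is_index_candidate"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


class ReferentialError(ValueError):
    """A cross-table reference does not resolve."""


@dataclass
class ClaimsBundle:
    """In-memory study dataset with integer-normalized dates."""

    patients: pd.DataFrame
    fills: pd.DataFrame
    diagnoses: pd.DataFrame
    hospitalizations: pd.DataFrame
    catalog: pd.DataFrame  # indexed by drug_code
    config: StudyConfig

    def counts(self) -> dict[str, int]:
        return {
            "patients": len(self.patients),
            "fills": len(self.fills),
            "diagnoses": len(self.diagnoses),
            "hospitalizations": len(self.hospitalizations),
            "drugs": len(self.catalog),
        }

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            patients=self.patients.copy(),
            fills=self.fills.copy(),
            diagnoses=self.diagnoses.copy(),
            hospitalizations=self.hospitalizations.copy(),
            catalog=self.catalog.copy(),
            config=self.config.model_copy(),
        )

    def canonical(self) -> "ClaimsBundle":
        """Return a copy with every table sorted into canonical order."""
        out = self.copy()
        out.patients = out.patients.sort_values("patient_id").reset_index(drop=True)
        out.fills = out.fills.sort_values(
            ["patient_id", "drug_code", "fill_date", "days_supplied"]
        ).reset_index(drop=True)
        out.diagnoses = out.diagnoses.sort_values(
            ["patient_id", "year_month", "icd10"]
        ).reset_index(drop=True)
        out.hospitalizations = out.hospitalizations.sort_values(
            ["patient_id", "admit_date", "discharge_date"]
        ).reset_index(drop=True)
        out.catalog = out.catalog.sort_index()
        return out


@dataclass
class ValidationIssue:
    table: str
    row: int
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def summary(self) -> str:
        if self.ok:
            return "no invariant violations"
        return "\n".join(
            f"{i.table}[{i.row}]: {i.message}" for i in self.issues
        )


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table '{table}' is missing column(s): {', '.join(missing)}"
        )


def _parse_day(series: pd.Series, config: StudyConfig) -> pd.Series:
    dates = pd.to_datetime(series, format="%Y-%m-%d").dt.date
    start = config.extraction_start
    return dates.map(lambda d: (d - start).days).astype(int)


def _parse_month(series: pd.Series, config: StudyConfig) -> pd.Series:
    parts = series.astype(str).str.split("-", expand=True)
    year = parts[0].astype(int)
    month = parts[1].astype(int)
    return (year - config.extraction_start.year) * 12 + (
        month - config.extraction_start.month
    )


def load_claims(paths: dict[str, str | Path] | str | Path,
                config: StudyConfig) -> ClaimsBundle:
    """Load the five CSV tables into a normalized, cross-checked bundle.

    ``paths`` is either a directory containing ``patients.csv`` etc., or a
    mapping from table name to file path.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ReferentialError
        if a fill references a drug_code absent from the catalog, or a fill
        or diagnosis references an unknown patient_id.
    """
    if not isinstance(paths, dict):
        root = Path(paths)
        paths = {name: root / f"{name}.csv" for name in TABLE_COLUMNS}

    raw = {}
    for name in TABLE_COLUMNS:
        df = pd.read_csv(paths[name], dtype={"patient_id": str}
                         if name != "drug_catalog" else None)
        _require_columns(df, name)
        raw[name] = df

    patients = raw["patients"].copy()
    patients["first_observed"] = _parse_day(patients["first_observed"], config)
    patients["last_observed"] = _parse_day(patients["last_observed"], config)
    patients["birth_year"] = patients["birth_year"].astype(int)

    fills = raw["fills"].copy()
    fills["fill_date"] = _parse_day(fills["fill_date"], config)
    fills["days_supplied"] = fills["days_supplied"].astype(int)
    fills["discharge_flag"] = fills["discharge_flag"].astype(bool)

    diagnoses = raw["diagnoses"].copy()
    diagnoses["year_month"] = _parse_month(diagnoses["year_month"], config)

    hosp = raw["hospitalizations"].copy()
    hosp["admit_date"] = _parse_day(hosp["admit_date"], config)
    hosp["discharge_date"] = _parse_day(hosp["discharge_date"], config)

    catalog = raw["drug_catalog"].copy()
    catalog["is_index_candidate"] = catalog["is_index_candidate"].astype(bool)
    catalog = catalog.set_index("drug_code")

    unknown_drugs = sorted(set(fills["drug_code"]) - set(catalog.index))
    if unknown_drugs:
        raise ReferentialError(
            "fills reference drug_code(s) absent from the catalog: "
            + ", ".join(unknown_drugs)
        )
    known_patients = set(patients["patient_id"])
    for name, df in (("fills", fills), ("diagnoses", diagnoses),
                     ("hospitalizations", hosp)):
        orphans = sorted(set(df["patient_id"]) - known_patients)
        if orphans:
            raise ReferentialError(
                f"{name} reference unknown patient_id(s): "
                + ", ".join(orphans[:10])
            )

    return ClaimsBundle(
        patients=patients, fills=fills, diagnoses=diagnoses,
        hospitalizations=hosp, catalog=catalog, config=config,
    ).canonical()


def write_claims(bundle: ClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle back to canonical CSV files (ISO dates)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = bundle.canonical()
    cfg = b.config

    def iso(days: pd.Series) -> pd.Series:
        return days.map(lambda d: (cfg.extraction_start
                                   + dt.timedelta(days=int(d))).isoformat())

    def ym(months: pd.Series) -> pd.Series:
        def fmt(m: int) -> str:
            total = (cfg.extraction_start.year * 12
                     + cfg.extraction_start.month - 1 + int(m))
            return f"{total // 12:04d}-{total % 12 + 1:02d}"
        return months.map(fmt)

    patients = b.patients.copy()
    patients["first_observed"] = iso(patients["first_observed"])
    patients["last_observed"] = iso(patients["last_observed"])

    fills = b.fills.copy()
    fills["fill_date"] = iso(fills["fill_date"])
    fills["discharge_flag"] = fills["discharge_flag"].astype(bool)

    diagnoses = b.diagnoses.copy()
    diagnoses["year_month"] = ym(diagnoses["year_month"])

    hosp = b.hospitalizations.copy()
    hosp["admit_date"] = iso(hosp["admit_date"])
    hosp["discharge_date"] = iso(hosp["discharge_date"])

    catalog = b.catalog.reset_index()

    written = {}
    for name, df in (("patients", patients), ("fills", fills),
                     ("diagnoses", diagnoses), ("hospitalizations", hosp),
                     ("drug_catalog", catalog)):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, columns=TABLE_COLUMNS[name],
                  lineterminator="\n")
        written[name] = path
    return written


def validate_bundle(bundle: ClaimsBundle) -> ValidationReport:
    """Report invariant violations without mutating the bundle.

    Checks: positive days supplied, fill dates inside the extraction window,
    enrollment and hospitalization interval ordering, diagnosis code syntax.
    """
    report = ValidationReport()
    cfg = bundle.config
    n_days = cfg.n_days

    for row in bundle.fills.itertuples():
        if row.days_supplied < 1:
            report.issues.append(ValidationIssue(
                "fills", row.Index,
                f"days_supplied={row.days_supplied} < 1 "
                f"(patient {row.patient_id}, {row.drug_code})"))
        if not (0 <= row.fill_date < n_days):
            report.issues.append(ValidationIssue(
                "fills", row.Index,
                f"fill_date day {row.fill_date} outside the extraction window "
                f"(patient {row.patient_id})"))
        if row.setting not in ("outpatient", "inpatient"):
            report.issues.append(ValidationIssue(
                "fills", row.Index, f"unknown setting '{row.setting}'"))

    for row in bundle.patients.itertuples():
        if row.first_observed > row.last_observed:
            report.issues.append(ValidationIssue(
                "patients", row.Index,
                f"first_observed > last_observed (patient {row.patient_id})"))
        if row.sex not in ("male", "female"):
            report.issues.append(ValidationIssue(
                "patients", row.Index, f"unknown sex '{row.sex}'"))

    for row in bundle.hospitalizations.itertuples():
        if row.admit_date > row.discharge_date:
            report.issues.append(ValidationIssue(
                "hospitalizations", row.Index,
                f"admit after discharge (patient {row.patient_id})"))

    icd_ok = bundle.diagnoses["icd10"].astype(str).str.match(
        r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")
    for idx in bundle.diagnoses.index[~icd_ok]:
        report.issues.append(ValidationIssue(
            "diagnoses", idx,
            f"malformed ICD-10 code '{bundle.diagnoses.loc[idx, 'icd10']}'"))

    return report
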