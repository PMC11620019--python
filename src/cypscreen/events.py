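"""EHR event tables and analysis periods.

Event streams arrive as flat TSV/CSV files with ISO-8601 dates:

* prescriptions: ``event_id, patient_id, stay_id, day, code, unit``
* labs:          ``event_id, patient_id, day, analyte, kind, value, status``
* patients:      ``patient_id, sex, birth_date``

Tables are held as pandas DataFrames with ``day``/``birth_date`` parsed to
``datetime.date``.  The analyte map links substances to laboratory codes:
a ``dosage`` section (substrate substance → blood-concentration analytes)
and a ``genotyping`` section (genotype-test label → genotyping-act analytes).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .kb import canonical_label

PRESCRIPTION_COLUMNS = ("event_id", "patient_id", "stay_id", "day", "code", "unit")
LAB_COLUMNS = ("event_id", "patient_id", "day", "analyte", "kind", "value", "status")
PATIENT_COLUMNS = ("patient_id", "sex", "birth_date")

LAB_KINDS = ("dosage", "genotyping")
DOSAGE_STATUSES = ("below", "in_range", "above", "unknown")


@dataclass(frozen=True, order=True)
class Period:
    """Closed calendar-date interval [start, end]."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"period start {self.start} after end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "Period":
        """Parse ``YYYY-MM-DD:YYYY-MM-DD``."""
        try:
            a, b = text.split(":")
            return cls(dt.date.fromisoformat(a), dt.date.fromisoformat(b))
        except ValueError as exc:
            raise ConfigurationError(f"bad period {text!r}: {exc}") from None

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]

    def __str__(self) -> str:
        return f"{self.start.isoformat()}:{self.end.isoformat()}"


def _read_table(path: str | Path, columns: tuple[str, ...],
                date_columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in date_columns:
        try:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").dt.date
        except ValueError as exc:
            raise SchemaError(f"{path}: column {col}: unparseable ISO date: {exc}")
    return df


def load_prescriptions(path: str | Path) -> pd.DataFrame:
    return _read_table(path, PRESCRIPTION_COLUMNS, ("day",))


def load_labs(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, LAB_COLUMNS, ("day",))
    bad = sorted(set(df["kind"]) - set(LAB_KINDS))
    if bad:
        raise SchemaError(f"{path}: unknown lab kind(s) {bad}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def load_patients(path: str | Path) -> pd.DataFrame:
    return _read_table(path, PATIENT_COLUMNS, ("birth_date",))


@dataclass(frozen=True)
class AnalyteMap:
    """Substance → lab analyte code mapping.

    ``dosage`` maps a substrate substance (canonical label) to the analyte
    codes of its blood-concentration assays; ``genotyping`` maps a
    genotype-test label (a mutation rule's perpetrator field) to the analyte
    codes under which the genotyping act is recorded.  Lab tests are not
    reliably standardized (e.g. with LOINC), so codes are free-form strings.
    """

    dosage: dict[str, tuple[str, ...]]
    genotyping: dict[str, tuple[str, ...]]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalyteMap":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalyteMap":
        def norm(section: dict | None) -> dict[str, tuple[str, ...]]:
            out: dict[str, tuple[str, ...]] = {}
            for label, codes in (section or {}).items():
                if isinstance(codes, str):
                    codes = [codes]
                out[canonical_label(str(label))] = tuple(str(c) for c in codes)
            return out

        return cls(dosage=norm(raw.get("dosage")), genotyping=norm(raw.get("genotyping")))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "dosage": {k: list(v) for k, v in sorted(self.dosage.items())},
            "genotyping": {k: list(v) for k, v in sorted(self.genotyping.items())},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def genotyping_analytes(self, label: str) -> tuple[str, ...]:
        key = canonical_label(label)
        if key not in self.genotyping:
            raise ConfigurationError(
                f"no genotyping analyte configured for {label!r}"
            )
        return self.genotyping[key]

    def dosage_analytes(self, substrate: str) -> tuple[str, ...]:
        key = canonical_label(substrate)
        if key not in self.dosage:
            raise ConfigurationError(
                f"no dosage analyte configured for substrate {substrate!r}"
            )
        return self.dosage[key]
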