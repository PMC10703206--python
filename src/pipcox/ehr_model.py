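"""Core data model for longitudinal primary-care records.

The analysis consumes four tables exported from a GP information system:
patients (with observation window), drug prescriptions (ATC-coded, with
inclusive start/end dates and a resolved daily dose in mg), ICPC-coded
diagnoses, and free-text journal notes.  This module defines the typed
records, a :class:`Cohort` container around four pandas DataFrames, CSV
readers/writers with row-level validation, and the calendar-age helper
used by age-conditioned prescribing criteria.

Conventions
-----------
* All dates are whole calendar days, serialized ISO 8601 (``YYYY-MM-DD``).
* All intervals are closed ``[start, end]``; two intervals *touch* when
  ``next.start == prev.end + 1 day``.
* Sex is coded ``"F"``/``"M"``.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DateInterval",
    "PatientRecord",
    "Prescription",
    "DiagnosisEvent",
    "JournalNote",
    "Cohort",
    "CohortValidationError",
    "RowError",
    "read_cohort",
    "write_cohort",
    "compute_age",
    "STUDY_START",
    "STUDY_END",
    "TABLE_COLUMNS",
]

#: Default observation window of the study database (8 calendar years).
STUDY_START = date(2007, 1, 1)
STUDY_END = date(2014, 12, 31)

_ICPC_RE = re.compile(r"^[A-Z]\d{2}$")

SEX_VALUES = ("F", "M")
EXIT_REASONS = ("study_end", "death", "left_practice")

TABLE_COLUMNS: Mapping[str, list] = {
    "patients": ["patient_id", "birth_date", "sex", "entry_date", "exit_date", "exit_reason"],
    "prescriptions": ["patient_id", "atc_code", "start_date", "end_date", "daily_dose_mg"],
    "diagnoses": ["patient_id", "icpc_code", "date"],
    "notes": ["patient_id", "date", "icpc_code", "text"],
}


@dataclass(frozen=True, order=True)
class DateInterval:
    """A closed interval of whole calendar days ``[start, end]``."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        """Number of days covered, both endpoints inclusive."""
        return (self.end - self.start).days + 1

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end

    def clip(self, window: "DateInterval") -> Optional["DateInterval"]:
        """Intersection with ``window``, or None when disjoint."""
        lo = max(self.start, window.start)
        hi = min(self.end, window.end)
        if lo > hi:
            return None
        return DateInterval(lo, hi)

    def days(self) -> Iterator[date]:
        d = self.start
        while d <= self.end:
            yield d
            d += timedelta(days=1)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: date
    sex: str  # "F" | "M"
    entry_date: date
    exit_date: date
    exit_reason: str  # study_end | death | left_practice

    @property
    def window(self) -> DateInterval:
        return DateInterval(self.entry_date, self.exit_date)


@dataclass(frozen=True)
class Prescription:
    patient_id: str
    atc_code: str
    start_date: date
    end_date: date
    daily_dose_mg: Optional[float] = None


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    icpc_code: str
    date: date


@dataclass(frozen=True)
class JournalNote:
    patient_id: str
    date: date
    icpc_code: Optional[str]
    text: str


@dataclass(frozen=True)
class RowError:
    """One rejected input row, reported with enough context to find it."""

    table: str
    line: int  # 1-based data-row number (header excluded)
    patient_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table} row {self.line} (patient {self.patient_id!r}): {self.message}"


class CohortValidationError(ValueError):
    """Raised when any input row violates the documented schema."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        lines = "\n".join(str(e) for e in errors[:50])
        more = "" if len(errors) <= 50 else f"\n... and {len(errors) - 50} more"
        super().__init__(f"{len(errors)} invalid row(s):\n{lines}{more}")


@dataclass
class Cohort:
    """The four input tables, held as typed pandas DataFrames.

    Date columns hold ``datetime.date`` objects; ``daily_dose_mg`` is
    float (NaN when absent); the note ``icpc_code`` may be empty string
    for un-coded notes.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    notes: pd.DataFrame

    def patient_records(self) -> list[PatientRecord]:
        return [
            PatientRecord(
                patient_id=r.patient_id,
                birth_date=r.birth_date,
                sex=r.sex,
                entry_date=r.entry_date,
                exit_date=r.exit_date,
                exit_reason=r.exit_reason,
            )
            for r in self.patients.itertuples(index=False)
        ]

    def grouped(self, table: str) -> Mapping[str, pd.DataFrame]:
        """Sub-frames of one table keyed by patient_id (missing -> empty)."""
        df = getattr(self, table)
        return dict(tuple(df.groupby("patient_id", sort=False)))

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def compute_age(birth_date: date, on_date: date) -> int:
    """Completed age in whole years on ``on_date``.

    Uses the birthday-anniversary convention: the age increments on the
    anniversary of the birth date; a Feb-29 birthday anniversaries on
    Mar 1 in non-leap years.
    """
    if on_date < birth_date:
        raise ValueError(f"on_date {on_date} precedes birth_date {birth_date}")
    anniv_m, anniv_d = birth_date.month, birth_date.day
    if (anniv_m, anniv_d) == (2, 29) and not calendar.isleap(on_date.year):
        anniv_m, anniv_d = 3, 1
    age = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (anniv_m, anniv_d):
        age -= 1
    return age


def anniversary_in_year(birth_date: date, year: int) -> date:
    """Birthday anniversary falling in ``year`` (Feb 29 -> Mar 1 rule)."""
    m, d = birth_date.month, birth_date.day
    if (m, d) == (2, 29) and not calendar.isleap(year):
        m, d = 3, 1
    return date(year, m, d)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_date(value, errors, table, line, pid, colname):
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value).strip())
    except (ValueError, TypeError):
        errors.append(RowError(table, line, pid, f"unparseable date in {colname}: {value!r}"))
        return None


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = TABLE_COLUMNS[table]
    if list(df.columns) != expected:
        raise CohortValidationError(
            [RowError(table, 0, "", f"header mismatch: expected {expected}, got {list(df.columns)}")]
        )
    return df


def read_cohort(
    patients_path,
    prescriptions_path,
    diagnoses_path,
    notes_path,
) -> Cohort:
    """Read and validate the four cohort CSVs.

    Every row is checked against the type invariants (date order, ICPC
    pattern, sex/exit-reason codes, non-negative dose).  All violations
    are collected and reported together in a
    :class:`CohortValidationError`; a missing file raises immediately.
    """
    raw = {
        "patients": _read_table(Path(patients_path), "patients"),
        "prescriptions": _read_table(Path(prescriptions_path), "prescriptions"),
        "diagnoses": _read_table(Path(diagnoses_path), "diagnoses"),
        "notes": _read_table(Path(notes_path), "notes"),
    }
    errors: list[RowError] = []

    pat_rows = []
    for i, r in enumerate(raw["patients"].itertuples(index=False), start=1):
        pid = r.patient_id
        bd = _parse_date(r.birth_date, errors, "patients", i, pid, "birth_date")
        en = _parse_date(r.entry_date, errors, "patients", i, pid, "entry_date")
        ex = _parse_date(r.exit_date, errors, "patients", i, pid, "exit_date")
        if r.sex not in SEX_VALUES:
            errors.append(RowError("patients", i, pid, f"sex must be F or M, got {r.sex!r}"))
        if r.exit_reason not in EXIT_REASONS:
            errors.append(RowError("patients", i, pid, f"unknown exit_reason {r.exit_reason!r}"))
        if None not in (en, ex) and en > ex:
            errors.append(RowError("patients", i, pid, f"entry_date {en} after exit_date {ex}"))
        pat_rows.append((pid, bd, r.sex, en, ex, r.exit_reason))

    rx_rows = []
    for i, r in enumerate(raw["prescriptions"].itertuples(index=False), start=1):
        pid = r.patient_id
        st = _parse_date(r.start_date, errors, "prescriptions", i, pid, "start_date")
        en = _parse_date(r.end_date, errors, "prescriptions", i, pid, "end_date")
        if not str(r.atc_code).strip():
            errors.append(RowError("prescriptions", i, pid, "empty atc_code"))
        dose = np.nan
        if str(r.daily_dose_mg).strip():
            try:
                dose = float(r.daily_dose_mg)
            except ValueError:
                errors.append(
                    RowError("prescriptions", i, pid, f"unparseable daily_dose_mg {r.daily_dose_mg!r}")
                )
            else:
                if dose < 0:
                    errors.append(RowError("prescriptions", i, pid, f"negative dose {dose}"))
        if None not in (st, en) and st > en:
            errors.append(RowError("prescriptions", i, pid, f"end_date {en} before start_date {st}"))
        rx_rows.append((pid, r.atc_code, st, en, dose))

    dx_rows = []
    for i, r in enumerate(raw["diagnoses"].itertuples(index=False), start=1):
        pid = r.patient_id
        d = _parse_date(r.date, errors, "diagnoses", i, pid, "date")
        if not _ICPC_RE.match(str(r.icpc_code)):
            errors.append(RowError("diagnoses", i, pid, f"invalid ICPC code {r.icpc_code!r}"))
        dx_rows.append((pid, r.icpc_code, d))

    note_rows = []
    for i, r in enumerate(raw["notes"].itertuples(index=False), start=1):
        pid = r.patient_id
        d = _parse_date(r.date, errors, "notes", i, pid, "date")
        code = str(r.icpc_code).strip()
        if code and not _ICPC_RE.match(code):
            errors.append(RowError("notes", i, pid, f"invalid ICPC code {code!r}"))
        note_rows.append((pid, d, code, r.text))

    if errors:
        raise CohortValidationError(errors)

    return Cohort(
        patients=pd.DataFrame(pat_rows, columns=TABLE_COLUMNS["patients"]),
        prescriptions=pd.DataFrame(rx_rows, columns=TABLE_COLUMNS["prescriptions"]),
        diagnoses=pd.DataFrame(dx_rows, columns=TABLE_COLUMNS["diagnoses"]),
        notes=pd.DataFrame(note_rows, columns=TABLE_COLUMNS["notes"]),
    )


def write_cohort(cohort: Cohort, patients_path, prescriptions_path, diagnoses_path, notes_path) -> None:
    """Write the four tables as UTF-8 CSVs with ISO-8601 dates.

    The output round-trips through :func:`read_cohort` unchanged.
    """
    paths = {
        "patients": patients_path,
        "prescriptions": prescriptions_path,
        "diagnoses": diagnoses_path,
        "notes": notes_path,
    }
    for table, path in paths.items():
        df = getattr(cohort, table).copy()
        for col in df.columns:
            if col.endswith("date") or col == "date":
                df[col] = df[col].map(lambda d: d.isoformat() if isinstance(d, date) else "")
        if "daily_dose_mg" in df.columns:
            df["daily_dose_mg"] = df["daily_dose_mg"].map(
                lambda v: "" if pd.isna(v) else format(float(v), "g")
            )
        df.to_csv(path, index=False, encoding="utf-8")


def empty_cohort() -> Cohort:
    return Cohort(
        **{t: pd.DataFrame(columns=cols) for t, cols in TABLE_COLUMNS.items()}
    )
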