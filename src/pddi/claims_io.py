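"""Reading, validating and calendar-bucketing pharmacy dispensation records.

The atomic record is one pharmacy fill: patient, dispense date, drug (code
and/or name), prescriber, and an optional prescribed daily dose in mg.  The
screen buckets fills into calendar months (:class:`MonthKey`) inside a
:class:`StudyWindow`, normally one calendar year.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

import pandas as pd
import yaml

#: Canonical internal column names for a claims table.
CLAIM_COLUMNS = ["patient_id", "dispense_date", "drug_code", "drug_name",
                 "prescriber_id", "daily_dose_mg"]


class ClaimsError(ValueError):
    """Raised when a claims file cannot be used (I/O or too many rejects)."""


class MonthKey(NamedTuple):
    """A calendar month: (year, month), month in 1..12."""
    year: int
    month: int

    @property
    def index(self) -> int:
        """Months since year 0; adjacent months differ by exactly 1."""
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_index(cls, idx: int) -> "MonthKey":
        return cls(idx // 12, idx % 12 + 1)


def month_of(d: Union[_dt.date, _dt.datetime, pd.Timestamp]) -> MonthKey:
    """Calendar month of a date.  No timezone logic: dates are civil dates."""
    return MonthKey(d.year, d.month)


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive month range analysed, plus the population denominator used
    for prevalence percentages (default: Poland's 2018 national population).
    """
    start: MonthKey
    end: MonthKey
    population_denominator: int = 38_413_139

    def __post_init__(self) -> None:
        for mk in (self.start, self.end):
            if not 1 <= mk.month <= 12:
                raise ValueError(f"month out of range in {mk}")
        if self.start.index > self.end.index:
            raise ValueError("window start is after its end")
        if self.n_months > 120:
            raise ValueError("window longer than 120 months")
        if self.population_denominator <= 0:
            raise ValueError("population denominator must be positive")

    @classmethod
    def year(cls, y: int, population_denominator: int = 38_413_139
             ) -> "StudyWindow":
        return cls(MonthKey(y, 1), MonthKey(y, 12), population_denominator)

    @property
    def n_months(self) -> int:
        return self.end.index - self.start.index + 1

    def __contains__(self, mk: MonthKey) -> bool:
        return self.start.index <= mk.index <= self.end.index


@dataclass(frozen=True)
class DispensationRecord:
    """One drug dispensed to one patient on one date by one prescriber.

    An empty ``prescriber_id`` means "unknown" and never matches another
    prescriber during attribution.  ``daily_dose_mg`` is taken as given (no
    DDD arithmetic) and only matters for dose-conditioned rules.
    """
    patient_id: str
    dispense_date: _dt.date
    drug_code: str = ""
    drug_name: str = ""
    prescriber_id: str = ""
    daily_dose_mg: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.drug_code and not self.drug_name:
            raise ValueError("record needs a drug code or a drug name")
        if self.daily_dose_mg is not None and self.daily_dose_mg < 0:
            raise ValueError("daily_dose_mg must be >= 0")

    @property
    def month(self) -> MonthKey:
        return month_of(self.dispense_date)


@dataclass
class Dialect:
    """Column mapping for a delimited claims file.

    ``columns`` maps canonical field names to the file's column headers;
    unmapped optional fields (dose, prescriber, one of code/name) may be
    absent from the file.
    """
    columns: dict = field(default_factory=dict)
    delimiter: str = ","
    date_format: Optional[str] = None  # None = ISO 8601 / pandas inference

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Dialect":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(columns=doc.get("columns", {}),
                   delimiter=doc.get("delimiter", ","),
                   date_format=doc.get("date_format"))


@dataclass
class ReadReport:
    """Outcome of reading a claims file: valid frame + reject bookkeeping."""
    frame: pd.DataFrame
    rejects: pd.DataFrame  # columns: row (1-based data row), reason
    n_read: int

    @property
    def n_valid(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def read_claims_frame(path: Union[str, Path],
                      dialect: Optional[Dialect] = None,
                      max_reject_fraction: float = 0.10,
                      rejects_path: Optional[Union[str, Path]] = None,
                      ) -> ReadReport:
    """Read a delimited claims file into a validated canonical DataFrame.

    Malformed rows (unparsable date, missing drug, negative dose) are
    counted, reported with their 1-based data-row numbers, optionally written
    to ``rejects_path`` as CSV, and skipped.  More than
    ``max_reject_fraction`` malformed rows is a hard failure.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                          keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ClaimsError(f"cannot read claims file {path}: {exc}") from exc

    for required in ("patient_id", "dispense_date"):
        if dialect.column(required) not in raw.columns:
            raise ClaimsError(
                f"claims file {path} lacks mapped column "
                f"{dialect.column(required)!r} for field {required!r}"
            )

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[dialect.column("patient_id")].str.strip()
    date_raw = raw[dialect.column("dispense_date")].str.strip()
    df["dispense_date"] = pd.to_datetime(
        date_raw, format=dialect.date_format or "ISO8601", errors="coerce")
    for opt in ("drug_code", "drug_name", "prescriber_id"):
        col = dialect.column(opt)
        df[opt] = raw[col].str.strip() if col in raw.columns else ""
    dose_col = dialect.column("daily_dose_mg")
    if dose_col in raw.columns:
        df["daily_dose_mg"] = pd.to_numeric(
            raw[dose_col].replace("", None), errors="coerce")
        bad_dose_text = raw[dose_col].str.strip().ne("") \
            & df["daily_dose_mg"].isna()
    else:
        df["daily_dose_mg"] = float("nan")
        bad_dose_text = pd.Series(False, index=df.index)

    reasons = pd.Series("", index=df.index)
    reasons[df["dispense_date"].isna()] = "invalid date"
    reasons[(df["drug_code"] == "") & (df["drug_name"] == "")] = \
        "missing drug code and name"
    reasons[df["patient_id"] == ""] = "missing patient_id"
    reasons[bad_dose_text] = "non-numeric dose"
    reasons[df["daily_dose_mg"] < 0] = "negative dose"

    bad = reasons != ""
    rejects = pd.DataFrame({
        "row": (df.index[bad] + 1).astype(int),  # 1-based data rows
        "reason": reasons[bad].to_numpy(),
    })
    if rejects_path is not None and len(rejects):
        rejects.to_csv(rejects_path, index=False)
    n_read = len(df)
    if n_read and len(rejects) / n_read > max_reject_fraction:
        raise ClaimsError(
            f"{len(rejects)}/{n_read} malformed rows in {path} exceeds the "
            f"allowed fraction {max_reject_fraction:.0%}"
        )
    return ReadReport(frame=df[~bad].reset_index(drop=True),
                      rejects=rejects, n_read=n_read)


def read_claims(path: Union[str, Path],
                dialect: Optional[Dialect] = None,
                max_reject_fraction: float = 0.10,
                rejects_path: Optional[Union[str, Path]] = None,
                ) -> list[DispensationRecord]:
    """Like :func:`read_claims_frame` but returns record objects."""
    report = read_claims_frame(path, dialect, max_reject_fraction,
                               rejects_path)
    return frame_to_records(report.frame)


def records_to_frame(records: Iterable[DispensationRecord]) -> pd.DataFrame:
    rows = [(r.patient_id, pd.Timestamp(r.dispense_date), r.drug_code,
             r.drug_name, r.prescriber_id,
             float("nan") if r.daily_dose_mg is None else r.daily_dose_mg)
            for r in records]
    return pd.DataFrame(rows, columns=CLAIM_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DispensationRecord]:
    out = []
    for row in frame.itertuples(index=False):
        dose = row.daily_dose_mg
        out.append(DispensationRecord(
            patient_id=row.patient_id,
            dispense_date=pd.Timestamp(row.dispense_date).date(),
            drug_code=row.drug_code, drug_name=row.drug_name,
            prescriber_id=row.prescriber_id,
            daily_dose_mg=None if pd.isna(dose) else float(dose)))
    return out


def write_claims(claims: Union[pd.DataFrame, Iterable[DispensationRecord]],
                 path: Union[str, Path],
                 dialect: Optional[Dialect] = None) -> None:
    """Write claims as CSV in the (possibly renamed) dialect columns."""
    dialect = dialect or Dialect()
    if not isinstance(claims, pd.DataFrame):
        claims = records_to_frame(claims)
    out = claims.copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]) \
        .dt.strftime(dialect.date_format or "%Y-%m-%d")
    out = out.rename(columns={c: dialect.column(c) for c in CLAIM_COLUMNS})
    out.to_csv(path, index=False, sep=dialect.delimiter)


def filter_window(frame: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Drop records dispensed outside the study window."""
    d = pd.to_datetime(frame["dispense_date"])
    idx = d.dt.year * 12 + (d.dt.month - 1)
    keep = (idx >= window.start.index) & (idx <= window.end.index)
    return frame[keep].reset_index(drop=True)
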