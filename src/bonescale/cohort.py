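"""Cohort data model for rated-radiograph records and its CSV reader/writer.

A cohort is an ordered collection of rated radiographs.  Each record carries
the child's sex, city, chronological age (CA, decimal years) and whichever
maturity ratings are available: a Greulich-Pyle bone age (GP BA, years), a
Tanner-Whitehouse Sum Maturity Score (SMS, 0-1000), and up to two TW3 bone
ages (automated and manual) for agreement analysis.  Subject ids need not be
unique: in the cross-sectional design emulated here a child may contribute
radiographs at several anniversary ages.

On disk a cohort is a plain CSV with a mandatory header.  Missing optional
values are empty fields, never sentinel numbers.  Numeric fields are written
at full ``repr`` precision so that write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .errors import CohortFormatError, RowValidationError

__all__ = ["Sex", "SubjectRecord", "Cohort", "read_cohort", "write_cohort"]

#: SMS saturates at full maturity.
SMS_MAX = 1000.0

MANDATORY_COLUMNS = ("subject_id", "sex", "ca")
OPTIONAL_COLUMNS = ("city", "gp_ba", "sms", "tw3_manual", "tw3_auto")
ALL_COLUMNS = ("subject_id", "sex", "city", "ca", "gp_ba", "sms", "tw3_manual", "tw3_auto")


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, token: str) -> "Sex":
        """Parse a sex token: 'male'/'female' (any case) or 'M'/'F'."""
        t = str(token).strip().lower()
        if t in ("male", "m"):
            return cls.MALE
        if t in ("female", "f"):
            return cls.FEMALE
        raise ValueError(f"unknown sex token {token!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One rated radiograph."""

    subject_id: str
    sex: Sex
    ca: float
    city: str = ""
    gp_ba: Optional[float] = None
    sms: Optional[float] = None
    tw3_manual: Optional[float] = None
    tw3_auto: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not self.ca > 0:
            raise ValueError(f"ca must be positive, got {self.ca}")
        if self.gp_ba is not None and not self.gp_ba > 0:
            raise ValueError(f"gp_ba must be positive, got {self.gp_ba}")
        if self.sms is not None and not (0 <= self.sms <= SMS_MAX):
            raise ValueError(f"sms must lie in [0, {SMS_MAX:g}], got {self.sms}")


@dataclass
class Cohort:
    """Ordered collection of :class:`SubjectRecord` with free-text provenance."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def filter(self, sex: Optional[Sex] = None) -> "Cohort":
        recs = [r for r in self.records if sex is None or r.sex == sex]
        return Cohort(recs, provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view; absent optional values become NaN/empty."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "city": [r.city for r in self.records],
                "ca": [r.ca for r in self.records],
                "gp_ba": [r.gp_ba for r in self.records],
                "sms": [r.sms for r in self.records],
                "tw3_manual": [r.tw3_manual for r in self.records],
                "tw3_auto": [r.tw3_auto for r in self.records],
            }
        )


def _parse_optional_float(token: str) -> Optional[float]:
    # Unparseable optional fields are treated as absent, per the data contract.
    if token is None:
        return None
    token = token.strip()
    if not token:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def read_cohort(path: str | Path, delimiter: str = ",") -> Cohort:
    """Read a cohort CSV.

    The header must name at least ``subject_id``, ``sex`` and ``ca``; the
    optional columns ``city``, ``gp_ba``, ``sms``, ``tw3_manual`` and
    ``tw3_auto`` are recognized by name.  Row order is preserved.

    Raises
    ------
    CohortFormatError
        if a mandatory column is missing.
    RowValidationError
        if a row has a non-numeric ``ca``, an unknown sex token, or an
        optional value violating a record invariant (e.g. SMS > 1000).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"mandatory column {col!r} missing from {path}")
    records: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            ca = float(row["ca"])
        except ValueError:
            raise RowValidationError(i, f"non-numeric ca {row['ca']!r}") from None
        try:
            sex = Sex.parse(row["sex"])
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
        optional = {
            name: _parse_optional_float(row.get(name))
            for name in ("gp_ba", "sms", "tw3_manual", "tw3_auto")
        }
        try:
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=sex,
                ca=ca,
                city=str(row.get("city", "") or ""),
                **optional,
            )
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
        records.append(rec)
    return Cohort(records, provenance=str(path))


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort as CSV (header + one row per record, full float precision).

    An empty cohort is an error, not an empty file.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ALL_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.subject_id,
                    r.sex.value,
                    r.city,
                    _fmt(r.ca),
                    _fmt(r.gp_ba),
                    _fmt(r.sms),
                    _fmt(r.tw3_manual),
                    _fmt(r.tw3_auto),
                ]
            )
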