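"""Cohort domain model: subjects, strata, scoring and CSV I/O.

A cohort is a flat table with one row per participant carrying group
membership (``control`` or ``dcm``), sex, age in whole years, the 10-s
grip-and-release test (GRT) repetition count for each hand, and grip
strength in kilograms for each hand (analog dynamometer, 0.5-kg
resolution).

Scoring follows the worse-hand convention: for each test the lower of the
left/right values is the subject's score, reflecting that myelopathic hand
dysfunction is detected by the more affected side.  Subjects are stratified
into eight sex-by-age cells (male/female crossed with 40-59, 60-69, 70-79
and 80-89 years, closed integer intervals) because both tests decline with
age and differ systematically between sexes.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AgeRangeError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

AGE_MIN = 40
AGE_MAX = 89

#: Canonical cohort CSV column order.
CANONICAL_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "age",
    "grt_left",
    "grt_right",
    "grip_left",
    "grip_right",
)

MEASUREMENT_COLUMNS = CANONICAL_COLUMNS[4:]


class Group(str, enum.Enum):
    CONTROL = "control"
    DCM = "dcm"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeBand(str, enum.Enum):
    """Closed integer age intervals used for stratification."""

    B40_59 = "40-59"
    B60_69 = "60-69"
    B70_79 = "70-79"
    B80_89 = "80-89"

    @property
    def bounds(self) -> tuple[int, int]:
        lo, hi = self.value.split("-")
        return int(lo), int(hi)


@dataclass(frozen=True, order=True)
class StratumKey:
    """One of the eight sex-by-age analysis cells."""

    sex: Sex
    age_band: AgeBand

    def label(self) -> str:
        return f"{self.sex.value} {self.age_band.value}"


#: All eight strata in canonical (male first, ascending age) order.
ALL_STRATA: tuple[StratumKey, ...] = tuple(
    StratumKey(sex, band) for sex in Sex for band in AgeBand
)


@dataclass(frozen=True)
class SubjectRecord:
    """Raw bilateral measurements for one participant.

    Invariants (checked by :meth:`validate`, enforced on file load):

    * ``40 <= age <= 89``;
    * GRT counts are nonnegative integers (complete open-close cycles);
    * grip values are nonnegative exact multiples of 0.5 kg.

    Synthetic records generated in ``raw`` mode deliberately bypass the
    quantization invariants (they carry continuous latent values), so
    validation is explicit rather than automatic.
    """

    subject_id: str
    group: Group
    sex: Sex
    age: int
    grt_left: float
    grt_right: float
    grip_left: float
    grip_right: float

    def validate(self) -> "SubjectRecord":
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise AgeRangeError(
                f"subject {self.subject_id!r}: age {self.age} outside "
                f"[{AGE_MIN}, {AGE_MAX}]"
            )
        for name in ("grt_left", "grt_right"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} is negative"
                )
            if float(v) != int(v):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} is not an "
                    "integer repetition count"
                )
        for name in ("grip_left", "grip_right"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} is negative"
                )
            if abs(v * 2 - round(v * 2)) > 1e-9:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} kg is not a "
                    "0.5-kg multiple (check units)"
                )
        return self


@dataclass(frozen=True)
class SubjectScore:
    """Per-subject analysis score: worse-hand minima plus stratum."""

    subject_id: str
    stratum: StratumKey
    group: Group
    grt_min: float
    grip_min: float


def assign_stratum(sex: Sex, age: int) -> StratumKey:
    """Map sex and age in years to the analysis stratum.

    Bands are closed intervals, so ages 59, 60, 89 fall in 40-59, 60-69 and
    80-89 respectively.  Ages outside 40-89 raise :class:`AgeRangeError`.
    """
    for band in AgeBand:
        lo, hi = band.bounds
        if lo <= age <= hi:
            return StratumKey(Sex(sex), band)
    raise AgeRangeError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")


def score_subject(record: SubjectRecord) -> SubjectScore:
    """Reduce bilateral measurements to the per-side minima.

    The lower (worse) hand is used for both tests; the result is symmetric
    under a left/right swap.
    """
    return SubjectScore(
        subject_id=record.subject_id,
        stratum=assign_stratum(record.sex, record.age),
        group=record.group,
        grt_min=min(record.grt_left, record.grt_right),
        grip_min=min(record.grip_left, record.grip_right),
    )


def score_cohort(records: Iterable[SubjectRecord]) -> list[SubjectScore]:
    return [score_subject(r) for r in records]


def _parse_enum(cls, raw, row: int, column: str):
    try:
        return cls(str(raw).strip().lower())
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"row {row}: {column}={raw!r} not one of {{{valid}}}"
        ) from None


def _parse_number(raw, row: int, column: str) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {column}={raw!r} is not numeric") from None
    if v < 0:
        raise ValidationError(f"row {row}: {column}={v} is negative")
    return v


def load_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[SubjectRecord]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path:
        CSV file with a header row, UTF-8, comma separated.
    schema:
        Optional map from canonical column names (``subject_id``, ``group``,
        ``sex``, ``age``, ``grt_left``, ``grt_right``, ``grip_left``,
        ``grip_right``) to the names actually used in the file, so
        third-party exports load without editing.

    Rows with one or more *missing* measurements are rejected and logged
    (no imputation; participants with incomplete test data are excluded
    wholesale).  Rows with *invalid* values — non-numeric, negative,
    non-integer GRT, grip not on the 0.5-kg grid, age outside 40-89 — raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)

    colmap = {c: c for c in CANONICAL_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [colmap[c] for c in CANONICAL_COLUMNS if colmap[c] not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[SubjectRecord] = []
    n_rejected = 0
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based with header line
        values = {c: row[colmap[c]] for c in CANONICAL_COLUMNS}
        blank = [
            c for c in MEASUREMENT_COLUMNS
            if pd.isna(values[c]) or str(values[c]).strip() == ""
        ]
        if blank:
            n_rejected += 1
            logger.warning(
                "row %d (subject %r) rejected: missing %s",
                rownum, values["subject_id"], ", ".join(blank),
            )
            continue
        age_f = _parse_number(values["age"], rownum, "age")
        if age_f != int(age_f):
            raise ValidationError(f"row {rownum}: age={values['age']!r} is not an integer")
        record = SubjectRecord(
            subject_id=str(values["subject_id"]),
            group=_parse_enum(Group, values["group"], rownum, "group"),
            sex=_parse_enum(Sex, values["sex"], rownum, "sex"),
            age=int(age_f),
            grt_left=_parse_number(values["grt_left"], rownum, "grt_left"),
            grt_right=_parse_number(values["grt_right"], rownum, "grt_right"),
            grip_left=_parse_number(values["grip_left"], rownum, "grip_left"),
            grip_right=_parse_number(values["grip_right"], rownum, "grip_right"),
        )
        try:
            record.validate()
        except ValidationError as err:
            raise type(err)(f"row {rownum}: {err}") from None
        records.append(record)
    if n_rejected:
        logger.info("loaded %d records, rejected %d with missing data", len(records), n_rejected)
    return records


def _fmt_count(v: float) -> str:
    # integral GRT counts print as integers; raw-mode latent values keep
    # full float precision
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write records as a canonical cohort CSV (stable column order/format)."""
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group.value,
            "sex": r.sex.value,
            "age": r.age,
            "grt_left": _fmt_count(r.grt_left),
            "grt_right": _fmt_count(r.grt_right),
            "grip_left": repr(float(r.grip_left)),
            "grip_right": repr(float(r.grip_right)),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, index=False)


def schema_json() -> str:
    """JSON description of the canonical cohort columns (for documentation)."""
    spec = {
        "columns": [
            {"name": "subject_id", "type": "string", "description": "opaque identifier"},
            {"name": "group", "type": "enum", "values": ["control", "dcm"]},
            {"name": "sex", "type": "enum", "values": ["male", "female"]},
            {"name": "age", "type": "integer", "unit": "years", "range": [AGE_MIN, AGE_MAX]},
            {"name": "grt_left", "type": "integer", "unit": "repetitions/10 s", "minimum": 0},
            {"name": "grt_right", "type": "integer", "unit": "repetitions/10 s", "minimum": 0},
            {"name": "grip_left", "type": "number", "unit": "kg", "resolution": 0.5, "minimum": 0},
            {"name": "grip_right", "type": "number", "unit": "kg", "resolution": 0.5, "minimum": 0},
        ]
    }
    return json.dumps(spec, indent=2)
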