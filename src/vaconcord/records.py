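"""Domain data model for verbal-autopsy (VA) deaths and cause assignments.

A cohort is a list of :class:`VARecord`: one death with demographics, a
tristate symptom-indicator vector drawn from a declared schema, and a
free-text narrative.  Cause-of-death labels live in a WHO-2012-style
category list (:class:`CauseCategory`); every assignment method (physician
coders, probabilistic engine, consensus, hospital ward, laboratory) emits
:class:`CauseAssignment` rows keyed by ``(record_id, method_id)``.

All tabular I/O is plain CSV (UTF-8, header row mandatory, empty cell =
missing) so that fixtures and pipeline artifacts stay human-readable and
round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "UNDETERMINED",
    "CANNOT_DETERMINE",
    "NOT_SCD",
    "ValidationError",
    "ParseError",
    "VARecord",
    "CauseCategory",
    "CauseAssignment",
    "GoldStandardRecord",
    "DEFAULT_CATEGORIES",
    "default_categories",
    "scd_code",
    "read_cohort",
    "write_cohort",
    "filter_eligible",
    "read_assignments",
    "write_assignments",
    "read_categories",
    "write_categories",
    "validate_assignments",
]

#: Sentinel for a method that produced no determinate underlying cause.
UNDETERMINED = "undetermined"

#: Sentinel for a physician coder who could not make a diagnosis.  Distinct
#: from :data:`UNDETERMINED`: it is an *input* state that never counts as
#: agreement with anything (including another ``cannot_determine``).
CANNOT_DETERMINE = "cannot_determine"

#: Code used by binary (SCD vs not-SCD) gold standards for the negative class.
NOT_SCD = "not_scd"

_SENTINELS = frozenset({UNDETERMINED, CANNOT_DETERMINE, NOT_SCD})

SEXES = ("male", "female", "unknown")
PLACES_OF_DEATH = ("home", "hospital", "elsewhere", "unknown")
TRISTATE = ("yes", "no", "missing")

#: Eligibility window: 28 days to 14 years (inclusive upper bound).
MIN_AGE_DAYS = 28
MAX_AGE_DAYS = 14 * 365


class ValidationError(ValueError):
    """A record, assignment or configuration violates a domain invariant."""


class ParseError(ValueError):
    """A tabular input file is malformed; the message names the offending row."""


@dataclass(frozen=True)
class VARecord:
    """One death: demographics, indicator vector, free-text narrative."""

    record_id: str
    age_days: int
    sex: str = "unknown"
    place_of_death: str = "unknown"
    indicators: Mapping[str, str] = field(default_factory=dict)
    narrative: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be non-empty")
        if self.age_days < 0:
            raise ValidationError(
                f"record {self.record_id!r}: age_days must be non-negative"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"record {self.record_id!r}: bad sex {self.sex!r}")
        if self.place_of_death not in PLACES_OF_DEATH:
            raise ValidationError(
                f"record {self.record_id!r}: bad place_of_death "
                f"{self.place_of_death!r}"
            )
        for key, value in self.indicators.items():
            if value not in TRISTATE:
                raise ValidationError(
                    f"record {self.record_id!r}: indicator {key!r} has "
                    f"non-tristate value {value!r}"
                )

    def with_indicator(self, indicator_id: str, value: str) -> "VARecord":
        """Return a copy with one indicator set (the original is unmodified)."""
        new = dict(self.indicators)
        new[indicator_id] = value
        return replace(self, indicators=new)


@dataclass(frozen=True)
class CauseCategory:
    """A WHO-2012 VA cause-of-death category, e.g. ``4.03`` sickle cell."""

    code: str
    label: str
    is_scd: bool = False


@dataclass(frozen=True)
class CauseAssignment:
    """The underlying cause one method assigned to one death.

    The data model keeps a single underlying cause per (record, method);
    an optional secondary cause may be carried through files but is ignored
    by every statistic, matching the usual analysis unit for VA validation.
    """

    record_id: str
    method_id: str
    cause_code: str
    secondary_cause_code: Optional[str] = None


@dataclass(frozen=True)
class GoldStandardRecord:
    """Reference information for one death: hospital COD and/or genotype."""

    record_id: str
    source: str  # "ward" | "lab"
    ward_cause_code: Optional[str] = None
    phenotype: Optional[str] = None  # HbAA | HbAS | HbSS

    def __post_init__(self) -> None:
        if self.source not in ("ward", "lab"):
            raise ValidationError(f"bad gold-standard source {self.source!r}")
        if self.source == "lab" and self.phenotype not in (None, "HbAA", "HbAS", "HbSS"):
            raise ValidationError(
                f"record {self.record_id!r}: bad phenotype {self.phenotype!r}"
            )

    @property
    def scd_positive(self) -> Optional[bool]:
        """HbSS is the only phenotype counted as sickle cell disease."""
        if self.phenotype is None:
            return None
        return self.phenotype == "HbSS"


# Default WHO-2012-style category list covering the major causes of death
# among children beyond the neonatal period in a rural East African setting.
# Exactly one category carries the SCD flag.
DEFAULT_CATEGORIES: tuple[CauseCategory, ...] = (
    CauseCategory("1.01", "Sepsis (non-obstetric)"),
    CauseCategory("1.02", "Acute respiratory infection, including pneumonia"),
    CauseCategory("1.03", "HIV/AIDS related death"),
    CauseCategory("1.04", "Diarrheal diseases"),
    CauseCategory("1.05", "Malaria"),
    CauseCategory("1.07", "Meningitis and encephalitis"),
    CauseCategory("3.02", "Severe malnutrition"),
    CauseCategory("4.03", "Sickle cell with crisis", is_scd=True),
    CauseCategory("10.06", "Congenital malformation"),
    CauseCategory("98", "Other unspecified non-communicable disease"),
)


def default_categories() -> list[CauseCategory]:
    """Fresh copy of the default cause-category list."""
    return list(DEFAULT_CATEGORIES)


def scd_code(categories: Sequence[CauseCategory] = DEFAULT_CATEGORIES) -> str:
    """Return the unique SCD category code in ``categories``."""
    codes = [c.code for c in categories if c.is_scd]
    if len(codes) != 1:
        raise ValidationError(
            f"category list must flag exactly one SCD cause, found {len(codes)}"
        )
    return codes[0]


_FIXED_COHORT_COLUMNS = ("record_id", "age_days", "sex", "place_of_death", "narrative")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])


def read_cohort(path: str | Path, schema: Sequence[str]) -> list[VARecord]:
    """Read a cohort CSV against a declared indicator schema.

    The header must contain the fixed columns plus exactly the indicator
    columns in ``schema``; unknown indicator columns are rejected so that a
    probbase/schema mismatch surfaces at load time rather than as silently
    ignored symptoms.  Empty indicator cells become ``missing``.
    """
    df = _read_csv(path)
    missing_cols = [c for c in _FIXED_COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    extra = [c for c in df.columns if c not in _FIXED_COHORT_COLUMNS and c not in schema]
    if extra:
        raise ParseError(f"{path}: unknown indicator columns {extra}")
    absent = [c for c in schema if c not in df.columns]
    if absent:
        raise ParseError(f"{path}: schema indicators absent from header: {absent}")

    records: list[VARecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        rid = row_d["record_id"]
        if rid in seen:
            raise ValidationError(f"{path}: duplicate record_id {rid!r} at row {i}")
        seen.add(rid)
        try:
            age = int(row_d["age_days"])
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {i} (record_id {rid!r}): bad age_days "
                f"{row_d['age_days']!r}"
            ) from exc
        indicators = {
            ind: (row_d[ind] if row_d[ind] != "" else "missing") for ind in schema
        }
        records.append(
            VARecord(
                record_id=rid,
                age_days=age,
                sex=row_d["sex"] or "unknown",
                place_of_death=row_d["place_of_death"] or "unknown",
                indicators=indicators,
                narrative=row_d["narrative"],
            )
        )
    return records


def write_cohort(
    records: Iterable[VARecord], path: str | Path, schema: Sequence[str]
) -> None:
    """Write a cohort CSV; ``missing`` indicators become empty cells."""
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "age_days": r.age_days,
            "sex": r.sex,
            "place_of_death": r.place_of_death,
            "narrative": r.narrative,
        }
        for ind in schema:
            v = r.indicators.get(ind, "missing")
            row[ind] = "" if v == "missing" else v
        rows.append(row)
    cols = list(_FIXED_COHORT_COLUMNS) + list(schema)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def filter_eligible(
    cohort: Sequence[VARecord],
    min_age_days: int = MIN_AGE_DAYS,
    max_age_days: int = MAX_AGE_DAYS,
) -> list[VARecord]:
    """Retain deaths aged 28 days to 14 years (both bounds inclusive).

    Idempotent and order-preserving.
    """
    return [r for r in cohort if min_age_days <= r.age_days <= max_age_days]


def read_assignments(path: str | Path) -> list[CauseAssignment]:
    df = _read_csv(path)
    required = ("record_id", "method_id", "cause_code")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out: list[CauseAssignment] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        key = (row_d["record_id"], row_d["method_id"])
        if key in seen:
            raise ValidationError(f"{path}: duplicate (record_id, method_id) {key} at row {i}")
        seen.add(key)
        secondary = row_d.get("secondary_cause_code", "") or None
        out.append(
            CauseAssignment(
                record_id=row_d["record_id"],
                method_id=row_d["method_id"],
                cause_code=row_d["cause_code"],
                secondary_cause_code=secondary,
            )
        )
    return out


def write_assignments(assignments: Iterable[CauseAssignment], path: str | Path) -> None:
    """Write an assignments CSV (round-trips bit-exactly through reading)."""
    rows = [
        {
            "record_id": a.record_id,
            "method_id": a.method_id,
            "cause_code": a.cause_code,
            "secondary_cause_code": a.secondary_cause_code or "",
        }
        for a in assignments
    ]
    cols = ["record_id", "method_id", "cause_code", "secondary_cause_code"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_categories(path: str | Path) -> list[CauseCategory]:
    df = _read_csv(path)
    cats = [
        CauseCategory(code=r["code"], label=r["label"], is_scd=r["is_scd"] == "true")
        for r in df.to_dict("records")
    ]
    codes = [c.code for c in cats]
    if len(set(codes)) != len(codes):
        raise ValidationError(f"{path}: duplicate category codes")
    return cats


def write_categories(categories: Iterable[CauseCategory], path: str | Path) -> None:
    rows = [
        {"code": c.code, "label": c.label, "is_scd": "true" if c.is_scd else "false"}
        for c in categories
    ]
    pd.DataFrame(rows, columns=["code", "label", "is_scd"]).to_csv(path, index=False)


def validate_assignments(
    assignments: Sequence[CauseAssignment],
    categories: Sequence[CauseCategory],
    allow_sentinels: bool = True,
) -> None:
    """Check every cause code against the category list (plus sentinels)."""
    valid = {c.code for c in categories}
    if allow_sentinels:
        valid |= _SENTINELS
    for a in assignments:
        if a.cause_code not in valid:
            raise ValidationError(
                f"assignment ({a.record_id}, {a.method_id}): unknown cause "
                f"code {a.cause_code!r}"
            )
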