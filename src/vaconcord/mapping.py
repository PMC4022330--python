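"""ICD-10 → WHO-2012 VA cause-category mapping and free-text SCD detection.

Physician coders and hospital physicians assign ICD-10 codes; the
probabilistic engine works on the WHO-2012 VA category list.  This module
collapses ICD-10 codes onto those categories through a replaceable lookup
table, and implements the automated free-text screen for sickle cell
disease ("sickle OR scd") used to populate the SCD indicator when the
questionnaire itself carries no SCD item.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import CauseAssignment, ValidationError

__all__ = [
    "CauseMap",
    "DEFAULT_CAUSE_MAP",
    "default_cause_map",
    "load_cause_map",
    "save_cause_map",
    "map_icd10",
    "map_assignments",
    "extract_scd_indicator",
]

logger = logging.getLogger(__name__)

#: Fallback category for ICD-10 codes absent from the map: "other
#: unspecified non-communicable disease".
FALLBACK_CODE = "98"

# "sickle" as a bare substring (so "sickler", "sickle-cell" match);
# "scd" only at word boundaries so e.g. "miSCoDed" cannot match.
_SICKLE_RE = re.compile(r"sickle", re.IGNORECASE)
_SCD_RE = re.compile(r"\bscd\b", re.IGNORECASE)


@dataclass
class CauseMap:
    """Total mapping from ICD-10 codes onto WHO-2012 VA categories.

    Totality is guaranteed by the fallback: any code absent from
    ``entries`` maps to ``fallback`` (and is counted, so a run log can
    report how much of the input fell through).
    """

    entries: Mapping[str, str]
    fallback: str = FALLBACK_CODE
    unmapped_seen: dict[str, int] = field(default_factory=dict)


# Reconstruction of a typical pediatric ICD-10 → WHO-2012 crosswalk for the
# category set used throughout this package.  It is a faithful stand-in for
# the kind of study-specific mapping table a VA validation uses, not a copy
# of any published supplementary table; replace via ``load_cause_map``.
DEFAULT_CAUSE_MAP_ENTRIES: dict[str, str] = {
    # Sickle cell disorders
    "D57": "4.03",
    "D57.0": "4.03",
    "D57.1": "4.03",
    "D57.2": "4.03",
    # Malaria
    "B50": "1.05",
    "B51": "1.05",
    "B52": "1.05",
    "B54": "1.05",
    # Pneumonia / acute respiratory infection
    "J12": "1.02",
    "J13": "1.02",
    "J15": "1.02",
    "J18": "1.02",
    "J22": "1.02",
    # HIV/AIDS
    "B20": "1.03",
    "B21": "1.03",
    "B22": "1.03",
    "B23": "1.03",
    "B24": "1.03",
    # Diarrheal diseases
    "A00": "1.04",
    "A03": "1.04",
    "A08": "1.04",
    "A09": "1.04",
    # Meningitis / encephalitis
    "G00": "1.07",
    "G03": "1.07",
    "G04": "1.07",
    "A87": "1.07",
    # Severe malnutrition
    "E40": "3.02",
    "E41": "3.02",
    "E42": "3.02",
    "E43": "3.02",
    "E46": "3.02",
    # Sepsis
    "A40": "1.01",
    "A41": "1.01",
    # Congenital malformations
    "Q03": "10.06",
    "Q05": "10.06",
    "Q24": "10.06",
    "Q89": "10.06",
    "Q90": "10.06",
    # Ill-defined / other
    "R95": "98",
    "R99": "98",
}

DEFAULT_CAUSE_MAP = CauseMap(entries=dict(DEFAULT_CAUSE_MAP_ENTRIES))


def default_cause_map() -> CauseMap:
    """Fresh copy of the shipped default mapping."""
    return CauseMap(entries=dict(DEFAULT_CAUSE_MAP_ENTRIES))


def load_cause_map(path: str | Path, fallback: str = FALLBACK_CODE) -> CauseMap:
    """Load a user mapping CSV with columns ``icd10_code, who2012_code``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("icd10_code", "who2012_code"):
        if col not in df.columns:
            raise ValidationError(f"{path}: cause-map file missing column {col!r}")
    entries = dict(zip(df["icd10_code"], df["who2012_code"]))
    return CauseMap(entries=entries, fallback=fallback)


def save_cause_map(cause_map: CauseMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(cause_map.entries.items()), columns=["icd10_code", "who2012_code"]
    ).to_csv(path, index=False)


def map_icd10(code: str, cause_map: CauseMap = DEFAULT_CAUSE_MAP) -> str:
    """Map one ICD-10 code to its WHO-2012 VA category.

    Deterministic lookup; an unmapped code falls back to category ``98``
    (other unspecified) with a logged warning, so mapping never drops a
    record.  Tries the exact code first, then its three-character block
    (``D57.1`` → ``D57``).
    """
    if not code:
        raise ValidationError("empty ICD-10 code")
    if code in cause_map.entries:
        return cause_map.entries[code]
    block = code.split(".")[0]
    if block in cause_map.entries:
        return cause_map.entries[block]
    cause_map.unmapped_seen[code] = cause_map.unmapped_seen.get(code, 0) + 1
    logger.warning("ICD-10 code %r not in cause map; using fallback %r", code, cause_map.fallback)
    return cause_map.fallback


def map_assignments(
    assignments: Iterable[CauseAssignment],
    cause_map: CauseMap = DEFAULT_CAUSE_MAP,
    sentinels: tuple[str, ...] = ("undetermined", "cannot_determine"),
) -> list[CauseAssignment]:
    """Map a whole assignment table, passing sentinels through untouched."""
    out = []
    for a in assignments:
        code = a.cause_code if a.cause_code in sentinels else map_icd10(a.cause_code, cause_map)
        secondary = (
            None
            if a.secondary_cause_code is None
            else a.secondary_cause_code
            if a.secondary_cause_code in sentinels
            else map_icd10(a.secondary_cause_code, cause_map)
        )
        out.append(
            CauseAssignment(
                record_id=a.record_id,
                method_id=a.method_id,
                cause_code=code,
                secondary_cause_code=secondary,
            )
        )
    return out


def extract_scd_indicator(narrative: str) -> bool:
    """Automated free-text screen for sickle cell disease.

    True iff the narrative contains "sickle" (any casing, as a substring,
    so "sickler" and "sickle-cell" match) or the standalone token "scd".
    """
    if not narrative:
        return False
    text = narrative.strip()
    return bool(_SICKLE_RE.search(text) or _SCD_RE.search(text))
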