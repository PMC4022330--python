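"""Physician-coder consensus resolution.

Two independent clinicians code every VA.  A cause is assigned when two
clinicians agree; on disagreement, or when a coder cannot make a
diagnosis, a third clinician is consulted; if the three still disagree the
case goes to arbitration.  Arbitration was a human meeting, so here it is
an optional external table — without it, unresolved cases come out as
``undetermined`` and are flagged, never raised.

``cannot_determine`` is a distinct sentinel that never agrees with
anything, including itself: two non-diagnoses still mean referral.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import CANNOT_DETERMINE, UNDETERMINED, CauseAssignment, CauseCategory, ValidationError
from .agreement import ContingencyTable, contingency_from_assignments

__all__ = ["ConsensusResult", "resolve", "resolve_cohort", "intercoder_table"]

TWO_AGREE = "two_agree"
THIRD_BREAKS_TIE = "third_breaks_tie"
ARBITRATION_REQUIRED = "arbitration_required"


@dataclass(frozen=True)
class ConsensusResult:
    record_id: str
    cause_code: str  # a category code or UNDETERMINED
    resolution_path: str  # two_agree | third_breaks_tie | arbitration_required


def _determinate(code: Optional[str]) -> bool:
    return code is not None and code != CANNOT_DETERMINE


def resolve(
    coder1: str,
    coder2: str,
    coder3: Optional[str] = None,
    arbitration: Optional[str] = None,
    record_id: str = "",
) -> ConsensusResult:
    """Resolve one record's consensus cause from up to three coders.

    Resolution order: (a) the two primary coders agree on a determinate
    cause; (b) a third coder matches either primary coder's determinate
    cause; (c) an externally supplied arbitration cause; otherwise
    ``undetermined`` with ``arbitration_required``.  The output cause is
    always one of the inputs — consensus never invents a code — and the
    rule is symmetric in the two primary coders.
    """
    if _determinate(coder1) and coder1 == coder2:
        return ConsensusResult(record_id, coder1, TWO_AGREE)
    if _determinate(coder3) and (coder3 in (coder1, coder2)):
        return ConsensusResult(record_id, coder3, THIRD_BREAKS_TIE)
    if arbitration is not None and _determinate(arbitration):
        return ConsensusResult(record_id, arbitration, ARBITRATION_REQUIRED)
    return ConsensusResult(record_id, UNDETERMINED, ARBITRATION_REQUIRED)


def resolve_cohort(
    coder1: Sequence[CauseAssignment],
    coder2: Sequence[CauseAssignment],
    coder3: Optional[Sequence[CauseAssignment]] = None,
    arbitration: Optional[Mapping[str, str]] = None,
    method_id: str = "consensus",
) -> tuple[list[CauseAssignment], Counter]:
    """Resolve a whole cohort; returns assignments plus a path summary.

    The two primary coders must cover the same record set; the third coder
    and the arbitration table may be partial.
    """
    by1 = {a.record_id: a.cause_code for a in coder1}
    by2 = {a.record_id: a.cause_code for a in coder2}
    if set(by1) != set(by2):
        raise ValidationError("coder1 and coder2 must cover the same record set")
    by3 = {a.record_id: a.cause_code for a in coder3} if coder3 else {}
    arb = dict(arbitration) if arbitration else {}

    out: list[CauseAssignment] = []
    paths: Counter = Counter()
    for a in coder1:
        rid = a.record_id
        res = resolve(by1[rid], by2[rid], by3.get(rid), arb.get(rid), record_id=rid)
        paths[res.resolution_path] += 1
        out.append(CauseAssignment(rid, method_id, res.cause_code))
    return out, paths


def intercoder_table(
    coder1: Sequence[CauseAssignment],
    coder2: Sequence[CauseAssignment],
    categories: Sequence[CauseCategory],
) -> ContingencyTable:
    """Q×Q cross-tabulation of the two primary coders over one cohort.

    Records where either coder holds a sentinel (cannot-determine /
    undetermined) are excluded pairwise, so cells sum to the number of
    jointly determinate records.
    """
    table, _ = contingency_from_assignments(coder1, coder2, categories)
    return table
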