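"""Diagnostic validity against a gold standard, and mortality fractions.

Per-cause one-vs-rest confusion counts (sensitivity, specificity, PPV,
NPV), cause-specific mortality fractions (CSMFs), the binary laboratory
gold standard (HbSS genotype = sickle cell disease), and the demographic
back-of-envelope for the expected share of child deaths due to SCD.

A metric with a zero denominator is reported as ``None`` ("undefined"),
never as 0.  Full precision is kept internally; rounding to integer
percentages happens only in report formatting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .records import (
    CANNOT_DETERMINE,
    NOT_SCD,
    UNDETERMINED,
    CauseAssignment,
    CauseCategory,
    GoldStandardRecord,
    ValidationError,
)
from ._util import round_half_up

__all__ = [
    "ValidityResult",
    "CSMFVector",
    "validity",
    "lab_gold_standard",
    "csmf",
    "csmf_delta",
    "expected_scd_death_share",
    "reconstruct_confusion_tables",
]

_SENTINELS = (UNDETERMINED, CANNOT_DETERMINE)


@dataclass(frozen=True)
class ValidityResult:
    """One-vs-rest confusion counts and the four validity metrics."""

    cause: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return self.tn / d if d else None


def validity(
    pred: Sequence[CauseAssignment],
    gold: Sequence[CauseAssignment],
    cause: str,
) -> ValidityResult:
    """One-vs-rest validity of ``pred`` against ``gold`` for one cause.

    Both methods must cover the same record set and the gold standard must
    be fully determinate.  An undetermined prediction counts as negative
    for the cause under test: the question is whether the cause was
    mentioned, and a non-diagnosis did not mention it.
    """
    by_p = {a.record_id: a.cause_code for a in pred}
    by_g = {a.record_id: a.cause_code for a in gold}
    if not by_g:
        raise ValidationError("empty record set")
    if set(by_p) != set(by_g):
        raise ValidationError("prediction and gold standard must cover the same records")
    for rid, code in by_g.items():
        if code in _SENTINELS:
            raise ValidationError(f"gold standard has undetermined entry for {rid!r}")
    tp = fp = fn = tn = 0
    for rid, g in by_g.items():
        p_pos = by_p[rid] == cause
        g_pos = g == cause
        if p_pos and g_pos:
            tp += 1
        elif p_pos:
            fp += 1
        elif g_pos:
            fn += 1
        else:
            tn += 1
    return ValidityResult(cause=cause, tp=tp, fp=fp, fn=fn, tn=tn)


def lab_gold_standard(
    lab_records: Sequence[GoldStandardRecord],
    scd_cause: str = "4.03",
    method_id: str = "lab",
) -> list[CauseAssignment]:
    """Binary SCD gold standard from hemoglobin phenotypes.

    HbSS is counted as SCD-positive; HbAA and HbAS (carriers are not
    diseased) as negative.  A record without a phenotype is dropped —
    genotype can adjudicate SCD status only, never the non-SCD cause, so
    the output is deliberately binary (``scd_cause`` vs :data:`NOT_SCD`).
    """
    out = []
    for r in lab_records:
        if r.phenotype is None:
            continue
        code = scd_cause if r.phenotype == "HbSS" else NOT_SCD
        out.append(CauseAssignment(r.record_id, method_id, code))
    return out


@dataclass(frozen=True)
class CSMFVector:
    """Cause-specific mortality fractions over determinate assignments."""

    fractions: Mapping[str, float]
    n_total: int
    n_undetermined: int


def csmf(
    assignments: Sequence[CauseAssignment],
    categories: Optional[Sequence[CauseCategory]] = None,
) -> CSMFVector:
    """CSMF per cause; undetermined deaths are counted separately.

    If ``categories`` is given, every listed cause appears in the output
    (zero-count causes included) and unknown codes raise.
    """
    counts: dict[str, int] = {}
    if categories is not None:
        counts = {c.code: 0 for c in categories}
    n_und = 0
    n_det = 0
    for a in assignments:
        if a.cause_code in _SENTINELS:
            n_und += 1
            continue
        if categories is not None and a.cause_code not in counts:
            raise ValidationError(f"cause code {a.cause_code!r} not in category list")
        counts[a.cause_code] = counts.get(a.cause_code, 0) + 1
        n_det += 1
    fractions = {
        code: (count / n_det if n_det else 0.0) for code, count in counts.items()
    }
    return CSMFVector(
        fractions=fractions, n_total=n_det + n_und, n_undetermined=n_und
    )


def csmf_delta(csmf_a: CSMFVector, csmf_b: CSMFVector) -> dict[str, float]:
    """Per-cause difference in percentage points (antisymmetric)."""
    if set(csmf_a.fractions) != set(csmf_b.fractions):
        raise ValidationError("CSMF vectors cover different category lists")
    return {
        code: 100.0 * (csmf_a.fractions[code] - csmf_b.fractions[code])
        for code in csmf_a.fractions
    }


def expected_scd_death_share(
    birth_prevalence: float,
    case_fatality_under5: float,
    cumulative_child_mortality: float,
) -> float:
    """Expected fraction of child deaths attributable to SCD.

    If a fraction ``birth_prevalence`` of births are affected, a fraction
    ``case_fatality_under5`` of those children die in early childhood, and
    cumulative all-cause childhood mortality is
    ``cumulative_child_mortality``, then SCD's expected share of deaths is
    birth_prevalence × case_fatality / cumulative_mortality.  With 0.8%
    affected births, 50% early-life case fatality and 40/1000 cumulative
    mortality this is 10%.
    """
    for name, v in (
        ("birth_prevalence", birth_prevalence),
        ("case_fatality_under5", case_fatality_under5),
        ("cumulative_child_mortality", cumulative_child_mortality),
    ):
        if not 0.0 < v <= 1.0:
            raise ValidationError(f"{name} = {v} outside (0, 1]")
    return birth_prevalence * case_fatality_under5 / cumulative_child_mortality


def reconstruct_confusion_tables(
    n: int,
    sensitivity_pct: int,
    specificity_pct: int,
    ppv_pct: int,
    npv_pct: int,
    marginal_range: tuple[int, int] = (4, 10),
) -> list[ValidityResult]:
    """All 2×2 tables consistent with rounded published validity metrics.

    Enumerates integer tables with both the gold-positive and the
    predicted-positive marginal inside ``marginal_range`` and returns
    those whose four metrics round (half-up) to the given integer
    percentages.  Used to check that a printed sensitivity/specificity/
    PPV/NPV row is arithmetically consistent with a small-prevalence 2×2
    table at the stated n — a consistency search, not asserted ground
    truth.
    """
    lo, hi = marginal_range
    hits = []
    for gold_pos, pred_pos in itertools.product(range(lo, hi + 1), repeat=2):
        for tp in range(0, min(gold_pos, pred_pos) + 1):
            fn = gold_pos - tp
            fp = pred_pos - tp
            tn = n - tp - fn - fp
            if tn < 0:
                continue
            r = ValidityResult("", tp=tp, fp=fp, fn=fn, tn=tn)
            metrics = (r.sensitivity, r.specificity, r.ppv, r.npv)
            targets = (sensitivity_pct, specificity_pct, ppv_pct, npv_pct)
            if any(m is None for m in metrics):
                continue
            if all(
                round_half_up(100.0 * m) == t for m, t in zip(metrics, targets)
            ):
                hits.append(r)
    return hits
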