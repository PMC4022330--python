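"""Gwet's AC1 chance-corrected agreement coefficient.

Cohen's kappa collapses when one category is very rare even though raters
almost always agree (the prevalence paradox) — exactly the situation for a
~5% cause of death like sickle cell disease.  AC1 corrects for chance with
a "hard to classify" weighting of the marginal probabilities and stays
high when observed agreement is high at extreme prevalence.

For a Q×Q cross-tabulation with cell proportions ``p_ql`` over ``n``
subjects and two raters:

    pa  = sum_q p_qq                       (observed agreement)
    pi_q = (p_{q.} + p_{.q}) / 2           (mean marginal)
    pe  = (1/(Q-1)) sum_q pi_q (1 - pi_q)  (chance agreement)
    AC1 = (pa - pe) / (1 - pe)

The standard error uses the subject-level linearization: with per-subject
agreement indicator ``pa_i`` and chance component
``pe_i = ((1-pi_k) + (1-pi_l)) / (2(Q-1))`` for a subject rated (k, l),

    g_i  = (pa_i - pe) / (1 - pe)
    g*_i = g_i - 2 (1 - AC1) (pe_i - pe) / (1 - pe)
    var  = sum_i (g*_i - AC1)^2 / (n (n-1))

and the 95% CI is ``AC1 ± t_{n-1,0.975} · SE`` truncated above at 1.  A
delete-one jackknife is provided as an independent variance cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    CANNOT_DETERMINE,
    UNDETERMINED,
    CauseAssignment,
    CauseCategory,
    ValidationError,
)

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "MethodComparison",
    "ac1",
    "jackknife_se",
    "cohens_kappa",
    "contingency_from_assignments",
    "cause_specific_table",
    "compare_methods",
    "population_ac1",
]

_EXCLUDED = (UNDETERMINED, CANNOT_DETERMINE)


@dataclass(frozen=True)
class ContingencyTable:
    """Q×Q cross-tabulation of two assignment methods over one cohort."""

    categories: tuple[str, ...]
    counts: np.ndarray  # Q×Q non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        q = len(self.categories)
        if q < 2:
            raise ValidationError("contingency table needs Q >= 2 categories")
        if counts.shape != (q, q):
            raise ValidationError(
                f"counts shape {counts.shape} does not match Q={q}"
            )
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.categories, self.counts.T.copy())


@dataclass(frozen=True)
class AgreementResult:
    ac1: float
    pa: float
    pe: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def _pa_pe(p: np.ndarray, q: int) -> tuple[float, float, np.ndarray]:
    pa = float(np.trace(p))
    pi = (p.sum(axis=0) + p.sum(axis=1)) / 2.0
    pe = float((pi * (1.0 - pi)).sum() / (q - 1))
    return pa, pe, pi


def ac1(table: ContingencyTable) -> AgreementResult:
    """Gwet's AC1 with linearization SE and t-based 95% CI."""
    n = table.n
    if n < 2:
        raise ValidationError("AC1 requires n >= 2 subjects")
    q = len(table.categories)
    p = table.counts / n
    pa, pe, pi = _pa_pe(p, q)
    if 1.0 - pe < 1e-12:
        raise ValidationError("degenerate table: chance agreement pe = 1")
    gamma = (pa - pe) / (1.0 - pe)

    # Subject-level linearized variance, vectorized over cells: every
    # subject in cell (k, l) contributes the same influence value.
    pa_i = np.eye(q)
    pe_i = ((1.0 - pi)[:, None] + (1.0 - pi)[None, :]) / (2.0 * (q - 1))
    g_i = (pa_i - pe) / (1.0 - pe)
    g_star = g_i - 2.0 * (1.0 - gamma) * (pe_i - pe) / (1.0 - pe)
    var = float((table.counts * (g_star - gamma) ** 2).sum() / (n * (n - 1)))
    se = float(np.sqrt(max(var, 0.0)))

    t = float(stats.t.ppf(0.975, n - 1))
    ci_low = gamma - t * se
    ci_high = min(1.0, gamma + t * se)
    return AgreementResult(
        ac1=gamma, pa=pa, pe=pe, se=se, ci_low=ci_low, ci_high=ci_high, n=n
    )


def jackknife_se(table: ContingencyTable) -> float:
    """Delete-one jackknife SE of AC1 (independent variance cross-check)."""
    n = table.n
    if n < 2:
        raise ValidationError("jackknife requires n >= 2")
    q = len(table.categories)
    ks, ls = np.nonzero(table.counts)
    estimates = []
    weights = []
    for k, l in zip(ks, ls):
        counts = table.counts.copy()
        counts[k, l] -= 1
        p = counts / (n - 1)
        pa, pe, _ = _pa_pe(p, q)
        estimates.append((pa - pe) / (1.0 - pe))
        weights.append(table.counts[k, l])
    est = np.asarray(estimates, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float((w * est).sum() / n)
    var = (n - 1) / n * float((w * (est - mean) ** 2).sum())
    return float(np.sqrt(var))


def cohens_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa, kept only as a contrast column in reports."""
    n = table.n
    p = table.counts / n
    pa = float(np.trace(p))
    pe = float((p.sum(axis=0) * p.sum(axis=1)).sum())
    if 1.0 - pe < 1e-12:
        raise ValidationError("degenerate table: kappa undefined (pe = 1)")
    return (pa - pe) / (1.0 - pe)


def _paired_codes(
    method_a: Sequence[CauseAssignment], method_b: Sequence[CauseAssignment]
) -> tuple[list[tuple[str, str]], int]:
    by_a = {a.record_id: a.cause_code for a in method_a}
    by_b = {b.record_id: b.cause_code for b in method_b}
    if set(by_a) != set(by_b):
        raise ValidationError("methods must cover the same record set")
    pairs = []
    excluded = 0
    for rid in by_a:
        ca, cb = by_a[rid], by_b[rid]
        if ca in _EXCLUDED or cb in _EXCLUDED:
            excluded += 1
            continue
        pairs.append((ca, cb))
    return pairs, excluded


def contingency_from_assignments(
    method_a: Sequence[CauseAssignment],
    method_b: Sequence[CauseAssignment],
    categories: Sequence[CauseCategory],
) -> tuple[ContingencyTable, int]:
    """All-cause Q×Q table; sentinel records are excluded pairwise.

    Returns the table plus the pairwise exclusion count (for the run log,
    so every denominator can be reconstructed).
    """
    codes = tuple(c.code for c in categories)
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=int)
    pairs, excluded = _paired_codes(method_a, method_b)
    for ca, cb in pairs:
        if ca not in index:
            raise ValidationError(f"cause code {ca!r} not in category list")
        if cb not in index:
            raise ValidationError(f"cause code {cb!r} not in category list")
        counts[index[ca], index[cb]] += 1
    return ContingencyTable(codes, counts), excluded


def cause_specific_table(
    method_a: Sequence[CauseAssignment],
    method_b: Sequence[CauseAssignment],
    cause: str,
) -> tuple[ContingencyTable, int]:
    """One-vs-rest 2×2 table for a single cause ("mentioned or not").

    Sentinel records are excluded pairwise; n reflects the exclusions.
    """
    pairs, excluded = _paired_codes(method_a, method_b)
    counts = np.zeros((2, 2), dtype=int)
    for ca, cb in pairs:
        counts[0 if ca == cause else 1, 0 if cb == cause else 1] += 1
    return ContingencyTable((cause, f"not_{cause}"), counts), excluded


@dataclass(frozen=True)
class MethodComparison:
    all_cause: AgreementResult
    per_cause: Mapping[str, AgreementResult]
    n_excluded: int


def compare_methods(
    method_a: Sequence[CauseAssignment],
    method_b: Sequence[CauseAssignment],
    categories: Sequence[CauseCategory],
    causes: Sequence[str] = (),
) -> MethodComparison:
    """All-cause AC1 plus one binary (one-vs-rest) AC1 per requested cause."""
    table, excluded = contingency_from_assignments(method_a, method_b, categories)
    per_cause = {}
    for cause in causes:
        t2, _ = cause_specific_table(method_a, method_b, cause)
        per_cause[cause] = ac1(t2)
    return MethodComparison(all_cause=ac1(table), per_cause=per_cause, n_excluded=excluded)


def population_ac1(joint: np.ndarray) -> float:
    """Population AC1 implied by an exact joint category distribution.

    ``joint[q, l]`` is P(rater A says q, rater B says l); used as the
    closed-form target for Monte-Carlo envelope checks on simulated
    cohorts.
    """
    joint = np.asarray(joint, dtype=float)
    if abs(joint.sum() - 1.0) > 1e-9:
        raise ValidationError("joint distribution must sum to 1")
    q = joint.shape[0]
    pa, pe, _ = _pa_pe(joint, q)
    return (pa - pe) / (1.0 - pe)
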