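"""Probabilistic cause-of-death assignment from indicator vectors.

A naive-Bayes classifier in the style of the InterVA family of tools: a
"probbase" supplies a prior probability per cause and a conditional
probability P(indicator = yes | cause) for every (indicator, cause) pair,
and the posterior for a record is

    posterior(c)  ∝  P(c) · Π_{s answered yes} P(s = yes | c)

renormalized over causes.  Only "yes" responses enter the likelihood;
"no" and "missing" are treated as uninformative.  This is deliberately a
simplified engine: it does not reproduce the distributed InterVA-4
program's letter-graded probbase, its three-cause output, or its
HIV/malaria prevalence presets — the probbase here is wholly user
configuration.

The free-text channel is wired in through :func:`inject_scd_indicator`,
which sets the ``scd_mention`` indicator from the narrative screen
("sickle OR scd") before assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import extract_scd_indicator
from .records import UNDETERMINED, CauseAssignment, VARecord, ValidationError

__all__ = [
    "Probbase",
    "PosteriorResult",
    "SCD_MENTION",
    "DEFAULT_THRESHOLD",
    "load_probbase",
    "save_probbase",
    "assign_probabilistic",
    "assign_cohort",
    "inject_scd_indicator",
]

#: Indicator carrying the free-text sickle-cell screen.
SCD_MENTION = "scd_mention"

#: Below this top-posterior the engine reports ``undetermined`` instead of
#: committing to a cause.
DEFAULT_THRESHOLD = 0.4

#: Probabilities are clamped to [EPS, 1-EPS] at load time so posteriors
#: stay finite even for a probbase with hard zeros.
EPS = 1e-6


@dataclass(frozen=True)
class Probbase:
    """Cause priors plus per-cause conditional indicator probabilities."""

    causes: tuple[str, ...]
    prior: Mapping[str, float]
    conditional: Mapping[tuple[str, str], float]  # (indicator_id, cause) -> P(yes|cause)
    indicators: tuple[str, ...]

    def __post_init__(self) -> None:
        total = sum(self.prior[c] for c in self.causes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probbase priors sum to {total}, not 1")
        for c in self.causes:
            if not 0.0 < self.prior[c] < 1.0:
                raise ValidationError(f"prior for cause {c!r} outside (0, 1)")
        for ind in self.indicators:
            for c in self.causes:
                if (ind, c) not in self.conditional:
                    raise ValidationError(
                        f"probbase missing conditional for ({ind!r}, {c!r})"
                    )
                v = self.conditional[(ind, c)]
                if not 0.0 < v < 1.0:
                    raise ValidationError(
                        f"conditional P({ind!r}|{c!r}) = {v} outside (0, 1)"
                    )

    @classmethod
    def from_arrays(
        cls,
        causes: Sequence[str],
        priors: Sequence[float],
        indicators: Sequence[str],
        cond: np.ndarray,  # shape (n_indicators, n_causes)
    ) -> "Probbase":
        cond = np.clip(np.asarray(cond, dtype=float), EPS, 1.0 - EPS)
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
        conditional = {
            (ind, c): float(cond[i, j])
            for i, ind in enumerate(indicators)
            for j, c in enumerate(causes)
        }
        return cls(
            causes=tuple(causes),
            prior={c: float(p) for c, p in zip(causes, priors)},
            conditional=conditional,
            indicators=tuple(indicators),
        )


def load_probbase(path: str | Path) -> Probbase:
    """Load a probbase CSV: cause code, prior, then one column per indicator.

    Values are clamped away from 0/1 by 1e-6 and priors renormalized, so a
    hand-edited file with a hard zero still yields finite posteriors.
    """
    df = pd.read_csv(path, dtype={0: str})
    cause_col, prior_col = df.columns[0], df.columns[1]
    indicators = list(df.columns[2:])
    causes = [str(c) for c in df[cause_col]]
    priors = df[prior_col].to_numpy(dtype=float)
    cond = df[indicators].to_numpy(dtype=float).T  # (n_ind, n_causes)
    return Probbase.from_arrays(causes, priors, indicators, cond)


def save_probbase(probbase: Probbase, path: str | Path) -> None:
    rows = []
    for c in probbase.causes:
        row = {"cause": c, "prior": probbase.prior[c]}
        for ind in probbase.indicators:
            row[ind] = probbase.conditional[(ind, c)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class PosteriorResult:
    record_id: str
    posterior: Mapping[str, float]
    top_cause: str  # cause code or UNDETERMINED
    top_posterior: float


def assign_probabilistic(
    record: VARecord,
    probbase: Probbase,
    threshold: float = DEFAULT_THRESHOLD,
) -> PosteriorResult:
    """Posterior over causes for one record; undetermined below threshold.

    The product of conditionals is accumulated in log space to avoid
    underflow with many positive indicators.  An indicator on the record
    that the probbase does not know is a schema mismatch and raises.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1)")
    known = set(probbase.indicators)
    for ind in record.indicators:
        if ind not in known:
            raise ValidationError(
                f"record {record.record_id!r}: indicator {ind!r} not in probbase"
            )
    log_post = np.array(
        [np.log(probbase.prior[c]) for c in probbase.causes], dtype=float
    )
    for ind, value in record.indicators.items():
        if value != "yes":
            continue  # no/missing are uninformative
        log_post += np.log(
            [probbase.conditional[(ind, c)] for c in probbase.causes]
        )
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    posterior = {c: float(p) for c, p in zip(probbase.causes, post)}
    top_idx = int(np.argmax(post))
    top_p = float(post[top_idx])
    top_cause = probbase.causes[top_idx] if top_p >= threshold else UNDETERMINED
    return PosteriorResult(
        record_id=record.record_id,
        posterior=posterior,
        top_cause=top_cause,
        top_posterior=top_p,
    )


def inject_scd_indicator(record: VARecord) -> VARecord:
    """Set ``scd_mention`` to yes iff the narrative screen fires.

    Pure and idempotent: returns a copy, leaves a positive free-text hit
    as yes, and otherwise marks the indicator no (the screen was run and
    found nothing, which is informative only through its absence).
    """
    hit = extract_scd_indicator(record.narrative)
    return record.with_indicator(SCD_MENTION, "yes" if hit else "no")


def assign_cohort(
    cohort: Sequence[VARecord],
    probbase: Probbase,
    threshold: float = DEFAULT_THRESHOLD,
    method_id: str = "interva",
    use_narrative: bool = True,
) -> list[CauseAssignment]:
    """Assign the whole cohort, optionally wiring in the free-text channel."""
    out = []
    for record in cohort:
        r = inject_scd_indicator(record) if use_narrative else record
        res = assign_probabilistic(r, probbase, threshold)
        out.append(CauseAssignment(record.record_id, method_id, res.top_cause))
    return out
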