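"""Rounding and table formatting for the published-style reports.

Agreement rows mirror the usual layout of a VA validation paper (method
pair, all-cause AC1 with SE and CI, per-cause AC1); validity rows mirror a
cause × four-metric table.  Percentages are rounded half-up, one decimal
for agreement values and integers for validity metrics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from ._util import percent, round_half_up
from .agreement import AgreementResult
from .validity import CSMFVector, ValidityResult

__all__ = [
    "round_half_up",
    "percent",
    "format_agreement",
    "agreement_rows_to_frame",
    "validity_rows_to_frame",
    "csmf_to_frame",
]


def format_agreement(result: AgreementResult) -> str:
    """``54.6 (2.0) (50.7 to 58.5)`` — AC1 % (SE) (95% CI)."""
    return (
        f"{round_half_up(100 * result.ac1, 1)} "
        f"({round_half_up(100 * result.se, 1)}) "
        f"({round_half_up(100 * result.ci_low, 1)} to "
        f"{round_half_up(100 * result.ci_high, 1)})"
    )


def agreement_rows_to_frame(
    rows: Sequence[tuple[str, int, Optional[AgreementResult], dict[str, AgreementResult]]],
    causes: Sequence[str],
) -> pd.DataFrame:
    """One row per method pair: formatted all-cause and per-cause AC1."""
    out = []
    for name, n, all_cause, per_cause in rows:
        row: dict[str, object] = {"methods": name, "n": n}
        row["ac1_all_cods"] = format_agreement(all_cause) if all_cause else "-"
        for cause in causes:
            res = per_cause.get(cause)
            row[f"ac1_{cause}"] = format_agreement(res) if res else "-"
        out.append(row)
    return pd.DataFrame(out)


def _fmt_metric(value: Optional[float]) -> str:
    return "undefined" if value is None else str(round_half_up(100.0 * value))


def validity_rows_to_frame(
    rows: Sequence[tuple[str, str, ValidityResult]],
) -> pd.DataFrame:
    """One row per (cause, method): integer-percent validity metrics."""
    out = []
    for cause_label, method, r in rows:
        out.append(
            {
                "cause": cause_label,
                "method": method,
                "n": r.n,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "sensitivity_pct": _fmt_metric(r.sensitivity),
                "specificity_pct": _fmt_metric(r.specificity),
                "ppv_pct": _fmt_metric(r.ppv),
                "npv_pct": _fmt_metric(r.npv),
            }
        )
    return pd.DataFrame(out)


def csmf_to_frame(vector: CSMFVector, method: str) -> pd.DataFrame:
    rows = [
        {
            "method": method,
            "cause": code,
            "fraction": frac,
            "percent": round_half_up(100.0 * frac, 1),
        }
        for code, frac in sorted(vector.fractions.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_total"] = vector.n_total
    df.attrs["n_undetermined"] = vector.n_undetermined
    return df
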