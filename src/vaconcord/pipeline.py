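"""End-to-end orchestration: simulate → assign → consensus → validate → report.

One :class:`RunConfig` drives a reproducible run.  The stage order mirrors
the study's data handling: inter-coder agreement first, then the
probabilistic engine against physician consensus, then both against the
hospital ward causes, and finally the consensus against the laboratory
gold standard.  Outputs are machine-readable CSVs laid out like the
published agreement and validity tables, plus a plain-text run log and a
structured JSON summary recording seed, n, and every exclusion count so
each denominator can be reconstructed.  Re-running with an identical
config reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import agreement, interva, reporting
from .consensus import resolve_cohort
from .validity import csmf, lab_gold_standard, validity as compute_validity
from .records import (
    CauseAssignment,
    ValidationError,
    write_assignments,
    write_cohort,
)
from .simulate import CohortSpec, SyntheticCohort, generate, kilifi_default_spec

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    n_deaths: int = 610
    threshold: float = interva.DEFAULT_THRESHOLD
    causes_of_interest: list[str] = field(default_factory=lambda: ["4.03"])
    cohort_spec: Optional[CohortSpec] = None  # None -> default spec at `seed`

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_deaths": self.n_deaths,
            "threshold": self.threshold,
            "causes_of_interest": list(self.causes_of_interest),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            out_dir=data.get("out_dir", "results/run"),
            seed=int(data.get("seed", 0)),
            n_deaths=int(data.get("n_deaths", 610)),
            threshold=float(data.get("threshold", interva.DEFAULT_THRESHOLD)),
            causes_of_interest=list(data.get("causes_of_interest", ["4.03"])),
        )


def _subset(assignments: Sequence[CauseAssignment], rids: set[str]) -> list[CauseAssignment]:
    return [a for a in assignments if a.record_id in rids]


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline; returns the paths of the report bundle.

    Any stage failure removes partial outputs and raises a
    :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [f"seed: {config.seed}", f"n_deaths: {config.n_deaths}"]
    summary: dict = {"seed": config.seed, "n_deaths": config.n_deaths}

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "simulate"
        spec = config.cohort_spec or kilifi_default_spec(
            seed=config.seed, n_deaths=config.n_deaths
        )
        sim = generate(spec)
        write_cohort(sim.cohort, emit(out_dir / "cohort.csv"), sim.schema)
        for name in ("truth", "coder1", "coder2", "coder3"):
            write_assignments(getattr(sim, name), emit(out_dir / f"{name}.csv"))
        write_assignments(sim.ward, emit(out_dir / "ward.csv"))
        log_lines.append(f"simulated {len(sim.cohort)} deaths; ward subset {len(sim.ward)}; lab subset {len(sim.lab)}")

        stage = "assign"
        probbase = spec.generative_probbase
        interva_assign = interva.assign_cohort(
            sim.cohort, probbase, threshold=config.threshold
        )
        write_assignments(interva_assign, emit(out_dir / "interva.csv"))
        n_und = sum(1 for a in interva_assign if a.cause_code == "undetermined")
        log_lines.append(f"probabilistic engine: {n_und} undetermined at threshold {config.threshold}")
        summary["interva_undetermined"] = n_und

        stage = "consensus"
        cons, paths = resolve_cohort(sim.coder1, sim.coder2, sim.coder3)
        write_assignments(cons, emit(out_dir / "consensus.csv"))
        log_lines.append(f"consensus paths: {dict(sorted(paths.items()))}")
        summary["consensus_paths"] = dict(sorted(paths.items()))

        stage = "validate-agreement"
        causes = config.causes_of_interest
        ward_rids = {a.record_id for a in sim.ward}
        lab_gold = lab_gold_standard(sim.lab)
        lab_rids = {a.record_id for a in lab_gold}
        comparisons = [
            ("coder1 vs coder2", sim.coder1, sim.coder2, spec.categories, True),
            ("interva vs consensus", interva_assign, cons, spec.categories, True),
            ("interva vs ward", _subset(interva_assign, ward_rids), sim.ward, spec.categories, True),
            ("consensus vs ward", _subset(cons, ward_rids), sim.ward, spec.categories, True),
        ]
        rows = []
        for name, a, b, cats, all_cause in comparisons:
            cmp = agreement.compare_methods(a, b, cats, causes=causes)
            rows.append((name, cmp.all_cause.n, cmp.all_cause if all_cause else None, dict(cmp.per_cause)))
            log_lines.append(f"{name}: n={cmp.all_cause.n}, excluded={cmp.n_excluded}")
        # Lab comparison is SCD-only (binary gold standard).
        scd = "4.03"
        lab_pairs = _subset(cons, lab_rids)
        if lab_pairs and causes:
            t2, excl = agreement.cause_specific_table(lab_pairs, lab_gold, scd)
            lab_res = agreement.ac1(t2)
            rows.append(("consensus vs lab", lab_res.n, None, {scd: lab_res}))
            log_lines.append(f"consensus vs lab: n={lab_res.n}, excluded={excl}")
        agreement_df = reporting.agreement_rows_to_frame(rows, causes)
        agreement_df.to_csv(emit(out_dir / "agreement.csv"), index=False)

        stage = "validate-metrics"
        labels = {c.code: f"{c.code}: {c.label}" for c in spec.categories}
        vrows = []
        ward_gold = sim.ward
        for method_name, assigns in (("interva", interva_assign), ("consensus", cons)):
            pred = _subset(assigns, ward_rids)
            for cause in causes or [c.code for c in spec.categories]:
                vrows.append(
                    (labels.get(cause, cause), method_name, compute_validity(pred, ward_gold, cause))
                )
        if lab_pairs:
            vrows.append(
                (labels.get(scd, scd), "consensus_vs_lab", compute_validity(lab_pairs, lab_gold, scd))
            )
        reporting.validity_rows_to_frame(vrows).to_csv(emit(out_dir / "validity.csv"), index=False)

        stage = "csmf"
        for method_name, assigns in (
            ("truth", sim.truth),
            ("coder1", sim.coder1),
            ("coder2", sim.coder2),
            ("consensus", cons),
            ("interva", interva_assign),
        ):
            vec = csmf(assigns, spec.categories)
            df = reporting.csmf_to_frame(vec, method_name)
            df.to_csv(emit(out_dir / f"csmf_{method_name}.csv"), index=False)
            summary.setdefault("csmf_undetermined", {})[method_name] = vec.n_undetermined

        stage = "report"
        (emit(out_dir / "run_log.txt")).write_text("\n".join(log_lines) + "\n")
        (emit(out_dir / "summary.json")).write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:  # remove partial outputs, name the stage
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return {p.name: p for p in written}
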