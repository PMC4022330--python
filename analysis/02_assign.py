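#!/usr/bin/env python
"""Assign causes of death: probabilistic engine and physician consensus.

Reads the cohort written by 01_simulate.py, runs the naive-Bayes engine
(with the free-text sickle-cell channel injected) and the two-coder
consensus with third-coder referral, and writes both assignment tables to
results/assignments/.  Reports how many deaths each route left
undetermined and how consensus was reached.
"""

from pathlib import Path

from vaconcord.consensus import resolve_cohort
from vaconcord.interva import assign_cohort
from vaconcord.records import UNDETERMINED, read_assignments, read_cohort, write_assignments
from vaconcord.simulate import default_probbase

IN = Path("results/cohort")
OUT = Path("results/assignments")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    probbase = default_probbase()
    cohort = read_cohort(IN / "cohort.csv", probbase.indicators)

    interva = assign_cohort(cohort, probbase)
    write_assignments(interva, OUT / "interva.csv")
    n_und = sum(a.cause_code == UNDETERMINED for a in interva)
    print(f"probabilistic engine: {len(interva)} assigned, {n_und} undetermined")

    coders = {name: read_assignments(IN / f"{name}.csv") for name in ("coder1", "coder2", "coder3")}
    consensus, paths = resolve_cohort(coders["coder1"], coders["coder2"], coders["coder3"])
    write_assignments(consensus, OUT / "consensus.csv")
    print("consensus resolution paths: " + ", ".join(f"{k}={v}" for k, v in sorted(paths.items())))
    n_und = sum(a.cause_code == UNDETERMINED for a in consensus)
    print(f"consensus left {n_und} deaths undetermined (no arbitration table supplied)")


if __name__ == "__main__":
    main()
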