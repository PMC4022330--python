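#!/usr/bin/env python
"""Diagnostic validity against the ward gold standard, and CSMFs.

For every cause category, computes sensitivity, specificity, PPV and NPV
of the probabilistic engine and of physician consensus against the
hospital ward causes (hospital-diagnosed subset), plus the SCD-specific
validity of consensus against the laboratory phenotype.  Also writes the
cause-specific mortality fractions per method and their pairwise
differences in percentage points.
"""

from pathlib import Path

import pandas as pd

from vaconcord.records import GoldStandardRecord, read_assignments, read_categories
from vaconcord.reporting import csmf_to_frame, validity_rows_to_frame
from vaconcord.validity import csmf, csmf_delta, lab_gold_standard, validity

COHORT = Path("results/cohort")
ASSIGN = Path("results/assignments")
OUT = Path("results/tables")
SCD = "4.03"


def read_lab():
    rows = (COHORT / "lab.csv").read_text().strip().splitlines()[1:]
    return [
        GoldStandardRecord(rid, "lab", phenotype=ph)
        for rid, ph in (line.split(",") for line in rows)
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    categories = read_categories(COHORT / "categories.csv")
    truth = read_assignments(COHORT / "truth.csv")
    ward = read_assignments(COHORT / "ward.csv")
    interva = read_assignments(ASSIGN / "interva.csv")
    consensus = read_assignments(ASSIGN / "consensus.csv")
    lab = lab_gold_standard(read_lab())

    ward_ids = {a.record_id for a in ward}
    lab_ids = {a.record_id for a in lab}
    sub = lambda assigns, ids: [a for a in assigns if a.record_id in ids]

    vrows = []
    for method, assigns in (("interva", interva), ("consensus", consensus)):
        pred = sub(assigns, ward_ids)
        for cat in categories:
            vrows.append((f"{cat.code}: {cat.label}", method, validity(pred, ward, cat.code)))
    lab_row = validity(sub(consensus, lab_ids), lab, SCD)
    vrows.append((f"{SCD}: sickle cell (lab gold standard)", "consensus_vs_lab", lab_row))
    vdf = validity_rows_to_frame(vrows)
    vdf.to_csv(OUT / "validity.csv", index=False)
    scd_rows = vdf[vdf["cause"].str.startswith(SCD)]
    print(scd_rows.to_string(index=False))

    csmfs = {}
    for method, assigns in (
        ("truth", truth), ("consensus", consensus), ("interva", interva),
    ):
        vec = csmf(assigns, categories)
        csmfs[method] = vec
        csmf_to_frame(vec, method).to_csv(OUT / f"csmf_{method}.csv", index=False)
        print(f"{method}: SCD CSMF {100 * vec.fractions[SCD]:.1f}% "
              f"({vec.n_undetermined} undetermined)")

    delta = csmf_delta(csmfs["interva"], csmfs["consensus"])
    pd.DataFrame(
        sorted(delta.items()), columns=["cause", "delta_pct_points"]
    ).to_csv(OUT / "csmf_delta_interva_vs_consensus.csv", index=False)
    within2 = sum(abs(d) <= 2.0 for d in delta.values())
    print(f"CSMF deltas (engine - consensus): {within2}/{len(delta)} causes within ±2 points")


if __name__ == "__main__":
    main()
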