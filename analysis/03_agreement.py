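#!/usr/bin/env python
"""Agreement between the assignment methods (all-cause and SCD-specific).

Builds the method-pair agreement table: the two physician coders against
each other, the probabilistic engine against consensus, each against the
hospital ward causes on the hospital-diagnosed subset, and consensus
against the laboratory SCD gold standard.  AC1 is reported as
% (SE) (95% CI) per row, all-cause and for sickle cell disease.
"""

from pathlib import Path

from vaconcord.agreement import ac1, cause_specific_table, compare_methods
from vaconcord.records import read_assignments, read_categories
from vaconcord.reporting import agreement_rows_to_frame, format_agreement
from vaconcord.validity import lab_gold_standard
from vaconcord.records import GoldStandardRecord

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
    coder1 = read_assignments(COHORT / "coder1.csv")
    coder2 = read_assignments(COHORT / "coder2.csv")
    ward = read_assignments(COHORT / "ward.csv")
    interva = read_assignments(ASSIGN / "interva.csv")
    consensus = read_assignments(ASSIGN / "consensus.csv")
    lab = lab_gold_standard(read_lab())

    ward_ids = {a.record_id for a in ward}
    lab_ids = {a.record_id for a in lab}
    sub = lambda assigns, ids: [a for a in assigns if a.record_id in ids]

    rows = []
    for name, a, b in [
        ("coder1 vs coder2", coder1, coder2),
        ("interva vs consensus", interva, consensus),
        ("interva vs ward", sub(interva, ward_ids), ward),
        ("consensus vs ward", sub(consensus, ward_ids), ward),
    ]:
        cmp = compare_methods(a, b, categories, causes=[SCD])
        rows.append((name, cmp.all_cause.n, cmp.all_cause, dict(cmp.per_cause)))
        print(f"{name} (n={cmp.all_cause.n}): all-cause AC1 {format_agreement(cmp.all_cause)}, "
              f"SCD AC1 {format_agreement(cmp.per_cause[SCD])}")

    t2, _ = cause_specific_table(sub(consensus, lab_ids), lab, SCD)
    lab_res = ac1(t2)
    rows.append(("consensus vs lab", lab_res.n, None, {SCD: lab_res}))
    print(f"consensus vs lab (n={lab_res.n}): SCD AC1 {format_agreement(lab_res)}")

    agreement_rows_to_frame(rows, [SCD]).to_csv(OUT / "agreement.csv", index=False)
    print(f"wrote {OUT / 'agreement.csv'}")


if __name__ == "__main__":
    main()
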