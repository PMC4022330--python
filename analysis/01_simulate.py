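#!/usr/bin/env python
"""Generate the default synthetic cohort and report its descriptive profile.

Writes the cohort and per-method assignment CSVs under results/cohort/ and
prints the marginals a study write-up would open with: cohort size, median
age, under-five and infant shares, sex, place of death, the sizes of the
hospital-diagnosed and genotyped subsets, and the phenotype mix among the
genotyped.
"""

from collections import Counter
from pathlib import Path

import numpy as np

from vaconcord.records import write_assignments, write_cohort, write_categories
from vaconcord.simulate import generate, kilifi_default_spec

SEED = 20140422
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = kilifi_default_spec(seed=SEED)
    sim = generate(spec)

    write_cohort(sim.cohort, OUT / "cohort.csv", sim.schema)
    for name in ("truth", "coder1", "coder2", "coder3", "ward"):
        write_assignments(getattr(sim, name), OUT / f"{name}.csv")
    write_categories(spec.categories, OUT / "categories.csv")
    with open(OUT / "lab.csv", "w") as fh:
        fh.write("record_id,phenotype\n")
        for g in sim.lab:
            fh.write(f"{g.record_id},{g.phenotype}\n")

    n = len(sim.cohort)
    ages = np.array([r.age_days for r in sim.cohort])
    places = Counter(r.place_of_death for r in sim.cohort)
    phen = Counter(g.phenotype for g in sim.lab)
    print(f"simulated {n} deaths (seed {SEED})")
    print(f"median age at death: {np.median(ages) / 365:.1f} years")
    print(f"under five: {100 * (ages < 5 * 365).mean():.0f}%; "
          f"infants among under-fives: {100 * (ages[ages < 5 * 365] < 365).mean():.0f}%")
    print(f"male: {100 * sum(r.sex == 'male' for r in sim.cohort) / n:.0f}%")
    print("place of death: " + ", ".join(f"{k} {100 * v / n:.0f}%" for k, v in places.most_common()))
    print(f"hospital-diagnosed subset: {len(sim.ward)} ({100 * len(sim.ward) / n:.0f}%)")
    print(f"genotyped subset: {len(sim.lab)} ({100 * len(sim.lab) / n:.0f}%), "
          "phenotypes: " + ", ".join(f"{k} {v}" for k, v in sorted(phen.items())))


if __name__ == "__main__":
    main()
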