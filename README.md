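# vaconcord

Verbal-autopsy (VA) cause-of-death assignment and validation for child
mortality surveillance, with a focus on sickle cell disease (SCD).

In populations where most children die outside hospital, the cause of
death (COD) is inferred from a structured interview with the family — a
verbal autopsy — interpreted either by physicians (PCVA) or by a
probabilistic model. Validating those interpretations, especially for a
rare cause like SCD (~5–6% of child deaths), requires an analysis chain
that this package implements end to end:

- **`vaconcord.records`** — domain model (deaths, cause categories,
  assignments, gold standards) and CSV I/O.
- **`vaconcord.mapping`** — ICD-10 → WHO-2012 VA category mapping and the
  free-text SCD screen (`"sickle" OR "scd"`).
- **`vaconcord.interva`** — naive-Bayes cause assignment from a probbase:
  posterior(c) ∝ P(c) · Π_{s:yes} P(s|c), with an abstention threshold.
- **`vaconcord.consensus`** — two-coder consensus with third-coder
  referral and optional arbitration.
- **`vaconcord.agreement`** — Gwet's AC1 chance-corrected agreement,
  AC1 = (p_a − p_e)/(1 − p_e) with p_e = (1/(Q−1)) Σ_q π_q(1 − π_q),
  linearized SE, t-based 95% CI, jackknife cross-check. AC1 is used
  because Cohen's kappa collapses at extreme prevalence even when raters
  almost always agree.
- **`vaconcord.validity`** — per-cause sensitivity/specificity/PPV/NPV
  against ward or laboratory (HbSS phenotype) gold standards,
  cause-specific mortality fractions (CSMFs), and the demographic
  expected-SCD-burden calculation.
- **`vaconcord.simulate`** — a synthetic Kilifi-like cohort generator
  (610 deaths, 6% SCD, 45/43/12% home/hospital/elsewhere, 22% hospital
  diagnosed, 15% genotyped at ~67/12/21% HbAA/HbAS/HbSS) so the whole
  chain is testable without confidential surveillance data.
- **`vaconcord.pipeline` / the `vaconcord` CLI** — one reproducible run:
  simulate → assign → consensus → validate → report.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
from vaconcord import ContingencyTable, ac1, expected_scd_death_share

# Agreement between two methods on a 2x2 cross-tabulation
res = ac1(ContingencyTable(("scd", "not_scd"), np.array([[40, 5], [5, 50]])))
print(f"AC1 = {res.ac1:.4f} (pa = {res.pa:.2f}, pe = {res.pe:.3f})")

# Expected share of child deaths due to SCD: 0.8% affected births,
# 50% early-life case fatality, cumulative child mortality 40/1000
print(f"expected SCD death share = {100 * expected_scd_death_share(0.008, 0.5, 0.04):.0f}%")
```

prints

```
AC1 = 0.8020 (pa = 0.90, pe = 0.495)
expected SCD death share = 10%
```

0.8020 is the chance-corrected agreement of a table with 90% raw
agreement and balanced-ish marginals; 10% is the demographic expectation
for SCD's share of deaths among children past the neonatal period, the
benchmark against which a ~6% VA-attributed share reads as plausible.

The analysis itself runs as numbered drivers from the repository root:

```bash
python analysis/01_simulate.py        # cohort + coder/ward/lab tables -> results/cohort/
python analysis/02_assign.py          # engine + consensus -> results/assignments/
python analysis/03_agreement.py       # method-pair AC1 table -> results/tables/agreement.csv
python analysis/04_validity.py        # sens/spec/PPV/NPV + CSMFs -> results/tables/
python analysis/05_expected_burden.py # burden arithmetic + 2x2 reconstruction
```

or as one command: `vaconcord run-all --seed 0 --out results/run`.

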