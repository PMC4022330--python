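# Methods

## Problem setting

In populations covered by demographic surveillance but not by medical
certification, the cause of a child's death (COD) is usually inferred by
verbal autopsy (VA): a structured interview with the family, interpreted
either by physicians (physician-coded VA, PCVA) or by a probabilistic
model. Sickle cell disease (SCD) is a particular challenge: most affected
children in sub-Saharan Africa die undiagnosed, older VA cause lists had
no SCD code at all, and the evidence for SCD often lives in the free-text
part of the interview ("known sickler", "attends the SCD clinic").

This package implements the full analysis chain such a validation study
needs — probabilistic assignment, physician-coder consensus, cause-category
mapping, agreement statistics, diagnostic validity, mortality fractions —
together with a synthetic cohort generator so every stage can be exercised
and tested end to end without access to confidential surveillance data.

## Probabilistic assignment (naive-Bayes engine)

The engine is a naive-Bayes classifier in the style of the InterVA family
of tools. A *probbase* supplies a prior P(c) for each cause c and a
conditional P(s = yes | c) for each (indicator, cause) pair. For a record
whose indicators answered "yes" form the set Y,

    posterior(c) ∝ P(c) · Π_{s ∈ Y} P(s = yes | c),

renormalized over causes. Design choices:

- **Only "yes" answers are informative.** "No" and "missing" contribute
  nothing to the likelihood. This mirrors the published behaviour of the
  cited tool family and keeps missingness neutral.
- **Log-space accumulation** avoids underflow with many indicators.
- **Clamping**: probbase values are clamped to [1e-6, 1 − 1e-6] at load
  time so a hand-edited file with a hard zero still yields finite
  posteriors; priors are renormalized.
- **Reporting threshold** (default 0.4, configurable): if the top
  posterior is below it the engine reports *undetermined* rather than
  committing. With the default synthetic cohort this abstains on roughly
  40% of deaths — a 12-symptom binary questionnaire simply does not
  separate ten syndromically overlapping causes for every record, and we
  prefer an explicit abstention to a coin-flip assignment. Mortality
  fractions are therefore always reported over determinate assignments
  with the undetermined count alongside.

This is deliberately **not** a re-implementation of the distributed
InterVA-4 program: no letter-graded probbase, no three-cause output with
likelihood redistribution, no HIV/malaria prevalence presets. The probbase
is wholly user configuration.

The free-text channel is the one SCD-specific part: a case-insensitive
screen for the substring "sickle" (so "sickler", "sickle-cell" match) or
the word-bounded token "scd" sets the `scd_mention` indicator before
assignment. Word-bounding "scd" avoids accidental substrings; "sickle" is
deliberately a bare substring.

## Physician-coder consensus

Two independent coders read every VA. The resolution contract is:

1. both primary coders name the same determinate cause → that cause;
2. otherwise, a third coder matching either primary coder's determinate
   cause → that cause;
3. otherwise an externally supplied arbitration cause, if any;
4. otherwise *undetermined*, flagged `arbitration_required` (never an
   exception — the pipeline must run to completion without a human
   arbitration meeting).

`cannot_determine` is a distinct input sentinel that never agrees with
anything, including itself: two non-diagnoses still mean referral. The
rule is symmetric in the two primary coders and never invents a code.

## Agreement: Gwet's AC1

Cohen's kappa collapses when a category is rare even though raters almost
always agree (the prevalence paradox); for a ~5% cause such as SCD this
matters decisively, which is why the analysis uses Gwet's AC1. For a Q×Q
table with cell proportions p and mean marginals π_q:

    pa = Σ_q p_qq,   pe = (1/(Q−1)) Σ_q π_q (1 − π_q),
    AC1 = (pa − pe) / (1 − pe).

The standard error uses the subject-level linearization (influence values
γ*_i = γ_i − 2(1 − AC1)(pe_i − pe)/(1 − pe), variance
Σ(γ*_i − AC1)²/(n(n−1))), and a delete-one jackknife is implemented as an
independent cross-check; the two agree within 15% relative difference for
n ≥ 200 in the test suite, and the 95% CI achieves 93–97% empirical
coverage over 500 simulated cohorts of a fixed joint distribution.

**CI convention** (ours, documented rather than matched to any published
table): AC1 ± t_{n−1,0.975}·SE, truncated above at 1. Cause-specific
agreement is one-vs-rest binary ("was the cause mentioned or not").
Records where either method is undetermined are excluded pairwise, with
the exclusion count logged so every denominator can be reconstructed.
Cohen's kappa is available only as a contrast column.

## Diagnostic validity and CSMFs

Per-cause one-vs-rest confusion counts give sensitivity, specificity, PPV
and NPV. A zero denominator yields *undefined*, never 0. Undetermined
predictions count as negative for the cause under test (a non-diagnosis
did not mention the cause); gold standards must be fully determinate.
The laboratory gold standard is binary — HbSS phenotype means SCD,
HbAA/HbAS (carriers are not diseased) mean not-SCD — because a genotype
can adjudicate SCD status but never the non-SCD cause.

The demographic back-of-envelope `expected_scd_death_share` computes
birth_prevalence × early-life case fatality / cumulative childhood
mortality; at 0.8% affected births, 50% case fatality and 40/1000
mortality this gives 10%.

`reconstruct_confusion_tables` is a consistency search, not an estimator:
it enumerates all integer 2×2 tables at a given n with both marginals in
a small-prevalence window and returns those whose four metrics round
(half-up) to given integer percentages. Within a 3–7.5% marginal window
at n = 134 the rounded quadruple 83/99/83/99 identifies TP=5, FN=1, FP=1,
TN=127 uniquely; 83/98/63/99 identifies TP=5, FN=1, FP=3, TN=125.

## Synthetic cohort generator

The generator emulates a Kilifi-like child-mortality VA study; its
defaults are the study conditions, fixed once:

- **n = 610** deaths aged 28 days to 14 years; 55% male.
- **True CSMF**: ten WHO-2012-style categories with SCD at 6%, malaria
  and pneumonia at 15% each, and a 20% "other" remainder.
- **Place of death** 45/43/12% home/hospital/elsewhere, independent of
  cause (the true joint distribution is unknown; independence is the
  documented simplification).
- **Ages**: a two-component mixture — a truncated log-normal (scale 599
  days, σ = 1.1, support 28–1824 days) with weight 0.74 for under-fives,
  and a log-uniform tail over 5–14 years. The scale was solved in closed
  form so the mixture median is exactly 2.0 years with 74% under five.
  A single log-normal cannot *simultaneously* reproduce the strong infant
  mode of real cohorts (~58% of under-five deaths in infancy) while
  keeping the overall median at 2 years; the default therefore matches
  the median and under-five share and under-represents infants, a known
  limitation.
- **Indicators** are drawn Bernoulli from the generative probbase given
  the true cause, with 5% missingness at random; the `scd_mention`
  channel is carried by the narrative instead (SCD phrases emitted with
  probability 0.7 for true SCD deaths, 1% otherwise) and injected by the
  engine's free-text screen. The default assignment probbase equals the
  generative one, i.e. the engine is evaluated under a well-specified
  model; tests that need misspecification construct it explicitly.
- **Coders** draw from per-cause confusion matrices: correct with a
  per-cause accuracy (0.55–0.80 for most causes, 0.90 for SCD, 0.95 for
  the hospital ward), otherwise an error drawn in proportion to cause
  base rates — except that SCD is downweighted ×0.2 as an error
  destination, since a spurious SCD call requires documentary evidence.
  This profile implies a closed-form population agreement of ≈0.48
  all-cause and ≈0.98 for SCD between the two primary coders: the
  moderate-overall / very-high-for-SCD pattern that motivates a
  prevalence-robust coefficient. Each coder also returns
  `cannot_determine` independently (3%, 2% for the referral coder).
- **Ward gold standard**: the hospital ward is modelled as a low-error
  coder (accuracy 0.95), not as truth itself — hospital diagnosis is a
  convenience gold standard, and deaths in hospital need not be
  representative. Ward CODs exist only for hospital deaths, thinned at
  rate 0.22/0.43 so the marginal hospital-diagnosed fraction is ~22%.
- **Laboratory subset**: 15% of deaths at random carry a hemoglobin
  phenotype. Given SCD-cause status the genotype model is
  P(HbSS|SCD) = 0.95, P(HbAS|SCD) = 0.02, P(HbSS|non-SCD) = 0.16,
  P(HbAS|non-SCD) = 0.13, chosen in closed form so the phenotype mix
  among the genotyped is ≈67/12/21% HbAA/HbAS/HbSS at a 6% SCD cause
  fraction. The elevated P(HbSS|non-SCD) encodes, without extra
  machinery, the real-world enrichment of genotyped subsets with
  sickle-cohort children who died of other causes. A structural
  consequence: VA sensitivity measured against the lab standard is much
  lower than against the ward standard, because HbSS children whose
  deaths were (correctly) attributed to other causes count against it.
  Passing tests on this generator therefore demonstrate the statistical
  machinery, not field performance of VA.

All randomness flows from one seeded NumPy generator; identical specs
produce bit-identical cohorts.

## Numerical and testing conventions

- Percentages are rounded half-up; agreement values print with one
  decimal, validity metrics as integers. Full precision is kept
  internally.
- AC1 is computed exactly from counts; the degenerate pe = 1 case is
  rejected (it cannot occur for Q ≥ 2 tables but is guarded).
- Posterior equivalence with exhaustive joint-table enumeration is
  asserted to 1e-12 for up to 4 causes × 6 indicators.
- Monte-Carlo recovery checks over a *family* of parameters (per-cause
  sensitivity and specificity across ten causes) use simultaneous
  Bonferroni-adjusted 95% binomial bounds; twenty independent 95%
  intervals would jointly fail ~64% of the time by construction, which is
  not a meaningful check. Single-parameter checks use plain 95% bounds.
- Simulation sizes in the suite: n = 5,000 cohorts for recovery checks,
  500 replicates of n = 200 for CI coverage — sizes at which binomial
  bounds are tight enough to detect real defects while the whole suite
  runs in seconds.

## Known limitations

- The engine is a simplified naive-Bayes stand-in for the InterVA family;
  no claim of bit-compatibility with any distributed program.
- The shipped ICD-10 → WHO-2012 cause map is a reconstruction covering
  the default category set plus common pediatric codes, fully replaceable
  by file; it is not a copy of any study-specific crosswalk.
- Cause and place of death are generated independently; real cohorts
  have hospital deaths enriched for some causes.
- The narrative channel emits stylized phrases; real free text is noisier
  and multilingual.
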