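"""Synthetic VA cohort generator.

Emulates the statistical structure of a child-mortality VA validation
cohort from a demographic surveillance site: ~610 deaths aged 28 days to
14 years, a multinomial cause distribution including ~6% sickle cell
disease, place-of-death mix 45/43/12% (home/hospital/elsewhere), symptom
indicators emitted from a per-cause Bernoulli model, free-text narratives
that mention sickle-cell phrases mostly for true SCD deaths, two
independent error-prone physician coders (plus a third for referrals), a
hospital-diagnosed subset (~22%) serving as a near-perfect ward gold
standard, and a laboratory-genotyped subset (~15%) with an
HbAA/HbAS/HbSS mix of ~67/12/21%.

Everything is driven by one :class:`CohortSpec`; all randomness flows
from a single seeded generator so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .interva import SCD_MENTION, Probbase
from .records import (
    CANNOT_DETERMINE,
    CauseAssignment,
    CauseCategory,
    GoldStandardRecord,
    VARecord,
    ValidationError,
    default_categories,
    scd_code,
)

__all__ = [
    "AgeMixture",
    "GenotypeModel",
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_INDICATORS",
    "default_probbase",
    "coder_confusion_from_accuracy",
    "population_joint",
    "kilifi_default_spec",
    "generate",
]

#: Indicator schema: twelve questionnaire symptoms plus the free-text
#: sickle-cell mention channel.
DEFAULT_INDICATORS: tuple[str, ...] = (
    "fever",
    "cough",
    "difficulty_breathing",
    "diarrhea",
    "convulsions",
    "stiff_neck",
    "jaundice",
    "pallor",
    "swollen_hands_feet",
    "bone_pain",
    "wasting",
    "birth_defect",
    SCD_MENTION,
)

_CAUSE_ORDER = ("1.01", "1.02", "1.03", "1.04", "1.05", "1.07", "3.02", "4.03", "10.06", "98")

# P(indicator = yes | cause); rows follow DEFAULT_INDICATORS, columns
# _CAUSE_ORDER.  Chosen to give each cause a recognizable syndrome (e.g.
# jaundice/pallor/dactylitis/bone pain for SCD, stiff neck for
# meningitis) over a nonzero background rate.
_DEFAULT_COND = np.array(
    [
        # 1.01  1.02  1.03  1.04  1.05  1.07  3.02  4.03 10.06   98
        [0.85, 0.70, 0.40, 0.50, 0.95, 0.85, 0.25, 0.50, 0.05, 0.30],  # fever
        [0.25, 0.95, 0.40, 0.15, 0.25, 0.15, 0.15, 0.15, 0.05, 0.20],  # cough
        [0.40, 0.90, 0.30, 0.10, 0.25, 0.15, 0.15, 0.30, 0.15, 0.20],  # difficulty_breathing
        [0.25, 0.10, 0.50, 0.95, 0.20, 0.10, 0.40, 0.10, 0.05, 0.20],  # diarrhea
        [0.20, 0.05, 0.05, 0.05, 0.60, 0.70, 0.05, 0.05, 0.05, 0.10],  # convulsions
        [0.08, 0.03, 0.03, 0.03, 0.10, 0.75, 0.03, 0.03, 0.03, 0.05],  # stiff_neck
        [0.15, 0.03, 0.08, 0.03, 0.20, 0.05, 0.05, 0.65, 0.03, 0.08],  # jaundice
        [0.30, 0.15, 0.25, 0.20, 0.55, 0.15, 0.35, 0.80, 0.05, 0.15],  # pallor
        [0.03, 0.02, 0.03, 0.02, 0.02, 0.02, 0.08, 0.45, 0.03, 0.03],  # swollen_hands_feet
        [0.04, 0.02, 0.04, 0.02, 0.04, 0.04, 0.02, 0.55, 0.02, 0.06],  # bone_pain
        [0.15, 0.10, 0.70, 0.35, 0.10, 0.08, 0.95, 0.15, 0.05, 0.20],  # wasting
        [0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.85, 0.08],  # birth_defect
        [0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.70, 0.01, 0.01],  # scd_mention
    ]
)

#: True cause-specific mortality fractions for the default cohort.
DEFAULT_CSMF: dict[str, float] = {
    "1.01": 0.08,
    "1.02": 0.15,
    "1.03": 0.05,
    "1.04": 0.08,
    "1.05": 0.15,
    "1.07": 0.08,
    "3.02": 0.09,
    "4.03": 0.06,
    "10.06": 0.06,
    "98": 0.20,
}

# Per-cause diagonal accuracy of the two primary physician coders and the
# referral coder.  SCD is coded well (the narrative makes it visible);
# syndromically overlapping infections less so.  The profile is set so the
# implied population agreement is moderate overall (~0.48) but very high
# for SCD (~0.98) — the pattern that motivates a chance-corrected
# coefficient robust to rare categories.
_CODER1_ACCURACY = {
    "1.01": 0.60, "1.02": 0.75, "1.03": 0.65, "1.04": 0.75, "1.05": 0.75,
    "1.07": 0.70, "3.02": 0.70, "4.03": 0.90, "10.06": 0.80, "98": 0.65,
}
_CODER2_ACCURACY = {
    "1.01": 0.55, "1.02": 0.80, "1.03": 0.60, "1.04": 0.70, "1.05": 0.80,
    "1.07": 0.65, "3.02": 0.60, "4.03": 0.90, "10.06": 0.75, "98": 0.70,
}
_WARD_ACCURACY = {c: 0.95 for c in _CAUSE_ORDER}

#: A coder's errors drift toward common syndromic diagnoses; a spurious
#: SCD call needs documentary evidence, so SCD is strongly downweighted
#: as an error destination.
_SCD_ERROR_DESTINATION_FACTOR = 0.2

_SCD_PHRASES = (
    "known sickler, attends the scd clinic",
    "sickle cell disease diagnosed in infancy",
    "had sickle cell anemia and frequent transfusions",
)
_GENERIC_PHRASES = (
    "the child had fever before death",
    "was taken to a dispensary but did not improve",
    "became weak and stopped feeding",
    "died at night after a short illness",
    "",
)


def default_probbase() -> Probbase:
    """Probbase matching the generator's emission model (well-specified)."""
    return Probbase.from_arrays(
        causes=_CAUSE_ORDER,
        priors=[DEFAULT_CSMF[c] for c in _CAUSE_ORDER],
        indicators=DEFAULT_INDICATORS,
        cond=_DEFAULT_COND,
    )


@dataclass(frozen=True)
class AgeMixture:
    """Two-component age-at-death model on days.

    A truncated log-normal covers deaths under five (weight
    ``weight_under5``, within which mass concentrates in infancy) and a
    log-uniform tail covers ages five to fourteen.  Defaults target a
    median near 2 years with ~74% of deaths under five.
    """

    weight_under5: float = 0.74
    lognorm_median_days: float = 599.0
    lognorm_sigma: float = 1.1
    under5_bounds: tuple[int, int] = (28, 1824)
    over5_bounds: tuple[int, int] = (1825, 5110)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weight_under5
        ages = np.empty(n, dtype=int)
        # truncated log-normal via inverse-CDF on the truncated range
        dist = stats.lognorm(s=self.lognorm_sigma, scale=self.lognorm_median_days)
        lo, hi = dist.cdf(self.under5_bounds[0]), dist.cdf(self.under5_bounds[1])
        u = rng.random(int(comp.sum()))
        ages[comp] = np.round(dist.ppf(lo + u * (hi - lo))).astype(int)
        b0, b1 = self.over5_bounds
        u2 = rng.random(int((~comp).sum()))
        ages[~comp] = np.round(np.exp(np.log(b0) + u2 * (np.log(b1) - np.log(b0)))).astype(int)
        return np.clip(ages, self.under5_bounds[0], self.over5_bounds[1])


@dataclass(frozen=True)
class GenotypeModel:
    """Hemoglobin phenotype probabilities by true SCD-cause status.

    Defaults reproduce a genotyped subset with ~67/12/21% HbAA/HbAS/HbSS
    when the SCD cause fraction is 6%: the elevated P(HbSS | non-SCD
    death) stands in for the enrichment of the real-world genotyped
    subset with sickle-cohort children who died of other causes.
    """

    p_hbss_given_scd: float = 0.95
    p_hbas_given_scd: float = 0.02
    p_hbss_given_nonscd: float = 0.16
    p_hbas_given_nonscd: float = 0.13

    def probs(self, is_scd_death: bool) -> np.ndarray:
        if is_scd_death:
            ss, asd = self.p_hbss_given_scd, self.p_hbas_given_scd
        else:
            ss, asd = self.p_hbss_given_nonscd, self.p_hbas_given_nonscd
        return np.array([1.0 - ss - asd, asd, ss])  # HbAA, HbAS, HbSS


def coder_confusion_from_accuracy(
    accuracy: Mapping[str, float],
    csmf: Mapping[str, float],
    causes: Sequence[str],
    destination_weights: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """Confusion matrix with given diagonal; errors spread by weight.

    Row c is the distribution of the coder's call given true cause c:
    correct with probability ``accuracy[c]``, otherwise one of the other
    causes in proportion to ``destination_weights`` (default: the cause
    fractions — a coder's mistakes drift toward common diagnoses).
    """
    q = len(causes)
    m = np.zeros((q, q))
    weights = destination_weights if destination_weights is not None else csmf
    base = np.array([weights[c] for c in causes], dtype=float)
    for i, c in enumerate(causes):
        acc = accuracy[c]
        if not 0.0 < acc <= 1.0:
            raise ValidationError(f"coder accuracy for {c!r} outside (0, 1]")
        off = base.copy()
        off[i] = 0.0
        if off.sum() > 0:
            off = off / off.sum() * (1.0 - acc)
        m[i] = off
        m[i, i] = acc
    return m


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort."""

    n_deaths: int = 610
    csmf_true: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CSMF))
    place_of_death_dist: tuple[float, float, float] = (0.45, 0.43, 0.12)  # home/hospital/elsewhere
    male_prob: float = 0.55
    age_distribution: AgeMixture = field(default_factory=AgeMixture)
    generative_probbase: Probbase = field(default_factory=default_probbase)
    narrative_rules: dict[str, float] = field(
        default_factory=lambda: {c: (0.70 if c == "4.03" else 0.01) for c in _CAUSE_ORDER}
    )
    coder_models: dict[str, np.ndarray] = field(default_factory=dict)
    cannot_determine_prob: dict[str, float] = field(
        default_factory=lambda: {"coder1": 0.03, "coder2": 0.03, "coder3": 0.02, "ward": 0.0}
    )
    indicator_missing_prob: float = 0.05
    ward_subset_prob: float = 0.22
    lab_subset_prob: float = 0.15
    genotype_model: GenotypeModel = field(default_factory=GenotypeModel)
    categories: list[CauseCategory] = field(default_factory=default_categories)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.coder_models:
            causes = list(self.csmf_true)
            dest = dict(self.csmf_true)
            if "4.03" in dest:
                dest["4.03"] *= _SCD_ERROR_DESTINATION_FACTOR
            profiles = {
                "coder1": _CODER1_ACCURACY,
                "coder2": _CODER2_ACCURACY,
                "coder3": _CODER1_ACCURACY,
                "ward": _WARD_ACCURACY,
            }
            self.coder_models = {
                name: coder_confusion_from_accuracy(
                    {c: prof.get(c, 0.7) for c in causes}, self.csmf_true, causes, dest
                )
                for name, prof in profiles.items()
            }

    @property
    def causes(self) -> list[str]:
        return list(self.csmf_true)

    def validate(self) -> None:
        """Raise a ValidationError naming the first offending field."""
        if self.n_deaths <= 0:
            raise ValidationError("n_deaths must be positive")
        if abs(sum(self.csmf_true.values()) - 1.0) > 1e-9:
            raise ValidationError("csmf_true must sum to 1")
        if abs(sum(self.place_of_death_dist) - 1.0) > 1e-9:
            raise ValidationError("place_of_death_dist must sum to 1")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ValidationError("male_prob outside [0, 1]")
        for name in ("ward_subset_prob", "lab_subset_prob", "indicator_missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        q = len(self.causes)
        for coder, m in self.coder_models.items():
            m = np.asarray(m)
            if m.shape != (q, q):
                raise ValidationError(f"coder_models[{coder!r}] has wrong shape")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError(f"coder_models[{coder!r}] rows must sum to 1")
        for coder, p in self.cannot_determine_prob.items():
            if not 0.0 <= p < 1.0:
                raise ValidationError(f"cannot_determine_prob[{coder!r}] outside [0, 1)")
        for c, p in self.narrative_rules.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"narrative_rules[{c!r}] outside [0, 1]")
        missing = [c for c in self.causes if c not in self.generative_probbase.causes]
        if missing:
            raise ValidationError(f"generative_probbase missing causes {missing}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Everything one simulated study produces."""

    cohort: list[VARecord]
    truth: list[CauseAssignment]
    coder1: list[CauseAssignment]
    coder2: list[CauseAssignment]
    coder3: list[CauseAssignment]
    ward: list[CauseAssignment]  # hospital-diagnosed subset only
    lab: list[GoldStandardRecord]  # genotyped subset only
    schema: tuple[str, ...]


def kilifi_default_spec(seed: int = 0, n_deaths: int = 610) -> CohortSpec:
    """The documented default: a Kilifi-like child-mortality cohort.

    610 deaths; SCD cause fraction 6%; place-of-death 45/43/12%
    home/hospital/elsewhere; 55% male; hospital-diagnosed subset 22%;
    genotyped subset 15% with an HbAA/HbAS/HbSS mix targeting 67/12/21%.
    """
    return CohortSpec(n_deaths=n_deaths, seed=seed)


def population_joint(
    csmf: Mapping[str, float],
    coder_a: np.ndarray,
    coder_b: np.ndarray,
) -> np.ndarray:
    """Exact joint P(A says q, B says l) for two conditionally independent
    coders: sum_c csmf(c) · A[c, q] · B[c, l].

    Independent cannot-determine thinning leaves this joint unchanged
    after pairwise exclusion, so it is the closed-form target for the
    sample AC1 of jointly determinate records.
    """
    weights = np.asarray(list(csmf.values()), dtype=float)
    return np.einsum("c,cq,cl->ql", weights, np.asarray(coder_a), np.asarray(coder_b))


def _draw_categorical_rows(
    rng: np.random.Generator, probs: np.ndarray, row_index: np.ndarray
) -> np.ndarray:
    """Vectorized draw: one categorical sample per record from probs[row]."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(len(row_index))
    return (u[:, None] > cdf[row_index]).sum(axis=1)


def generate(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_deaths
    causes = spec.causes
    q = len(causes)
    scd = scd_code(spec.categories)

    cause_probs = np.array([spec.csmf_true[c] for c in causes])
    truth_idx = _draw_categorical_rows(rng, cause_probs[None, :], np.zeros(n, dtype=int))
    ages = spec.age_distribution.sample(n, rng)
    sexes = np.where(rng.random(n) < spec.male_prob, "male", "female")
    places = np.array(["home", "hospital", "elsewhere"])[
        _draw_categorical_rows(rng, np.array(spec.place_of_death_dist)[None, :], np.zeros(n, dtype=int))
    ]

    # Symptom indicators: Bernoulli from the generative probbase given the
    # true cause; the scd_mention channel is carried by the narrative and
    # left missing here (the engine injects it from free text).
    pb = spec.generative_probbase
    observed = [ind for ind in pb.indicators if ind != SCD_MENTION]
    cond = np.array([[pb.conditional[(ind, c)] for c in causes] for ind in observed])
    yes = rng.random((n, len(observed))) < cond[:, truth_idx].T
    miss = rng.random((n, len(observed))) < spec.indicator_missing_prob

    narr_p = np.array([spec.narrative_rules.get(c, 0.0) for c in causes])
    scd_phrase = rng.random(n) < narr_p[truth_idx]
    generic_pick = rng.integers(0, len(_GENERIC_PHRASES), size=n)
    scd_pick = rng.integers(0, len(_SCD_PHRASES), size=n)

    width = len(str(n))
    records: list[VARecord] = []
    truth: list[CauseAssignment] = []
    for i in range(n):
        rid = f"D{i + 1:0{width}d}"
        indicators = {}
        for j, ind in enumerate(observed):
            indicators[ind] = "missing" if miss[i, j] else ("yes" if yes[i, j] else "no")
        indicators[SCD_MENTION] = "missing"
        narrative = _GENERIC_PHRASES[generic_pick[i]]
        if scd_phrase[i]:
            narrative = (narrative + ". " if narrative else "") + _SCD_PHRASES[scd_pick[i]]
        records.append(
            VARecord(
                record_id=rid,
                age_days=int(ages[i]),
                sex=str(sexes[i]),
                place_of_death=str(places[i]),
                indicators=indicators,
                narrative=narrative,
            )
        )
        truth.append(CauseAssignment(rid, "truth", causes[truth_idx[i]]))

    rids = [r.record_id for r in records]

    def draw_coder(name: str) -> np.ndarray:
        m = np.asarray(spec.coder_models[name])
        idx = _draw_categorical_rows(rng, m, truth_idx)
        codes = np.array(causes, dtype=object)[idx]
        p_cd = spec.cannot_determine_prob.get(name, 0.0)
        if p_cd > 0:
            cd = rng.random(n) < p_cd
            codes[cd] = CANNOT_DETERMINE
        return codes

    coder_codes = {name: draw_coder(name) for name in ("coder1", "coder2", "coder3", "ward")}
    coders = {
        name: [CauseAssignment(rid, name, str(code)) for rid, code in zip(rids, codes)]
        for name, codes in coder_codes.items()
    }

    # Ward COD exists only for hospital deaths, thinned so the marginal
    # hospital-diagnosed fraction is ~ward_subset_prob of all deaths.
    p_hospital = spec.place_of_death_dist[1]
    p_sel = min(1.0, spec.ward_subset_prob / p_hospital) if p_hospital > 0 else 0.0
    ward_sel = rng.random(n) < p_sel
    ward = [
        a
        for a, r, sel in zip(coders["ward"], records, ward_sel)
        if sel and r.place_of_death == "hospital"
    ]

    lab_sel = rng.random(n) < spec.lab_subset_prob
    phen_names = np.array(["HbAA", "HbAS", "HbSS"])
    lab: list[GoldStandardRecord] = []
    for i in range(n):
        if not lab_sel[i]:
            continue
        is_scd = causes[truth_idx[i]] == scd
        probs = spec.genotype_model.probs(is_scd)
        pick = _draw_categorical_rows(rng, probs[None, :], np.zeros(1, dtype=int))[0]
        lab.append(
            GoldStandardRecord(
                record_id=rids[i], source="lab", phenotype=str(phen_names[pick])
            )
        )

    return SyntheticCohort(
        cohort=records,
        truth=truth,
        coder1=coders["coder1"],
        coder2=coders["coder2"],
        coder3=coders["coder3"],
        ward=ward,
        lab=lab,
        schema=tuple(pb.indicators),
    )
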