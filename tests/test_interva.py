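"""Naive-Bayes cause assignment engine against brute-force enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaconcord.interva import (
    SCD_MENTION,
    Probbase,
    assign_probabilistic,
    inject_scd_indicator,
)
from vaconcord.records import UNDETERMINED, VARecord, ValidationError


def brute_force_posterior(record, probbase):
    """Independent oracle: exhaustive joint-table computation.

    Builds the full joint P(cause, s_1..s_k) over every indicator
    configuration assuming conditional independence, then conditions on
    the observed yes-set by summing the joint over all configurations
    whose yes-set indicators are yes (no/missing indicators are summed
    out, i.e. unconstrained).
    """
    yes_set = {k for k, v in record.indicators.items() if v == "yes"}
    inds = list(probbase.indicators)
    post = {}
    for c in probbase.causes:
        total = 0.0
        for config in itertools.product([True, False], repeat=len(inds)):
            if any(ind in yes_set and not val for ind, val in zip(inds, config)):
                continue
            p = probbase.prior[c]
            for ind, val in zip(inds, config):
                q = probbase.conditional[(ind, c)]
                p *= q if val else (1.0 - q)
            total += p
        post[c] = total
    z = sum(post.values())
    return {c: v / z for c, v in post.items()}


def make_probbase(causes, priors, indicators, cond_rows):
    return Probbase.from_arrays(causes, priors, indicators, np.array(cond_rows))


TWO_CAUSE = make_probbase(
    ["scd", "malaria"], [0.1, 0.9], ["jaundice"], [[0.8, 0.1]]
)


class TestAssignProbabilistic:
    def test_no_yes_indicators_returns_prior(self):
        record = VARecord("d1", 100, indicators={"jaundice": "no"})
        res = assign_probabilistic(record, TWO_CAUSE, threshold=0.0)
        assert res.posterior["scd"] == pytest.approx(0.1, abs=1e-9)
        assert res.posterior["malaria"] == pytest.approx(0.9, abs=1e-9)

    def test_worked_two_cause_jaundice_example(self):
        # 0.1*0.8 / (0.1*0.8 + 0.9*0.1) = 0.08/0.17
        record = VARecord("d1", 100, indicators={"jaundice": "yes"})
        res = assign_probabilistic(record, TWO_CAUSE, threshold=0.0)
        assert res.posterior["scd"] == pytest.approx(0.08 / 0.17, abs=1e-9)
        assert res.posterior["scd"] == pytest.approx(
            brute_force_posterior(record, TWO_CAUSE)["scd"], abs=1e-12
        )

    def test_threshold_yields_undetermined(self):
        record = VARecord("d1", 100, indicators={"jaundice": "yes"})
        res = assign_probabilistic(record, TWO_CAUSE, threshold=0.99)
        assert res.top_cause == UNDETERMINED
        assert res.top_posterior == pytest.approx(0.09 / 0.17, abs=1e-9)

    def test_unknown_indicator_names_it(self):
        record = VARecord("d1", 100, indicators={"rash": "yes"})
        with pytest.raises(ValidationError, match="rash"):
            assign_probabilistic(record, TWO_CAUSE)

    def test_posterior_sums_to_one(self):
        record = VARecord("d1", 100, indicators={"jaundice": "yes"})
        res = assign_probabilistic(record, TWO_CAUSE, threshold=0.0)
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)


@st.composite
def random_problem(draw):
    n_causes = draw(st.integers(2, 4))
    n_inds = draw(st.integers(1, 6))
    causes = [f"c{i}" for i in range(n_causes)]
    inds = [f"s{i}" for i in range(n_inds)]
    priors = [draw(st.floats(0.05, 1.0)) for _ in causes]
    cond = [
        [draw(st.floats(0.01, 0.99)) for _ in causes] for _ in inds
    ]
    values = [draw(st.sampled_from(["yes", "no", "missing"])) for _ in inds]
    pb = make_probbase(causes, priors, inds, cond)
    record = VARecord("d1", 100, indicators=dict(zip(inds, values)))
    return record, pb


class TestEquivalenceWithBruteForce:
    @settings(max_examples=60)
    @given(random_problem())
    def test_matches_exhaustive_joint_enumeration(self, problem):
        record, pb = problem
        res = assign_probabilistic(record, pb, threshold=0.0)
        oracle = brute_force_posterior(record, pb)
        for c in pb.causes:
            assert res.posterior[c] == pytest.approx(oracle[c], abs=1e-12)


class TestModelInvariants:
    def test_posterior_invariant_under_conditional_scaling(self):
        """Multiplying one indicator's conditionals by a constant is
        absorbed by normalization."""
        record = VARecord("d1", 100, indicators={"s0": "yes", "s1": "yes"})
        base = make_probbase(
            ["a", "b", "c"], [0.2, 0.3, 0.5], ["s0", "s1"],
            [[0.8, 0.4, 0.2], [0.3, 0.6, 0.1]],
        )
        scaled = make_probbase(
            ["a", "b", "c"], [0.2, 0.3, 0.5], ["s0", "s1"],
            [[0.4, 0.2, 0.1], [0.3, 0.6, 0.1]],  # s0 row halved
        )
        p1 = assign_probabilistic(record, base, 0.0).posterior
        p2 = assign_probabilistic(record, scaled, 0.0).posterior
        for c in "abc":
            assert p1[c] == pytest.approx(p2[c], abs=1e-9)

    @given(st.floats(0.1, 0.85))
    def test_monotone_in_observed_conditional(self, low):
        """Raising P(s|c) for an observed-yes indicator never lowers
        posterior(c)."""
        record = VARecord("d1", 100, indicators={"s0": "yes"})
        high = low + 0.1
        pb_low = make_probbase(["a", "b"], [0.5, 0.5], ["s0"], [[low, 0.5]])
        pb_high = make_probbase(["a", "b"], [0.5, 0.5], ["s0"], [[high, 0.5]])
        assert (
            assign_probabilistic(record, pb_high, 0.0).posterior["a"]
            >= assign_probabilistic(record, pb_low, 0.0).posterior["a"]
        )

    def test_flat_conditionals_return_prior_for_any_record(self):
        pb = make_probbase(
            ["a", "b", "c"], [0.2, 0.3, 0.5], ["s0", "s1"],
            [[0.4, 0.4, 0.4], [0.7, 0.7, 0.7]],
        )
        record = VARecord("d1", 100, indicators={"s0": "yes", "s1": "yes"})
        post = assign_probabilistic(record, pb, 0.0).posterior
        assert post["a"] == pytest.approx(0.2, abs=1e-9)
        assert post["c"] == pytest.approx(0.5, abs=1e-9)


class TestInjectScdIndicator:
    def test_narrative_hit_sets_yes(self):
        r = VARecord("d1", 100, narrative="attends the sickle cell clinic")
        assert inject_scd_indicator(r).indicators[SCD_MENTION] == "yes"

    def test_no_hit_sets_no_and_original_unmodified(self):
        r = VARecord("d1", 100, narrative="pneumonia and fever")
        out = inject_scd_indicator(r)
        assert out.indicators[SCD_MENTION] == "no"
        assert SCD_MENTION not in r.indicators

    def test_idempotent(self):
        r = VARecord("d1", 100, narrative="known sickler")
        assert inject_scd_indicator(inject_scd_indicator(r)) == inject_scd_indicator(r)
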