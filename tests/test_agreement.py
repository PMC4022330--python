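"""Gwet AC1: formula, variance, CI, and prevalence-paradox behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaconcord.agreement import (
    ContingencyTable,
    ac1,
    cause_specific_table,
    cohens_kappa,
    compare_methods,
    contingency_from_assignments,
    jackknife_se,
    population_ac1,
)
from vaconcord.records import CauseAssignment, ValidationError, default_categories


def oracle_ac1(counts):
    """Independent evaluation of AC1 from the definitional quantities.

    Written directly from the definitions: observed agreement is the
    diagonal mass; the chance term averages the two marginals per
    category and sums pi(1-pi)/(Q-1) by explicit loop.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    q = counts.shape[0]
    pa = sum(counts[i, i] for i in range(q)) / n
    pe = 0.0
    for i in range(q):
        pi = (counts[i, :].sum() / n + counts[:, i].sum() / n) / 2.0
        pe += pi * (1.0 - pi)
    pe /= q - 1
    return (pa - pe) / (1.0 - pe)


def table(counts, categories=None):
    counts = np.asarray(counts, dtype=int)
    cats = categories or tuple(f"c{i}" for i in range(counts.shape[0]))
    return ContingencyTable(tuple(cats), counts)


class TestAC1Point:
    def test_perfect_agreement_is_one(self):
        for counts in ([[40, 0], [0, 5]], [[10, 0, 0], [0, 1, 0], [0, 0, 30]]):
            res = ac1(table(counts))
            assert res.pa == 1.0
            assert res.ac1 == pytest.approx(1.0, abs=1e-12)

    def test_worked_2x2_example(self):
        # pa = 0.90, pi = (0.45, 0.55), pe = 0.495, ac1 = 0.405/0.505
        res = ac1(table([[40, 5], [5, 50]]))
        assert res.pa == pytest.approx(0.90, abs=1e-12)
        assert res.pe == pytest.approx(0.495, abs=1e-12)
        assert res.ac1 == pytest.approx(0.405 / 0.505, abs=1e-12)
        assert res.ac1 == pytest.approx(oracle_ac1([[40, 5], [5, 50]]), abs=1e-12)

    def test_zero_diagonal_gives_minus_one(self):
        res = ac1(table([[0, 3], [3, 0]]))
        assert res.pa == 0.0
        assert res.pe == pytest.approx(0.5, abs=1e-12)
        assert res.ac1 == pytest.approx(-1.0, abs=1e-12)

    def test_identity_relation_holds(self):
        res = ac1(table([[12, 3, 1], [2, 20, 4], [0, 5, 9]]))
        assert res.ac1 == pytest.approx((res.pa - res.pe) / (1 - res.pe), abs=1e-12)
        assert res.ci_low <= res.ac1 <= res.ci_high

    def test_balanced_binary_marginals_give_pe_half(self):
        # Q=2 with both mean marginals 0.5
        res = ac1(table([[25, 10], [10, 25]]))
        assert res.pe == pytest.approx(0.5, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            ac1(table([[1, 0], [0, 0]]))

    @settings(max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ).filter(lambda c: sum(map(sum, c)) >= 2)
    )
    def test_permutation_invariance(self, counts):
        counts = np.array(counts)
        perm = np.array([2, 0, 1])
        permuted = counts[np.ix_(perm, perm)]
        assert ac1(table(counts)).ac1 == pytest.approx(
            ac1(table(permuted)).ac1, abs=1e-12
        )

    @settings(max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ).filter(lambda c: sum(map(sum, c)) >= 2)
    )
    def test_agrees_with_independent_oracle(self, counts):
        assert ac1(table(np.array(counts))).ac1 == pytest.approx(
            oracle_ac1(counts), abs=1e-12
        )


class TestPrevalenceParadox:
    def test_ac1_stays_high_at_extreme_prevalence(self):
        """High observed agreement with a <5% category: AC1 > 0.9 where
        kappa collapses — the reason this coefficient is used."""
        counts = [[4, 2], [2, 192]]  # pa = 0.98, prevalence 3%
        t = table(counts)
        res = ac1(t)
        assert res.pa > 0.95
        assert res.ac1 > 0.9
        assert cohens_kappa(t) < res.ac1

    def test_all_negative_cause_table_defined_and_one(self):
        # both methods never assign the cause: pi = (0, 1) so pe = 0, ac1 = 1
        res = ac1(table([[0, 0], [0, 20]]))
        assert res.pe == 0.0
        assert res.ac1 == 1.0


class TestVariance:
    def _simulated_table(self, rng, n=300):
        joint = np.array([[0.35, 0.05, 0.05], [0.05, 0.20, 0.05], [0.03, 0.02, 0.20]])
        idx = rng.choice(9, size=n, p=joint.ravel())
        counts = np.bincount(idx, minlength=9).reshape(3, 3)
        return table(counts)

    def test_linearized_se_close_to_jackknife(self, rng):
        """The subject-level linearization and the delete-one jackknife are
        two routes to the same sampling variance; for n >= 200 they must
        agree within 15% relative difference."""
        for _ in range(5):
            t = self._simulated_table(rng)
            se_lin = ac1(t).se
            se_jack = jackknife_se(t)
            assert se_lin == pytest.approx(se_jack, rel=0.15)

    def test_perfect_agreement_zero_se(self):
        res = ac1(table([[40, 0], [0, 60]]))
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.ci_high == 1.0

    def test_ci_truncated_at_one(self):
        res = ac1(table([[40, 1], [0, 60]]))
        assert res.ci_high <= 1.0


class TestCauseSpecific:
    def _assign(self, method, codes):
        return [CauseAssignment(f"d{i}", method, c) for i, c in enumerate(codes)]

    def test_binarization_counts(self):
        a = self._assign("a", ["4.03", "1.05", "4.03", "98"])
        b = self._assign("b", ["4.03", "4.03", "1.02", "98"])
        t, excluded = cause_specific_table(a, b, "4.03")
        assert excluded == 0
        assert t.counts.tolist() == [[1, 1], [1, 1]]

    def test_undetermined_excluded_pairwise(self):
        a = self._assign("a", ["4.03", "undetermined", "1.05"])
        b = self._assign("b", ["4.03", "1.05", "1.05"])
        t, excluded = cause_specific_table(a, b, "4.03")
        assert excluded == 1
        assert t.n == 2

    def test_record_set_mismatch_rejected(self):
        a = self._assign("a", ["4.03"])
        b = [CauseAssignment("other", "b", "4.03")]
        with pytest.raises(ValidationError):
            cause_specific_table(a, b, "4.03")

    def test_reconstructed_scd_table_metrics(self):
        """A 2x2 with TP=5, FN=1, FP=1, TN=127 (n=134, ~5% marginals) has
        sensitivity and PPV both 5/6 ~ 83%."""
        counts = np.array([[5, 1], [1, 127]])
        t = table(counts, categories=("4.03", "not_4.03"))
        assert t.n == 134
        sens = counts[0, 0] / counts[0].sum()
        ppv = counts[0, 0] / counts[:, 0].sum()
        assert sens == pytest.approx(5 / 6)
        assert ppv == pytest.approx(5 / 6)
        assert ac1(t).ac1 > 0.9


class TestCompareMethods:
    def _assign(self, method, codes):
        return [CauseAssignment(f"d{i}", method, c) for i, c in enumerate(codes)]

    def test_identical_methods_all_ones(self):
        cats = default_categories()
        codes = [c.code for c in cats] * 3
        a = self._assign("a", codes)
        b = self._assign("b", codes)
        cmp = compare_methods(a, b, cats, causes=["4.03", "1.05"])
        assert cmp.all_cause.ac1 == pytest.approx(1.0, abs=1e-12)
        for res in cmp.per_cause.values():
            assert res.ac1 == pytest.approx(1.0, abs=1e-12)

    def test_swapped_arguments_identical(self, default_sim):
        cats = default_categories()
        ab = compare_methods(default_sim.coder1, default_sim.coder2, cats, ["4.03"])
        ba = compare_methods(default_sim.coder2, default_sim.coder1, cats, ["4.03"])
        assert ab.all_cause.ac1 == pytest.approx(ba.all_cause.ac1, abs=1e-12)
        assert ab.per_cause["4.03"].se == pytest.approx(ba.per_cause["4.03"].se, abs=1e-12)


class TestPopulationAC1:
    def test_diagonal_joint_gives_one(self):
        joint = np.diag([0.3, 0.3, 0.4])
        assert population_ac1(joint) == pytest.approx(1.0)

    def test_matches_sample_estimate_at_large_n(self, rng):
        joint = np.array([[0.40, 0.05], [0.05, 0.50]])
        idx = rng.choice(4, size=100_000, p=joint.ravel())
        counts = np.bincount(idx, minlength=4).reshape(2, 2)
        sample = ac1(table(counts)).ac1
        assert sample == pytest.approx(population_ac1(joint), abs=0.02)
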