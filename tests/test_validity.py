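"""Diagnostic validity, CSMFs, lab gold standard, expected SCD burden."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vaconcord.records import (
    CauseAssignment,
    GoldStandardRecord,
    ValidationError,
    default_categories,
)
from vaconcord.validity import (
    ValidityResult,
    csmf,
    csmf_delta,
    expected_scd_death_share,
    lab_gold_standard,
    reconstruct_confusion_tables,
    validity,
)


def assign(method, codes):
    return [CauseAssignment(f"d{i}", method, c) for i, c in enumerate(codes)]


class TestValidity:
    def test_perfect_prediction_all_metrics_one(self):
        codes = ["4.03", "1.05", "1.02", "4.03", "98"]
        r = validity(assign("p", codes), assign("g", codes), "4.03")
        assert (r.sensitivity, r.specificity, r.ppv, r.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_reconstructed_scd_row_arithmetic(self):
        r = ValidityResult("4.03", tp=5, fn=1, fp=1, tn=127)
        assert r.sensitivity == pytest.approx(5 / 6, abs=1e-3)
        assert r.specificity == pytest.approx(127 / 128, abs=1e-3)
        assert r.ppv == pytest.approx(5 / 6, abs=1e-3)
        assert r.npv == pytest.approx(127 / 128, abs=1e-3)

    def test_gold_all_negative_sensitivity_undefined(self):
        pred = assign("p", ["4.03", "1.05"])
        gold = assign("g", ["1.05", "1.05"])
        r = validity(pred, gold, "4.03")
        assert r.sensitivity is None  # undefined, never 0
        assert r.specificity is not None

    def test_undetermined_prediction_counts_negative(self):
        pred = assign("p", ["undetermined", "4.03"])
        gold = assign("g", ["4.03", "4.03"])
        r = validity(pred, gold, "4.03")
        assert (r.tp, r.fn) == (1, 1)

    def test_undetermined_gold_rejected(self):
        with pytest.raises(ValidationError):
            validity(assign("p", ["4.03"]), assign("g", ["undetermined"]), "4.03")

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValidationError):
            validity([], [], "4.03")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["4.03", "1.05", "98"]),
                st.sampled_from(["4.03", "1.05", "98"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_exchange_consistency(self, pairs):
        """Swapping prediction and gold swaps sensitivity<->PPV and
        specificity<->NPV."""
        pred = assign("p", [p for p, _ in pairs])
        gold = assign("g", [g for _, g in pairs])
        fwd = validity(pred, gold, "4.03")
        rev = validity(gold, pred, "4.03")
        assert fwd.sensitivity == rev.ppv
        assert fwd.specificity == rev.npv


class TestLabGoldStandard:
    def test_phenotype_rules(self):
        lab = [
            GoldStandardRecord("d1", "lab", phenotype="HbSS"),
            GoldStandardRecord("d2", "lab", phenotype="HbAS"),
            GoldStandardRecord("d3", "lab", phenotype="HbAA"),
        ]
        out = {a.record_id: a.cause_code for a in lab_gold_standard(lab)}
        assert out["d1"] == "4.03"  # HbSS is SCD
        assert out["d2"] == "not_scd"  # carriers are not diseased
        assert out["d3"] == "not_scd"

    def test_missing_phenotype_excluded(self):
        lab = [
            GoldStandardRecord("d1", "lab", phenotype="HbSS"),
            GoldStandardRecord("d2", "lab", phenotype=None),
        ]
        assert [a.record_id for a in lab_gold_standard(lab)] == ["d1"]


class TestCSMF:
    def test_single_cause(self):
        vec = csmf(assign("m", ["1.05"] * 10))
        assert vec.fractions == {"1.05": 1.0}
        assert vec.n_undetermined == 0

    def test_malaria_fraction_example(self):
        codes = ["1.05"] * 84 + ["98"] * 526
        vec = csmf(assign("m", codes))
        assert vec.fractions["1.05"] == pytest.approx(84 / 610, abs=1e-12)
        assert round(100 * vec.fractions["1.05"]) == 14

    def test_undetermined_counted_separately(self):
        vec = csmf(assign("m", ["1.05", "4.03", "undetermined", "undetermined"]))
        assert vec.n_undetermined == 2
        assert vec.fractions["1.05"] == 0.5
        assert sum(vec.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_category_list_includes_zero_causes(self):
        vec = csmf(assign("m", ["1.05"]), default_categories())
        assert vec.fractions["4.03"] == 0.0

    def test_order_invariance(self):
        codes = ["1.05", "4.03", "98", "1.05"]
        assert (
            csmf(assign("m", codes)).fractions
            == csmf(assign("m", list(reversed(codes)))).fractions
        )


class TestCSMFDelta:
    def test_identical_vectors_all_zero(self):
        v = csmf(assign("m", ["1.05", "4.03"]))
        assert all(d == 0 for d in csmf_delta(v, v).values())

    def test_percentage_point_arithmetic(self):
        a = csmf(assign("m", ["A"] * 60 + ["B"] * 40))
        b = csmf(assign("m", ["A"] * 55 + ["B"] * 45))
        delta = csmf_delta(a, b)
        assert delta["A"] == pytest.approx(5.0, abs=1e-9)
        assert delta["B"] == pytest.approx(-5.0, abs=1e-9)

    def test_antisymmetry(self):
        a = csmf(assign("m", ["A", "A", "B"]))
        b = csmf(assign("m", ["A", "B", "B"]))
        dab, dba = csmf_delta(a, b), csmf_delta(b, a)
        assert all(dab[c] == pytest.approx(-dba[c]) for c in dab)

    def test_category_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            csmf_delta(csmf(assign("m", ["A"])), csmf(assign("m", ["B"])))


class TestExpectedScdDeathShare:
    def test_study_assumptions_give_ten_percent(self):
        # 0.8% affected births, half dying under five, 40/1000 mortality
        assert expected_scd_death_share(0.008, 0.5, 0.04) == pytest.approx(0.10)

    def test_identity_case(self):
        assert expected_scd_death_share(0.03, 1.0, 0.03) == pytest.approx(1.0)

    def test_higher_case_fatality(self):
        assert expected_scd_death_share(0.008, 0.9, 0.04) == pytest.approx(0.18)

    def test_zero_mortality_rejected(self):
        with pytest.raises(ValidationError):
            expected_scd_death_share(0.008, 0.5, 0.0)


class TestReconstruction:
    def test_search_recovers_published_style_scd_row(self):
        hits = reconstruct_confusion_tables(134, 83, 99, 83, 99)
        assert len(hits) == 1
        r = hits[0]
        assert (r.tp, r.fn, r.fp, r.tn) == (5, 1, 1, 127)

    def test_search_recovers_consensus_style_row(self):
        hits = reconstruct_confusion_tables(134, 83, 98, 63, 99)
        assert any((r.tp, r.fn, r.fp, r.tn) == (5, 1, 3, 125) for r in hits)
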