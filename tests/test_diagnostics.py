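"""Confusion matrices, Wilson intervals, odds ratios, cutoff selection and
reconstruction of integer 2x2 tables from rounded percentages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thyrisk.diagnostics import (
    ConfusionMatrix,
    ProportionTest,
    Rounding,
    balanced_accuracy,
    compare_proportions,
    confusion_from_scores,
    exclude_subgroup,
    mcnemar_test,
    odds_ratio,
    performance,
    reconstruct_matrix,
    select_cutoff,
    wilson_ci,
)
from thyrisk.errors import ValidationError
from thyrisk.risk import Truth

MAL, BEN = Truth.MALIGNANT, Truth.BENIGN


def scores_labels_for(m: ConfusionMatrix, positive=0.9, negative=0.1):
    """Score/label vectors realizing a given confusion matrix at cutoff 0.9."""
    scores = [positive] * m.tp + [negative] * m.fn + [positive] * m.fp + [negative] * m.tn
    truths = [MAL] * (m.tp + m.fn) + [BEN] * (m.fp + m.tn)
    return scores, truths


class TestConfusionFromScores:
    def test_tally(self):
        m = confusion_from_scores([0.9, 0.1], [MAL, BEN], cutoff=0.9)
        assert m.as_tuple() == (1, 0, 0, 1)

    def test_all_below_cutoff(self):
        m = confusion_from_scores([0.1, 0.2], [MAL, BEN], cutoff=0.9)
        assert m.tp == 0 and m.fp == 0

    def test_cutoff_comparison_is_inclusive_with_tolerance(self):
        m = confusion_from_scores([0.2 + 0.5], [MAL], cutoff=0.7)
        assert m.tp == 1

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="scores vs"):
            confusion_from_scores([0.9], [MAL, BEN], 0.9)

    def test_empty_input(self):
        with pytest.raises(ValidationError, match="empty"):
            confusion_from_scores([], [], 0.9)


class TestPerformance:
    def test_trs_table_metrics(self, trs_table):
        p = performance(trs_table)
        assert p.sensitivity == pytest.approx(22 / 26)
        assert p.specificity == pytest.approx(18 / 21)
        assert p.ppv == pytest.approx(0.88)
        assert p.npv == pytest.approx(18 / 22)
        # forward metrics re-round to the published presentation
        assert (round(p.sensitivity * 100, 1), round(p.specificity * 100, 1)) == (84.6, 85.7)
        assert (round(p.ppv * 100), round(p.npv * 100, 1)) == (88, 81.8)

    def test_xus_table_metrics(self, xus_table):
        p = performance(xus_table)
        assert p.sensitivity == pytest.approx(9 / 26)
        assert p.specificity == pytest.approx(19 / 21)
        assert p.ppv == pytest.approx(9 / 11)
        assert p.npv == pytest.approx(19 / 36)

    def test_empty_positive_margin_gives_undefined_ppv(self):
        p = performance(ConfusionMatrix(tp=0, fp=0, fn=1, tn=1))
        assert p.ppv is None and p.ci_ppv is None
        assert p.sensitivity == 0.0

    def test_every_ci_contains_its_point_estimate(self, trs_table):
        p = performance(trs_table)
        for value, ci in [
            (p.sensitivity, p.ci_sensitivity),
            (p.specificity, p.ci_specificity),
            (p.ppv, p.ci_ppv),
            (p.npv, p.ci_npv),
        ]:
            assert ci[0] <= value <= ci[1]


def wilson_closed_form(k, n, z=1.959963984540054):
    """Independent closed-form oracle for the Wilson score interval."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestWilsonCI:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (22, 25, (0.700, 0.958)),
            (19, 36, (0.370, 0.680)),
            (18, 22, (0.615, 0.927)),
        ],
    )
    def test_published_style_intervals(self, k, n, expected):
        low, high = wilson_ci(k, n)
        assert round(low, 3) == expected[0]
        assert round(high, 3) == expected[1]

    def test_zero_successes_hits_exact_zero(self):
        low, _ = wilson_ci(0, 10)
        assert low == 0.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValidationError):
            wilson_ci(0, 0)

    @settings(derandomize=True, max_examples=150)
    @given(n=st.integers(1, 200), k=st.data())
    def test_interval_properties_against_closed_form(self, n, k):
        k = k.draw(st.integers(0, n))
        low, high = wilson_ci(k, n)
        tol = 1e-12
        assert 0.0 <= low <= k / n + tol and k / n - tol <= high <= 1.0
        ref_low, ref_high = wilson_closed_form(k, n)
        assert low == pytest.approx(max(ref_low, 0.0), abs=1e-10)
        assert high == pytest.approx(min(ref_high, 1.0), abs=1e-10)
        # reflection symmetry: the interval for n-k mirrors about 1/2
        rlow, rhigh = wilson_ci(n - k, n)
        assert rlow == pytest.approx(1 - high, abs=1e-10)
        assert rhigh == pytest.approx(1 - low, abs=1e-10)


class TestBalancedAccuracy:
    def test_published_accuracies(self, trs_table, xus_table):
        assert round(balanced_accuracy(trs_table) * 100, 1) == 85.2
        assert round(balanced_accuracy(xus_table) * 100, 1) == 62.5

    def test_perfect_matrix(self):
        assert balanced_accuracy(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5)) == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            balanced_accuracy(ConfusionMatrix(tp=1, fp=0, fn=1, tn=0))

    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_equals_single_threshold_roc_auc(self, tp, fp, fn, tn):
        """Balanced accuracy of a dichotomized test is its ROC AUC."""
        if tp + fn == 0 or fp + tn == 0:
            return
        from sklearn.metrics import roc_auc_score

        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        calls = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        y = [1] * (tp + fn) + [0] * (fp + tn)
        assert balanced_accuracy(m) == pytest.approx(roc_auc_score(y, calls))


class TestOddsRatio:
    def test_xus_odds_ratio_reproduces_published_values(self, xus_table):
        res = odds_ratio(xus_table)
        assert round(res.or_value, 2) == 5.03
        assert round(res.ci[0], 2) == 0.95
        assert round(res.ci[1], 1) == 26.6

    def test_symmetric_table(self):
        assert odds_ratio(ConfusionMatrix(1, 1, 1, 1)).or_value == pytest.approx(1.0)

    def test_zero_cell_continuity_correction(self):
        res = odds_ratio(ConfusionMatrix(tp=5, fp=0, fn=2, tn=7))
        assert math.isfinite(res.or_value) and res.or_value > 0
        assert res.ci[0] > 0 and math.isfinite(res.ci[1])
        assert "haldane" in res.method

    def test_matches_woolf_closed_form(self, xus_table):
        m = xus_table
        or_hand = m.tp * m.tn / (m.fp * m.fn)
        se = math.sqrt(1 / m.tp + 1 / m.fp + 1 / m.fn + 1 / m.tn)
        z = stats.norm.ppf(0.975)
        res = odds_ratio(m)
        assert res.or_value == pytest.approx(or_hand)
        assert res.ci[0] == pytest.approx(or_hand * math.exp(-z * se), rel=1e-9)
        assert res.ci[1] == pytest.approx(or_hand * math.exp(z * se), rel=1e-9)


class TestSelectCutoff:
    def test_picks_highest_balanced_accuracy_verified_exhaustively(self):
        # cohort over the ultrasound lattice; candidate accuracies differ
        scores = [0.9] * 12 + [0.2] * 10 + [0.1] * 4 + [0.9] * 3 + [0.2] * 6 + [0.1] * 12
        truths = [MAL] * 26 + [BEN] * 21
        candidates = [0.1, 0.2, 0.9]
        best, table = select_cutoff(scores, truths, candidates)
        by_hand = {
            c: balanced_accuracy(confusion_from_scores(scores, truths, c)) for c in candidates
        }
        assert best == max(by_hand, key=by_hand.get)
        assert len(table) == 3
        assert set(table["cutoff"]) == set(candidates)

    def test_specificity_tiebreak_prefers_more_specific_cutoff(self):
        # two cutoffs with equal balanced accuracy; the higher one is more specific
        scores = [0.9] * 5 + [0.2] * 5 + [0.2] * 5 + [0.1] * 5
        truths = [MAL] * 10 + [BEN] * 10
        best, table = select_cutoff(scores, truths, [0.2, 0.9], specificity_tiebreak_tol=0.5)
        spec = dict(zip(table["cutoff"], table["specificity"]))
        assert spec[best] == max(spec.values())

    def test_identical_candidates_first_listed_wins(self):
        scores, truths = [0.9, 0.1], [MAL, BEN]
        best, _ = select_cutoff(scores, truths, [0.5, 0.5])
        assert best == 0.5

    def test_single_candidate(self):
        best, _ = select_cutoff([0.9, 0.1], [MAL, BEN], [0.9])
        assert best == 0.9

    def test_single_class_truths_rejected(self):
        with pytest.raises(ValidationError, match="single class"):
            select_cutoff([0.9, 0.1], [MAL, MAL], [0.9])


class TestCompareProportions:
    def test_two_proportion_z_matches_hand_computation(self):
        """Pooled z for 9/26 vs 22/26 is about 3.67, p about 2.4e-4."""
        p = compare_proportions(9, 26, 22, 26, ProportionTest.TWO_PROP_Z)
        pooled = 31 / 52
        se = math.sqrt(pooled * (1 - pooled) * (1 / 26 + 1 / 26))
        z = (22 / 26 - 9 / 26) / se
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)
        assert p < 0.001

    def test_identical_proportions_give_p_one(self):
        assert compare_proportions(5, 10, 10, 20) == 1.0

    def test_fisher_extreme_table(self):
        p = compare_proportions(0, 10, 10, 10, ProportionTest.FISHER)
        # exact hypergeometric tail of the 0/10 vs 10/10 table
        assert p == pytest.approx(stats.fisher_exact([[0, 10], [10, 0]]).pvalue)
        assert p < 1e-4

    def test_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            compare_proportions(0, 0, 1, 2)

    def test_mcnemar_paired_variant(self):
        assert mcnemar_test(5, 5) == pytest.approx(1.0)
        assert mcnemar_test(10, 0) < 0.01


class TestExcludeSubgroup:
    def test_mtc_removal_from_trs_table(self, trs_table):
        sub = exclude_subgroup(trs_table, remove_tp=3)
        assert sub.as_tuple() == (19, 3, 4, 18)
        assert round(sub.tp / sub.malignant_margin * 100, 1) == 82.6

    def test_zero_removal_is_identity(self, trs_table):
        assert exclude_subgroup(trs_table) == trs_table

    def test_over_removal_rejected(self, trs_table):
        with pytest.raises(ValidationError):
            exclude_subgroup(trs_table, remove_tp=trs_table.tp + 1)


class TestReconstructMatrix:
    def test_xus_quadruple_unique(self):
        sols = reconstruct_matrix(
            {"sensitivity": (34.6, 1), "specificity": (90, 0),
             "ppv": (81.8, 1), "npv": (52.8, 1)},
            n_total=47,
        )
        assert [m.as_tuple() for m in sols] == [(9, 2, 17, 19)]

    def test_trs_quadruple_unique(self):
        sols = reconstruct_matrix(
            {"sensitivity": (84.6, 1), "specificity": (85.7, 1),
             "ppv": (88, 0), "npv": (81.8, 1)},
            n_total=47,
        )
        assert [m.as_tuple() for m in sols] == [(22, 3, 4, 18)]

    def test_perfect_classifier_family(self):
        sols = reconstruct_matrix(
            {"sensitivity": (100, 0), "specificity": (100, 0),
             "ppv": (100, 0), "npv": (100, 0)},
            n_total=4,
        )
        assert {m.as_tuple() for m in sols} == {(1, 0, 0, 3), (2, 0, 0, 2), (3, 0, 0, 1)}

    def test_inconsistent_quadruple_has_no_solution(self):
        sols = reconstruct_matrix(
            {"sensitivity": (80.7, 1), "specificity": (94.7, 1),
             "ppv": (92.3, 1), "npv": (80, 0)},
            n_total=47,
            rounding=Rounding.ANY,
        )
        assert sols == []

    def test_truncated_sensitivity_needs_floor_mode(self):
        """80.7 truncates 21/26 = 80.769...; half-up alone cannot match it."""
        printed = {"sensitivity": (80.7, 1)}
        bounds = ((26, 26), (1, 1))
        half_up = reconstruct_matrix(printed, margin_bounds=bounds)
        any_mode = reconstruct_matrix(printed, margin_bounds=bounds, rounding="any")
        assert all(m.tp != 21 for m in half_up)
        assert any(m.tp == 21 and m.fn == 5 for m in any_mode)

    def test_unbounded_search_rejected(self):
        with pytest.raises(ValidationError, match="bound"):
            reconstruct_matrix({"sensitivity": (50, 0)})

    @settings(derandomize=True, max_examples=25)
    @given(
        tp=st.integers(0, 12), fp=st.integers(0, 12),
        fn=st.integers(0, 12), tn=st.integers(0, 12),
        decimals=st.integers(0, 2),
    )
    def test_round_trip_contains_original(self, tp, fp, fn, tn, decimals):
        """Rounding a matrix's metrics and reconstructing recovers it."""
        if tp + fn == 0 or fp + tn == 0 or tp + fp == 0 or tn + fn == 0:
            return
        m = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        p = performance(m)
        printed = {
            "sensitivity": (round(p.sensitivity * 100, decimals), decimals),
            "specificity": (round(p.specificity * 100, decimals), decimals),
            "ppv": (round(p.ppv * 100, decimals), decimals),
            "npv": (round(p.npv * 100, decimals), decimals),
        }
        sols = reconstruct_matrix(printed, n_total=m.total, rounding=Rounding.ANY)
        assert m in sols
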