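"""Confusion counting, performance metrics, aggregation and exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycograd import (ConfusionMatrix, aggregate_metrics, confusion,
                       mann_whitney_exact, matrix_from_events, performance,
                       wilcoxon_exact)
from glycograd.errors import AnalysisError


def _events(outcomes, **extra):
    df = pd.DataFrame({"outcome": list(outcomes)})
    for key, values in extra.items():
        df[key] = values
    return df


class TestConfusion:
    def test_simple_counting(self):
        cm = matrix_from_events(_events(["TP", "TP", "TP", "FN"]))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 0, 0, 1)

    def test_empty_group_omitted(self):
        out = confusion(_events([], hypothesis=[]), ("hypothesis",))
        assert out.empty

    def test_pooled_equals_sum_of_per_width(self):
        rng = np.random.default_rng(3)
        ev = _events(rng.choice(["TP", "TN", "FP", "FN"], 200),
                     width_minutes=rng.choice([20, 40, 60], 200))
        per_width = confusion(ev, ("width_minutes",))
        pooled = confusion(ev)
        for col in ("tp", "tn", "fp", "fn"):
            assert per_width[col].sum() == pooled.loc[0, col]

    def test_counts_match_bruteforce_recount(self):
        rng = np.random.default_rng(8)
        outcomes = rng.choice(["TP", "TN", "FP", "FN"], 150)
        cm = matrix_from_events(_events(outcomes))
        assert cm.tp == sum(o == "TP" for o in outcomes)
        assert cm.fn == sum(o == "FN" for o in outcomes)
        assert cm.total == 150


class TestPerformance:
    def test_worked_small_matrix(self):
        ms = performance(ConfusionMatrix(2, 2, 1, 1))
        assert ms.accuracy == pytest.approx(4 / 6)
        assert ms.mcc == pytest.approx(1 / 3)

    def test_perfect_matrix(self):
        ms = performance(ConfusionMatrix(3, 4, 0, 0))
        for name in ("accuracy", "precision", "sensitivity", "specificity",
                     "f1", "mcc"):
            assert getattr(ms, name) == 1.0

    def test_degenerate_column_undefined_not_zero(self):
        ms = performance(ConfusionMatrix(0, 5, 0, 0))
        assert ms.specificity == 1.0
        assert math.isnan(ms.precision)
        assert math.isnan(ms.sensitivity)
        assert math.isnan(ms.f1)
        assert math.isnan(ms.mcc)

    def test_empty_matrix_rejected(self):
        with pytest.raises(AnalysisError):
            performance(ConfusionMatrix(0, 0, 0, 0))

    def test_mcc_bounds_and_extremes(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            cm = ConfusionMatrix(*(int(v) for v in rng.integers(0, 30, 4)))
            if cm.total == 0:
                continue
            mcc = performance(cm).mcc
            if not math.isnan(mcc):
                assert -1.0 <= mcc <= 1.0
        assert performance(ConfusionMatrix(5, 5, 0, 0)).mcc == 1.0
        assert performance(ConfusionMatrix(0, 0, 5, 5)).mcc == -1.0


class TestAggregate:
    def test_single_value(self):
        agg = aggregate_metrics([88.2])
        assert agg.mean == agg.median == agg.mode == 88.2
        assert math.isnan(agg.std)

    def test_even_count_median_midpoint(self):
        agg = aggregate_metrics([1.0, 2.0, 3.0, 10.0])
        assert agg.median == 2.5

    def test_mode_ties_resolve_to_smallest_with_flag(self):
        agg = aggregate_metrics([1.0, 1.0, 4.0, 4.0, 9.0])
        assert agg.mode == 1.0
        assert agg.multimodal

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            aggregate_metrics([])


class TestWilcoxonExact:
    def test_eight_uniform_pairs(self):
        """Perfect directional consistency: W=0, p=2/256, r=1."""
        res = wilcoxon_exact([5, 6, 7, 8, 9, 10, 11, 12],
                             [1, 2, 3, 4, 5, 6, 7, 8])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 256)
        assert res.effect_size == 1.0

    def test_balanced_pair_zero_effect(self):
        res = wilcoxon_exact([1.0, -1.0])
        assert res.effect_size == 0.0

    def test_three_positive_pairs(self):
        res = wilcoxon_exact([0.5, 1.0, 2.0])
        assert res.p_value == pytest.approx(2 / 8)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(AnalysisError):
            wilcoxon_exact([0.0, 0.0])

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_p_matches_full_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.3, 1.0, n)
        d = d[d != 0]
        res = wilcoxon_exact(d)
        ranks = stats.rankdata(np.abs(d))
        # brute force over all 2^n sign assignments
        count_le = 0
        for signs in itertools.product([1, -1], repeat=len(d)):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w_plus <= res.statistic + 1e-12:  # null distribution of W+
                count_le += 1
        expected_p = min(1.0, 2 * count_le / 2 ** len(d))
        assert res.p_value == pytest.approx(expected_p)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            d = rng.normal(0.4, 1.0, 9)
            ours = wilcoxon_exact(d)
            ref = stats.wilcoxon(d, method="exact")
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)


class TestMannWhitneyExact:
    def test_complete_separation_of_eights(self):
        res = mann_whitney_exact(range(10, 18), range(8))
        assert res.statistic == 64.0
        assert res.method == "mann_whitney_exact"

    def test_identical_groups_half_max(self):
        res = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # m*n/2

    def test_two_vs_two_enumeration(self):
        res = mann_whitney_exact([1, 2], [3, 4])
        assert res.statistic == 4.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            mann_whitney_exact([], [1.0])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            a = rng.normal(0.0, 1.0, 7)
            b = rng.normal(0.8, 1.0, 6)
            ours = mann_whitney_exact(a, b)
            ref = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            u_max = max(ref.statistic, len(a) * len(b) - ref.statistic)
            assert ours.statistic == pytest.approx(u_max)
            assert ours.p_value == pytest.approx(ref.pvalue)
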