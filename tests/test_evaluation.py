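"""Metrics and the repeated-subsampling / calibration protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from emrprep import evaluation
from emrprep.evaluation import (auprc, auroc, brier, f1, recall,
                                reliability_curve, subsample_evaluate)


def brute_force_auroc(scores, labels):
    """Exhaustive pairwise concordance with half-credit ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def brute_force_auprc(scores, labels):
    """Step integration of the precision envelope over all thresholds."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    pts = []  # (recall, precision) at every distinct threshold
    n_pos = y.sum()
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tp = float((pred & (y == 1)).sum())
        pts.append((tp / n_pos, tp / pred.sum()))
    pts = sorted(pts)
    area, prev_r = 0.0, 0.0
    for i, (r, _) in enumerate(pts):
        env = max(p for rr, p in pts if rr >= r)
        area += (r - prev_r) * env
        prev_r = r
    return area


class TestAUROC:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.6, 0.6], [1, 0]) == 0.5

    def test_single_inversion_is_eight_ninths(self):
        # 3 pos / 3 neg, one swapped pair -> 8 of 9 concordant
        scores = [0.9, 0.8, 0.4, 0.5, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        assert auroc(scores, labels) == pytest.approx(8 / 9)
        assert brute_force_auroc(scores, labels) == pytest.approx(8 / 9)

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_exhaustive_pair_counting(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(4, 21)
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() == n:
            labels[0] = 0
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=15),
           st.floats(0.1, 3.0))
    def test_invariant_under_monotone_transform(self, raw, scale):
        # scores on a 0.1 grid keep exp() numerically injective
        scores = np.asarray(raw) / 10.0
        labels = (np.arange(len(scores)) % 2)
        transformed = np.exp(scale * scores)
        assert auroc(scores, labels) == pytest.approx(
            auroc(transformed, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAUPRC:
    def test_perfect_scorer(self):
        assert auprc([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_envelope(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = rng.integers(4, 16)
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() == n:
            labels[0] = 0
        scores = np.round(rng.random(n), 1)
        assert auprc(scores, labels) == pytest.approx(
            brute_force_auprc(scores, labels), abs=1e-9)


class TestBrier:
    def test_perfect_probabilities(self):
        assert brier([1.0, 1.0, 0.0], [1, 1, 0]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 8, [1, 0] * 4) == 0.25

    def test_hand_arithmetic(self):
        assert brier([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2, 0.5], [1, 0])

    @pytest.mark.parametrize("p,pi", [(0.3, 0.2), (0.5, 0.5), (0.9, 0.05)])
    def test_constant_predictor_decomposition(self, p, pi):
        n = 200
        labels = np.zeros(n)
        labels[: int(pi * n)] = 1
        pi_emp = labels.mean()
        expected = pi_emp * (1 - p) ** 2 + (1 - pi_emp) * p ** 2
        assert brier(np.full(n, p), labels) == pytest.approx(expected)


class TestReliability:
    def test_calibrated_probabilities(self):
        rng = np.random.default_rng(0)
        p = rng.random(30_000)
        y = (rng.random(30_000) < p).astype(int)
        bins = reliability_curve(p, y, n_bins=10)
        assert len(bins) == 10
        for b in bins:
            assert abs(b["mean_predicted"] - b["observed_fraction"]) < 0.03

    def test_all_probabilities_in_one_bin(self):
        bins = reliability_curve([0.55, 0.56, 0.57], [1, 0, 1], n_bins=10)
        assert len(bins) == 1 and bins[0]["n"] == 3

    def test_single_bin_gives_prevalence(self):
        y = [1, 0, 0, 0]
        bins = reliability_curve([0.2, 0.4, 0.6, 0.8], y, n_bins=1)
        assert bins[0]["observed_fraction"] == pytest.approx(0.25)

    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        bins = reliability_curve(p, y, n_bins=7)
        assert sum(b["n"] for b in bins) == 500


class TestSubsampleEvaluate:
    def _data(self, n=300, seed=0, effect=3.0):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[: n // 3] = 1
        X = effect * y[:, None] + rng.normal(size=(n, 2))
        return X, y

    def test_strong_signal_high_auroc_with_ci_ordering(self):
        X, y = self._data()
        summary = subsample_evaluate(LogisticRegression(max_iter=500), X, y,
                                     B=20, seed=0)
        m = summary.metrics["auroc"]
        assert m["ci_low"] <= m["mean"] <= m["ci_high"]
        assert m["mean"] > 0.95
        for metric in summary.metrics.values():
            assert 0.0 <= metric["mean"] <= 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(800, 2))
        y = rng.integers(0, 2, 800)
        summary = subsample_evaluate(LogisticRegression(max_iter=500), X, y,
                                     B=30, seed=2)
        assert abs(summary.metrics["auroc"]["mean"] - 0.5) < 0.07

    def test_single_repeat_ci_equals_estimate(self):
        X, y = self._data(seed=3)
        summary = subsample_evaluate(LogisticRegression(max_iter=500), X, y,
                                     B=1, seed=3)
        m = summary.metrics["auroc"]
        assert m["ci_low"] == m["mean"] == m["ci_high"]

    def test_deterministic_under_seed(self):
        X, y = self._data(seed=4)
        a = subsample_evaluate(LogisticRegression(max_iter=500), X, y,
                               B=5, seed=7)
        b = subsample_evaluate(LogisticRegression(max_iter=500), X, y,
                               B=5, seed=7)
        assert a.metrics == b.metrics


class TestRatioExperiment:
    def test_balanced_cohort_ratios_collapse(self):
        from emrprep.synthetic import CohortSpec, generate_cohort
        cohort = generate_cohort(CohortSpec(n_pos=150, n_neg=150,
                                            n_continuous=3, n_discrete=0,
                                            n_diagnosis=0, seed=5))
        res = evaluation.ratio_experiment(
            cohort, LogisticRegression(max_iter=500), ratios=[(1, 1)],
            seed=5, B=3)
        balanced, original = res["ratios"]
        # 1:1 on already-balanced data keeps every row -> same n_train
        assert balanced["n_train"] == original["n_train"]
        assert balanced["test"]["auroc"] == pytest.approx(
            original["test"]["auroc"], abs=0.02)

    def test_rebalancing_trades_recall_for_calibration(self):
        from emrprep.synthetic import generate_cohort, study_spec
        cohort = generate_cohort(study_spec(seed=6, n_pos=150, n_neg=2850,
                                            missing=False))
        labs = cohort.variables_of_kind("continuous", "discrete")
        res = evaluation.ratio_experiment(
            cohort, LogisticRegression(max_iter=1000), ratios=[(1, 1)],
            seed=6, B=3, features=labs)
        balanced, original = res["ratios"]
        assert balanced["test"]["recall"] > original["test"]["recall"]
        assert balanced["test"]["brier"] > original["test"]["brier"]
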