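"""Model building: filters, separation handling, forward selection, zoo."""

import numpy as np
import pandas as pd
import pytest

from emrprep import modeling, pca
from emrprep.synthetic import CohortSpec, generate_cohort
from .conftest import toy_cohort


def _cohort_from_table(table):
    """variable x outcome contingency table -> toy cohort."""
    values, outcome = [], []
    for level, row in enumerate(table):
        for y, count in enumerate(row):
            values += [float(level)] * count
            outcome += [y] * count
    return toy_cohort({"v": values}, {"v": "discrete"}, outcome=outcome)


def _brute_chi2(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / total
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquareFilter:
    def test_independent_table_excluded(self):
        trace = modeling.chi_square_filter(_cohort_from_table([[25, 25],
                                                               [25, 25]]))
        rec, = trace.chi_square_excluded
        assert rec["statistic"] == pytest.approx(0.0)
        assert rec["p"] == pytest.approx(1.0)

    def test_associated_table_kept_with_hand_statistic(self):
        # [[30,10],[10,30]]: all expected counts 20 -> chi2 = 4*100/20 = 20
        trace = modeling.chi_square_filter(_cohort_from_table([[30, 10],
                                                               [10, 30]]))
        rec, = trace.chi_square_kept
        assert rec["statistic"] == pytest.approx(20.0)
        assert rec["df"] == 1 and rec["p"] < 0.10

    def test_three_level_variable_df(self):
        trace = modeling.chi_square_filter(
            _cohort_from_table([[30, 5], [20, 20], [5, 30]]))
        rec = (trace.chi_square_kept + trace.chi_square_excluded)[0]
        assert rec["df"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(5, 40, size=(3, 2))
        trace = modeling.chi_square_filter(_cohort_from_table(table))
        rec = (trace.chi_square_kept + trace.chi_square_excluded)[0]
        assert rec["statistic"] == pytest.approx(_brute_chi2(table))

    def test_zero_margin_level_dropped(self):
        # level present only via zero row: table collapses, noted
        cohort = toy_cohort({"v": [0.0] * 50}, {"v": "discrete"},
                            outcome=[0, 1] * 25)
        trace = modeling.chi_square_filter(cohort)
        rec, = trace.chi_square_excluded
        assert "degenerate" in rec.get("note", "")


class TestUnivariateFilter:
    def test_null_predictor_excluded_signal_kept(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        cohort = toy_cohort(
            {"signal": (y + rng.normal(0, 0.5, 400)).astype(float),
             "noise": rng.normal(size=400)},
            {"signal": "continuous", "noise": "continuous"},
            outcome=y.tolist())
        trace = modeling.univariate_lr_filter(cohort,
                                              variables=["signal", "noise"])
        assert [r["variable"] for r in trace.univariate_kept] == ["signal"]
        assert [r["variable"] for r in trace.univariate_excluded] == ["noise"]

    def test_wald_ci_is_exp_of_beta_pm_1p96_se(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        x = y + rng.normal(0, 1.0, 300)
        cohort = toy_cohort({"x": x.astype(float)}, {"x": "continuous"},
                            outcome=y.tolist())
        trace = modeling.univariate_lr_filter(cohort, variables=["x"])
        rec = (trace.univariate_kept + trace.univariate_excluded)[0]
        import statsmodels.api as sm
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert rec["or"] == pytest.approx(np.exp(res.params[1]), rel=1e-6)
        assert rec["ci_low"] == pytest.approx(
            np.exp(res.params[1] - 1.96 * res.bse[1]), rel=1e-6)

    def test_perfectly_separated_predictor_flagged(self):
        y = [0] * 5 + [1] * 5
        cohort = toy_cohort({"x": [float(v) for v in y]}, {"x": "diagnosis"},
                            outcome=y)
        trace = modeling.univariate_lr_filter(cohort, variables=["x"])
        rec, = trace.univariate_kept
        assert rec["separation"] is True


class TestReintroduce:
    def _trace(self):
        trace = modeling.SelectionTrace()
        trace.chi_square_excluded = [{"variable": "sodium"}]
        trace.univariate_excluded = [{"variable": "chloride"}]
        trace.univariate_kept = [{"variable": "potassium"}]
        return trace

    def test_empty_is_noop(self):
        trace = self._trace()
        modeling.reintroduce(trace, [])
        assert trace.reintroduced == []

    def test_candidates_grow(self):
        trace = self._trace()
        before = len(trace.candidates())
        modeling.reintroduce(trace, ["sodium", "chloride"])
        assert len(trace.candidates()) == before + 2

    def test_never_excluded_rejected(self):
        with pytest.raises(ValueError, match="potassium"):
            modeling.reintroduce(self._trace(), ["potassium"])


class TestMultivariateFit:
    def test_zero_variance_column_rejected(self):
        cohort = toy_cohort({"c": [1.0] * 20, "x": list(range(20))},
                            {"c": "continuous", "x": "continuous"})
        with pytest.raises(ValueError, match="zero-variance"):
            modeling.fit_multivariate_lr(cohort, ["c", "x"])

    def test_null_model_or_near_one(self):
        rng = np.random.default_rng(2)
        cohort = toy_cohort(
            {"a": rng.normal(size=2000), "b": rng.normal(size=2000)},
            {"a": "continuous", "b": "continuous"},
            outcome=rng.integers(0, 2, 2000).tolist())
        fit = modeling.fit_multivariate_lr(cohort)
        assert not fit.separation_flag
        assert np.allclose(fit.odds_ratios, 1.0, atol=0.15)
        assert abs(fit.intercept) < 0.15
        assert ((fit.ci_low <= fit.odds_ratios)
                & (fit.odds_ratios <= fit.ci_high)).all()

    def test_or_ci_ordering_preserved_by_exp(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        cohort = toy_cohort({"x": (0.5 * y + rng.normal(size=500))},
                            {"x": "continuous"}, outcome=y.tolist())
        fit = modeling.fit_multivariate_lr(cohort)
        assert (fit.ci_low <= fit.odds_ratios).all()
        assert (fit.odds_ratios <= fit.ci_high).all()
        assert (fit.odds_ratios > 0).all()

    def test_separable_diagnosis_matrix_flagged(self):
        spec = CohortSpec(n_pos=80, n_neg=720, n_continuous=0, n_discrete=0,
                          n_diagnosis=6, diagnosis_prevalence=0.15,
                          separating_vars=("dx_00",), seed=4)
        cohort = generate_cohort(spec)
        fit = modeling.fit_multivariate_lr(cohort)
        assert fit.separation_flag

    def test_bootstrap_ci_mode(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        cohort = toy_cohort({"x": (y + rng.normal(size=300))},
                            {"x": "continuous"}, outcome=y.tolist())
        fit = modeling.fit_multivariate_lr(cohort, ci_method="bootstrap",
                                           bootstrap_B=20, seed=0)
        assert fit.ci_method == "bootstrap"
        assert fit.ci_low[0] < fit.ci_high[0]


class TestDetectSeparation:
    def test_null_fit_not_flagged(self):
        fit = modeling.FitResult(["x"], np.array([0.2]), 0.0,
                                 np.exp([0.2]), np.array([0.9]),
                                 np.array([1.5]), np.array([0.3]),
                                 converged=True, separation_flag=False,
                                 n_obs=100)
        assert modeling.detect_separation(fit) is False

    def test_huge_coefficient_flagged(self):
        fit = modeling.FitResult(["x"], np.array([25.0]), 0.0,
                                 np.exp([25.0]), np.array([0.0]),
                                 np.array([np.inf]), np.array([1.0]),
                                 converged=True, separation_flag=False,
                                 n_obs=100)
        assert modeling.detect_separation(fit) is True

    def test_infinite_threshold_disables_with_warning(self):
        fit = modeling.FitResult(["x"], np.array([25.0]), 0.0,
                                 np.exp([25.0]), np.array([0.0]),
                                 np.array([np.inf]), np.array([1.0]),
                                 converged=True, separation_flag=False,
                                 n_obs=100)
        with pytest.warns(UserWarning):
            assert modeling.detect_separation(fit, np.inf) is False


class TestForwardGroupSelection:
    def _signal_cohort(self, seed=0, n=600):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        cols = {"s1": y + rng.normal(0, 1.2, n),
                "s2": y + rng.normal(0, 1.2, n),
                "n1": rng.normal(size=n), "n2": rng.normal(size=n)}
        return toy_cohort(cols, {c: "continuous" for c in cols},
                          outcome=y.tolist())

    def test_single_group_is_final(self):
        cohort = self._signal_cohort()
        trace = modeling.forward_group_selection(cohort,
                                                 {"only": ["s1", "s2"]}, B=5)
        assert trace.final_variables == ["s1", "s2"]

    def test_noise_group_rejected(self):
        cohort = self._signal_cohort()
        trace = modeling.forward_group_selection(
            cohort, {"signal": ["s1", "s2"], "noise": ["n1", "n2"]},
            B=20, seed=0)
        assert trace.final_variables == ["s1", "s2"]
        step = [s for s in trace.forward_path if s["group"] == "noise"][0]
        assert step["accepted"] is False

    def test_identical_groups_second_rejected(self):
        cohort = self._signal_cohort()
        trace = modeling.forward_group_selection(
            cohort, {"a": ["s1"], "b": ["s1"]}, B=10, seed=0)
        assert trace.final_variables == ["s1"]

    def test_accepted_steps_never_decrease_auroc(self):
        cohort = self._signal_cohort(seed=1)
        trace = modeling.forward_group_selection(
            cohort, {"g1": ["s1"], "g2": ["s2"], "g3": ["n1"]}, B=10, seed=1)
        best = -np.inf
        for step in trace.forward_path:
            if step["accepted"]:
                assert step["auroc_after"] > best or best == -np.inf
                best = step["auroc_after"]


class TestPCRegression:
    def test_independent_outcome_gives_unit_ors(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(1500, 5)).astype(float)
        y = rng.integers(0, 2, 1500)
        model = pca.pca_fit(X)
        Y = pca.transform(X, model, k=4)
        fit, interp = modeling.pc_regression(Y, y, model)
        assert np.allclose(fit.odds_ratios, 1.0, atol=0.25)
        assert not fit.separation_flag

    def test_single_signal_direction_concentrates_on_pc1(self):
        rng = np.random.default_rng(7)
        n = 2000
        y = rng.integers(0, 2, n)
        # the only class difference lies along one high-variance direction
        base = rng.normal(size=(n, 1)) + 1.2 * y[:, None]
        X = base @ np.array([[1.0, 1.0, 1.0]]) \
            + 0.3 * rng.normal(size=(n, 3))
        model = pca.pca_fit(X)
        Y = pca.transform(X, model, k=3)
        fit, _ = modeling.pc_regression(Y, y, model)
        logors = np.abs(fit.coefficients)
        assert logors[0] > 2 * max(logors[1], logors[2])


def test_model_zoo_deterministic_and_separates_strong_signal():
    spec = CohortSpec(n_pos=80, n_neg=220, n_continuous=4, n_discrete=0,
                      n_diagnosis=0, effect_sizes=2.5, seed=8)
    cohort = generate_cohort(spec)
    X, y = cohort.data.to_numpy(), cohort.outcome.to_numpy()
    zoo = {"LR": modeling.default_zoo(0)["LR"],
           "RF": modeling.default_zoo(0)["RF"]}
    a = modeling.train_model_zoo(X, y, models=zoo, seed=0, B=5)
    b = modeling.train_model_zoo(X, y, models=zoo, seed=0, B=5)
    for name in zoo:
        assert a[name]["best_params"] == b[name]["best_params"]
        assert a[name]["eval"].metrics["auroc"]["mean"] > 0.95
        assert a[name]["eval"].metrics["auroc"]["mean"] == \
            b[name]["eval"].metrics["auroc"]["mean"]


def test_grid_of_size_one_equals_direct_fit():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 200)
    X = y[:, None] + rng.normal(size=(200, 2))
    from sklearn.linear_model import LogisticRegression
    zoo = {"LR": (LogisticRegression(max_iter=500), {"C": [1.0]})}
    result = modeling.train_model_zoo(X, y, models=zoo, seed=0, B=3)
    direct = LogisticRegression(max_iter=500, C=1.0).fit(X, y)
    assert np.allclose(result["LR"]["estimator"].coef_, direct.coef_)
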