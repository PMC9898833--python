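"""Variable selection and logistic model building for the case study.

Selection proceeds: chi-square prefilter (drop P > .10) -> univariate
logistic filter (drop P > .05) -> expert reintroduction of clinically
relevant exclusions -> named variable groups -> forward group selection
driven by repeated-subsampling AUROC (a group enters iff mean AUROC strictly
improves) -> multivariate logistic fit reported as odds ratios with 95% CIs.
Quasi-complete separation (a predictor combination perfectly identifying
positives, endemic in sparse diagnosis indicators) is detected and flagged
rather than reported as a trustworthy OR; principal-component regression is
the data-side remedy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import evaluation
from .pca import PCModel, loading_report

#: |log OR| beyond which a coefficient is treated as a separation artifact;
#: clinically plausible ORs sit well under e^10 while separated fits blow
#: past 1e9.
SEPARATION_BETA = 10.0


@dataclass
class FitResult:
    """Logistic fit reported on the odds-ratio scale."""

    variable_names: list[str]
    coefficients: np.ndarray
    intercept: float
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    converged: bool
    separation_flag: bool
    n_obs: int
    ci_method: str = "wald"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variable_names,
            "OR": self.odds_ratios,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "P": self.pvalues,
        })


@dataclass
class SelectionTrace:
    """Audit trail of the variable-selection pipeline."""

    chi_square_excluded: list[dict] = field(default_factory=list)
    chi_square_kept: list[dict] = field(default_factory=list)
    univariate_excluded: list[dict] = field(default_factory=list)
    univariate_kept: list[dict] = field(default_factory=list)
    reintroduced: list[str] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)
    group_metrics: dict[str, dict] = field(default_factory=dict)
    forward_path: list[dict] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)

    def candidates(self) -> list[str]:
        kept = [r["variable"] for r in self.univariate_kept]
        return kept + [v for v in self.reintroduced if v not in kept]

    def excluded_names(self) -> set[str]:
        return ({r["variable"] for r in self.chi_square_excluded}
                | {r["variable"] for r in self.univariate_excluded})


# --------------------------------------------------------------------- filters
def chi_square_filter(cohort, alpha: float = 0.10,
                      variables: list[str] | None = None,
                      trace: SelectionTrace | None = None) -> SelectionTrace:
    """Pearson chi-square of each categorical variable against the outcome.

    Variables with P > alpha are excluded.  Levels with a zero margin are
    dropped from the contingency table (and noted) so expected counts stay
    positive; df = (levels - 1) x 1.
    """
    trace = trace or SelectionTrace()
    if variables is None:
        variables = cohort.variables_of_kind("ordinal", "discrete", "diagnosis")
    y = cohort.outcome
    for name in variables:
        col = cohort.data[name]
        table = pd.crosstab(col, y)
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
        record = {"variable": name}
        if table.shape[0] < 2 or table.shape[1] < 2:
            record.update(statistic=0.0, df=0, p=1.0,
                          note="degenerate table (zero-margin levels dropped)")
            trace.chi_square_excluded.append(record)
            continue
        stat, p, df, _ = chi2_contingency(table.to_numpy(), correction=False)
        record.update(statistic=float(stat), df=int(df), p=float(p))
        if p > alpha:
            trace.chi_square_excluded.append(record)
        else:
            trace.chi_square_kept.append(record)
    return trace


def _logit_fit(X: np.ndarray, y: np.ndarray, maxiter: int = 200):
    """statsmodels Logit with a lbfgs fallback when newton hits separation."""
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, maxiter=maxiter, method="newton")
        except (np.linalg.LinAlgError, Exception):
            return model.fit(disp=0, maxiter=maxiter, method="lbfgs")


def _wrap_fit(res, names: list[str], n_obs: int,
              threshold: float = SEPARATION_BETA) -> FitResult:
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    coef, se, p = params[1:], bse[1:], pvals[1:]
    with np.errstate(over="ignore"):  # separated fits overflow to inf CIs
        fit = FitResult(
            variable_names=list(names),
            coefficients=coef,
            intercept=float(params[0]),
            odds_ratios=np.exp(coef),
            ci_low=np.exp(coef - 1.96 * se),
            ci_high=np.exp(coef + 1.96 * se),
            pvalues=p,
            converged=converged,
            separation_flag=False,
            n_obs=n_obs,
        )
    fit.separation_flag = detect_separation(fit, threshold=threshold)
    return fit


def detect_separation(fit: FitResult,
                      threshold: float = SEPARATION_BETA) -> bool:
    """Flag a fit whose MLE is diverging: any |log OR| beyond the threshold,
    a non-finite standard error, or an optimizer that hit its cap."""
    if np.isinf(threshold):
        warnings.warn("separation threshold is infinite; detection disabled")
        return False
    if not fit.converged:
        return True
    if np.any(np.abs(fit.coefficients) > threshold):
        return True
    if np.any(~np.isfinite(fit.ci_high)) or np.any(~np.isfinite(fit.ci_low)):
        return True
    return False


def univariate_lr_filter(cohort, alpha: float = 0.05,
                         variables: list[str] | None = None,
                         trace: SelectionTrace | None = None) -> SelectionTrace:
    """One-predictor logistic fit per variable; exclude Wald P > alpha.

    A variable whose univariate fit trips the separation check is flagged
    and retained for the separation report instead of being judged on a
    meaningless P value.
    """
    trace = trace or SelectionTrace()
    if variables is None:
        variables = [r["variable"] for r in trace.chi_square_kept] \
            or cohort.variables
    y = cohort.outcome.to_numpy()
    for name in variables:
        x = cohort.data[[name]].to_numpy()
        if np.isnan(x).any():
            raise ValueError(f"variable '{name}' has missing values")
        res = _logit_fit(x, y)
        fit = _wrap_fit(res, [name], n_obs=len(y))
        record = {"variable": name, "or": float(fit.odds_ratios[0]),
                  "ci_low": float(fit.ci_low[0]),
                  "ci_high": float(fit.ci_high[0]),
                  "p": float(fit.pvalues[0]),
                  "separation": fit.separation_flag}
        if fit.separation_flag:
            record["note"] = "separated; retained for separation report"
            trace.univariate_kept.append(record)
        elif record["p"] > alpha:
            trace.univariate_excluded.append(record)
        else:
            trace.univariate_kept.append(record)
    return trace


def reintroduce(trace: SelectionTrace, variables: list[str]) -> SelectionTrace:
    """Move previously excluded variables back into the candidate set
    (expert/literature override); unknown names are an error."""
    excluded = trace.excluded_names()
    unknown = [v for v in variables if v not in excluded]
    if unknown:
        raise ValueError(
            f"cannot reintroduce variables that were never excluded: {unknown}")
    for v in variables:
        if v not in trace.reintroduced:
            trace.reintroduced.append(v)
    return trace


# ------------------------------------------------------------------ model fits
def fit_multivariate_lr(cohort_or_X, variables: list[str] | None = None,
                        outcome=None, ci_method: str = "wald",
                        bootstrap_B: int = 200, seed: int = 0,
                        separation_threshold: float = SEPARATION_BETA
                        ) -> FitResult:
    """Maximum-likelihood multivariate logistic fit with OR 95% CIs.

    ``ci_method='wald'`` uses exp(beta +- 1.96 SE); ``'bootstrap'`` replaces
    the CIs with percentile intervals of the OR across ``bootstrap_B``
    stratified 70/30 refits (the repeated-subsampling protocol).
    """
    from .cohort import Cohort
    if isinstance(cohort_or_X, Cohort):
        if variables is None:
            variables = cohort_or_X.variables
        X = cohort_or_X.data[variables].to_numpy()
        y = cohort_or_X.outcome.to_numpy()
    else:
        X = np.asarray(cohort_or_X, dtype=float)
        y = np.asarray(outcome, dtype=int)
        if variables is None:
            variables = [f"x{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("selected columns contain missing values; impute first")
    const = [v for v, s in zip(variables, X.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"zero-variance predictor columns: {const}")
    res = _logit_fit(X, y)
    fit = _wrap_fit(res, variables, n_obs=len(y),
                    threshold=separation_threshold)
    if ci_method == "bootstrap":
        from sklearn.model_selection import StratifiedShuffleSplit
        splitter = StratifiedShuffleSplit(n_splits=bootstrap_B, train_size=0.7,
                                          random_state=seed % (2**31 - 1))
        ors = []
        for tr, _ in splitter.split(X, y):
            r = _logit_fit(X[tr], y[tr])
            ors.append(np.exp(np.asarray(r.params)[1:]))
        ors = np.asarray(ors)
        fit.ci_low = np.percentile(ors, 2.5, axis=0)
        fit.ci_high = np.percentile(ors, 97.5, axis=0)
        fit.ci_method = "bootstrap"
    elif ci_method != "wald":
        raise ValueError("ci_method must be 'wald' or 'bootstrap'")
    return fit


def forward_group_selection(cohort, groups: dict[str, list[str]],
                            evaluator=None, seed: int = 0, B: int = 50,
                            trace: SelectionTrace | None = None
                            ) -> SelectionTrace:
    """AUROC-driven forward selection over named variable groups.

    ``evaluator(variables) -> mean AUROC`` defaults to the repeated-
    subsampling protocol with a plain logistic learner.  The group with the
    best standalone AUROC seeds the model; remaining groups are tried in
    descending standalone order and kept iff the mean AUROC strictly
    improves.  A group whose evaluation fails is recorded and skipped.
    """
    if len(groups) < 1:
        raise ValueError("at least one variable group required")
    trace = trace or SelectionTrace()
    trace.groups = {k: list(v) for k, v in groups.items()}

    if evaluator is None:
        X_all = cohort.data
        y = cohort.outcome.to_numpy()
        est = LogisticRegression(max_iter=1000)

        def evaluator(variables):
            summary = evaluation.subsample_evaluate(
                est, X_all[variables].to_numpy(), y, B=B, seed=seed)
            return summary.metrics["auroc"]["mean"]

    standalone: dict[str, float] = {}
    for name, vars_ in groups.items():
        try:
            score = float(evaluator(list(vars_)))
        except Exception as exc:  # evaluator failure: record, skip
            trace.group_metrics[name] = {"auroc": None, "error": str(exc)}
            continue
        standalone[name] = score
        trace.group_metrics[name] = {"auroc": score}
    if not standalone:
        raise ValueError("every group failed evaluation")

    order = sorted(standalone, key=standalone.get, reverse=True)
    base = order[0]
    current = list(groups[base])
    best = standalone[base]
    trace.forward_path.append({"group": base, "auroc_before": None,
                               "auroc_after": best, "accepted": True})
    for name in order[1:]:
        candidate = current + [v for v in groups[name] if v not in current]
        try:
            score = float(evaluator(candidate))
        except Exception as exc:
            trace.forward_path.append({"group": name, "auroc_before": best,
                                       "auroc_after": None, "accepted": False,
                                       "error": str(exc)})
            continue
        accepted = score > best
        trace.forward_path.append({"group": name, "auroc_before": best,
                                   "auroc_after": score, "accepted": accepted})
        if accepted:
            current, best = candidate, score
    trace.final_variables = current
    return trace


def pc_regression(scores, outcome, model: PCModel, alpha: float = 0.05,
                  top_m: int = 3,
                  separation_threshold: float = SEPARATION_BETA
                  ) -> tuple[FitResult, dict]:
    """Logistic regression on PC scores + loading-based interpretation.

    Components whose Wald P < alpha are ranked by |log OR| (furthest from
    OR = 1 first) and their top-|loading| variables are reported as the
    interpreted risk-factor set.
    """
    Y = np.asarray(scores, dtype=float)
    k = Y.shape[1]
    names = [f"PC{i + 1}" for i in range(k)]
    fit = fit_multivariate_lr(Y, variables=names, outcome=outcome,
                              separation_threshold=separation_threshold)
    sig = [i + 1 for i in range(k) if fit.pvalues[i] < alpha]
    sig.sort(key=lambda c: -abs(np.log(fit.odds_ratios[c - 1])))
    loadings = loading_report(model, sig, top_m=top_m) if sig else {}
    interpreted: list[str] = []
    for c in sig:
        for var, _ in loadings[c]:
            if var not in interpreted:
                interpreted.append(var)
    return fit, {"significant_components": sig, "loadings": loadings,
                 "interpreted_variables": interpreted}


# ------------------------------------------------------------------- model zoo
def default_zoo(seed: int = 0) -> dict[str, tuple]:
    """(estimator, small hyperparameter grid) per comparison model."""
    return {
        "LR": (LogisticRegression(max_iter=1000),
               {"C": [0.1, 1.0, 10.0]}),
        "LASSO": (LogisticRegression(penalty="l1", solver="liblinear",
                                     max_iter=1000),
                  {"C": [0.1, 1.0, 10.0]}),
        "RF": (RandomForestClassifier(random_state=seed),
               {"n_estimators": [100], "max_depth": [None, 8]}),
        "GBM": (GradientBoostingClassifier(random_state=seed),
                {"n_estimators": [100], "learning_rate": [0.1]}),
        "SVM": (SVC(probability=True, random_state=seed),
                {"C": [1.0], "kernel": ["rbf"]}),
    }


def train_model_zoo(X, y, models: dict | None = None, cv_folds: int = 5,
                    seed: int = 0, B: int = 100) -> dict[str, dict]:
    """Grid-search each model by stratified k-fold CV (AUROC), then run the
    repeated-subsampling evaluation on the tuned estimator."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if models is None:
        models = default_zoo(seed=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                         random_state=seed % (2**31 - 1))
    out: dict[str, dict] = {}
    for name, (estimator, grid) in models.items():
        search = GridSearchCV(estimator, grid, scoring="roc_auc", cv=cv)
        search.fit(X, y)
        summary = evaluation.subsample_evaluate(search.best_estimator_, X, y,
                                                B=B, seed=seed)
        out[name] = {
            "best_params": search.best_params_,
            "estimator": search.best_estimator_,
            "eval": summary,
        }
    return out
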