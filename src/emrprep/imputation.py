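"""Random-forest single imputation and its validation protocol.

The imputation sweep is a single pass over variables in ascending order of
missingness.  For each target variable the rows observed for it form the
training set and the rows missing it the test set; any still-missing
covariate cells are temporarily filled with the covariate's observed mean
(continuous) or mode (discrete) to form a complete design matrix, and the
temporary fills are discarded after that variable's fit.  A regression
forest handles continuous targets and a classification forest categorical
ones.  Unlike iterative schemes (missForest), no second sweep is run.

Validation holds out 20% of each variable's observed rows and scores the
forest's predictions with R^2 (continuous) or Cohen's kappa (categorical);
mean/mode/median constant fills serve as the comparison baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .cohort import Cohort

CATEGORICAL_KINDS = ("discrete", "diagnosis", "ordinal")


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Defined on the degenerate single-category table as 1.0 for perfect
    agreement and 0.0 otherwise (the closed form is 0/0 there).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    labels = np.union1d(y_true, y_pred)
    n = y_true.size
    p_o = float(np.mean(y_true == y_pred))
    p_e = 0.0
    for lab in labels:
        p_e += (np.mean(y_true == lab)) * (np.mean(y_pred == lab))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ImputationReport:
    """Per-variable validation metrics plus median/IQR summaries."""

    #: records with keys name, kind, metric (R2|kappa), value, n_train,
    #: n_validation, evaluable
    per_variable: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def summarize(self) -> None:
        r2 = [r["value"] for r in self.per_variable
              if r["evaluable"] and r["metric"] == "R2"]
        kap = [r["value"] for r in self.per_variable
               if r["evaluable"] and r["metric"] == "kappa"]

        def med_iqr(vals):
            if not vals:
                return None, None
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            return float(q2), float(q3 - q1)

        self.summary["r2_median"], self.summary["r2_iqr"] = med_iqr(r2)
        self.summary["kappa_median"], self.summary["kappa_iqr"] = med_iqr(kap)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"per_variable": self.per_variable, "summary": self.summary},
            indent=2))


def _mode(series: pd.Series) -> float:
    modes = series.mode(dropna=True)
    if modes.empty:
        raise ValueError("cannot take mode of an all-missing column")
    return float(modes.iloc[0])


def _temporary_fill(data: pd.DataFrame, meta: pd.DataFrame,
                    exclude: str) -> pd.DataFrame:
    """Complete the covariate matrix with observed means/modes.

    Fills are recomputed from currently observed values only and exist just
    for one target variable's fit.
    """
    cov = data.drop(columns=[exclude]).copy()
    for name in cov.columns:
        if not cov[name].isna().any():
            continue
        if cov[name].isna().all():
            cov[name] = 0.0
            continue
        if meta.loc[name, "kind"] == "continuous":
            cov[name] = cov[name].fillna(cov[name].mean())
        else:
            cov[name] = cov[name].fillna(_mode(cov[name]))
    return cov


def _forest(kind: str, seed: int, n_estimators: int, forest_params: dict | None):
    params = dict(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    params.update(forest_params or {})
    if kind == "continuous":
        return RandomForestRegressor(**params)
    return RandomForestClassifier(**params)


def _imputable(cohort: Cohort, variables: list[str] | None) -> list[str]:
    if variables is None:
        variables = [v for v in cohort.variables
                     if bool(cohort.meta.loc[v, "impute"])]
    all_missing = [v for v in variables if cohort.data[v].isna().all()]
    if all_missing:
        raise ValueError(
            f"variables with no observed values must be screened out first: "
            f"{all_missing}")
    return variables


def rf_impute(cohort: Cohort, n_estimators: int = 100, seed: int = 0,
              forest_params: dict | None = None,
              variables: list[str] | None = None) -> Cohort:
    """Single-sweep random-forest imputation; observed cells are preserved.

    Variables are processed in ascending order of missing fraction (ties by
    column order), so better-observed variables provide cleaner covariates
    for the harder ones.  Per-variable forests are seeded deterministically
    from ``seed`` and the variable's position.
    """
    variables = _imputable(cohort, variables)
    out = cohort.copy()
    order = sorted(
        (v for v in variables if cohort.data[v].isna().any()),
        key=lambda v: (float(cohort.data[v].isna().mean()),
                       cohort.variables.index(v)))
    for j, name in enumerate(order):
        miss = out.data[name].isna()
        cov = _temporary_fill(out.data, out.meta, exclude=name)
        kind = out.meta.loc[name, "kind"]
        y_train = out.data.loc[~miss, name]
        model = _forest("continuous" if kind == "continuous" else "categorical",
                        seed=(seed + 7919 * (j + 1)) % (2**31 - 1),
                        n_estimators=n_estimators, forest_params=forest_params)
        if kind != "continuous":
            model.fit(cov.loc[~miss], y_train.astype(int))
            pred = model.predict(cov.loc[miss]).astype(float)
        else:
            model.fit(cov.loc[~miss], y_train)
            pred = model.predict(cov.loc[miss])
        out.data.loc[miss, name] = pred
    return out


def baseline_impute(cohort: Cohort, strategy: str = "mean",
                    variables: list[str] | None = None) -> Cohort:
    """Constant-fill comparison arm: mean/median (continuous) or mode."""
    if strategy not in ("mean", "median", "mode"):
        raise ValueError("strategy must be 'mean', 'median', or 'mode'")
    variables = _imputable(cohort, variables)
    out = cohort.copy()
    for name in variables:
        col = out.data[name]
        if not col.isna().any():
            continue
        kind = out.meta.loc[name, "kind"]
        if strategy in ("mean", "median") and kind != "continuous":
            raise ValueError(
                f"{strategy} imputation is invalid for {kind} variable '{name}'")
        if strategy == "mean":
            fill = col.mean()
        elif strategy == "median":
            fill = col.median()
        else:
            fill = _mode(col)
        out.data[name] = col.fillna(fill)
    return out


def evaluate_imputation(cohort: Cohort, split: float = 0.2, seed: int = 0,
                        method: str = "rf", n_estimators: int = 100,
                        min_obs: int = 25,
                        variables: list[str] | None = None,
                        forest_params: dict | None = None) -> ImputationReport:
    """Hold-out validation of the imputation model, per variable.

    For every variable with missing cells, its observed rows are split
    80/20 (by default); the imputation model is trained on the 80% part and
    scored on the 20% part — R^2 for continuous targets, Cohen's kappa for
    categorical ones.  ``method`` selects the model: ``rf`` (the forest) or a
    constant baseline (``mean``/``median``/``mode``; mean and median fall
    back to mode on categorical variables so every variable stays
    comparable).  Variables with fewer than ``min_obs`` observed rows are
    reported as not evaluable rather than silently skipped.
    """
    if not 0 < split < 1:
        raise ValueError("split must lie in (0,1)")
    if method not in ("rf", "mean", "median", "mode"):
        raise ValueError("method must be rf/mean/median/mode")
    variables = _imputable(cohort, variables)
    report = ImputationReport()
    targets = [v for v in variables if cohort.data[v].isna().any()]
    for j, name in enumerate(targets):
        kind = cohort.meta.loc[name, "kind"]
        metric = "R2" if kind == "continuous" else "kappa"
        obs = cohort.data.index[~cohort.data[name].isna()]
        record = {"name": name, "kind": kind, "metric": metric,
                  "value": None, "n_train": 0, "n_validation": 0,
                  "evaluable": False}
        if len(obs) < min_obs:
            report.per_variable.append(record)
            continue
        rs = (seed + 104729 * (j + 1)) % (2**31 - 1)
        train_idx, val_idx = train_test_split(obs, test_size=split,
                                              random_state=rs)
        y_train = cohort.data.loc[train_idx, name]
        y_val = cohort.data.loc[val_idx, name]
        if method == "rf":
            cov = _temporary_fill(cohort.data, cohort.meta, exclude=name)
            model = _forest(
                "continuous" if kind == "continuous" else "categorical",
                seed=rs, n_estimators=n_estimators,
                forest_params=forest_params)
            if kind != "continuous":
                model.fit(cov.loc[train_idx], y_train.astype(int))
                pred = model.predict(cov.loc[val_idx]).astype(float)
            else:
                model.fit(cov.loc[train_idx], y_train)
                pred = model.predict(cov.loc[val_idx])
        else:
            if kind == "continuous" and method == "mean":
                const = y_train.mean()
            elif kind == "continuous" and method == "median":
                const = y_train.median()
            else:
                const = _mode(y_train)
            pred = np.full(len(val_idx), const)
        if metric == "R2":
            value = float(r2_score(y_val, pred))
        else:
            value = float(cohen_kappa(y_val.astype(int),
                                      np.asarray(pred).astype(int)))
        record.update(value=value, n_train=len(train_idx),
                      n_validation=len(val_idx), evaluable=True)
        report.per_variable.append(record)
    report.summarize()
    return report
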