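"""Repeated-subsampling internal validation and calibration assessment.

"B-fold bootstrapping" here means B independent stratified 70/30
train/test splits *without* replacement (repeated subsampling), matching the
validation protocol the toolkit implements; each repeat refits the model and
scores the held-out 30%, and the summary is the mean with a 2.5/97.5
percentile interval across repeats.  Calibration is assessed with the Brier
score and equal-width reliability bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import (f1_score, precision_recall_curve, recall_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedShuffleSplit

METRICS = ("auroc", "auprc", "recall", "f1")


def _check_two_classes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    return labels


def auroc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative
    (ties count one half)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step integration of the
    precision envelope (interpolated precision), which avoids the optimism
    of linear PR interpolation."""
    labels = _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # arrays run from high recall to recall 0; flip to increasing recall
    precision, recall = precision[::-1], recall[::-1]
    # envelope: interpolated precision at recall r = max precision at >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    return float(np.sum(np.diff(np.concatenate([[0.0], recall])) * env))


def recall(predictions, labels) -> float:
    _check_two_classes(labels)
    return float(recall_score(labels, predictions, zero_division=0))


def f1(predictions, labels) -> float:
    _check_two_classes(labels)
    return float(f1_score(labels, predictions, zero_division=0))


def brier(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def reliability_curve(probabilities, labels, n_bins: int = 10) -> list[dict]:
    """Equal-width reliability bins: mean predicted vs observed fraction.

    Empty bins are omitted (their absence is visible from the midpoints).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        bins.append({
            "bin_midpoint": float((edges[b] + edges[b + 1]) / 2),
            "mean_predicted": float(p[sel].mean()),
            "observed_fraction": float(y[sel].mean()),
            "n": int(sel.sum()),
        })
    return bins


@dataclass
class EvalSummary:
    """Mean + percentile CI per metric over B train/test repetitions."""

    metrics: dict[str, dict] = field(default_factory=dict)
    B: int = 0
    train_fraction: float = 0.7
    brier: float | None = None
    reliability: list[dict] | None = None
    events: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"metrics": self.metrics, "B": self.B,
                "train_fraction": self.train_fraction, "brier": self.brier,
                "reliability": self.reliability, "events": self.events}


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    # margin scores rescaled to [0,1] so thresholding at 0.5 matches sign
    s = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-s))


def subsample_evaluate(estimator, X, y, B: int = 500,
                       train_fraction: float = 0.7, seed: int = 0,
                       threshold: float = 0.5) -> EvalSummary:
    """B stratified train/test subsamples; refit and score each repeat.

    Returns per-metric mean and 2.5/97.5 percentile interval over repeats.
    Stratification guarantees both classes in every test split.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y).astype(int)
    splitter = StratifiedShuffleSplit(n_splits=B, train_size=train_fraction,
                                      random_state=seed % (2**31 - 1))
    per_repeat: dict[str, list[float]] = {m: [] for m in METRICS}
    summary = EvalSummary(B=B, train_fraction=train_fraction)
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[test_idx])) < 2:  # unreachable with stratification
            summary.events.append("single-class test split resampled")
            continue
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        s = _scores(model, X[test_idx])
        pred = (s >= threshold).astype(int)
        per_repeat["auroc"].append(auroc(s, y[test_idx]))
        per_repeat["auprc"].append(auprc(s, y[test_idx]))
        per_repeat["recall"].append(recall(pred, y[test_idx]))
        per_repeat["f1"].append(f1(pred, y[test_idx]))
    for m, vals in per_repeat.items():
        vals = np.asarray(vals)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        summary.metrics[m] = {"mean": float(vals.mean()),
                              "ci_low": float(lo), "ci_high": float(hi)}
    return summary


def ratio_experiment(cohort, estimator, ratios=None, seed: int = 0,
                     B: int = 100, test_fraction: float = 0.3,
                     features: list[str] | None = None,
                     n_bins: int = 10) -> dict:
    """Train at several class ratios; compare on one original-ratio test set.

    A stratified test set at the ORIGINAL ratio is held out before any
    undersampling, so cluster-based selection never sees test rows.  Per
    ratio: the training majority is undersampled, discrimination is measured
    by the repeated-subsampling protocol *within* the rebalanced training
    data, and calibration (Brier, reliability) plus threshold-0.5
    recall/F1/AUROC are measured on the common test set with the model fit on
    the full rebalanced training data.
    """
    from .rebalance import DEFAULT_RATIOS, build_ratio_datasets

    if ratios is None:
        ratios = DEFAULT_RATIOS
    if features is None:
        features = cohort.variables
    X = cohort.data[features].to_numpy()
    y = _check_two_classes(cohort.outcome.to_numpy()).astype(int)
    rng = np.random.default_rng(seed)
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                      random_state=seed % (2**31 - 1))
    (train_idx, test_idx), = splitter.split(X, y)
    train_cohort = cohort.subset_rows(train_idx)

    datasets = build_ratio_datasets(train_cohort, ratios=ratios,
                                    seed=int(rng.integers(0, 2**31 - 1)),
                                    features=features)
    results: dict = {"test_n": len(test_idx), "ratios": []}
    for ds in datasets:
        sub = ds.select(train_cohort)
        Xr = sub.data[features].to_numpy()
        yr = sub.outcome.to_numpy()
        summary = subsample_evaluate(estimator, Xr, yr, B=B,
                                     seed=int(rng.integers(0, 2**31 - 1)))
        model = clone(estimator).fit(Xr, yr)
        s = _scores(model, X[test_idx])
        pred = (s >= 0.5).astype(int)
        results["ratios"].append({
            "ratio": ds.ratio,
            "n_train": len(sub.data),
            "train_eval": summary.to_dict(),
            "test": {
                "auroc": auroc(s, y[test_idx]),
                "auprc": auprc(s, y[test_idx]),
                "recall": recall(pred, y[test_idx]),
                "f1": f1(pred, y[test_idx]),
                "brier": brier(s, y[test_idx]),
                "reliability": reliability_curve(s, y[test_idx], n_bins),
            },
        })
    return results
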