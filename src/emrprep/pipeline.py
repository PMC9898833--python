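"""End-to-end pipeline runner: screen -> impute -> rebalance -> (PCA for the
diagnosis track) -> select/fit -> evaluate, with every intermediate artifact
written to a run directory and a manifest linking outputs to the config and
master seed.  Stages communicate only through written artifacts, so a run can
be resumed or audited from any checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from . import evaluation, imputation, modeling, pca, rebalance, screening
from .cohort import Cohort
from .synthetic import CohortSpec, generate_cohort, study_spec


@dataclass
class PipelineConfig:
    """All stage parameters; study defaults preset and overridable."""

    cohort_csv: str | None = None
    meta_csv: str | None = None
    synonym_csv: str | None = None
    simulate: bool = True          # generate the built-in synthetic cohort
    sim_n_pos: int = 250
    sim_n_neg: int = 4750
    seed: int = 0
    out_dir: str = "run"
    miss_threshold: float = 0.8
    prev_threshold: float = 0.05
    prev_per_class: bool = True
    discretize: bool = True
    impute_trees: int = 100
    ratios: list = field(default_factory=lambda: [[1, 10], [1, 5], [1, 2], [1, 1]])
    variance_target: float = 0.982
    pc_k: int | None = None        # overrides variance_target when set
    B: int = 500
    train_fraction: float = 0.7
    groups: dict = field(default_factory=dict)
    expert_variables: list = field(default_factory=list)
    chi_alpha: float = 0.10
    lr_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.miss_threshold <= 1:
            raise ValueError("miss_threshold must lie in (0,1]")
        if not 0 <= self.prev_threshold < 1:
            raise ValueError("prev_threshold must lie in [0,1)")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must lie in (0,1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0,1)")
        if not self.simulate:
            for attr in ("cohort_csv", "meta_csv"):
                path = getattr(self, attr)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{attr} missing or not found: {path}")
        if self.synonym_csv is not None and not Path(self.synonym_csv).exists():
            raise FileNotFoundError(f"synonym_csv not found: {self.synonym_csv}")


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=2, default=default))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage error halts the run with the stage name; artifacts written so
    far are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed,
                      "artifacts": {}, "stages": []}

    def checkpoint(stage: str, **artifacts) -> None:
        manifest["stages"].append(stage)
        manifest["artifacts"].update(artifacts)
        _dump_json(manifest, out / "manifest.json")

    stage = "load"
    try:
        # ------------------------------------------------------------- load
        if config.simulate:
            cohort = generate_cohort(study_spec(
                seed=config.seed, n_pos=config.sim_n_pos,
                n_neg=config.sim_n_neg))
        else:
            cohort = Cohort.from_csv(config.cohort_csv, config.meta_csv)
        cohort.to_csv(out / "cohort.csv", out / "meta.csv", out / "mask.csv")
        checkpoint("load", cohort="cohort.csv", meta="meta.csv", mask="mask.csv")

        # ------------------------------------------------------------ screen
        stage = "screen"
        if config.synonym_csv:
            mapping = dict(pd.read_csv(config.synonym_csv)
                           .itertuples(index=False, name=None))
            cohort, merge_report = screening.merge_synonyms(cohort, mapping)
        else:
            merge_report = screening.ScreenReport()
        miss_report = screening.filter_missingness(cohort, config.miss_threshold)
        cohort = miss_report.apply(cohort)
        prev_report = screening.filter_prevalence(
            cohort, config.prev_threshold, per_class=config.prev_per_class)
        cohort = prev_report.apply(cohort)
        _dump_json({"merge_log": merge_report.merge_log,
                    "missingness": {"kept": miss_report.kept,
                                    "dropped": miss_report.dropped},
                    "prevalence": {"kept": prev_report.kept,
                                   "dropped": prev_report.dropped}},
                   out / "screen_report.json")
        checkpoint("screen", screen_report="screen_report.json")

        # ------------------------------------------------------------ impute
        stage = "impute"
        imp_report = imputation.evaluate_imputation(
            cohort, seed=config.seed, n_estimators=config.impute_trees)
        imp_report.to_json(out / "imputation_report.json")
        cohort = imputation.rf_impute(cohort, seed=config.seed,
                                      n_estimators=config.impute_trees)
        if config.discretize:
            cohort = screening.discretize_lnh(cohort)
        cohort.to_csv(out / "imputed.csv", out / "imputed_meta.csv")
        checkpoint("impute", imputed="imputed.csv",
                   imputation_report="imputation_report.json")

        # --------------------------------------------------------- rebalance
        stage = "rebalance"
        lab_vars = cohort.variables_of_kind("continuous", "ordinal", "discrete")
        datasets = rebalance.build_ratio_datasets(
            cohort, ratios=[tuple(r) for r in config.ratios],
            seed=config.seed, features=lab_vars or None)
        _dump_json([{"ratio": ds.ratio, "indices": ds.indices,
                     "provenance": ds.provenance} for ds in datasets],
                   out / "ratio_datasets.json")
        checkpoint("rebalance", ratio_datasets="ratio_datasets.json")

        # ----------------------------------------------------- select / fit
        stage = "select"
        balanced = datasets[-2].select(cohort) if len(datasets) > 1 else cohort
        trace = modeling.chi_square_filter(balanced, alpha=config.chi_alpha,
                                           variables=lab_vars)
        trace = modeling.univariate_lr_filter(balanced, alpha=config.lr_alpha,
                                              trace=trace)
        if config.expert_variables:
            modeling.reintroduce(trace, config.expert_variables)
        groups = {k: list(v) for k, v in config.groups.items()}
        if not groups:
            cands = trace.candidates()
            if cands:
                half = max(1, len(cands) // 2)
                groups = {"group_1": cands[:half], "group_2": cands[half:]}
        fit = None
        if groups and any(groups.values()):
            trace = modeling.forward_group_selection(
                balanced, groups, seed=config.seed,
                B=min(config.B, 50), trace=trace)
            fit = modeling.fit_multivariate_lr(balanced,
                                               trace.final_variables)
            _dump_json(fit.table().to_dict(orient="records"),
                       out / "multivariate_fit.json")
        _dump_json({
            "chi_square_excluded": trace.chi_square_excluded,
            "univariate_excluded": trace.univariate_excluded,
            "reintroduced": trace.reintroduced,
            "groups": trace.groups,
            "group_metrics": trace.group_metrics,
            "forward_path": trace.forward_path,
            "final_variables": trace.final_variables,
        }, out / "selection_trace.json")
        checkpoint("select", selection_trace="selection_trace.json")

        # ------------------------------------------------- diagnosis track
        stage = "reduce"
        dx_vars = cohort.variables_of_kind("diagnosis")
        if len(dx_vars) >= 2:
            Xdx = cohort.data[dx_vars].to_numpy()
            model = pca.pca_fit(Xdx, dx_vars)
            k = config.pc_k or pca.select_k(model, config.variance_target)
            model.k = k
            model.to_json(out / "pc_model.json")
            scores = pca.transform(Xdx, model, k)
            pd.DataFrame(scores,
                         columns=[f"PC{i+1}" for i in range(k)]
                         ).to_csv(out / "pc_scores.csv", index=False)
            pc_fit, interp = modeling.pc_regression(
                scores, cohort.outcome.to_numpy(), model)
            _dump_json({"fit": pc_fit.table().to_dict(orient="records"),
                        "k": k, "interpretation": interp},
                       out / "pc_regression.json")
            checkpoint("reduce", pc_model="pc_model.json",
                       pc_scores="pc_scores.csv",
                       pc_regression="pc_regression.json")

        # ---------------------------------------------------------- evaluate
        stage = "evaluate"
        estimator = LogisticRegression(max_iter=1000)
        results = evaluation.ratio_experiment(
            cohort, estimator, ratios=[tuple(r) for r in config.ratios],
            seed=config.seed, B=min(config.B, 100),
            features=lab_vars or None)
        _dump_json(results, out / "ratio_experiment.json")
        checkpoint("evaluate", ratio_experiment="ratio_experiment.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out


def render_report(run_dir: str | Path) -> list[Path]:
    """Assemble table-shaped CSV reports from a completed run's artifacts.

    Produces: a missingness summary, chi-square and univariate filter tables,
    the group-comparison table, the multivariate OR table, diagnosis
    prevalence counts, and the PC-regression OR table.  Missing artifacts
    yield an explicit gap note instead of a table.
    """
    run_dir = Path(run_dir)
    written: list[Path] = []
    gaps: list[str] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = run_dir / name
        frame.to_csv(path, index=False)
        written.append(path)

    cohort_path = run_dir / "cohort.csv"
    if cohort_path.exists():
        frame = pd.read_csv(cohort_path)
        outcome = frame.pop("outcome")
        miss = frame.isna().mean()
        emit(pd.DataFrame({"variable": miss.index,
                           "missing_fraction": miss.values}),
             "report_missingness.csv")
        meta_path = run_dir / "meta.csv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path).set_index("name")
            dx = [v for v in frame.columns
                  if v in meta.index and meta.loc[v, "kind"] == "diagnosis"]
            if dx:
                pos = outcome == 1
                emit(pd.DataFrame({
                    "variable": dx,
                    "n_pos": [int(frame.loc[pos, v].fillna(0).sum()) for v in dx],
                    "n_neg": [int(frame.loc[~pos, v].fillna(0).sum()) for v in dx],
                }), "report_diagnosis_counts.csv")
    else:
        gaps.append("cohort.csv")

    trace_path = run_dir / "selection_trace.json"
    if trace_path.exists():
        trace = json.loads(trace_path.read_text())
        emit(pd.DataFrame(trace["chi_square_excluded"]),
             "report_chi_square_excluded.csv")
        emit(pd.DataFrame(trace["univariate_excluded"]),
             "report_univariate_excluded.csv")
        rows = [{"group": g, **m} for g, m in trace["group_metrics"].items()]
        emit(pd.DataFrame(rows), "report_group_comparison.csv")
    else:
        gaps.append("selection_trace.json")

    fit_path = run_dir / "multivariate_fit.json"
    if fit_path.exists():
        emit(pd.DataFrame(json.loads(fit_path.read_text())),
             "report_multivariate_or.csv")
    else:
        gaps.append("multivariate_fit.json")

    pc_path = run_dir / "pc_regression.json"
    if pc_path.exists():
        emit(pd.DataFrame(json.loads(pc_path.read_text())["fit"]),
             "report_pc_or.csv")
    else:
        gaps.append("pc_regression.json (no diagnosis track in this run)")

    (run_dir / "report_gaps.txt").write_text(
        "\n".join(gaps) if gaps else "none\n")
    return written
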