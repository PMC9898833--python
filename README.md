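# emrprep

Preprocessing and model-building toolkit for emergency-department (ED)
tabular data with three endemic quality problems: **missing values**
(per-variable missingness routinely reaching 80–100%), **class imbalance**
(outcomes such as sudden death at ~5% prevalence), and **sparse binary
diagnosis features** (hundreds of free-text-derived indicators, each present
in few patients, some perfectly separating the outcome classes).

It is written for biostatisticians and clinical-informatics researchers
building risk prediction models from EMR extracts, and packages the pipeline
of a sudden-death prediction case study as reusable, tested components.

## What it implements

1. **Variable screening** — free-text synonym merging (logical OR of
   indicator columns), an 80%-missingness filter (missing fraction ≥ 0.8
   drops), a >5% prevalence filter for diagnosis indicators (per-outcome-class
   by default), and L/N/H ordinal coding of labs against reference ranges
   (value < low → L, low ≤ value ≤ high → N, value > high → H).
2. **Random-forest single imputation** — one sweep over variables in
   ascending missingness; per target variable, rows observed for it train a
   forest (regression for continuous, classification for categorical) and
   rows missing it are predicted; remaining missing covariates are
   temporarily mean/mode-filled for that fit only. Validation holds out 20%
   of observed rows per variable and scores R² (continuous) or Cohen's κ
   (categorical), with mean/mode/median constant fills as baselines.
3. **K-means centroid-proximal undersampling** — the majority class is
   clustered into k clusters on z-scored features and each cluster
   contributes the real sample nearest its centroid, realizing ratios
   1:10, 1:5, 1:2, 1:1 (k = round(n_minority·b/a)) without discarding
   representative patients at random.
4. **PCA for sparse features** — covariance eigendecomposition
   C = XᵀX/(n−1) = VΛVᵀ of the centered diagnosis matrix; keep the smallest
   k components explaining ≥ 98.2% of variance (or a fixed k); regress on
   scores Y = (X − x̄)P. The scores are exactly uncorrelated and no longer
   separate the classes, so the logistic MLE converges where the raw sparse
   fit diverges; loadings map significant components back to diagnoses.
5. **Model building** — chi-square prefilter (P > .10 out), univariate
   logistic filter (P > .05 out), expert reintroduction, forward selection
   over variable groups accepting a group only if mean AUROC strictly
   improves, multivariate logistic fits with OR (95% CI), separation
   detection (|log OR| > 10, non-finite CI, or non-convergence), and a
   grid-searched comparison zoo (LR, LASSO, RF, GBM, SVM; 5-fold CV).
6. **Evaluation** — B repeated stratified 70/30 train/test subsamples
   (default B = 500) with mean and 2.5/97.5-percentile CIs for AUROC, AUPRC,
   recall, and F1; Brier score and reliability curves for calibration; and a
   ratio experiment training at each class ratio while scoring calibration
   on a common original-ratio test set.
7. **Synthetic EMR cohorts** — a first-class generator reproducing the
   pathologies above (5% prevalence, MCAR/MAR/MNAR missingness up to 85%,
   18 study-shaped diagnosis indicators including two positives-only
   separating ones) with ground truth retained for recovery testing.

## Worked example

```python
from emrprep import (generate_cohort, study_spec, filter_missingness,
                     filter_prevalence, rf_impute, evaluate_imputation,
                     pca_fit, select_k, transform)
from emrprep import modeling

cohort = generate_cohort(study_spec(seed=7))      # 5000 patients, 5% positive

report = filter_missingness(cohort, threshold=0.8)
cohort = report.apply(cohort)                     # drops 'lab_09' (85% missing)
prev = filter_prevalence(cohort, threshold=0.05)
cohort = prev.apply(cohort)

val = evaluate_imputation(cohort, seed=7)         # hold-out validation
cohort = rf_impute(cohort, seed=7)                # fill remaining gaps

dx = cohort.variables_of_kind("diagnosis")
raw = modeling.fit_multivariate_lr(cohort, dx)    # raw sparse fit

model = pca_fit(cohort.data[dx].to_numpy(), dx)
k = select_k(model, 0.982)
scores = transform(cohort.data[dx].to_numpy(), model, k)
fit, interp = modeling.pc_regression(scores, cohort.outcome.to_numpy(), model)
```

Output (printed by the statements above wrapped in `print`s):

```
cohort: 5000 patients, 33 variables, 250 positives
missingness filter dropped: ['lab_09']
prevalence filter kept 18 of 18 diagnoses
imputation validation: median R2 = 0.508, median kappa = 0.388
raw diagnosis fit: separation=True, max OR = 1.62e+05
PC regression: k=15, separation=False, max OR = 3.3
interpreted risk factors: ['renal_dysfunction', 'chest_tightness', 'chest_pain', 'abdominal_pain']
```

Reading: the forest recovers held-out lab values far better than a constant
fill (whose R² is ~0 and κ is 0); the raw logistic fit on the 18 diagnosis
indicators is flagged for quasi-complete separation — cardiac and
respiratory arrest occur only among positives, so their ORs diverge — while
the same data projected onto the 15 components that explain ≥ 98.2% of
variance fit cleanly with all ORs in a plausible range, and the component
loadings name the diagnoses driving the significant components.

## Command line

Every stage is also a subcommand of `emrprep`:

```bash
emrprep simulate --out data/ --seed 1
emrprep screen   --cohort data/cohort.csv --meta data/meta.csv --out screened.csv
emrprep impute   --cohort screened.csv --meta screened.meta.csv \
                 --out imputed.csv --report imputation.json --seed 1
emrprep rebalance --cohort imputed.csv --ratios 1:10,1:5,1:2,1:1 --out ratios/
emrprep reduce   --cohort imputed.csv --variance 0.982 --out scores.csv
emrprep run      --out run/ --seed 1      # full pipeline + manifest
emrprep report   --run-dir run/           # table-shaped CSV reports
```

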