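# Methods

`emrprep` implements a three-part strategy for preparing low-quality
emergency-department (ED) tabular data for risk modelling — random-forest
(RF) single imputation of missing values, k-means centroid-proximal
undersampling of the majority class, and principal-component (PC) regression
for sparse binary diagnosis features — plus the screening, selection, and
validation protocol of a sudden-death prediction case study. This note
records the models, their assumptions, the tunable parameters, and the
design choices made where the procedure was genuinely open.

## The synthetic cohort generator

Hospital EMR extracts cannot be redistributed, so the package ships a
generator (`emrprep.synthetic`) that emulates the *statistical pathologies*
the pipeline targets rather than any particular hospital's marginals.

A cohort is drawn as follows. The binary outcome has exactly `n_pos`
positives and `n_neg` negatives (default 250/4750, i.e. the ~5% positive
prevalence typical of ED sudden-death cohorts). Every feature loads on one
shared standard-normal latent severity factor `z`:

* **Continuous labs** `x_j = beta_j * y + 0.8 z + 0.6 eps`, so a variable's
  effect size `beta_j` is its positive-class mean shift in SD units. The
  default signal effect is **0.4 SD** on half the variables (the other half
  pure noise); this puts a plain logistic model trained at the original class
  ratio near AUROC 0.81 on held-out data — the moderate-discrimination
  regime reported for laboratory-panel sudden-death models, and the regime in
  which the imbalance/calibration trade-off is visible. Reference ranges
  (−1, 1) correspond to the central range of the negative class.
* **Discrete variables** are quantile-binned versions of the same latent
  construction (default 3 levels).
* **Diagnosis indicators** are Bernoulli with a negative-class baseline
  prevalence and a log-odds shift for positives. The study-shaped default
  (`study_spec`) uses the per-class prevalences of the 18 retained ED
  diagnoses (0.5%–17%), including two *separating* diagnoses — cardiac
  arrest and respiratory arrest — that occur **only** among positives and
  therefore induce quasi-complete separation in an unpenalized logistic fit.

The shared latent factor is what makes RF imputation learnable: variables
carry information about each other, as correlated lab panels do in practice.

**Missingness** is applied per variable at a requested rate under one of
three mechanisms. MCAR masks cells independently. MAR masks as a function of
a named, fully observed driver variable (rows above the driver's median are
masked at twice the target rate; the driver must be complete, and a driver
with missing cells is rejected). MNAR deterministically masks the top
`rate` fraction of the variable's own values, so missingness depends on the
unobserved value. The study-shaped default spreads MAR rates from 0 to 0.85
across the labs — one variable deliberately beyond the 80% screening
threshold — with the first lab kept complete as the driver. Real EMR
missingness is a mixture of mechanisms and is block-structured by test
panel; the generator does not emulate panel structure, so passing tests show
recovery of *variable-level* MAR missingness, not panel-level patterns.

Determinism: the same spec and seed produce a bit-identical cohort; all
sub-seeds derive from the spec seed.

## Variable screening

* **Missingness filter**: a variable is dropped when its missing fraction is
  **≥ 0.8** (boundary drops; the threshold is the conventional "80% missing"
  screening rule).
* **Prevalence filter** (diagnosis indicators): kept when prevalence is
  **strictly > 0.05**. By default prevalence is computed per outcome class
  and a variable survives if it passes in *either* class, so a diagnosis
  common among the rare positives (e.g. cardiac arrest) is retained even
  though it is globally rare; an overall-denominator mode is available.
  A missing diagnosis cell counts as absence (free-text diagnoses are
  recorded only when present).
* **Synonym merging** (free-text diagnosis names): many-to-one mapping,
  columns combined by logical OR, applied *before* the filters.
* **L/N/H coding**: continuous labs are mapped to ordinal codes 0/1/2 —
  below / within / above the reference range, with the bounds inclusive into
  N (boundary handling is a convention; reference-range limits are
  themselves "normal"). Converted variables change kind to `ordinal`, so the
  operation cannot be applied twice. Downstream, an L/N/H variable enters
  regressions as a single ordinal predictor, so its odds ratio refers to one
  ordinal step (L→N or N→H).

## Random-forest single imputation

One sweep over variables in ascending order of missing fraction (better-
observed variables provide cleaner covariates early; the order is otherwise
a free choice). For each target variable: rows observed for it form the
training set, rows missing it the test set; still-missing covariate cells
are *temporarily* filled with the covariate's observed mean (continuous) or
mode (categorical), and the fills are discarded after that variable's fit —
they never propagate. A regression forest imputes continuous targets, a
classification forest categorical ones (100 trees, unlimited depth,
per-variable seeds derived from the global seed). Unlike missForest there is
no iteration to convergence: the procedure is a deliberate single pass.
Identifier-style variables (age, gender) can be excluded from imputation via
the metadata `impute` flag while remaining available as covariates.

**Validation**: per variable with missing cells, observed rows are split
80/20; the model is trained on the 80% and scored on the held-out 20% with
R² (continuous) or Cohen's κ (categorical); the report summarises medians
and IQRs, and variables with fewer than `min_obs` (default 25) observed rows
are reported as *not evaluable* rather than silently skipped. Constant-fill
baselines (mean/median/mode) are evaluated through the identical protocol
for comparison; a constant prediction has R² ≈ 0 and κ = 0 by construction.
κ is computed from the closed form (p_o − p_e)/(1 − p_e), defined as 1 for a
perfect degenerate single-class table and 0 otherwise.

## K-means centroid-proximal undersampling

The majority class is clustered into k clusters (k-means, Euclidean
distance) and each cluster contributes the *real* member row nearest its
centroid — a cluster centroid is an average, not a patient, so the nearest
real sample stands in for it. Adjusting k realizes any minority:majority
ratio (defaults 1:10, 1:5, 1:2, 1:1, plus the untouched original), with
k = round(n_minority · b/a) clamped to the majority count.

Numerical choices: features are z-scored before clustering because Euclidean
distance is scale-sensitive across lab units (ordinal L/N/H codes enter as
0/1/2 and binary indicators as 0/1 — a documented approximation); 10 seeded
k-means restarts, best inertia kept; nearest-member ties break to the lowest
row index; if duplicate-heavy data leave clusters empty, the selection is
topped up with the unselected row farthest from the current selection so the
cardinality contract (exactly k distinct real rows) always holds.

## PCA for sparse diagnosis features

Sparse 0/1 diagnosis matrices produce quasi-complete separation (some
indicator or combination perfectly predicts the outcome) and
multicollinearity, making maximum-likelihood logistic estimates diverge.
The data-side remedy: center the matrix (no unit-variance scaling — the
variance p(1−p) of an indicator carries its prevalence information),
eigendecompose the covariance C = X'X/(n−1) (the 1/(n−1) normalisation does
not affect directions or variance fractions), sort eigenpairs by descending
eigenvalue, clamp eigenvalues within −1e-10 of zero to zero, and fix each
component's sign by making its largest-|loading| entry positive for
reproducible reports. The retained rank k is the smallest whose cumulative
variance fraction reaches a target (default **98.2%**); a fixed-k mode is
also exposed since a count and a variance target are interchangeable ways to
state the same cut. Regression then runs on the scores Y = (X − center)P.

Why this removes separation: the separating indicators are rare, so their
variance directions sit in the discarded eigen-tail; the retained scores mix
them with noise and no linear combination of scores perfectly splits the
classes. The scores are exactly uncorrelated (orthogonal components), which
removes multicollinearity. Interpretation flows back through the loadings:
for each component significant in the logistic fit (Wald P < .05, ranked by
|log OR|), the top-|loading| variables are reported as the interpreted risk
factors. This is a ranked report, not a hard cutoff — component
"importance" has no canonical significance rule.

## Model building and separation detection

Selection pipeline on the (rebalanced) lab track: Pearson chi-square
prefilter of each categorical variable against the outcome (exclude P > .10;
zero-margin levels dropped from the table and noted), univariate logistic
filter (exclude Wald P > .05; a separated univariate fit is flagged and
retained for the separation report instead of being judged on a meaningless
P), expert reintroduction of clinically relevant exclusions, then forward
selection over named variable groups: the group with the best standalone
repeated-subsampling AUROC seeds the model and remaining groups are tried in
descending standalone order, kept only if the mean AUROC *strictly*
improves. Group order is otherwise unspecified in such protocols; descending
standalone AUROC is this package's choice.

Multivariate logistic fits use statsmodels maximum likelihood (Newton,
falling back to L-BFGS when Newton hits separation), reporting OR =
exp(beta) with 95% CIs. Two CI modes: Wald exp(beta ± 1.96 SE) (default)
and a bootstrap-percentile mode across repeated 70/30 refits — repeated-fit
summaries produce much narrower intervals than single-fit Wald CIs, and both
are legitimate summaries of different things, so the mode is recorded in the
output. **Separation detection**: a fit is flagged when any |log OR|
exceeds 10, a CI endpoint is non-finite, or the optimizer fails to
converge. The e^10 threshold separates clinically plausible ORs (< ~20)
from the 10⁹–10¹¹ artifacts separation produces by several orders of
magnitude. Classification at threshold 0.5 defines recall/F1.

The comparison model zoo (LR, L1-logistic/LASSO, RF, GBM, SVM) is tuned by
AUROC-scored 5-fold stratified grid search, then evaluated with the same
subsampling protocol. An estimator without probability outputs contributes
logistic-squashed decision scores.

## Evaluation protocol

"B-fold bootstrapping" is implemented as B independent **stratified 70/30
subsamples without replacement** — that is what "randomly split 70%/30%"
describes — not resampling with replacement; the naming here is deliberate.
Stratification guarantees both classes in every test split even at 5%
prevalence. Per metric (AUROC, AUPRC, recall, F1) the summary is the mean
and the 2.5/97.5 percentile interval across repeats. AUROC is the pairwise
concordance probability with half-credit ties; AUPRC uses step integration
of the precision envelope (interpolated precision), because linear PR
interpolation is optimistically biased. Calibration: Brier score (mean
squared error of the predicted probability) and equal-width reliability
bins (empty bins omitted).

**Ratio experiment**: a stratified test set at the *original* ratio is held
out before any undersampling (so clustering never sees test rows); per
ratio, discrimination is measured by the subsampling protocol within the
rebalanced training data, and calibration plus threshold-0.5 recall/F1 are
measured on the common test set. The expected qualitative behavior, which
the acceptance tests assert: balancing raises recall (and F1, when the
original-ratio model predicts almost no positives at threshold 0.5) while
*worsening* the Brier score — undersampling shifts the model's intercept by
roughly the log of the sampling ratio, inflating predicted probabilities on
original-prevalence data.

## Problem sizes and degenerate inputs

The default test-suite and acceptance-script problem sizes are scaled to
desk hardware as the package's own study conditions: cohorts of 1,000–5,000
rows, 10 continuous + 5 discrete + 18 diagnosis variables, 100-tree forests,
B = 2–100 subsampling repeats (the library default remains B = 500).
Degenerate inputs fail loudly: all-missing variables must be screened before
imputation, constant matrices break rank selection (zero total variance),
zero-variance predictors are rejected before a logistic fit, and
single-class label vectors are rejected by every metric.

## Known limitations

* Single imputation understates uncertainty in the filled values by design;
  no multiple-imputation mode is provided.
* The generator's Gaussian/latent-factor structure is friendlier to RF
  imputation than mixed-type real EMR data; recovery margins on real data
  will be smaller.
* Ordinal codes entering Euclidean distance as 0/1/2 treats category gaps as
  equal; binary indicators contribute at a different scale than z-scored
  labs.
* Penalized alternatives to the separation problem (e.g. Firth-type
  corrections) are out of scope; the package's answer is the data-side PCA
  transform.
* No recalibration (isotonic or otherwise) is provided for the
  undersampling-induced miscalibration it demonstrates.
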