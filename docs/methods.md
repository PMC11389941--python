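# Methods

This note documents the models, conventions and design choices behind
`crlmrad`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Problem setting

Patients resected for colorectal-cancer liver metastases (CRLM) differ
widely in time to recurrence (TTR) and disease-specific survival (DSS).
The pipeline asks whether quantitative features of the baseline
contrast-enhanced CT — radiomics — add prognostic information beyond the
Fong clinical risk score (CRS), and which way of collapsing a
multi-lesion patient into one feature vector preserves the most signal.
Both outcomes are right-censored: patients without recurrence or
cancer-related death contribute follow-up time up to their last visit.

## Image preprocessing and native features

Image/mask pairs are resampled to isotropic 1×1×1 mm (B-spline for the
image; nearest-neighbour for the mask, since interpolated binary labels
are ill-defined), clipped to the [−100, 200] HU soft-tissue window,
cropped 1 mm around the lesion, and discretized with a fixed 25 HU bin
width: `bin(v) = floor((v + 100)/25) + 1`, the upper clip value assigned
to the top (12th) bin so no empty trailing bin exists.

The native catalog is a deliberately compact, verifiable subset of the
standard radiomics families — 10 first-order statistics, 5 shape
descriptors, 5 GLCM and 5 GLRLM texture features — computed on the
original channel and on Laplacian-of-Gaussian (LoG) channels at
σ = 1…5 mm (125 features in total).  Conventions, chosen where catalogs
in the field differ:

* **GLCM**: symmetric co-occurrences at voxel distance 1 over the 13
  unique 3-D directions, restricted to in-mask pairs; matrices are
  normalized per direction and then averaged (unweighted), features
  computed on the averaged matrix.  Single-level regions return
  correlation 1 by convention.
* **GLRLM**: maximal in-mask runs per direction; the five feature
  values are averaged over directions.
* **Shape**: voxel-count volume, exposed-face surface area (a voxel
  face counts when it borders background), centre-to-centre maximum 3-D
  diameter (0 for a single voxel), sphericity π^{1/3}(6V)^{2/3}/A.
  Face-counting overestimates the area of smooth bodies by ~30–50%
  relative to a mesh; it is used because it is exactly checkable by
  hand (a 3³-voxel cube has area 54 mm²) and consistent across lesions.
* **LoG**: Gaussian smoothing followed by the discrete 6-point
  Laplacian, scale-normalized by σ² and with reflective boundaries.
  The discrete Laplacian is exactly zero on constant images, which a
  truncated analytic LoG kernel is not.  Filtering runs after
  resampling so σ in mm equals σ in voxels.
* All channels, including LoG outputs (which are not in HU), share the
  clip-window + bin-width discretization rule.  This is an assumption —
  fixed bin width is only physically motivated for the original HU
  channel — and is the single place where the discretization of derived
  channels had to be decided.

Lesions smaller than 2 voxels after resampling keep shape and
first-order features; texture features are set to NaN and a warning is
logged.  The full 1,317-feature catalogs produced by external
extractors (wavelet channels, GLSZM/NGTDM/GLDM families) are ingested
from CSV/TSV via `ingest_feature_table` rather than recomputed.

## Multi-lesion aggregation and the Fong score

Seven strategies collapse an *m*-lesion patient to one vector: largest
lesion only, smallest lesion only, unweighted average, volume-weighted
average, volume-weighted average of the three largest lesions, and the
largest lesion augmented with either the lesion count or the total
metastatic volume.  Whenever several lesions are combined, *geometric*
features are summed (size accumulates over tumour burden) and *texture*
features averaged (tissue character does not add).  The default
taxonomy treats the shape family and the appended burden features as
geometric and everything else — including first-order intensity
statistics, which are arguably either — as texture; the taxonomy is an
explicit, overridable mapping.  Weighted averages renormalize volume
ratios over the included lesions (weights must sum to one, which forces
renormalization for the top-3 variant).  Volume ties are broken by
lexicographic lesion id for determinism.

The Fong CRS adds one point per adverse criterion — node-positive
primary, disease-free interval < 12 months, more than one CRLM, largest
CRLM > 5 cm, CEA > 200 ng/mL — with strict inequalities, and is
dichotomized low (0–2) vs high (3–5).

## Selection cascade and signature

On the training partition only:

1. **MRMR** (difference criterion) ranks features and keeps the top
   k = 50.  The published pipeline does not state the MRMR target or
   discretization; here relevance is mutual information against the
   event indicator, with features discretized at their quartiles.  Both
   choices are assumptions and are isolated in one function.
2. **Univariate Cox filter**: per feature, a one-covariate Cox model
   (Newton iteration, Breslow ties); features survive iff the training
   concordance of their risk score exceeds 0.53.  Non-convergent fits
   (e.g. monotone likelihood) drop the feature with a warning.
3. **Lasso-Cox**: L1-penalized Cox over a decreasing penalty path
   (glmnet-style coordinate descent via scikit-survival), penalty
   chosen by 5-fold cross-validated partial likelihood on held-out
   folds; no one-standard-error rule.  Features are standardized
   internally; coefficients are reported on the original scale.  A
   requested penalty of exactly 0 dispatches to the unpenalized Newton
   solver.

The cascade is repeated on 100 random 85% subsamples of the training
set; per-feature selection counts are recorded and the consensus
signature keeps features selected in ≥ 50% of runs (configurable),
with the mean coefficient over the runs where they were selected.  The
filter threshold is applied per run.  Eventless subsamples are redrawn
and logged.

## Survival models

**Random survival forest** — scikit-survival's implementation:
bootstrap ensemble, log-rank splitting over √d sampled features,
default 200 trees and minimum leaf size 5 (the source protocol states
no values; forests overfit small cohorts easily, hence a conservative
leaf size, all exposed in config).  Risk = ensemble-mean cumulative
hazard summed over the event-time grid.

**Neural Cox model ("DeepSurv-44")** — a NumPy multilayer perceptron:
input → [linear(4) → batch-norm → ReLU → dropout 0.1] × 2 → linear(1),
trained full-batch with Adam at learning rate 1e-5 to minimize the
event-averaged negative Cox partial log-likelihood (Breslow ties).
Notes on the protocol:

* The source architecture lists linear/batch-norm/dropout blocks with
  no activation; without one the network is affine, so a ReLU is
  inserted after batch-norm, the standard DeepSurv backbone.
* Full-batch training keeps partial-likelihood risk sets intact;
  mini-batching would truncate them on cohorts this small.
* At learning rate 1e-5, Adam's per-epoch parameter displacement is of
  order 1e-5, so thousands of epochs move parameters by only ~0.01.
  The epoch budget is therefore large (default 100,000) with
  early-stopping patience of 20,000 epochs on the loss of an internal
  15% validation split (evaluated in inference mode every 10 epochs;
  the returned weights are the snapshot at the validation minimum).
  The long patience rides out the transient while batch-norm running
  statistics settle, during which validation loss can drift
  non-monotonically; fits on outcome-free data stop after the patience
  window, so null fits are cheap.
* Inputs are standardized with training-split statistics, frozen for
  holdout scoring; inference disables dropout and uses running
  batch-norm statistics, so repeated scoring is deterministic.

CRS enters a survival model, when requested, as one appended column
(dichotomous 0/1 by default; the raw 0–5 score optionally).

## Evaluation design

One stratified holdout (15% of patients, event-ratio-matched, size
`round(0.15 n)`) is drawn per outcome.  Per training subsample (85%,
default 100 runs) the cascade is refit from scratch — the holdout never
reaches any selection or fitting step, and a runtime assertion checks
the intersection is empty — then survival models are fit on the
surviving features and the holdout is scored.

* **C-index** (Harrell): over pairs whose strictly earlier time is an
  event, the fraction where the higher score belongs to the earlier
  event, half credit for score ties.  Pairs tied on time are not
  comparable.
* **Classification**: outcomes are landmark-dichotomized (recurrence by
  18 months for TTR, death by 36 months for DSS).  Patients censored
  before the horizon have indeterminate status and are excluded from
  both fitting and AUC — the landmark convention; exclusion counts are
  recoverable from the labels.  A logistic model (effectively
  unpenalized) maps the survival score, alone or with CRS, to the
  label; direct logistic/random-forest baselines on the selected
  features are optional.
* **Confidence intervals**: percentile bootstrap, default 2,000
  resamples.  In the repeated-split report the point estimate is the
  mean of the per-run holdout metrics and the CI bootstraps those
  per-run values; how the original 100-run distribution was reduced to
  one interval is not stated at the source, so the report schema
  records this choice explicitly.  Degenerate resamples (undefined
  metric) are redrawn with a bounded budget.

Failed cells in the experiment grid (e.g. a run whose cascade retains
nothing) are recorded as NaN with the error message, not fatal.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at configurable scale (defaults: 300 patients, 60 features, 3
informative):

* lesion count = 1 + Poisson(2), log-normal volumes
  (median ≈ 8 cm³, σ_log = 1.2, sizes spanning ~0.5–20 cm diameter);
* per-lesion features are equicorrelated Gaussian blocks (ρ = 0.3,
  block size 10) so that selection has to contend with correlated
  noise; informative features carry reserved names so recovery can be
  scored;
* the hazard's linear predictor reads the informative features off the
  *largest* lesion (log-hazard ±0.7 per SD) plus 0.4 for a high
  dichotomized CRS — planting the signal where the largest-lesion
  aggregation looks for it, which is the behaviour the strategy
  comparison is designed to detect;
* TTR is exponential proportional hazards with baseline 0.06/month
  (median ≈ 12 months at the null); DSS uses half that baseline;
* censoring = min(exponential dropout at 0.03/month, 84-month
  administrative horizon), yielding ≈ one third censoring for TTR;
* clinical fields are sampled so the Fong score spans 0–5 with most
  mass at 2–3 (node-positive 60%, P(DFI < 12 mo) ≈ 0.55, multiple
  lesions ≈ 86%, large lesion ≈ 10%, high CEA ≈ 13%).

`true_linear_predictor` recomputes the exact generation-time log-hazard
for any bundle and serves as the concordance-optimal oracle in
parameter-recovery tests.

What the generator does **not** emulate: scanner/kernel heterogeneity,
real radiomics inter-feature correlation structure (features are
Gaussian blocks, not texture computed from images), informative
censoring, competing risks, or chemotherapy response dynamics.  Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and leak-free under its own assumptions — not that the original
clinical effect sizes are reproduced.  Small 3-D phantoms (ellipsoidal
lesion, correlated in-mask texture, seed-free geometry) give the
extraction module a ground-truthed substrate.

## Numerical choices and degenerate inputs

* Breslow approximation for tied event times everywhere (solver, loss,
  penalized path) — the simplest internally consistent choice.
* The Newton solver uses damped steps with step-halving and raises on
  monotone likelihoods instead of returning divergent coefficients.
* Constant features: zero MRMR relevance (never picked while any
  feature has positive relevance), skipped by the univariate filter,
  unit SD substituted in standardization to avoid division by zero.
* Zero-event inputs raise everywhere (loss, fits, filter, bootstrap
  pipelines redraw instead where a redraw is meaningful).
* Split sizes round to nearest; the training side absorbs remainders.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-run seeds are spawned from the global
  seed so any run is reproducible in isolation.

## Scale of the packaged experiments

The packaged tests and the acceptance script exercise the design at
desk scale, chosen so the full suite runs on one CPU in minutes: 300
patients, 60 features, 5–10 repeated splits, 10 strategy-ordering
replicates, 200 bootstrap-coverage replicates at 2,000 resamples.  The
experiment layer itself accepts the full-size design (100 runs, all
seven strategies, both outcomes) unchanged.

## Known limitations

* The native feature subset is not IBSI-certified; it is a verifiable
  core, with full catalogs expected via ingestion.
* MRMR's target/discretization and the per-run application of the
  univariate filter threshold are assumptions where the source is
  silent (flagged above).
* The neural model's epoch budget dominates experiment runtime; the
  conservative learning rate is kept for fidelity rather than speed.
* Bootstrap CIs over repeated splits understate variability relative to
  patient-level resampling when runs share the single holdout.
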