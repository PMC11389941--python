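# crlmrad

Baseline-CT radiomics pipeline for predicting **time to recurrence
(TTR)** and **disease-specific survival (DSS)** in patients with
colorectal-cancer liver metastases (CRLM).

Patients with resectable CRLM are routinely triaged with the Fong
clinical risk score (CRS) — five preoperative criteria, dichotomized
low (0–2) vs high (3–5) — but that score poorly separates patients who
will recur early from those who will not.  `crlmrad` implements, as a
tested and reusable library, the full radiomics alternative: per-lesion
texture features from segmented CT lesions, strategies for collapsing a
multi-lesion patient into one feature vector, a repeated
feature-selection cascade producing a prognostic signature, survival
models (random survival forest and a compact neural Cox network), and a
leak-free repeated-split evaluation with bootstrap confidence
intervals.  A synthetic cohort generator with a planted, recoverable
hazard signal makes every stage testable without any patient data.

Audience: imaging/biostatistics researchers who want either the full
pipeline on their own per-lesion feature tables (CSV/TSV, or NIfTI
image/mask pairs for native extraction) or the individual components
(aggregation rules, Lasso-Cox signature, Harrell C-index, landmark
classification) as library functions.

## The model at the core

Per patient *i* with feature vector **x**ᵢ (one aggregation of its
lesions), outcomes are modelled by proportional hazards,
h(t | **x**ᵢ) = h₀(t)·exp(f(**x**ᵢ)), with two choices of risk score f:

* the **radiomics signature** f(**x**) = Σⱼ βⱼ xⱼ, where the βⱼ come
  from an L1-penalized Cox fit after MRMR ranking (top 50) and a
  univariate-Cox concordance filter (keep C > 0.53), repeated on 100
  random 85% subsamples of the training set with per-feature selection
  counting;
* a **neural Cox model** ("DeepSurv-44"): two blocks of
  [linear(4) → batch-norm → ReLU → dropout 0.1] and a linear output,
  trained full-batch with Adam (lr 1e-5) on the negative Cox partial
  log-likelihood (Breslow ties), early-stopped at the minimum loss of
  an internal 15% validation split;

plus a random survival forest as the ensemble alternative.  Models are
evaluated on a stratified 15% holdout by Harrell's concordance index
and, after landmark dichotomization (recurrence by 18 months for TTR,
death by 36 months for DSS), by ROC AUC of a logistic model on the risk
score ± CRS.  Confidence intervals are percentile bootstrap (2,000
resamples).

## Worked example

```python
import numpy as np
from crlmrad import SyntheticConfig, generate_cohort
from crlmrad.evaluate import ExperimentConfig, run_experiment

# 300 patients, 60 features of which 3 carry log-hazard +/-0.7 per SD
# planted in the largest lesion, ~1/3 censoring
cohort = generate_cohort(SyntheticConfig(seed=2024))

report = run_experiment(cohort, ExperimentConfig(
    strategies=("largest_only",), outcomes=("ttr",),
    models=("rsf", "deepsurv"), with_crs=(False,),
    n_runs=4, n_boot=200, seed=7,
))
print(report.table[report.table.metric == "cindex"]
      [["model", "estimate", "ci_lo", "ci_hi"]])
```

Output (a few minutes on one CPU; the neural model dominates):

```
       model  estimate     ci_lo     ci_hi
1   deepsurv  0.684939  0.655055  0.712602
3        rsf  0.704577  0.693648  0.713115
5  signature  0.743511  0.737022  0.753099
```

Reading: on the held-out 15% of the cohort, all three risk scores rank
recurrence times far better than chance (C-index 0.5) — the Lasso-Cox
signature at C ≈ 0.74, the random survival forest at ≈ 0.70 and the
neural Cox model at ≈ 0.68 — because the cascade recovers the three
informative features planted in the largest lesion.  The intervals are
percentile bootstraps over the repeated training splits.

The same pipeline is scriptable from the shell:

```bash
crlmrad all --config my_config.yaml      # simulate -> evaluate -> report tables
crlmrad extract --image ct.nii.gz --mask lesion.nii.gz --output-dir out/
```

An empty config reproduces the study defaults (MRMR k = 50, Cox filter
0.53, 100×85% splits, 15% holdout, horizons 18/36 months, 2,000
bootstrap iterations); every stage writes a JSON provenance sidecar
with the config hash and seed.

## Layout

```
src/crlmrad/
  synthetic.py    cohort + phantom generators, cohort CSV/NIfTI IO
  radiomics.py    preprocessing, LoG, first-order/shape/GLCM/GLRLM, ingestion
  aggregation.py  seven multi-lesion strategies, Fong CRS
  selection.py    MRMR, univariate Cox filter, Lasso-Cox, repeated signature
  models.py       random survival forest, neural Cox model, CRS attachment
  evaluate.py     splits, C-index/AUC, bootstrap, repeated-split experiment
  config.py/cli.py  validated config, provenance, subcommands
docs/methods.md   model documentation: assumptions, conventions, limitations
```
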