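# pdacsig

A tested, reusable implementation of a prognostic gene-signature pipeline
for **localized pancreatic ductal adenocarcinoma (PDAC)**.  Resectable PDAC
has a median survival under two years and current staging poorly separates
patients who will do well from those who will rapidly relapse.  The idea
implemented here: contrast primary tumors at the two extremes of the
disease — nonmetastatic (resected) vs metastatic — to find a small set of
genes whose expression carries prognostic information, then use that
signature to stratify new patients into high- and low-risk groups before
treatment decisions are made.

The package is aimed at computational biologists who want each stage as a
library function with a thin CLI on top: every step is importable, seeded,
and validated against independent oracles.

## The method

Given two-color microarray log-ratios `x = log2(R/G)`:

1. **Preprocess** — MA-lowess normalization (`M − fit(M ~ A)`), intensity
   filtering (a gene is kept when one channel's mean intensity exceeds 10 in
   ≥ 70 % of experiments), and k-nearest-neighbor imputation (k = 10,
   gene-row neighbors, inverse-distance weights).
2. **Batch adjustment** — Distance Weighted Discrimination (DWD) finds the
   direction *w* separating the two cohorts by minimizing
   `Σᵢ 1/rᵢ + C·Σᵢ ξᵢ` subject to `rᵢ = yᵢ(w·xᵢ + b) + ξᵢ ≥ 0`, `‖w‖ ≤ 1`;
   each cohort is translated along *w* so the systematic bias vanishes while
   all within-cohort geometry is preserved exactly.
3. **Signature derivation** — Significance Analysis of Microarrays (SAM):
   `dᵢ = (x̄ᵢ₂ − x̄ᵢ₁)/(sᵢ + s₀)` with a permutation-estimated false
   discovery rate; the threshold Δ is tuned to FDR ≤ 5 %.
4. **Single-sample prediction** — the resected-class centroid (per-gene mean
   over nonmetastatic derivation tumors, signature genes only) classifies
   each new sample by the distance `1 − Pearson r`; a distance cut-point of
   1 corresponds to r = 0.
5. **Risk stratification** — an X-tile-style scan maximizes the two-group
   log-rank statistic over candidate cut-points on a training cohort (with a
   Miller–Siegmund-corrected minimum p reported alongside the naive one),
   and the *frozen* cut-point is applied to an independent test cohort.
6. **Validation** — Kaplan–Meier curves, the log-rank test, Cox proportional
   hazards (`HR = exp(β)`, Efron ties by default), Fisher exact and Pearson
   chi-square association tests against clinicopathological variables, and
   an intensity × proportion immunohistochemistry score.

A fully seeded synthetic-data module generates two-cohort derivation designs
(matched tumor–normal pairs, per-gene batch offset, a small spiked-gene
class effect) and validation cohorts whose survival hazard depends on the
true correlation to a centroid, so the whole pipeline is testable with no
download.  See `docs/methods.md` for models, parameter choices and
limitations.

## Worked example

Simulate a study (600 genes; 15 + 15 tumor–normal pairs per cohort; 34
training and 67 test patients; four-fold true hazard ratio) and run the full
pipeline:

```sh
pdacsig simulate --out-dir study --seed 5 --n-genes 600
pdacsig run --config study/pipeline_config.json
pdacsig report --out-dir study/results
```

which prints (numbers from this exact invocation):

```
## Derivation
- 600 genes x 60 samples
- signature (5 genes): G00139, G00200, G00300, G00397, G00423
- SAM s0=0.2592, delta=0.3807, est. FDR=0.0244

## Training
- optimal distance cut-point 0.09079 (log-rank chi2=14.3)
- naive p=0.000153, corrected p=0.00415
- groups at cut-point: 19 low / 15 high

## Independent test
- frozen cut-point 0.09079: 35 high / 32 low risk
- median OS high 12.527317147559144 vs low 49.30708924278928 months
- log-rank p = 0.001441
- Cox HR (high vs low) = 2.64 [1.43, 4.9], p = 0.00201
```

Reading this: SAM recovered 5 of the 6 planted genes at an estimated FDR of
2.4 %; the training scan split 34 patients at the distance cut-point with
the largest log-rank separation; applying that frozen cut-point to the 67
independent test patients produced high- and low-risk groups with median
overall survival of 12.5 vs 49.3 months, a log-rank p of 0.0014 and a Cox
hazard ratio of 2.6 — attenuated from the simulated truth of 4 by imperfect
classification, as expected for a correlation over a handful of genes.
Every artifact (SAM table, centroids, risk calls, KM curves, JSON + markdown
report) lands in `study/results/`; re-running with the same seed reproduces
it byte for byte.

The same stages are available as library calls (`pdacsig.pipeline.derive`,
`.train` and `.test` operate on DataFrames), and
`pdacsig preprocess` builds an expression matrix from spot-level two-color
intensity tables.  Real datasets are supplied as the same tab-separated
matrix and clinical CSV formats; a gene-by-sample log-ratio matrix exported
from a GEO series drops in directly.

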