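# Methods

`pdacsig` re-implements, as a tested pipeline, the derivation and validation
of a prognostic gene-expression signature for localized pancreatic ductal
adenocarcinoma (PDAC): nonmetastatic and metastatic primary tumors are
contrasted to derive a small gene list, new samples are classified one at a
time by correlation to the resected-tumor centroid, and the resulting
high/low-risk split is validated on independent cohorts with survival
statistics.  This note records the models, the parameter choices, and the
places where the design was genuinely open.

## Data model

Expression is carried as log2(red/green) ratios from two-color arrays
(Cy5-labeled sample against a Cy3-labeled common reference), in a
gene-by-sample `pandas.DataFrame`.  Missing entries are permitted until
imputation; every statistical stage downstream of imputation requires a
complete matrix.

## Preprocessing

* **Lowess normalization** removes intensity-dependent dye bias: with
  M = log2(R/G) and A = ½·log2(R·G), a locally weighted regression of M on A
  (global fit, default span 0.3) is subtracted from M.  A global MA-lowess
  (not print-tip-wise) is the minimal variant; spots with a nonpositive
  channel have no defined ratio and propagate as missing.
* **Intensity filtering** keeps a gene when at least one channel's mean
  intensity strictly exceeds 10 in at least 70% of experiments
  (`ceil(fraction × n_experiments)`, so 7 of 10 passes at 0.7).  Spots
  flagged poor-quality count as failing their experiment.  The boundary
  value 10 fails (strict inequality).
* **KNN imputation** (k = 10) replaces each missing value with the
  inverse-distance-weighted average of the k nearest gene rows, where
  distance is plain Euclidean over the columns observed in both rows and
  only rows observed in the target column are candidates.  Distance ties
  break by matrix row order; exact matches (distance 0) short-circuit to
  their plain mean.  When no candidate row carries the needed column the
  row's own observed mean is used.  This is the gene-row-neighbor scheme of
  the classical microarray imputation literature; `sklearn`'s imputer (row =
  sample semantics, nan-scaled distances) is intentionally not used.

## Batch adjustment (DWD)

Distance Weighted Discrimination finds the direction separating two batches
by minimizing the sum of inverse margins plus a slack penalty C — unlike an
SVM every sample pulls on the solution, which behaves well when genes vastly
outnumber samples.  The package solves the equivalent smooth convex program
(DWD loss `V_C(u) = 1/u` for `u ≥ 1/√C`, linear below) over the span of the
samples with an SLSQP solver under the unit-norm constraint; C defaults to
100/(median between-batch distance)².  Each batch is then translated along
the unit direction — a pure translation, so all within-batch geometry
(distances, covariance) is preserved exactly.

Two translation targets exist.  The default (`target="zero"`) is symmetric:
every batch moves to mean projection zero and neither cohort is privileged.
The pipeline instead anchors (`target="reference"`): in the derivation stage
the resected cohort stays fixed and the metastatic cohort is translated onto
it, and later stages keep the established space fixed while only the
incoming cohort moves.  The reason is specific to the correlation-based
classifier: the translation vector `m·w` varies across genes, so a
symmetric adjustment mixes half the batch offset into the resected centroid
and compresses every SSP distance toward zero, while re-adjusting all
cohorts at each stage changes the frame between where the cut-point is
learned and where it is applied.  Anchoring keeps the centroid in the raw
resected frame and the frozen cut-point valid; in simulation it restores
the expected distance geometry and measurably improves risk-call accuracy.
How the original analysis anchored its adjustment on the tumor–normal pairs
is not fully specified; fitting the batch direction on all paired samples
(tumors and normals) of the two derivation cohorts is this package's
documented interpretation.

PCA of the gene-centered matrix (PC1×PC2 sample scores) provides the
standard before/after mixing diagnostic.

## Signature derivation (SAM)

Two-class unpaired SAM scores gene i with `d_i = (mean₂ − mean₁)/(s_i + s0)`
where `s_i` is the pooled two-sample standard error and the fudge factor
`s0` minimizes the coefficient of variation of the within-window spread of d
across scatter-quantile windows (candidates: 5%-grid percentiles of s; with
identical scatters the 5th percentile is returned by convention).  Expected
order statistics come from label permutations — all distinct assignments
when there are at most `n_perm` (default 1000), otherwise seeded random
shuffles — and genes are called where the sorted observed d departs from the
permutation average by more than delta, scanning outward from the origin.

Delta is the smallest candidate whose estimated FDR meets the target (5%
default).  Candidate deltas are the actually attained |d − d̄| deviations;
they are never interpolated or thinned in the tail, because a candidate
between two attained values can silently skip a real call set.  The FDR at a
delta is the mean (over permutations) number of *non-called* genes beyond
the cut thresholds, divided by the observed call count.  Restricting the
false-count pool to non-called genes removes the contamination of the
permutation null by genuinely differential genes — the known upward bias of
permutation FDR estimates under strong signal; with it, a complete-null
design (1,000 genes, 15 vs 15) calls no gene in the median replicate while a
6-gene 3σ spike is recovered completely in essentially every replicate, at a
realized FDR close to nominal.  The per-permutation summary can be switched
to the median (`fdr_method="median"`), which is reported by later SAM
software but is liberal for one-gene call sets (the median false count of an
extreme singleton is typically zero).  Per-gene q-values are the smallest
estimated FDR over the thresholds at which the gene is called.

## Single-sample predictor

Centroids are per-gene means over a class's derivation tumors, restricted to
the signature.  Both class centroids are computed, but risk is called only
against the resected (nonmetastatic) centroid: a sample's distance is
1 − Pearson r over the signature genes, and distance below the cut-point is
low risk; the boundary goes to high risk (conservative toward poor
prognosis).  A cut-point of 1 is exactly r = 0.  With a six-gene signature
the correlation runs over six points and is intrinsically noisy; this is a
property of the method, not repaired here.  Derivation normals do not enter
the centroid.

## Survival statistics

Kaplan–Meier estimation and the log-rank test are delegated to `lifelines`;
the Cox partial likelihood is maximized by `statsmodels`' PHReg with Efron
tie handling by default (month-resolution data tie heavily) and Breslow
available by flag for parity with software whose default is Breslow.  The KM
median is the first time with S(t) ≤ 0.5; a curve that never reaches 0.5 has
no median.  Rows with missing covariates are dropped and counted, matching
complete-case multivariable tables.

The cut-point scanner emulates the X-tile procedure: candidates are
midpoints between consecutive distinct scores leaving at least `min_group`
(default 5) samples per side; every candidate is scored with the two-group
log-rank statistic (computed for all prefix splits at once via cumulative
sums over the score order), and the maximizer is returned with its naive p
and a Miller–Siegmund-corrected minimum p.  The naive minimum p of such a
scan is strongly anti-conservative (observed ~45% of null scans below 0.05);
the corrected p restores approximately nominal level (~5–8%).  On a
continuous marker the argmax split wanders one to three samples around a
true changepoint at any sample size, so exact threshold recovery should be
judged on binned marker populations — the real cut-point software bins
markers into at most 100 populations — where recovery of the true gap
exceeds 90% at a few hundred samples under a four-fold hazard ratio.
Published analyses validate the chosen cut-point on an independent cohort
rather than correcting; the pipeline therefore reports both p-values and
freezes the cut-point before touching the test set.

## Association tests and IHC scoring

Fisher's exact test is two-sided by the probability-mass rule and the
Pearson chi-square carries no continuity correction; these conventions
reproduce the published high/low-risk association tables (e.g. neoadjuvant
0.136, margin 0.344, T-stage 0.886) to the printed third decimal.
Immunohistochemistry cores are scored as intensity (0–4) × proportion of
positive epithelial cells, with staining below 5% positive cells treated as
negative (score forced to 0); scores are dichotomized at a cutoff (sample
median by default), boundary to low.

## Synthetic studies

The generator produces the structure the pipeline assumes, not realistic
pancreatic biology:

* **Derivation design:** two cohorts of 15 tumor + 15 matched normal samples
  (the two-cohort derivation design), additive Gaussian noise on log2 ratios
  (σ = 0.5), a per-gene batch offset on cohort B drawn once per gene
  (σ = 1.0), and 6 differential genes shifted by ±1.5 (3σ) in cohort-B
  tumors only — normals carry the batch offset but no class effect.
  Missingness is injected completely at random (2% default) without ever
  emptying a gene row.
* **Validation cohorts:** each sample is the standardized centroid deviation
  scaled by the effect size, with a random ±1 orientation, plus noise; the
  *true* risk label is then read off the realized correlation sign, exactly
  as the classifier would.  Survival is exponential with hazard
  `baseline × HR^high`; baseline is ln 2 / 49 per month (low-risk median 49
  months) and HR defaults to 4, the magnitude of the published multivariable
  hazard ratio.  Censoring is independent exponential with per-sample rate
  `h·q/(1−q)`, which gives expected censored fraction q (30% default)
  regardless of a sample's own hazard.

What passing simulated tests do **not** show: robustness to probe-level
artifacts, non-Gaussian heavy-tailed noise, confounding between batch and
biology beyond a location shift, cohort heterogeneity, or informative
censoring.  The per-gene and per-sample magnitudes are free parameters of
the simulation, not estimates from the original cohorts (within-class
variance and batch magnitude are not reported there).

## Problem sizes and numerics

Replicated experiments in the test-suite and the acceptance script use
1,000-gene, 15-vs-15 designs with 300 permutations for SAM calibration (50
replicates per arm), 40 replicates of n = 500 for Cox recovery, 100
replicates of n = 300 for cut-point recovery and 200 null scans of n = 100 —
sizes chosen so each experiment is stable at its decision boundary while a
full run stays in the tens of seconds.  The DWD solver runs to an SLSQP
tolerance of 1e−10 with analytic gradients; Cox fits iterate to the PHReg
default gradient tolerance; Fisher p-values agree with brute-force
hypergeometric enumeration to machine precision.  All randomness flows
through explicit integer seeds; identical config and seed give bit-identical
studies and reports.

## Known limitations

* The SAM implementation covers the two-class unpaired design only.
* DWD is two-batch; chains of cohorts are handled sequentially through the
  reference-target adjustment, not by a joint multi-batch fit.
* The cut-point scan assumes a single changepoint; X-tile's two-cut
  (three-group) mode is out of scope.
* Probe-to-gene collapsing, background subtraction and dye-swap averaging
  are out of scope; spot tables are taken at face value.
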