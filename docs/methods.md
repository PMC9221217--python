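# Methods

`atlasfusion` implements a classification framework for separating mild
cognitive impairment (MCI) patients from healthy controls (HC) using two
feature families extracted under interchangeable brain parcellations:
regional gray-matter volume (GMV) from structural MRI and the regional mean
Hurst exponent (HE) of the resting-state BOLD signal.  This note documents
the models, the numerical choices, and what the synthetic validation does
and does not establish.

## Temporal preprocessing

Inputs are assumed spatially preprocessed (realigned, normalized, smoothed).
The package covers the temporal steps that precede Hurst estimation:

* **Leading-volume removal.** The first volumes of an acquisition are
  discarded (default workflow: 10 of 239 volumes at TR = 2 s, leaving 229)
  to let magnetization reach equilibrium.
* **Nuisance regression.** Each voxel series is replaced by its OLS residual
  against `[intercept, confounds]`, where confounds typically comprise six
  head-motion parameters, mean white-matter and CSF signals, and a linear
  drift (a demeaned unit ramp; given the intercept, any affine
  reparameterization of the ramp leaves the residuals unchanged).  A
  rank-deficient design triggers a pseudo-inverse solve and a warning rather
  than an error — the residuals are identical for any least-squares solution.
* **Band-pass filtering (0.01–0.10 Hz).** The default filter is a
  discrete-Fourier ideal (brick-wall) band-pass: frequency bins outside the
  band, including DC, are zeroed.  It is idempotent (a projection), which
  makes pipeline algebra predictable; its known cost is ringing around sharp
  spectral edges.  An order-5 zero-phase Butterworth is available via
  `bandpass(..., method="butterworth")` for users who prefer smooth rolloff.
  Regression runs before filtering.

## Rescaled-range (R/S) Hurst estimation

For a series of length N and a block length n, the series is cut into
⌊N/n⌋ non-overlapping blocks.  Per block, the mean-adjusted cumulative-sum
profile is formed; R is its range (max − min) and S the block standard
deviation under the population (divide-by-n) convention.  R/S is averaged
over blocks, and the estimate h is the least-squares slope of
log(mean R/S) against log n.

Numerical choices, fixed for reproducibility:

* **Window ladder**: powers of two from 8 to ⌊N/2⌋ (N = 229 → {8, 16, 32,
  64}; N = 1024 → {8, …, 512}); configurable.
* **Degenerate blocks** (S = 0) are skipped with a warning; a window with no
  valid blocks is dropped from the fit; a series with fewer than two valid
  windows (e.g. a constant series) raises `DegenerateSeriesError`.  In
  `hurst_map`, degenerate voxels become NaN and are counted; only an
  all-degenerate mask aborts.
* **Partial trailing blocks** are discarded.
* **No clipping**: estimates outside (0, 1) are reported and flagged, never
  truncated.

The estimator is exactly invariant under affine scaling of the input and
carries the classical finite-sample bias: at N = 1024 the mean estimate for
white noise (true h = 0.5) sits near 0.55–0.56, and the bias shrinks as h
grows (≈ −0.02 at h = 0.8).  The acceptance checks therefore assert a bias
band at h = 0.5 and ±0.08 recovery for h ≥ 0.6, rather than pretending the
plain (uncorrected, non-overlapping) R/S variant is unbiased.  At the
in-vivo length N = 229 the per-voxel spread is considerably larger
(empirical SD ≈ 0.08–0.10); regional averaging is what makes the feature
usable.  Anis–Lloyd-type small-sample corrections are deliberately not
applied, keeping the estimator the plain textbook variant; the window
ladder is the only tuning surface.

## Parcellation handling

Atlases are maximum-probability integer label images.  Loading applies an
exclusion list (e.g. cerebellar regions 95–120 and the two regions lost at
3 mm resampling, 133–134, for an AAL3-style 166-region atlas → 138 retained;
brain stem 97–98 for a Harvard–Oxford-style 112-region atlas → 110).
Atlas/data grid mismatches are resolved by nearest-neighbour resampling of
the atlas onto the data grid (labels stay integral); regions that vanish on
a coarser grid are dropped with a warning rather than raising, since this is
exactly how small structures behave at 3 mm.  Grids may differ per modality
(functional at 3 mm, structural at 1 mm); each modality resamples the atlas
independently.

Regional reduction is the mean (HE) or sum (GMV) over voxels with the
region's label, in ascending label order; regions emptied by an analysis
mask yield NaN and are dropped from feature tables with a warning.  GMV uses
volume-preserving semantics: sum of modulated map values × voxel volume,
reported in ml (the `get_totals` convention).  A per-voxel mean variant
exists behind `statistic="mean"` for users who want size-normalized values;
total volume is the default because modulated maps are constructed to
preserve tissue volume under warping.

## Feature selection: MRMR + SFC

Continuous features are discretized into 5 equal-frequency (quantile) bins —
rank-then-split, so ties at bin edges divide between bins — and mutual
information is the plug-in estimate in bits.  The bin count trades bias for
variance at n ≈ 125 subjects; 5 is the common default and is configurable.

MRMR ranking is the greedy mean-redundancy difference (MID) scheme: the
first pick maximizes relevance I(f, class); each subsequent pick maximizes
I(f, class) − mean over selected s of I(f, s).  Ties break to the lowest
column index.  The top k = 50 ranked features feed the sequential feature
collection (SFC): every contiguous window [s, e] of the ranking
(1 ≤ s < e ≤ k, hence k(k−1)/2 windows) is scored by inner-LOOCV accuracy of
the SVM on the training partition, and the best window wins — ties resolve
to the highest score, then the fewest features, then the smallest start
index (parsimony first).

The SFC evaluator either re-runs the full hyperparameter grid search per
window (faithful, default) or scores all windows at a fixed (C, γ) and grid
searches only the chosen window (`sfc_hyperparams=(C, γ)`), trading a
second-order dependence for a ~grid-size speedup.  Simulation-heavy tests
and the acceptance script use the fixed-evaluator mode with a reduced 3×3
grid; the selection structure (ranking, exhaustive windows, training-only
fitting) is identical in both modes.

## Classification and validation

The classifier is a C-SVM with RBF kernel (linear available).  C and γ are
grid-searched over 2^−8, 2^−7.5, …, 2^8 (33 values each) by inner-LOOCV
accuracy; ties break to the smallest C, then the smallest γ.  Features are
z-scored with training-partition statistics at every level — each inner
LOOCV fold re-standardizes on its own n−1 rows, and the outer-fold model's
scaler is fit on the outer training set only — so no moment of a held-out
subject ever reaches a model that predicts it.

Generalization is estimated with nested LOOCV: for each held-out subject,
MRMR + SFC and the grid search run on the remaining subjects only; the
fold's model predicts the held-out subject once.  Out-of-fold predictions
aggregate into accuracy, sensitivity (patient class), specificity (control
class), and AUC by the trapezoidal rule over the empirical ROC of the signed
decision values from each outer-fold model.  Because each fold may select a
different window, the reported feature count is the mode of per-fold window
sizes (all per-fold details are kept in the result).  A non-nested selection
helper (`select_features` on a whole table) exists for exploration and is
flagged optimistic: its score reuses the data that chose the features.

Inner loops run through the same libsvm solver that backs
`sklearn.svm.SVC`, called via a thin internal wrapper that skips per-call
input validation (tens of thousands of ~40-row fits make validation the
dominant cost); a test pins prediction equivalence against the public
estimator, and outer-fold models use public `SVC` directly.

## Integration strategies

Four strategies mirror the single/multi-modality × single/multi-atlas
design space:

1. **single-modality, single-atlas** — one table, one nested LOOCV;
2. **single-modality, multi-atlas bagging** — majority vote over the
   out-of-fold predictions of three independently trained single-atlas
   models; the member count must be odd so binary votes cannot tie, and
   hard votes carry no decision values, so bagging rows report no AUC;
3. **multi-modality, single-atlas** — feature-level concatenation of both
   modalities under one atlas, then the standard pipeline;
4. **multi-modality, multi-atlas** — concatenation of one (modality, atlas)
   table per modality, pairing the top atlases per modality.

"Top" atlases default to the single-modality accuracy ranking computed
first, which reuses evaluation data and is therefore optimistically biased;
the runner logs a warning and accepts explicit a-priori member lists to
avoid the bias.  Votes always operate on out-of-fold predictions, never on
refit in-sample ones.

## Synthetic data: what it emulates and what it does not

* `simulate_fgn` draws exact fractional Gaussian noise by Davies–Harte
  circulant embedding of the theoretical autocovariance
  γ(k) = ½(|k+1|^{2h} − 2|k|^{2h} + |k−1|^{2h}), with a logged Cholesky
  fallback for the rare non-embeddable small-n case.  It is the ground
  truth for the R/S estimator: its lag-1 autocorrelation and sample-moment
  expectations (the mean-adjusted sample variance has expectation
  1 − N^{2h−2}) are verified against closed forms.
* `simulate_cohort` plants group-dependent persistence (fGn with per-group
  h) in chosen regions of a toy lattice atlas and group-dependent atrophy
  (mean shift of d voxel-SDs) in others, on grids of 6³–16³ voxels so
  image-space tests run in seconds.  Default series length is 229 to mirror
  the retained-volume count of a TR = 2 s acquisition; tests needing tight
  HE recovery use 512–2048 points and say so.
* `simulate_feature_table` plants a standardized mean difference d in an
  equicorrelated (ρ) block of otherwise independent Gaussian features.

None of these emulate hemodynamics, physiological noise, motion artifacts,
spatial autocorrelation, or registration error.  Passing tests therefore
establish the *statistical machinery* — estimator recovery, selection
correctness, leak-free validation, fusion behaviour — not clinical
performance on real MRI, which depends on cohort, scanner and preprocessing
quality.

## Study conditions used by the validation suite

The leakage and power checks run the full nested pipeline on 40-subject
tables (20/20, 16 features, 3 informative at d = 3), with 20 label
permutations for the null; the fusion comparison uses two independently
informative 30-subject tables (10 features, 2 informative at d = 2 each)
over 10 seeds.  These sizes keep each check's Monte-Carlo noise well inside
its acceptance band while the whole suite stays desk-scale.  Hurst recovery
uses 100 replicates of N = 1024 per true h ∈ {0.5, 0.6, 0.7, 0.8}.

## Known limitations

* The plain R/S estimator is biased at short N; regional averages inherit a
  smaller version of that bias.  Only the ordering across h and banded
  recovery are guaranteed by tests.
* Plug-in MI on 5 quantile bins underestimates strong dependencies at small
  n and is noisy below ~30 subjects.
* LOOCV accuracy has high variance at n ≈ 40; single-run numbers on small
  cohorts should be read with ±1-subject granularity in mind (2.5 points at
  n = 40).
* Bagging is hard-vote only; soft/weighted fusion and probability
  calibration are out of scope.
* Probabilistic (soft) atlases and surface parcellations are not supported —
  maximum-probability label volumes only.
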