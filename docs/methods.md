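# Methods

This note documents the modelling and numerical choices in `docprog`: what
each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Preprocessing

A single resting-state run is represented as a `BoldRun`: a 4D grid, TR,
brain mask, and a 6-column motion trace (translations in mm, then
rotations in radians) aligned to the current time axis. `kept_volumes`
maps back to the original acquisition indices. Stages, in order:

1. **Initial discard** — the first 5 volumes (scanner equilibration);
   `drop_k` configurable.
2. **Spatial smoothing** — separable Gaussian, FWHM 6 mm per axis
   (σ_vox = FWHM / (voxel size · 2√(2 ln 2))).
3. **Nuisance regression** — per-voxel least squares against the 6 motion
   parameters, their first backward differences, the global mean over the
   brain mask (computed after smoothing), a linear trend and an intercept.
   Collinear columns are dropped via QR before solving, so residuals are
   numerically orthogonal to the retained design (max |dot| ≤ 1e−8 ×
   norms). A rank-deficient design logs a warning rather than failing —
   all-zero motion traces are legitimate in synthetic data.
4. **Motion censoring** — framewise displacement
   FD_t = Σ|Δtranslation| + 50 mm · Σ|Δrotation|, FD_1 = 0. Because FD_t
   measures the t−1 → t transition, both endpoints are contaminated: each
   FD_t > 1.5 mm removes volumes t−1 and t. A `censor_margin` option
   widens the window by whole volumes on each side for stricter readings
   of "preceded or followed"; the default removes exactly the bracketing
   pair. Runs left with fewer than 50 volumes return an `ExclusionSignal`
   (a value, not an exception — exclusion is an expected outcome recorded
   in the QC report).
5. **Band-pass filtering** — 0.01–0.08 Hz, zero-phase Butterworth of
   order 4 (applied forward and backward with `sosfiltfilt`), on the
   concatenated retained series per voxel; censoring gaps are ignored,
   matching a filter applied only to surviving volumes. Even-symmetric
   edge padding keeps edge transients inside the stop-band bound. The
   contract is behavioural, not kernel-specific: a 0.04 Hz sinusoid
   retains ≥ 90 % amplitude (away from the edges), a 0.2 Hz sinusoid ≤
   10 %, and DC is removed. Global-signal regression is applied before
   censoring (the pipeline order as listed); whether it should instead be
   restricted to retained volumes is an open question in the source
   procedure — the chosen order is deterministic and documented.

## Imaging features

22 spherical ROIs (configurable centers, radius 6 mm by default — the
radius is not specified in the source protocol) across six networks. The
ROI order is canonical and fixes the 231-long pairwise connectivity vector
(upper triangle, i < j, row-major). Correlations of ±1 are clipped at
|r| = 1 − 1e−7 before the Fisher atanh so degenerate synthetic inputs stay
finite.

Network templates are one-sample t maps across healthy controls of the
Fisher-z seed maps of each network's averaged ROI series; voxels with zero
across-control variance get a capped t of ±100 (the template is used only
through spatial correlation, which is insensitive to the cap). Resemblance
feature i is the Pearson correlation, across in-mask voxels, between ROI
i's z-map and its network's template; it is invariant to positive affine
rescaling of either map.

The full model vector is [22 resemblance, 231 FC, age, duration,
dummy_stroke, dummy_anoxia], trauma being the etiology reference level.

## Selection

* **Stage 1** — keep imaging features with two-sided Pearson p < 0.05
  against the follow-up CRS-R, uncorrected (a permissive screen ahead of
  the subset search; both feature families are treated identically).
  Constant features get r = 0, p = 1.
* **Stage 2 (CARS-PLSR)** — N = 50 Monte-Carlo runs, 80 % row sampling,
  5-fold cross-validation, latent variables capped at min(10, n−2). Per
  run i: fit PLS on the sampled rows and retained variables; keep the top
  ⌈p·a·e^(−k i)⌉ by |coefficient| with a = (p/2)^(1/(N−1)) and
  k = ln(p/2)/(N−1) (retention p at run 1, 2 at run N); then draw p
  candidates with replacement with probability ∝ normalized |coefficient|
  and retain the unique set; record the cross-validated RMSE of a refit.
  The subset minimizing RMSECV wins. Run counts, sampling fraction and CV
  scheme are conventions (the source states none); all are exposed in
  `ModelConfig`. Per-run sub-seeds derive from the master seed, so the
  whole procedure is a pure function of (X, y, hyperparameters, seed).

## Regression, importance, cutoff

The PLS1 fit uses three latent variables by default (`n_latent="cv"`
selects by cross-validated RMSE, ties toward fewer components). Predictors
are z-scored with training constants; the response stays on the CRS-R
scale, so the intercept and cutoff are interpretable scores. At full rank
the PLS solution coincides with least squares — tested against a
normal-equations oracle.

sMC F-values: with centered fitted values ŷ = Xb, each centered predictor
x_j is projected onto ŷ; F_j = SSR_j / (SSE_j / (n−2)) with df (1, n−2).
Predictors orthogonal to the prediction direction get F = 0; exact
collinearity gives F = ∞ (flagged, serialized as null).

ROC cutoff: candidate thresholds are the midpoints between consecutive
unique scores plus ±∞, which makes an exhaustive search exact; the winner
maximizes sensitivity + specificity (ties → higher specificity, then the
lower threshold). The source describes "the maximal sum of true positive
and false negative rates", which is internally inconsistent (that sum is
1 everywhere); Youden's criterion is the standard reading and the default,
and the criterion is configurable. A predicted score exactly at the cutoff
classifies as recovery. AUC is the tie-corrected Mann–Whitney statistic
(equal to the trapezoid over the full step curve).

## Validation

* **Optimism bootstrap** — per replicate: resample rows with replacement,
  re-run the *entire* pipeline (filter + CARS + PLS) on the resample,
  score on both the resample and the original table; optimism is the mean
  difference of the two R² values, subtracted from the apparent R².
  Selection must sit inside the loop: freezing it outside collapses the
  measured optimism on null data, which is the classic leakage bug this
  construction guards against. Degenerate replicates (constant response)
  are skipped and reported via `b_effective`.
* **OOB classification** — for each subject, B bootstrap models trained on
  resamples of the remaining n−1 rows vote; ties go to non-recovery (the
  conservative clinical call); degenerate resamples abstain.
* **Permutation test** — permute the response, re-run the full pipeline
  per permutation, p = (1 + #{permuted ≥ observed}) / (1 + B).
* **Bland–Altman** — mean difference and ±1.96 SD limits of predicted −
  observed, with a one-sample t test (p reported as 1 with a note when the
  differences have zero variance).
* **Domain comparison** — clinical-only, imaging-only and combined models
  fitted per bootstrap resample; accuracies on each test table feed a
  one-way repeated-measures ANOVA, pairwise paired t-tests, and Ψ. Ψ is
  implemented as sign(mean difference) × RMS of per-replicate standardized
  differences (pooled SD); the RMS form is named but not defined in the
  source, and the sign factor keeps negative effects representable.

Library defaults use B = 1000 for the bootstrap procedures; examples and
the acceptance script use B = 100–200 and cohorts of n ≤ 63, sizes at
which every reported behaviour is already stable.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
scanner physics:

* a cohort of 63 patients + 30 controls by default; ages uniform on
  18–71 y, durations log-uniform on 1–36 months, etiology
  trauma/stroke/anoxia at 17/21/25 proportions — ranges matching the
  published cohort bands, with uniform/categorical draws where the source
  gives only ranges;
* a latent **recovery capacity** c ∈ [0, 1] per patient (controls fixed at
  1): resemblance features rise with c, and the default-mode × executive
  connectivity carries an anti-correlation −0.3·c that vanishes as
  capacity is lost;
* the outcome CRS-R(T1) = clip(round(3 + features·w + ε), 3, 23) with a
  sparse ground-truth w (positive weights on three resemblance features,
  a negative weight on the DMN–ECN connectivity, negative age and anoxia
  effects) and ε ~ N(0, 2²). The defaults land the outcome near the
  published cohort profile (mean ≈ 9, SD ≈ 4, ~20 % recovery at the
  GOS ≥ 3 threshold of CRS-R ≥ 14). GOS is a deterministic band of
  CRS-R(T1) — 2 / 3 / 4 — so the recovery label is consistent with the
  stored score by construction;
* ROI time series are multivariate normal with unit variances,
  within-network correlation 0.4, DMN×ECN blocks at −0.3·c, other
  between-network entries 0 (values chosen to land pairwise r in the
  plausible resting-state range; a non-positive-definite configuration
  raises a generation error naming the coupling);
* 4D volumes paint the ROI series into non-overlapping spheres plus white
  noise inside an ellipsoidal brain mask (round-trip exact at zero noise);
  motion traces combine a low-amplitude random-walk drift with
  Bernoulli-rate persistent step displacements, so FD exceeds the spike
  magnitude exactly at spiked volumes.

What passing tests on this generator **do** show: the pipeline recovers
planted sparse effects, respects its own contracts, and its validation
machinery is calibrated under the null. What they do **not** show:
performance on real DOC cohorts — no spatial autocorrelation, physiological
noise, lesioned anatomy, registration error or site effects are simulated,
and the published patient-data results (R² = 0.65 apparent / 0.28
corrected, AUC = 0.96, cutoff 13.9) are context, not reproduction targets.

## Degenerate inputs and tie-breaks

Constant response → zero PLS coefficients and a constant prediction.
Constant predictors are standardized with SD 1 (they contribute nothing).
Zero-variance Bland–Altman differences → p = 1 with a note. OOB vote ties
→ non-recovery. CV fold splits are deterministic (no shuffling), and every
Monte-Carlo loop draws sub-seeds below 2³¹ from its master generator, so
all results are bit-reproducible under a seed.

## Pipeline configuration

`docprog <stage> --config run.yaml` reads a single YAML file; top-level
keys mirror `RunConfig` fields (`output_dir`, `seed`, cohort sizes, volume
geometry), with nested `preprocess:` (`drop_k`, `fwhm_mm`,
`fd_threshold_mm`, `min_volumes`, band edges, `censor_margin`) and
`model:` (`filter_alpha`, `use_cars`, `cars_runs`, `n_latent`, `domain`)
sections. CLI flags `--output-dir` and `--seed` override config keys.
Unknown keys are rejected. Each stage writes a manifest (config snapshot,
seed, input checksums, package version) sufficient to re-run it.

## Known limitations

* ROI coordinates are a required configuration input; the shipped
  `example_roiset()` is a literature-style illustration, not a validated
  clinical set.
* Slice-timing correction, realignment estimation and template-space
  normalization are out of scope (synthetic data shares one grid); real
  data must be aligned upstream.
* The band-pass ignores censoring gaps; gap-aware spectral estimation is
  not implemented.
* OOB and the domain comparison re-fit the full pipeline per vote; at
  B = 1000 and n = 63 this is hours of compute — use the smaller example
  sizes unless a cluster run is intended.
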