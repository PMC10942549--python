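# Methods

This package implements a dynamic functional network connectivity (dFNC)
state analysis for multivariate biological timeseries — in its motivating use
case, post-ICA fMRI component timecourses — together with a synthetic cohort
generator that plants the ground truth the analysis is supposed to recover.

## The analysis model

**Inputs.** Each subject contributes a T × C matrix of component activity
(C = 53 components grouped into seven functional networks by default: SCN,
ADN, SMN, VSN, CCN, DMN, CBN) sampled every TR seconds, plus a phenotype
table with longitudinal symptom scores (PCL-5, range 0–80, at WK2, WK8, M3,
M6, M12) and demographic/socioeconomic covariates.

**Cleaning** (`prep`). Four per-column stages in order: (1) least-squares
polynomial detrending, degrees 0..3; (2) optional nuisance regression on a
T × R regressor matrix (e.g. six realignment parameters plus temporal
derivatives), implemented as projection onto the orthogonal complement after
standardization, dropping collinear regressors with a warning; (3) despiking:
samples with |x − median| > k·1.4826·MAD (k = 4) are replaced by linear
interpolation of the nearest clean neighbours, with clamped ends, and
zero-MAD or all-outlier columns left untouched; (4) zero-phase 5th-order
Butterworth low-pass at 0.15 Hz (forward–backward `sosfiltfilt`, chosen so the
filter adds no phase distortion to the windowed correlations). Each stage is
a projection or pointwise repair; detrending and nuisance regression are
individually idempotent, but their composition is not (the nuisance
projection can reintroduce low-order polynomial components), so no
whole-pipeline idempotence is claimed.

**Windowed connectivity** (`windows`). The taper is a unit rectangle of
20 samples (47.2 s at the default TR = 2.36 s — the TR is inferred from that
product and configurable) convolved with a Gaussian of σ = 3 samples
truncated at ±3σ, trimmed below 1e−8 of its maximum and normalized to unit
mass; its effective length is L = 38. At each window position (step 1) the
Pearson correlation of every component pair is computed with the taper as
observation weights (weighted means and variances), giving W = T − L + 1
windows of P = C(C−1)/2 values (1378 for C = 53), vectorized in row-major
upper-triangle order. Columns whose windowed standard deviation is at
rounding level relative to the signal RMS get correlation 0 with a warning.
Static connectivity is the plain Pearson correlation over the full recording;
it is only approximately the mean of the windowed values and the two are
never equated.

**States** (`states`). All subjects' window vectors are pooled and clustered
by k-means (Euclidean distance, k-means++ initialization, best of 10
restarts, up to 1000 iterations). A `distance="correlation"` option clusters
row-standardized vectors instead (squared Euclidean distance on z-scored
vectors is an affine function of one minus the Pearson correlation).
Internally the solver runs in single precision with Elkan bounds — on
well-separated data this reproduces the double-precision partition at about
half the cost — and final centroids are recomputed in double precision.
States are relabeled by descending pooled occupancy, so "state 1" is always
the most visited. Each subject's state vector assigns every window to its
nearest centroid, and the occupancy rate (OCR) of state k is the fraction of
that subject's own windows labeled k (the K occupancies sum to 1).

**Choosing K.** The elbow criterion sweeps k = 2..9 and computes
ratio(k) = (mean Euclidean distance of windows to their own centroid) /
(mean pairwise centroid distance). K is the point of maximum curvature —
the largest second-order difference of the ratio curve. Because a second
difference is undefined at the left endpoint, the curve is anchored by a
virtual k = 1 point whose numerator is the mean distance to the global
centroid and whose denominator is the k = 2 between-centroid distance; this
lets a true two-cluster structure select k = 2. Note the ratio curve is
*not* monotone in k: past the true cluster count the mean pairwise centroid
distance shrinks faster than the within-cluster distance, so the ratio
typically rises again — which is precisely what gives the elbow its
curvature. The k-means objective (inertia), by contrast, is monotone
non-increasing in k at best-of-restarts, and that is the monotonicity the
tests assert.

**Cross-group state matching.** Two state models with equal K are matched by
maximizing the summed Pearson correlation between centroid pairs (Hungarian
assignment), returning the permutation and the K matched correlations. This
is used to compare states estimated separately in posttraumatic-stress (PTS:
WK2 PCL-5 strictly above 31) and non-PTS subjects; the boundary score 31 is
assigned to non-PTS.

**Association** (`association`). For each state's OCR and each of the five
timepoints, symptoms are regressed on [intercept, OCR, covariates] by OLS
with listwise deletion — 15 models per stratum, run for the whole cohort and
separately for females and males (sex is dropped as a covariate in the
stratified runs). Covariates: age, sex, years of education, income (ordered
category coded by level index), marital status, employment, scanning site
(all dummy-coded with first level dropped and collinear columns removed with
a warning), and ADI percentile. The OCR t-statistic is converted to a
partial correlation r = sign(t)·√(t²/(t²+df)) with df the residual degrees of
freedom, and 95% confidence intervals use t-quantiles (a normal-quantile CI
is indistinguishable at the reported precision). Benjamini–Hochberg FDR is
applied within each stratum's family of tests. Models with fewer complete
cases than 10, or with fewer than 3 residual degrees of freedom, are skipped
and logged. Two independent correlations are compared by Fisher's r-to-z:
Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)), one-tailed by default (the
tail convention under which a |Z| of 1.734 corresponds to p = 0.041).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the physics of the scanner: no volumes, motion, or ICA — the simulation
starts at component timecourses.

- **States** are C × C correlation matrices built from network blocks: a
  within-block strength per network and a between-block strength per network
  pair. Matrices that are not positive definite are repaired by convex
  shrinkage toward the identity (unit diagonal preserved). White observation
  noise of sd σ attenuates off-diagonal correlations by 1/(1+σ²).
- **Dynamics** are a K-state Markov chain (default: three states, mean dwell
  50 TRs, stationary initial distribution). Each subject's transition matrix
  is a row-wise Dirichlet perturbation of the group matrix (concentration
  200), which is what gives occupancy rates between-subject variance for the
  association layer to detect.
- **Emissions** are zero-mean Gaussian draws with the active state's
  covariance — the minimal model under which windowed Pearson correlation
  estimates the planted values.
- **Phenotypes** mirror the study cohort's marginals: age ~ N(35, 13)
  truncated to 18–65, 66% female, education ~ N(15.2, 2.3), six ordered
  income levels with the observed frequencies, five scanning sites, ADI
  percentile uniform on 0–100. Symptom scores at each timepoint are a
  timepoint intercept (30.1, 26.6, 23.5, 21.0, 20.3 — the observed means)
  plus modest fixed covariate effects, plus effectᵀ·OCR for the planted
  states, plus N(0, 16²) noise, rounded and clipped to 0–80. Missingness is
  completely at random per timepoint at rates (0, 0.116, 0.178, 0.244, 0.36)
  reproducing the observed per-timepoint sample sizes (275 → 243 → 226 → 208
  → 176 of 275); the real dropout mechanism is unknown, so nothing stronger
  than MCAR is claimed.
- **Effect sizing.** `effect_for_target_r` converts a target partial
  correlation into a regression coefficient given the OCR standard deviation
  (estimated by Monte Carlo from the Markov design via `simulated_ocr_sd`)
  and the outcome noise sd.

What passing tests on these cohorts shows: the estimator chain (taper →
weighted correlation → pooled k-means → OCR → adjusted GLM → FDR) recovers
planted states, occupancies, cluster counts and regression effects at
realistic noise levels, with correct null behaviour (uniform p-values, FDR
conservative). What it does not show: robustness to head motion, scanner
site effects on the timecourses themselves, non-Gaussian or nonstationary
emissions, informative dropout, or ICA estimation error.

## Validation scales and numerical choices

- State-recovery and elbow experiments use 30 subjects × T = 400 at C = 53
  with strongly separated archetypes (`presets.three_state_archetypes`):
  elbow replicates use mean dwell 50 TRs; the label/occupancy-recovery check
  uses dwell 100, since windows spanning a state switch are intrinsically
  ambiguous (the truth label of a window is defined as the taper-weighted
  modal state within it). Statistical-layer replicate experiments (power,
  bias, null calibration) run on planted occupancies directly, which is
  exact and orders of magnitude faster than regenerating imaging data.
- Mean dwell times in validation designs always exceed the taper length
  (38 samples); below that, most windows are state mixtures and a cluster of
  transition windows can displace a true state.
- k-means never yields empty clusters (scikit-learn relocates); ties in
  nearest-centroid assignment go to the lowest state index; non-convergence
  at max_iter returns a flagged result with a warning.
- Degenerate inputs: zero-variance windows/columns produce correlation 0
  with a warning; constant predictors and out-of-range p-values raise;
  all-outlier columns in despiking are left unchanged with a warning.
- Reproducibility: every stochastic stage derives its seed from one root
  seed via `numpy.random.SeedSequence`; equal seeds give byte-identical CSV
  outputs (floats written at %.17g). The run manifest records SHA-256
  checksums of every stage's inputs and outputs, and a stage is re-run only
  when a checksum no longer matches.

## Known limitations

- The elbow's virtual k = 1 anchor is one of several defensible
  operationalizations of "maximum curvature"; alternatives (distance-to-chord,
  gap statistic) may pick different k on weakly structured data.
- OCR ground truth is defined over timepoints while estimates are over
  windows; the two differ slightly at recording edges.
- The GLM layer is cross-sectional per timepoint (as in the motivating
  analysis); no longitudinal or mixed-effects modeling.
- Window counts depend on the taper's effective length (T − 38 + 1 at the
  defaults), which matches neither of the two window counts sometimes quoted
  for T = 210 recordings (201 or 210) — conventions differ in whether the
  Gaussian tails extend the window; the count is never hard-coded.
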