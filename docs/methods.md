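# Methods

## Problem setting

The package classifies subjects into two groups (patients vs controls)
from connectome-derived feature vectors and interrogates which
connections drive the separation. Two feature families are supported:

* **Functional connectivity (FC).** Region-averaged BOLD time series are
  linearly detrended, confound-regressed (ordinary least squares
  residuals, intercept included), band-pass filtered with a zero-phase
  second-order Butterworth filter (default 0.01–0.08 Hz, the conventional
  resting-state band), correlated pairwise (Pearson), Fisher r-to-z
  transformed (|r| clamped at 1 − 1e−7 so duplicated-region pathologies
  stay finite; the clamp never triggers on valid data), and vectorized as
  the strict upper triangle with canonical names `A--B`. Each subject's
  vector is then standardized to mean 0 / variance 1 (population
  convention) across that subject's own features.
* **Effective connectivity (EC).** Per-network directed coupling matrices
  (DCM A-matrix convention, units 1/s, self-connections on the diagonal)
  are vectorized row-major per network, names `network:src->dst`. No
  rescaling: coupling parameters already share a physical scale.
  Coupling estimation (spectral-DCM inversion) is out of scope; matrices
  are inputs. Only the model-space bookkeeping of the post-hoc reduced
  search is implemented: all 2^p on/off combinations of p free parameters,
  capped at 2^8 once p ≥ 16 by the greedy pre-selection rule.

## Feature selection

A two-stage univariate reduction, re-fit inside every cross-validation
fold:

1. A two-sided one-sample t-test per feature against zero at level α
   (default 0.05). Degenerate conventions, chosen from the limit behavior
   of the statistic: a feature constant at a nonzero value is retained, a
   feature constant at zero is removed. Note this screen tests the pooled
   mean against zero; a genuinely discriminative feature whose two group
   means straddle zero can be screened out. That is a property of the
   procedure, not of this implementation.
2. The pair-concordance weight w = |n_c − n_d|/(m·n) over all m·n
   patient–control pairs, with ties counted as neither concordant nor
   discordant (the standard Kendall convention, shrinking w toward 0).
   The printed sign orientation of the concordance definition is
   immaterial because of the absolute value. Absent ties w equals the
   absolute rank-biserial correlation |2U/(mn) − 1|, so the ranking is
   invariant under strictly increasing transforms of a feature. Ties in w
   break by ascending feature index (deterministic).

The retained count k is found by a coarse grid over
[fine_step, n_surviving] with step `coarse_step`, then a fine grid with
step `fine_step` inside the coarse winner ± coarse_step (clipped). Ties
resolve to the smallest k. Defaults: 200/10 for FC tables, 3/3 for the
57-feature coupling table. The search optimizes the same LOOCV accuracy
later reported; a fully nested variant can be obtained by passing a
custom `evaluate` functional to `search_k`.

## Classification and inference

Leave-one-out cross-validation with the entire selection stage wrapped in
each fold. Subjects are processed in sorted-id order, so results are
invariant to input row order. If a fold's screen removes every feature,
the fold falls back to ranking all features; if k exceeds a fold's
survivor count it is clipped with a logged warning. Classifiers (via
scikit-learn): linear SVM (C=1), RBF SVM (C=1, width 1/(k·feature
variance)), 5-nearest-neighbors (Euclidean), L2 logistic regression
(C=1). Decision scores for the pooled ROC: signed margin for SVMs,
positive-class probability for logistic, positive-neighbor fraction for
k-NN. AUC is the trapezoidal area; tied scores step the curve diagonally.
Undefined metrics (zero denominators) are reported as NaN, never 0.

The permutation test permutes labels across the whole cohort once per
replicate — equivalent to permuting every training fold consistently —
and re-runs screening, ranking, selection and LOOCV from scratch;
p = (#{acc′ > acc} + 1)/(m + 1) with a strict inequality, so the
attainable floor is 1/(m+1). k is held fixed across replicates
(re-searching k per replicate would be conservative in the other
direction but multiplies runtime by the grid size). Default m = 10,000;
the test suite uses m ∈ {19, 99} to stay within desk-scale runtimes.

## Reporting

Consensus features are the intersection of all folds' selected sets,
ordered by mean within-fold rank. Importance for the linear SVM is the
mean |primal coefficient| over the folds that selected the feature
(magnitude, since reported rankings are sign-free). Region weights assign
half of each connection's weight to each endpoint; a self-connection
contributes its full weight to its single region. Total region weight
therefore equals total connection weight exactly — a conservation law the
tests check to 1e−12, and the published connection-to-region arithmetic
reproduces exactly for every region whose incident connections are fully
listed. Per-edge group differences use Welch's two-sample t-test,
uncorrected by default (matching common reporting practice); group means
are always reported so sign flips between groups are visible.

## Synthetic-data generator

The generator emulates a balanced clinical cohort — 24 patients + 24
controls, 235 retained volumes at TR = 2 s — with planted, known group
differences:

* **Feature tables**: per-feature population mean μ_i ~ N(0, 1) shared by
  both groups (so a realistic fraction of features has a nonzero typical
  value, as Fisher-z connectivity does, and the one-sample screen retains
  a realistic subset), subject noise N(0, σ) with σ = 1; planted features
  shift the patient mean by d·σ.
* **Time series**: i.i.d. multivariate-normal rows from a group
  correlation template (uniform off-diagonal baseline r = 0.1); planted
  pairs differ between group templates by Δr split symmetrically.
  Templates are repaired to the nearest valid correlation matrix
  (statsmodels' Higham-style projection), which can shrink the planted
  Δr; the realized template difference is returned in the ground-truth
  record. No temporal autocorrelation or hemodynamic forward model is
  simulated — sufficient to exercise the correlation/Fisher-z machinery,
  but passing tests say nothing about autocorrelation-induced biases in
  real BOLD data.
* **Coupling sets**: per-edge population mean N(0, σ) with σ = 0.2
  off-diagonal; self-connections N(−0.5, σ) truncated negative (DCM
  stability convention, via the truncated-normal quantile so determinism
  is preserved); planted directed edges shift additively by d·σ. Planted
  shifts on self-connections pass through the truncation, so their
  realized effect can be slightly smaller than requested when the shifted
  mean approaches zero.

One global seed fans out through `numpy.random.SeedSequence`: child 0
drives population-level draws, child 1+i drives subject i (patients
first). Outputs are bit-identical across runs with equal seeds and do not
depend on cohort-order bookkeeping.

## Numerical and design choices

* Order of FC preprocessing is detrend → confound regression → band-pass,
  with confounds regressed unfiltered; all three steps are linear, and the
  zero-phase filter preserves phase. Both the order and the band are
  configurable.
* Normalization is per subject (leakage-free by construction); a
  per-feature-across-subjects alternative would have to be fit on
  training folds only and is deliberately not the default.
* The leakage-safe wrapped screen is the default everywhere; an
  `unwrapped_screen` flag reproduces the screen-on-all-participants
  variant for comparison studies.
* Correlation-template repair accepts tolerance 1e−8 on the smallest
  eigenvalue; requested |r| is clipped to 0.99 before repair so unit
  correlations are never emitted.
* Desk-scale problem sizes in the test suite: permutation calibration
  uses 8+8 cohorts, 20 features, k=3, m=99 over 100 replicates; recovery
  and chance-level checks use 24+24 cohorts with 100 features over 10–20
  seeds. These sizes were chosen so the full suite and the acceptance
  script each complete in minutes on one CPU while keeping Monte-Carlo
  bands tight enough to be informative.

## Known limitations

* The generator's i.i.d.-in-time model understates the variance of sample
  correlations relative to autocorrelated BOLD; effective sample sizes in
  real data are smaller than the nominal 235.
* The one-sample screen is mean-targeted: group differences centered on
  zero are invisible to the full pipeline (demonstrated in the tests).
* The k search optimizes the reported LOOCV accuracy, which is
  optimistically biased for the selected k; fully nested model selection
  is supported through the `evaluate` hook but not the default.
* Coupling matrices are consumed, not estimated; nothing here validates a
  DCM inversion.
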