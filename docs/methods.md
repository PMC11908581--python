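# Methods

## Signal model

A chromatogram is modelled as Y(t) = B(t) + P(t) + N(t):

- **B(t)**, baseline: linear, `intercept + slope * t`. Real baselines drift
  slowly; over the 25-minute default window a linear model captures the
  drift the measurements must be invariant to without inviting overfitting.
- **P(t)**, peaks: exponentially modified Gaussians (EMG) — a Gaussian of
  height h, centre μ and width σ convolved with a normalised one-sided
  exponential of time constant τ. The EMG is the standard model for real
  chromatographic peaks, which are typically tailing; τ = 0 degenerates to
  the pure Gaussian, and the convolution preserves the total area
  h·σ·√(2π) for every τ. The profile is evaluated with the scaled
  complementary error function (`erfcx`) where the naive exponent would
  overflow (z ≥ 0) and with the plain exp·erfc product in the far tail
  (z < 0), so the evaluation is stable over the full parameter range.
- **N(t)**, noise: i.i.d. Gaussian with standard deviation `noise_sd` in
  detector units, seeded per run.

Default grid: 0–25 min sampled at 0.005 min. At this sampling the
half-height crossings of a σ ≥ 0.04 min peak are resolved by linear
interpolation to well below 0.5% relative error.

## Quality measurements

All metrics operate on the baseline-subtracted signal. The baseline is a
least-squares line through the idle points (everything outside an exclusion
window of ±2 min around the rough peak position); the noise sd is the
sample standard deviation of the idle residuals. Consequently SNR, skewness
and area are invariant under affine baseline drift.

- **Apex**: maximum of the subtracted signal in the search window, refined
  by a 3-point parabolic fit through the grid maximum and its neighbours.
  The refinement gives sub-grid retention-time precision, which is needed
  because replicate retention jitter (down to 0.005 min) is of the order of
  the sampling interval. Peaks not rising above `snr_floor` (default 3)
  times the noise sd are reported as absent.
- **Half-widths** WL(x), WR(x): first crossings of x·(apex height) walking
  left/right from the apex, linearly interpolated between the bracketing
  grid points; a grid point exactly on the threshold is taken as the
  crossing (inner tie-break). Taking the *first* crossing makes the widths
  robust to distant secondary peaks.
- **Skewness** Qs,0(x) = WR(x)/WL(x), default x = 0.5; exposed as a
  parameter since the definition holds for any x ∈ (0, 1).
- **SNR** = apex height / noise sd. A noiseless signal yields +inf, which
  is flagged during table assembly rather than propagated.
- **Area**: trapezoidal integral of max(signal − baseline, 0) between the
  integration bounds — the first points, walking out from the apex, where
  the subtracted signal falls below max(0.5·noise sd, 1e−12·height),
  capped at the search window.
- **ΔtR = tR,1 − tR,2** (signed; negative means the compound eluted later
  in the second run). Quality metrics (SNR, skewness, area, tR) come from
  run 1 by default; run 2 contributes only tR,2. Rows with any failed
  metric are flagged and dropped before modelling, mirroring how real
  datasets report only non-null instances.

## Feature table and preprocessing

Clustering features: ΔtR, SNR, skewness, peak area, sequence length,
sulfur count. The prediction target tR is never a clustering feature.
Preprocessing is a per-feature z-score followed by a per-feature min–max
rescaling to [0, 1], both fitted on the same rows ("standardize, then
normalize"). The alternative reading — L2 row normalisation — was rejected
because it entangles features. For the unsupervised stage the transform is
fitted on all rows; the per-cluster supervised stage refits its own scaler
on the training split only, to avoid leakage. Zero-variance features raise
a named error rather than producing NaNs downstream.

## Clustering

PCA is applied to the preprocessed matrix; the component count is either
fixed (default 2, which keeps the cluster maps plottable and captures
≈85–90% of the variance under the default generator) or chosen as the
smallest count whose cumulative variance ratio reaches a threshold. k-means
(k-means++ seeding, 10 restarts, 300 iterations, tol 1e−4) runs on the
scores; k is pre-identified by the elbow method — the k maximising the
second forward difference of the WCSS curve over k = 1…8, ties to the
smaller k, with an explicit no-elbow error for curves without positive
curvature — and validated by the mean silhouette (points in singleton
clusters score 0). Cluster indices are re-ordered by descending cluster-mean
SNR so that cluster 0 is always the strongest-signal cluster regardless of
the k-means seed.

## Per-cluster validation

Each cluster of at least 10 rows is split 80/20 within itself (smaller
clusters are reported as skipped), and an exhaustive grid search (5-fold CV
by default, minimising RMSE) fits a regressor per cluster:

- support vector regression (RBF kernel; C over 8 values spanning 1–1000,
  gamma {0.1, 0.01, 0.001}, epsilon {1e−4 … 2e−4}), preceded by per-cluster
  feature standardization fitted inside each fold (kernel methods are
  scale-sensitive);
- gradient-boosted trees (max_depth {5, 10, 15, 20, 50}, learning rate
  {0.001, 0.01, 0.1, 0.2}, 100–1000 trees, max_leaf_nodes {2, 5, 10}),
  used unscaled (trees are scale-free).

SVR is the default family. On data whose retention target is a smooth
function of composition, the boosted-tree fit noise on ~100-row clusters
(≈0.05–0.1 min test RMSE scatter) is of the same order as the per-cluster
quality differences and can mask the ordering; the SVR tracks the target
down to the measurement-noise floor. Both families are selectable per run.

Clusters are ranked by ascending test RMSE (ties: descending test R², then
cluster index) with high/medium/low verdicts by rank. R² on a constant test
target is reported as missing rather than as a misleading number. The run
report's feedback section names the features with the largest standardized
mean difference between the best- and worst-ranked clusters.

## Synthetic cohorts: what they emulate

`simulate_cohort` draws compounds in three latent quality tiers and renders
two replicate runs per compound. The tier profiles encode the qualitative
signature of good versus poor chromatography — poor runs are noisier, more
tailing, with larger replicate retention jitter and weaker signals:

| tier   | noise sd | τ (min)    | jitter sd | height   | P(sulfur)/pos | length |
|--------|----------|------------|-----------|----------|---------------|--------|
| high   | 0.5–1    | 0–0.02     | 0.005     | 250–450  | 0.1           | 12–20  |
| medium | 2–5      | 0.05–0.15  | 0.02      | 60–150   | 0.4           | 5–12   |
| low    | 8–15     | 0.2–0.5    | 0.1       | 150–400  | 0.9           | 12–20  |

Peak width σ is uniform on 0.04–0.09 min for all tiers. Sequence
composition is tier-structured on purpose: in real ASO chromatography data
the quality strata differ strongly in length and degree of
phosphorothioation (heavily sulfur-modified sequences produce poorer
signals), so an independent draw of length and sulfur count would be the
unrealistic choice. Sulfur counts are binomial over the length − 1 backbone
positions with the tier's modification probability.

The underlying retention model is linear in composition,
tR = 2.0 + 0.6·length + 0.22·sulfur + ε with ε ~ N(0, 0.005 min), i.e.
retention is essentially composition-determined, at the scale of the best
replicate reproducibility. This makes the *measured* tR of a compound the
target, so each tier's prediction error is dominated by how well its
signals can be measured: the high tier by the tiny apex-localization error,
the medium tier by noise-driven apex error on weak signals, the low tier by
severe tailing (whose apex shift depends on the unobserved σ and τ) plus
low-SNR geometry. That is precisely the mechanism the framework is supposed
to detect, and it produces the expected behaviour under the defaults:
elbow k = 3, mean silhouette ≈ 0.6–0.7, ARI ≥ 0.9 against the generating
tiers, and the high tier ranked first by test RMSE, in 20/20 seeded
replications of a 300-compound cohort.

These free parameters (heights, widths, composition structure, retention
scatter) were fixed by forward simulation so that the generator realises
those qualitative findings, and then frozen; the noise, tailing and jitter
ranges above are the package's stated study conditions.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: co-eluting or overlapping peaks, non-Gaussian
or correlated detector noise, nonlinear baseline drift, gradient-program
effects, missing-not-at-random failures, and any mass-spectral dimension.
Real quality strata are also not cleanly separable tiers; the ARI ≥ 0.9
recovery holds for the simulated geometry, not for arbitrary instruments.

## Determinism and numerical choices

One master seed drives everything: cohorts spawn per-compound seed
sequences (compound i's replicate pair depends only on the master seed and
i), each run derives a 31-bit render seed, and the k-means and split seeds
come from the fit seed. Reruns of a fixed configuration write byte-identical
CSV/JSON artifacts (floats are formatted with 12 significant digits, JSON
keys sorted, no timestamps in data artifacts).

Degenerate inputs are handled explicitly: apex at a window edge or a signal
that never falls below the crossing threshold raises an unresolved-peak
error; a zero left half-width raises a degenerate-peak error; too few idle
points raise baseline/noise errors; k = 1 silhouettes, over-rank PCA
requests and elbow-less WCSS curves raise named errors.

## Known limitations

- Single-peak measurement per window; no deconvolution of overlaps.
- Linear baseline only (by design); heavily curved baselines bias SNR.
- The elbow criterion (max second difference) assumes the WCSS curve is
  sampled on an evenly spaced k grid and has a genuine curvature maximum;
  data with nested or unbalanced cluster scales can elbow at the first
  dominant split.
- Grid-searched SVR/GB on clusters of a few dozen rows carries meaningful
  selection noise; rankings from clusters near the minimum size should be
  read with that in mind.
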