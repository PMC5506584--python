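# Methods

This note documents the models, procedures and numerical choices behind
`restcombine`: what each stage assumes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the design was genuinely
open.

## Synthetic cohorts

The generator produces balanced two-group cohorts of 4-D voxel time series
on an X×Y×Z grid (X even) with an integer atlas of R mirror-paired 3×3×3
ROI blocks (labels 1..R/2 in the x < X/2 half, their x-mirrored twins
R/2+1..R on the other side; label 0 is non-brain). The signal model is
deliberately minimal: each ROI r has one latent band-limited (0.01–0.1 Hz)
unit-variance signal u_r, built as
`u_r = sqrt(h) * pair_latent + sqrt(1 - h) * own_latent` with a baseline
homotopic share h = 0.3, and every voxel in the ROI is
`loading * u_r + white noise` with loadings drawn from U(0.8, 1.2) and noise
SD 1.0 by default. This is the smallest model in which every one of the
eleven feature types has a distinct, controllable handle:

| effect tag | manipulation in group +1 |
|---|---|
| ALFF | latent amplitude in the target ROI × (1 + e) |
| ReHo | within-ROI voxel noise SD ÷ (1 + e) |
| VMHC | homotopic share h of the target pair + e (clipped to 0.99) |
| TC | both pair members mixed with a shared latent, `(u + e·s)/sqrt(1+e²)` |
| GC | sink latent gains `e · u_source(t-1)`, then re-standardised |
| seed name | target ROI latent mixed with the seed pair's latent |

The TC mixing adds ≈ e²/(1+e²) to the pair correlation (≈ 0.39 at e = 0.8).
Nuisance structure: two shared very-low-frequency confound signals are
mixed into five WM and five CSF ensemble rows (plus noise) and leaked
weakly (amplitude 0.15) into all brain voxels, so nuisance regression has
something real to remove. Motion is six smooth random walks (step SD 0.02)
plus Bernoulli step excursions of magnitude 0.5 (rate 0.03/frame), whose
frame-to-frame Euclidean norm reliably exceeds the 0.35 censoring
threshold.

What the generator does **not** emulate: hemodynamic response shapes,
spatial autocorrelation beyond ROI blocks, scanner noise physics, spatial
smoothing, anatomical geometry. Consequently, passing tests demonstrate
the correctness and calibration of the *pipeline* (no leakage, null
calibration, effect recovery, statistic definitions), not the absolute
accuracy attainable on real cohorts; published whole-cohort accuracies on
hundreds of scanned subjects are outside what a desk-scale synthetic
cohort can or should reproduce.

## Preprocessing

Frames with frame-to-frame motion change (Euclidean norm over 6
parameters) strictly greater than 0.35 are censored; the *later* frame of
each offending pair is dropped (which frame to drop is a convention; the
generator's ground truth uses the same one). Subjects whose censored
fraction strictly exceeds 1/3 are excluded. Both inequalities are strict
because the rules are phrased as "exceeding" the threshold.

Nuisance regression and band-passing are simultaneous: each voxel's
kept-frame series is projected onto the column space of [6 motion traces |
first 3 WM PCs | first 3 CSF PCs | sine/cosine pairs at every DFT frequency
outside 0.01–0.1 Hz | intercept], and the residual is returned. A joint
least-squares projection was chosen over an FFT mask because censoring
makes the sampling irregular, and sequential filtering-then-regression can
reintroduce removed variance; the projection handles both in one step and
is idempotent and linear by construction. PCs are computed on the raw
ensembles (whether to recompute them after filtering is unspecified in the
procedure being modelled; raw is adopted). Two cleaned variants are kept:
ALFF and Granger causality consume nuisance-regressed but *uncensored*
data (their definitions need a regular time grid), everything else the
censored variant.

Note a structural consequence of joint projection: with T = 120 frames at
TR = 2 s the out-of-band basis has ~75 columns, so heavy censoring can
leave fewer kept frames than basis columns. That situation is an error by
contract; it can only occur for subjects already past the 1/3 exclusion
rule, for whom the censored variant is not computed.

## Feature extraction

* **ALFF**: one-sided FFT amplitude (square root of power) averaged over
  in-band bins, DC excluded (DC is the mean, not a fluctuation); divided by
  the mean over brain voxels only.
* **ReHo**: Kendall's W of a voxel and its 26 neighbours,
  `W = 12 S / (m²(T³ − T))` with average-rank ties and rank-sum deviations
  about m(T+1)/2; brain-edge voxels use whatever brain neighbours exist
  rather than being dropped. No tie correction is applied (the data are
  continuous). Normalised to brain mean 1.
* **VMHC**: Fisher z of the correlation with the x-mirrored voxel; voxels
  whose mirror is non-brain stay missing (NaN), not zero.
* **FCS**: mean Fisher-z correlation with all other gray-matter voxels; in
  the synthetic case the gray-matter mask is all atlas-labelled voxels.
* **Seed networks**: the bilateral seed pair is pooled into a single mean
  reference time course (one reference per network); the map is the
  Fisher-z correlation of every brain voxel with it. Seed assignments come
  from a configurable map; the default assigns the five network names to
  homotopic ROI pairs in order, cycling when the atlas has fewer pairs
  than networks.
* **TC**: lower-triangle (i > j, row-major) Fisher-z correlations of ROI
  mean series, named `i~j`.
* **GC**: bivariate (pairwise, not conditional) Granger causality for all
  ordered pairs, named `i->j`. Per pair the VAR order p minimises
  `AIC(p) = ln det(Σ̂) + 2k/T_eff` over p = 1..p_max (default 10), with
  k = 2(2p+1) coefficients and T_eff = T − p; the F-statistic compares the
  restricted regression of y on its own p lags against the unrestricted
  one adding p lags of x, `F = ((RSS_r − RSS_u)/p) / (RSS_u/(T_eff − 2p − 1))`.

Correlations pass through the Fisher transform exactly once, clipped at
|r| = 1 − 1e-7. Degenerate inputs (constant series, empty neighbourhoods)
yield 0 with a warning rather than NaN, so matrices stay assemblable; an
empty ROI is an error.

A note on AIC order selection: like any AIC-based choice it retains a
non-vanishing over-selection probability (~20% even at T = 500 with strong
VAR(2) data), never under-selecting. Tests assert the modal order and the
bounds the simulation actually supports rather than near-certain recovery.

## Selection and the fusion frameworks

Ranking uses |t| (pooled variance) rather than signed t — both directions
of group difference are discriminative. Zero-variance features rank last;
ties break by ascending feature index for determinism. The kept count is
`max(1, ceil(percent · F / 100))`.

The (percent, C, γ) triple is searched *jointly* on one inner stratified
10-fold CV rather than as a triple-nested loop: both schemes use exactly
the same information (inner-training folds only), and the joint search is
orders of magnitude cheaper with 11 × 11 × 14 grid points. Within every
inner fold the t-ranking and the z-scoring statistics are recomputed on
the inner-training part only. Standardisation before the RBF kernel is
essential: the feature types live on very different scales and an
unstandardised mixed kernel degenerates. Ties in inner accuracy resolve
toward the smaller percent, then smaller C, then smaller γ (prefer the
simpler model).

The kernel combination reuses each type's selection-time γ for its Gram
matrix and re-searches only C on the combined precomputed kernel; a global
re-search of all per-type γs would defeat the purpose of the heuristic
weighting. The weights zero out any type with Acc_m ≤ 0.5 (strict), and
the denominator sums only over above-chance types; when exactly one type
beats chance its weight is 1, and when none does the weights fall back to
uniform with a flag. `sign(0)` in the weighted vote resolves to +1 (logged
convention). The canonical feature-type order (ALFF, ReHo, VMHC, FCS, DMN,
ECN, SN, LN, StrN, TC, GC) fixes concatenation, kernel-list and weight
ordering everywhere.

## Cross-validation and significance

The outer loop is a balanced stratified 10-fold CV (equal class counts per
fold, deterministic given a seed). Selection runs once per outer fold on
the training subjects and is shared by all frameworks being compared —
they would receive identical selection outputs regardless. A guard raises
if any held-out index reaches a selection call. Metrics are computed on
confusion counts pooled over the outer folds (pooling matches whole-cohort
percentage reporting); the positive class is group +1.

Selection significance pools kept-feature masks over folds (and, in
shell-pipeline use, over the three frameworks' separate runs, 30 folds in
total). The empirical null redraws, per repeat, a uniformly random subset
of the same size each fold actually kept, pools per-feature null counts
across repeats and features within a type (the type-wide pooling matches
reporting a single per-type fold threshold), and thresholds observed
counts at the smallest c with null exceedance probability < α. In the
degenerate case where every fold keeps everything, the null equals the
observed counts and nothing is flagged. One caveat is inherent to the
procedure: masks taken from overlapping CV folds are *not* exchangeable
(folds share most subjects, so rankings correlate), and the independent
null does not model that correlation; calibration statements therefore
refer to exchangeable masks of fold-matched sizes.

## Problem sizes and numerical choices

Library defaults are the full grids (11 percents × 11 C × 14 γ, inner
k = 10, p_max = 10). The test suite and the acceptance script run the
stochastic end-to-end checks at desk scale as the package's own choice of
problem size: 8×8×8 grids with 8 ROIs, T = 120 at TR = 2 s, 20 subjects
per group, reduced grids (3 percents × 3 C × 3 γ, inner k = 5) and feature
subsets ({ALFF, VMHC, TC} for null calibration, {ALFF, TC} for planted
effects), with 10–20 seeds per check. Planted effect sizes are 0.8 (TC)
and 1.5 (ALFF). PSD checks on combined kernels tolerate eigenvalues down
to −1e-9 (floating-point noise on an exactly PSD matrix); oracle
agreements are asserted at 1e-10 (concordance, absolute) and 1e-8
(Granger F, relative).

## Known limitations

* Bivariate GC only; no conditional/multivariate variant, no fALFF, no
  windowed connectivity, no ICA-derived networks.
* The joint projection's in-band residual dimension shrinks as censoring
  grows; with very short series the band may contain too few DFT bins for
  a meaningful ALFF (an error by contract).
* The weighting heuristic is a one-step rule; no iterative multi-kernel
  weight optimisation is provided, by design.
* Synthetic cohorts are stationary and spatially blocky; they validate the
  machinery, not clinical effect sizes.
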