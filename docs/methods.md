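# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `capdyn`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The synthetic cohort model

The generator emulates a two-group rodent resting-state study: by default
18 wild-type (WT) and 19 heterozygous (HET) subjects, 1200 frames each at
TR 0.5 s, on a 20×20×6 voxel grid parcellated into 14 bilateral ROIs (28
labels) plus one cerebellum-like region excluded from analysis. Each ROI
in the default grid exceeds 30 voxels, the conventional floor for ROI
reporting.

**Hidden states.** Each subject's brain occupies one of `K_true` states
per frame (default 4), organised as anti-correlated pattern pairs. Pair 0
is the DMLN/LCN pair: cingulate, retrosplenial, orbital, visual,
hippocampal and rhinal regions co-activate while somatosensory, motor,
frontal-association and caudate-putamen regions co-deactivate, and vice
versa. Further pairs get seeded random ROI coefficients. Patterns carry a
mild within-ROI linear gradient (15%) so they are not piecewise constant,
and each pattern's complement is its exact negation (spatial correlation
−1). Patterns are spatially mean-centred: activation is modelled as a
deviation pattern, so the whole-brain mean (global signal) carries no
state information — without this, global signal regression on a noise-free
cohort removes an entire dimension of the low-rank state subspace (see
Limitations).

**Dynamics.** The state process is a first-order Markov chain whose
self-transition probability is `1 − 1/dwell_mean`, giving geometric dwell
times with a controllable mean — the simplest process with independently
tunable duration and occurrence, the two temporal metrics under test. The
default mean dwell is 5 frames (2.5 s), a plausible value for transient
resting-state events; it is a plausibility choice, not a calibrated one.
Off-diagonal transition mass is distributed proportionally to per-state
occurrence biases, so stationary occupancy is tunable separately.

**Group effects.** Two mechanisms mirror the temporal and spatial
alterations the pipeline is meant to detect: a fractional reduction of the
HET dwell mean on the DMLN/LCN pair (default study configuration: 30%),
and a multiplicative reduction of HET activation amplitude in DMLN ROIs
(default 30%). Setting both to zero yields the null cohort used for
calibration.

**Noise.** I.i.d. Gaussian voxel noise, default SD 1.0 against
unit-magnitude patterns (frame-level pattern-to-noise correlation ≈ 0.7);
an AR(1) temporal option exists and defaults to off. No haemodynamic
response convolution, no motion, no scanner artefacts — deliberate
non-goals with consequences discussed below.

## Preprocessing

Stage order: in-plane Gaussian smoothing (FWHM 2 voxels, σ = FWHM/2.3548,
within 2-D slices only) → 5+5-frame pre-trim (scanner transients) →
optional motion regression → zero-phase Butterworth band-pass 0.01–0.2 Hz
(order 5, forward–backward; order unstated in common practice varies, 5 is
a standard neuroimaging default and configurable) → quadratic detrend →
5+5-frame post-trim (filter edges) → global signal regression → per-voxel
z-scoring. A 1200-frame input therefore leaves 1180 frames; a config
switch collapses the two trims into one for the alternative reading of the
frame-exclusion rule. Every stage is individually toggleable and logged.

Degenerate cases: constant voxels are flagged and zeroed by z-scoring
rather than erroring; a numerically constant global signal (the noise-free
synthetic limit) degrades GSR to plain temporal mean removal, since the
regressor would be collinear with the intercept.

## Clustering and model selection

Correlation distance is computed by row-centring and unit-norm scaling, so
Pearson r is a dot product; any zero-variance operand (frame, centroid, or
the global centroid of perfectly balanced data) is assigned the neutral
distance 1 with a warning. k-means++ seeding uses D² sampling under the
correlation distance; Lloyd iterations use mean-of-members centroids,
converge when labels stop changing (cap 100 iterations), and re-seed an
empty cluster at the frame farthest from its current centroid. Five
replicates by default, best objective kept; all randomness flows from one
integer seed. Cluster ids are re-ordered by descending occupancy, so CAP 1
is always the most frequent pattern — the field has no canonical ordering
and this one is reproducible.

The fractional gain at K is defined on the EV scale, `EV(K) − EV(K−1)`,
matching the "< 0.5% gain in variance" selection rule; a relative-gain
variant is config-selectable. The selected K is the smallest one whose
every later gain is below threshold; if the curve never saturates the
largest K is returned with an explicit warning flag (K_max satisfying the
rule only vacuously does not count as saturation).

## Statistics

One-sample t-maps run across a CAP's occurrences within the concatenated
(group) image-series — not across subjects — matching how voxel-level CAP
activation is defined; subjects enter the temporal-metric comparisons
instead. Bonferroni counts only analysis-mask voxels. The two-sample map
uses the pooled-variance (Student) t — its df `n1+n2−2` gives 35 for 18 vs
19 — restricted to voxels significant in either group, with BH-FDR at
q = 0.05 over that domain. Runs touching the ends of a label sequence
count as full runs (no censoring). Subjects missing a CAP are dropped
pairwise from that CAP's group comparison, with a logged count; both the
two-sample t and the Wilcoxon rank-sum test are available because the two
are used interchangeably for this comparison in practice, with the t-test
as default.

Seven-category ROI decomposition: a voxel is "activated" if significantly
activated in either group, else "deactivated" if significantly deactivated
in either, else non-significant; within the first two classes the FDR mask
and the sign of the WT−HET t split "WT-higher", "no difference" and
"HET-higher" by activation *magnitude* (for deactivated voxels a more
negative WT mean is the higher magnitude, so the sign flips).

## Classification

The regularization parameter is the L2 penalty weight λ = 10
(scikit-learn `C = 1/λ`); the two-class problem is handled as the binomial
case of the multinomial model. Missing-CAP features are imputed as the
subject's worst rank (zeros before within-subject z-scoring): absence of a
state is information, not missingness at random. Chance trials reuse the
trial's split and features and permute class identities across all
subjects; only labels change, features are never recomputed. ANOVA and
Tukey–Kramer comparisons across conditions report degrees of freedom
computed from their actual inputs.

## Problem sizes

The defaults emulate the full study (37 subjects × 1180 frames × ~2000
analysis voxels). Tests and the acceptance script use scaled cohorts —
typically a 10×10×3 or 12×12×4 grid, 80–200 frames, 8–37 subjects — chosen
so every property (planted-K recovery, ARI, calibration, power) is
measured at well-powered but desk-scale sizes. The acceptance script's
chance-level experiment uses the full 18+19 subject count with 150 frames
per subject and 4 ROIs per hemisphere.

## Limitations, and what passing tests do not show

- **No haemodynamic convolution.** Synthetic state dynamics are square
  waves; with a 5-frame mean dwell at TR 0.5 s much of their power lies
  above the 0.2 Hz band edge. The 0.01–0.2 Hz filter therefore blurs
  transition frames, and quadratic detrending slightly blends states near
  switches. Real BOLD is haemodynamically smoothed before sampling, so
  this is a mismatch between generator and filter, not an estimator
  defect. Consequently the recovery properties (selected K = K_true,
  frame-label ARI > 0.9 at noise SD ≤ 1) are evaluated with the temporal
  filter disabled, while the filter itself is verified against its
  analytic magnitude response. Passing these tests shows the clustering
  chain recovers planted structure; it does not show that 0.01–0.2 Hz
  filtering is harmless for arbitrarily fast state dynamics.
- **GSR on low-rank signals.** A noise-free K-state pair cohort spans only
  K/2 temporal dimensions; regressing out any state-correlated global
  component removes one of them entirely. Mean-centred patterns make the
  global signal state-free in the exact limit, but in-plane smoothing's
  boundary handling reintroduces a small state-dependent global component.
  The noise-free rank-preservation test therefore runs without GSR; at
  realistic noise GSR is exercised and recovery is unaffected
  (ARI ≈ 0.95).
- **Stationarity check.** Consecutive Markov frames are autocorrelated, so
  the χ² goodness-of-fit against the stationary law is applied to a
  thinned chain (every 25th frame); an unthinned χ² would over-reject for
  purely temporal-dependence reasons.
- Occurrence-ordered CAP ids are stable within a run but not comparable
  across different datasets; cross-run CAP matching should use
  `cap_spatial_correlation`.
- The classifier's measured accuracies on synthetic cohorts depend
  directly on the planted effect sizes and say nothing about effect sizes
  in real cohorts; the transferable results are the calibrations (chance
  at 50%, FWER/FDR control, leakage invariance) and the monotonicity of
  accuracy in effect size.
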