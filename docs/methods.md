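# Methods

## Model and conventions

All angles are degrees; meridians live on the half-open interval [0, 180)
with 180 ≡ 0. A cylinder is a net astigmatism `M @ α` with `M ≥ 0`; a
zero-magnitude cylinder carries meridian 0 by convention and is retained in
all aggregates (eyes with any degree of astigmatism are analysable).

Polar values about a reference meridian Φ are
`KP(Φ) = M cos 2(α − Φ)` and `KP(Φ+45) = M sin 2(α − Φ)`. Their Euclidean
norm equals `M` for every Φ, and cylinders add linearly in these
coordinates. The reference is *variable*: for each eye and each corneal
modality, Φ is that measurement's own steep meridian, which makes the
corneal contribution `(M_CA, 0)` exactly and gives the two DA components
direct clinical readings (magnitude error along the steep meridian;
torsional error oblique to it).

Reconversion to a net cylinder uses the half-angle of the two-argument
arctangent, `angle = atan2(KP(Φ+45), KP(Φ)) / 2` normalized to [0, 180).
This equals the printed single-argument half-angle form
`arctan((M − KP(Φ)) / KP(Φ+45))` wherever the latter is defined, and is
total: the pair `(−x, 0)` maps to 90° relative to Φ, and `(0, 0)` maps to
`0 @ 0` without raising. Equality of the two forms in all four sign
quadrants is asserted in the tests.

Plus-cylinder refraction `(S, C, axis)` maps to a net cylinder as
`M = C, α = axis`: for myopic astigmatism written in plus-cylinder form the
cylinder axis coincides with the steep (more myopic) meridian. This is a
recording convention, not a property of the eye, so
`cohort.refraction_to_net` exposes `axis_is_steep=False` for data recorded
the other way. Refractions are assumed referred to the corneal plane (zero
vertex distance); no vertex conversion is performed.

Orientation classes partition [0, 180): with-the-rule 61–120, against-the-
rule 0–30 and 151–179 (180 ≡ 0), oblique 31–60 and 121–150. Subgrouping
uses the automated keratometer's steep meridian.

The IOL-position filter keeps an eye iff total decentration ≤ 0.4 mm and
the larger absolute per-axis tilt ≤ 5°; the thresholds are strict
exclusions, so the boundary values pass. Whether the tilt limit should
apply per axis or to a resultant tilt vector is genuinely open; the
per-axis maximum is used because the clinical tilt ranges are reported per
axis.

## Statistics

Inference is nonparametric throughout, matching how such cohorts are
analysed when the KS screen rejects normality (the screen itself —
one-sample KS against a normal with the sample moments — is advisory only).

* One- and two-sample Wilcoxon signed-rank tests: zero differences are
  dropped (Wilcoxon's original treatment), tied absolute differences get
  mid-ranks, the exact null distribution is used for effective n ≤ 25
  without ties, and the tie-corrected normal approximation otherwise. A
  vacuous test (all values at the null) returns p = 1 with a warning.
* Friedman test across the corneal modalities, with mid-ranks and tie
  correction; a fully tied matrix returns statistic 0, p = 1; incomplete
  matrices are rejected rather than imputed. Two variants of the
  across-measurements test exist: polar components across the 14
  modalities, and cylinder magnitudes with RA optionally included as a
  15th treatment (`magnitude_matrix(include_ra=True)`); which variant a
  given published table used is ambiguous, so both are exposed.
* Summaries report the centroid (net cylinder of the mean components) and
  the mean of per-eye DA magnitudes separately; the former never exceeds
  the latter (triangle inequality — asserted on every summary). "Within
  0.50 D" is inclusive. Groups below 5 eyes get summaries but suppressed
  p-values.

The regression `KP(Φ)_RA = a + b·KP(Φ)_CA + c·cos 2α` is fitted by OLS
(statsmodels), each modality with its *own* steep meridian in the cos 2α
regressor. Fitting is in-sample, mirroring the retrospective optimization
design; consequently the post-optimization mean ΔKP(Φ) is exactly zero (OLS
residual property) and the ΔKP(Φ) spread can only shrink. ΔKP(Φ+45) is
carried over bitwise — the model corrects magnitude, not direction.
Published coefficient sets ship as presets (`optimize.PRESETS`), including
the automated-keratometry equation `(−0.04, 0.92, 0.39)` whose canonical
predictions (1.0 D @ 90 → 0.49 D; 1.0 D @ 0 → 1.27 D) anchor the tests.
Two variants of that equation exist for keratometric indices 1.3375 and
1.3315; the 1.3375 form is primary (it is the one consistent with the full
fitted table) and `radius_to_power` accepts either index.

Confidence ellipses around DA centroids are Hotelling T² regions for the
*mean* (F-scaled, axes shrinking like 1/√n), matching what accuracy plots
draw around centroids; a χ²-scaled tolerance ellipse for the data cloud is
available behind `kind="tolerance"`. Whether the classical double-angle
plotting tool uses F- or χ²-scaling is not documented; the F choice is a
package decision, validated by a coverage simulation (95% ± 2% over 500
replicates).

## Synthetic cohort generator

The generator emulates the study population's documented structure, not the
raw data (which are unavailable):

* Orientation mixture 0.474 / 0.358 / 0.168 (WTR / ATR / oblique), drawn
  multinomially. True corneal astigmatism is bivariate Gaussian in
  double-angle space around group centroids of 0.65 D magnitude (steep at
  90°, 0°, 45°) with isotropic spread 0.35 D. The centroid magnitude was
  set so that the implied mean refractive cylinder lands near the clinical
  0.70 D; a larger centroid (0.9 D) reproduces the cluster separation
  better but overshoots the refractive-magnitude marginal, and the
  0.70 D anchor was judged the more consequential target since the
  magnitude scale propagates into every accuracy statistic.
* Refractive astigmatism is generated *through the regression structure*:
  `KP(Φ)_RA = a + b·M_true + c·cos 2Φ + N(0, 0.32)` about the true steep
  corneal meridian, plus an independent `N(0, 0.30)` oblique component.
  Defaults `(a, b, c) = (−0.04, 0.92, 0.39)`; the noise SDs match the
  residual spread reported for optimized keratometry. One canonical
  coefficient set generates RA (a single eye cannot satisfy fourteen
  different generative regressions); per-modality differences arise from
  the modality biases below.
* Each modality observes the true cylinder plus a per-modality (radial,
  tangential) bias applied in the eye's own steep-meridian frame — radial
  biases default to the clinically observed over-reading of each
  Scheimpflug modality relative to automated keratometry — plus isotropic
  double-angle noise (SD 0.10 D). A frame-relative rather than
  fixed-direction bias is used because the clinical over-reading appears in
  WTR and ATR eyes alike, which no fixed double-angle offset can produce.
* IOL decentration and tilt are uniform within the clinically observed
  ranges (|h| ≤ 0.38 mm, |v| ≤ 0.35 mm, total resampled to ≤ 0.39 mm,
  |tilt| ≤ 3.0°/3.5°), so every generated eye passes the position filter.
* Everything is reproducible from the seed; identical config + seed gives a
  bitwise-identical cohort CSV.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: the right-skew of clinical cylinder magnitudes (a
double-angle Gaussian cannot match mean 0.70 D and SD 0.61 D
simultaneously; the synthetic magnitude SD is ~0.31 D, which also lowers
the synthetic r² to ~0.6 versus ~0.76 clinically), modality-specific
*residual* correlations with RA (all modalities share one RA noise draw, so
the synthetic ranking of modalities is driven by the bias defaults rather
than by genuinely different measurement physics), covariance between the
two DA components (assumed independent), and fellow-eye correlation (one
eye per synthetic patient).

## Numerical choices

* Equality tolerance for dioptres and degrees: 1e-9 absolute; the
  round-trip identity net→polar→net holds to 1e-9 over a dense
  magnitude × meridian × reference grid.
* Degenerate inputs: zero-magnitude cylinders reconvert to `0 @ 0`;
  degenerate covariance raises with a jitter hint; constant samples give
  KS p = 0 with a warning; all-null Wilcoxon gives p = 1 with a warning.
* Before/after optimization differences below 1e-10 D are treated as ties
  (p = 1): data exactly satisfying the fitted model would otherwise have
  float round-off of order 1e-16 "detected" by the signed-rank test.
* Rank-deficient regression designs (e.g. all steep meridians equal, making
  cos 2α constant) raise naming the collinear column.
* SVG plot output is byte-stable for fixed input (fixed hash salt, no
  timestamp metadata).

## Problem sizes

The test suite runs the full pipeline at the study size (n = 95), parameter
recovery at n = 500 over 200 replicates, distributional checks at
n = 2000–5000, and coverage/calibration simulations at 100–500 replicates —
sizes at which the Monte-Carlo error is comfortably below each assertion's
tolerance while the whole suite stays fast.

## Known limitations

Scheimpflug image acquisition, ray-tracing computation of total corneal
power, and image-based measurement of IOL tilt/decentration are out of
scope: the package starts from tabulated measurements. Toric IOL power
selection (vergence calculations at the corneal plane) is likewise out of
scope — the optimization regressions quantify measurement agreement, they
are not an IOL calculator. Cross-validated (out-of-sample) optimization is
not the default anywhere; `compare_before_after` accepts an external model
for that purpose.
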