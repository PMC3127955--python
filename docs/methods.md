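# Methods

## Model

A Gaussian luminance profile (GLP) is an elliptical 2-D Gaussian blob with
major/minor radii interpreted as the standard deviations of the luminance
density and orientation θ (counterclockwise from horizontal, period 180°).
Finite visual resolution is modelled as convolution of the retinal image
with an elliptical Gaussian kernel of covariance
Σ_kernel = [[a_h², r], [r, a_v²]] (degrees² of visual angle; r = 0 gives an
axis-aligned kernel). Gaussian∗Gaussian convolution adds covariances, so
the perceived profile has Σ_perceived = Σ_glp + Σ_kernel and the perceived
orientation is the principal axis ½·atan2(2·s_xy, s_xx − s_yy) of
Σ_perceived. The orientation bias is the principal-axis rotation, wrapped
to (−90°, 90°] with the tie at ±90° mapped to +90°; positive is
counterclockwise. For a vertically elongated kernel (a_v > a_h) the bias is
strictly positive on θ ∈ (0°, 90°), strictly negative on (90°, 180°),
antisymmetric under reflection across the vertical axis, and zero at
θ = 90°.

Two boundary phenomena of the model are worth stating because they are not
obvious:

- At θ = 0° the smoothed axis never rotates obliquely: the bias is 0 when
  the stimulus elongation (major² − minor²) exceeds the kernel anisotropy
  (a_v² − a_h²), and exactly +90° (an axis swap — the blob is perceived
  vertical) when the kernel overturns it. The group-mean kernel estimate
  (0.84, 2.08) has anisotropy 3.62 deg², larger than any stimulus
  elongation in the design (max 3.61 deg²), so under that kernel every
  near-horizontal GLP is perceived near-vertical, with biases up to ≈80°
  at θ = 7.5°.
- Predictions for oblique orientations therefore live on the full
  (−90°, 90°] circle, and all data reduction must be circular (below).

## Experimental design and synthetic observers

The design is fixed by the study it models: reference orientations
7.5° + 15°·k (k = 0..11; cardinals excluded), aspect ratios 0.5 / 0.65 /
0.8 with the major radius at 1.9°, two viewing-frame conditions (circular,
square — a control label with no effect in the generator), 3 blocks of
180 trials per frame condition, 5 repetitions per condition per block:
1080 trials per participant, 15 per condition per session, 30 per condition
after frame pooling. Trial order is a seeded uniform shuffle within block.

A synthetic observer responds with

    response = quantize₁°( θ + bias(θ, ratio; kernel) + ε ),  ε ~ N(0, sd²)

wrapped to [0, 180); the probe moves in 1° steps, hence the quantization.
The response-noise scale follows the roundness of the *smoothed* profile:
with q = λ_min/λ_max of Σ_perceived,

    sd = sigma_base · q^κ · (1 − q)^(−1/2),

strictly increasing in q (a rounder perceived blob is harder to orient).
Defaults: sigma_base = 4° (a realistic adjustment-noise scale for smooth,
low-contrast stimuli), κ = 0.5, lapse rate 0 (so the noiseless limit is
exact). With a vertically elongated kernel this law reproduces the observed
dispersion anisotropy — most response spread for horizontal-adjacent GLPs,
least for vertical-adjacent — for any a_v > a_h. Note that the *thickness*
ordering of the spread is not globally monotone: away from horizontal
(θ ≳ 37.5°) thicker GLPs are noisier, but near horizontal the strong
vertical kernel smooths the thinnest GLP closest to circular and the
ordering inverts. (1 − q) is floored at 10⁻² to cap the sd for
near-circular smoothed profiles.

What the generator does *not* emulate: systematic deviations of human
biases from the smoothing model (the generator is model-faithful), learning
or fatigue across blocks, reaction times, and any frame effect. A direct
consequence: synthetic explained variances are ≈0.99, far above the 3–27%
range typical of human observers on these stimuli — with model-faithful
generation and sigma_base = 4° the systematic signal (biases spanning tens
of degrees) dwarfs the noise. Matching the human explained-variance range
would require near-uniform response noise, which destroys parameter
recovery through wrap-around; passing recovery tests on this generator
therefore demonstrates correctness of the estimation machinery, not
realism of human noise levels.

## Aggregation (circular statistics)

Mirror-pair aggregation folds orientations θ and 180° − θ onto the
canonical member θ ∈ (0°, 90°), flipping the bias sign of the mirrored
member; 12 orientations collapse to 6 and the angular model's parameter
count from 36 to 18. Because biases near horizontal reach ≈80°, response
noise straddles the ±90° wrap of bias space; arithmetic means and variances
are badly distorted there (variance inflated up to 3× in simulation), so
all condition means and variances are circular on the 180° orientation
circle (`scipy.stats.circmean` / `circstd`), and all residuals are wrapped
to (−90°, 90°]. Per-condition variances are pooled within pairs and floored
at (0.5°)² — one probe step — to keep inverse-variance weights finite.

## Fitting: the flat ridge and the two-stage estimator

The predicted bias depends on an axis-aligned kernel only through
δ = a_v² − a_h²: adding a_h²·I to a covariance shifts both eigenvalues
equally and cannot rotate the principal axis. The weighted least-squares
objective on mean biases,

    WRSS_cells = Σ_cells (mean_bias − predicted_bias)² / variance,

is therefore *exactly flat* along the ridge of kernels sharing δ (and r),
and mean biases alone cannot identify the absolute kernel scale. The fit
proceeds in two stages:

1. **Bias stage.** Bounded multistart L-BFGS-B minimization of WRSS_cells
   per kernel group (the objective separates across groups): 8 starts on a
   log-spaced (a_h, a_v) grid over [0.1°, 6°], r started at 0 and
   parametrized internally as ρ = r/(a_h·a_v) ∈ [−0.99, 0.99] so the
   positive-definiteness constraint is a box bound. Heterogeneous models
   additionally start each group at the nested homogeneous solution, which
   guarantees WRSS monotonicity along the nesting chain. This stage pins
   δ (and r) for every group.
2. **Scale stage.** The within-condition response dispersion *does* depend
   on the absolute scale, through the smoothed roundness
   q(a_h) = (μ_min + a_h²)/(μ_max + a_h²) (μ_i the eigenvalues of
   Σ_glp + diag(0, δ)). With the dispersion law above, log sd is linear in
   log sigma_base, so the per-participant noise scale is profiled out and a
   1-D bounded search over a_h (with a_v = √(a_h² + δ)) minimizes the
   misfit of the q-profile to the observed log-SDs, with κ held at its
   structural default 0.5 and the probe-quantization variance (1/12 deg²)
   subtracted from the cell variances. The ridge is exactly flat, so this
   stage changes the reported radii but provably not the WRSS, F tests, or
   explained variances. Groups with fewer than three cells keep the
   stage-1 point.

On synthetic data at the full design, almost all of the sampling variation
in the recovered radii sits in the scale direction of the ridge: δ is
pinned by ~1000 trials of mean-bias information while the scale rests on
18 dispersion cells, so per-participant horizontal-radius estimates
scatter substantially around the truth while recovered vertical radii are
much tighter (their scale sensitivity is damped by a factor a_h/a_v). The
test suite verifies that the median recovered radii across 20 synthetic
participants, and the group means across 6, land within 15% of the
generating (0.84, 2.08); the horizontal radius can fall outside that band
at unlucky seeds purely through this sampling variation. The noiseless
limit recovers δ to <10⁻³ but leaves the scale undefined (all cell
variances collapse to the floor), which is the identifiability structure,
not an optimizer failure.

## F tests and explained variance

Nested models are compared with
F = ((WRSS₁ − WRSS₂)/(p₂ − p₁)) / (WRSS₂/(n − p₂)), p-values from the
F(p₂−p₁, n−p₂) distribution, with n the trial-level observation count
(1080 per participant), giving the canonical df shapes (2, 1078),
(4, 1074), (15, 1062) for isotropic→homogeneous, homogeneous→radial, and
oriented-homogeneous→angular. For that convention to be statistically
coherent, `FitResult.wrss` is the *trial-level* WRSS,

    Σ_cells [ n_cell·(mean − pred)² + within_cell_SS ] / variance_cell,

whose within-cell term is parameter-free (the cell-level objective above is
what the optimizer minimizes; it is exposed as `cell_wrss`). Under the
null (homogeneous truth, radial alternative) the test is calibrated
at-or-below the nominal level: it runs conservative because the counted
parameters (2 per kernel) include the scale that mean biases do not
identify, so the effective numerator dof is smaller than p₂ − p₁. The
statistic is invariant under uniform rescaling of the weights. If the
full model's WRSS exceeds the restricted model's (an optimizer-failure
signal that the extra homogeneous start makes unreachable in practice),
F is clipped at 0 with a warning. The three model comparisons are
reported with raw p-values; no multiplicity correction.

Explained variance is plain R² of trial-level biases against the model's
per-condition predictions (computed on the canonical pair member and
sign-flipped for mirrored orientations), with wrapped residuals; the
systematic ceiling substitutes each condition's circular mean as its own
prediction and upper-bounds any model's R². A weighted variant
(inverse-variance weights) is available as a diagnostic.

## Numeric oracle

The analytic route (covariance addition + principal axis) is validated
against an independent numeric route: render the GLP at 32 px/deg over an
8-major-radius extent, convolve with the sampled kernel (truncated at 4 SD
of the largest principal radius, renormalized to unit mass, full linear
convolution so mass is conserved), and extract the orientation from second
central image moments. Across all 36 design conditions with the group-mean
kernel the two routes agree far inside the 0.5° tolerance the test suite
enforces. Rendering-moment error is truncation-dominated — Gaussian
midpoint sums are spectrally accurate, so enlarging the extent (not the
resolution) drives the error to zero.

## Numerical choices and degenerate inputs

- Orientation of an isotropic covariance is undefined: `orientation_of`
  returns NaN as a sentinel; `predict_bias` maps it to bias 0 with a
  `DegenerateOrientationWarning` (avoids silent ±90° jumps).
- Bias wrapping uses the half-open interval (−90°, 90°] with ties at ±90°
  mapped to +90°.
- Fits whose best predictions are all ≈0 (any isotropic kernel fits
  equally well) are flagged non-identifiable.
- Kernel sampling raises an undersampling error when the smallest
  principal SD falls below one pixel.
- Optimizer convergence is judged across multistarts: ties at the minimum
  (ubiquitous on the flat ridge) count as convergence if any tied start
  terminated cleanly or at least two starts agree.
- All randomness flows through named integer seeds (numpy Generator);
  identical seeds reproduce trial tables bit-for-bit.

## Known limitations

- The dispersion law (and hence the scale stage) is this package's own
  model; the original study reports only the qualitative dispersion
  pattern. On real data the recovered absolute radii inherit whatever
  misfit that law has; the covariance difference δ does not.
- Heterogeneous models estimate per-subset constants, not a true
  spatially-varying convolution.
- The angular model's 3-cell groups give very weak scale information;
  their reported radii are ridge positions constrained mainly by the
  positive-definiteness bound, and only their (δ, r) components are
  data-determined.
- Monitor calibration, probe-line rendering, and the enclosing frame are
  out of scope; the frame is a design label only.
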