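# Methods

## Model and estimators

The object Y is summarized by its area function f(x) = Area(S(x)), the
cross-sectional area at axial position x; the volume is Q = ∫ f.  Section
planes at random positions x_0 < … < x_N (strictly bracketing the
support, so f(x_0) = f(x_N) = 0) yield areas A_k and slice thicknesses
h_k = x_k − x_{k−1}.  Three volume estimators are implemented:

* Cavalieri, `T · Σ A_k`, with T the *intended* spacing;
* generalized Cavalieri, `mean(h) · Σ A_k`;
* trapezoidal, `Σ_{k=1}^{N−1} (h_k + h_{k+1})/2 · A_k`, the
  trapezoid-rule integral of the observed profile.

All are unbiased under stationary (translation-invariant) sampling.  Note
that the generalized variant carries an extra O(T²) variance component —
the random mean-gap factor multiplies the whole area sum — which makes it
asymptotically inferior even to the fixed-T Cavalieri estimator under
perturbed sampling; the Monte Carlo studies therefore use the fixed-T
form as the classical comparator.

Smoothness is tracked by m ∈ {0, 1}: m = 0 when f jumps (a flat face of Y
parallel to the sections — avoid this orientation when possible), m = 1
when f is continuous with jumps in f′ (typical smooth convex objects).
The trapezoidal variance decomposes into an extension term c·T^(2m+2), an
oscillating Zitterbewegung Z(T) and a faster-decaying remainder.  All
variance estimators target the extension term.  For 1-oriented objects
|Z| never exceeds the extension term, so `conservative_bound` (×2) gives
a guaranteed-coverage estimate; no such bound exists for m = 0.

## Variance estimators

With the empirical covariogram g^(k) = Σ_j A_j A_{j+k} (lags 0–2 suffice)
and the gap moments γ^_{i,j} (model-free), (T^, θ^₂, θ^₄) (perturbed
model) or ν^_j = mean(h^j) (cumulative model), the m = 0 estimators are
`(3g^(0) − 4g^(1) + g^(2))/12` times γ^₁,₃, `T^² + 3θ^₂`, or `ν^₃/T^`
respectively.  The m = 1 estimators share one kernel,

    [g^(0)(γ₂₂−γ₁₂) − g^(1)γ₂₂ + g^(2)γ₁₂] / [γ₁₂γ₂₃ − γ₂₂γ₁₃]
      × (12γ₁₅ − 10γ₁₃²)/120 ,

into which the model-specific moment substitutions are inserted
(perturbed: γ₁₂ = (T²+θ₂)/T, γ₂₂ = (4T²+θ₂)/T, γ₁₃ = T²+3θ₂,
γ₂₃ = 8T²+6θ₂, γ₁₅ = T⁴+10T²θ₂+5θ₄; cumulative: γ₁₂ = ν₂/T,
γ₂₂ = 2(ν₂+T²)/T, γ₁₃ = ν₃/T, γ₂₃ = (2ν₃+6Tν₂)/T, γ₁₅ = ν₅/T).  With
constant gaps every estimator reduces *exactly* to the classical
equidistant forms (T²/12 and T²/240 times the covariogram combination);
these reductions are locked by tests at 1e−12 relative tolerance and
disambiguate the formula groupings.

Model-specific estimators are refused for series with dropouts (the model
no longer holds after thinning); the model-free estimator remains valid
there because it uses only the observed merged gaps.  A `refined` flag
substitutes the bias-corrected moments θ^₂N²/(N²−1) and
T^² − θ^₂/(N²−1); the correction is stated only for the perturbed m = 0
form and the flag is ignored for m = 1.  Negative estimates (possible on
very short or pathological series, since the covariogram combination is
not a positive form) are clamped to zero with a `NegativeVarianceWarning`.

## Sampling models and calibration

* equidistant: grid U + jT, U ~ uniform[0, T);
* perturbed: grid plus iid N(0, σ²) displacements truncated to
  (−T/2, T/2) — the largest symmetric bound that keeps planes ordered;
* cumulative: renewal sequence with iid N(T, s²) gaps truncated to
  (T/2, 3T/2), started one uniform offset below the window (the exact
  equilibrium renewal start is not implemented; for variance-order
  studies the uniform start is adequate).

Dispersion is parametrized by the average relative thickness deviation
E|h − T|/T (default 0.05, the realistic magnitude for guided slab
cutting).  σ resp. s are calibrated by root-finding on exact
truncated-normal functionals (E|D − D′| via 2∫F(1−F); E|Z| in closed
form); both scale linearly in T and are cached at T = 1.  The attainable
deviation is capped by the truncation (1/3 resp. 1/4 in the uniform
limit); a `CalibrationError` is raised beyond.

Sampled positions always over-cover the window by two mean gaps per side,
and series construction trims to exactly one non-hitting plane on each
side.  If no plane hits the object (possible at very coarse spacing) the
replicate contributes a legitimate zero estimate.  Dropouts are simulated
as independent thinning of *all* sampled planes before trimming; thinning
only interior planes while pinning the bracketing planes would shorten
the boundary weights systematically and bias the estimator low (measured
≈ −1.5% at T = 0.25, p = 0.2).  `apply_dropout`, which operates on an
already-trimmed series and retains its end planes, is provided for
thinning user tables but is not used by the study engine for that reason.

Reproducibility: each study derives one child seed per grid point from a
root seed via `numpy.random.SeedSequence`; replicates consume one shared
stream per grid point.

## Synthetic data

`synthesize_lobe_profile` emulates a point-counted primate parietal-lobe
slab table: 13 slabs (12–15 supported) of nominal 2.5 mm cut with 5%
perturbed positions, a smooth unimodal area profile
amp · t(1−t)(1+0.35t) strictly inside the cut range, and Poisson point
counts with grid constant 2.29 mm²/point.  The amplitude is calibrated so
the expected total count is ≈ 645 per specimen.  The bump's nonzero end
slopes make the spline profile genuinely weakly (1,1)-smooth; shapes with
vanishing end slopes are effectively smoother and would show steeper
variance decrease than a 1-oriented object.  Poisson noise stands in for
the binomial-like variability of a uniformly superimposed counting grid.
What the generator does *not* emulate: slab compression, cut-position
measurement error, within-section area-estimation error beyond point
counting, or any real lobe geometry — so green tests demonstrate the
estimator and variance theory on realistic *profiles*, not agreement with
any particular specimen.

`typical_lobe_area_function` averages the spline profiles of 18 synthetic
specimens on a common grid (after mapping each support onto a common
frame) and re-interpolates.  Averaging suppresses the knot-scale
curvature noise of individual interpolants; a single noisy spline carries
an ∫f″²-driven positive bias in the m = 1 variance estimators that decays
only ∝ T and dominates through the whole practical spacing range, whereas
the averaged profile shows the expected vanishing bias.  Variance-
estimator behaviour is therefore studied on the averaged object (m = 1)
and its truncation (m = 0).

## Monte Carlo studies

`run_variance_study` draws independent section series per grid value of
T, computes the requested estimators (vectorized when no dropouts or
per-replicate variance estimates are needed), and reports empirical means
and variances, the least-squares decrease rate α^ (slope of log var vs
log T), the extension constant c fitted through the origin against
T^(2m+2), and per-estimator bias and coefficient-of-error curves
(CE = SD of the variance estimator / extension term).

Default grids are geometric with 7 points spanning mean section counts
6.25–100 (ratio 2^(2/3)); α^ fits over ≥ 6 points average out the
Zitterbewegung.  Two study-size choices depart from that default, both
because the quantities are asymptotic orders: the cumulative-model
Cavalieri study on the 0-oriented object uses counts 50–800 (its order-T
coefficient scales with the small gap-law variance θ₂ ≈ 0.004 T², so the
order-T regime emerges only at finer spacing), and variance-estimator
bias studies on the lobe start at counts ≥ 12.5 (sections must resolve
the 2.5 mm knot scale before the T^(2m+2) regime applies).  Studies use
5000 replicates per grid point; unbiasedness checks use 10^4; the
doubling-point scan uses 10^5 per grid point.

### Doubling point

The equidistant Cavalieri variance of the ball carries a Zitterbewegung
as large as the extension term (the bound is sharp there), dipping nearly
to zero once per unit of n = 2/T.  A pointwise perturbed/equidistant
variance ratio therefore oscillates between ≈1.5 and ≈16 within each
period, and "the count where the ratio first reaches 2" would be an
artefact of the scan grid.  The implemented doubling point compares
smooth trends instead: on a dense grid spanning whole periods
(n = 3…9 step 1/8), the equidistant trend c_eq·T⁴ is the period average
of var_eq/T⁴ (var_eq computed by exact quadrature over the start offset),
the perturbed trend a·T³ + c_p·T⁴ comes from a linear regression of
var_pert/T³ on T, and n* solves the trend ratio = 2, i.e.
T* = a/(2c_eq − c_p).  At 5% relative deviation with truncated-normal
perturbations this yields n* ≈ 4.8 for the unit ball, stable to ±0.02
across seeds at 10^5 replicates per grid point.  The exact value depends
on the perturbation family and on how the crossing of two oscillating
curves is read; alternative pointwise readings on coarse grids range from
≈3.3 (first dip) to ≈9.4 (peaks only).

## Numerical choices and limitations

* Splines are natural cubics, clipped below at zero; volumes integrate
  the positive part exactly (piecewise between spline roots).
* Truncated normals are drawn by inverse-CDF (`ndtr`/`ndtri`) and clipped
  a hair inside the bounds against rounding.
* Equidistant-variance quadrature uses a 4096-point midpoint rule over
  the start offset.
* The extension constant c has no closed form here and is only ever
  fitted; the Zitterbewegung and remainder are not modelled, only
  bounded (×2 rule, m = 1).
* Higher-order (m ≥ 2) section estimators, fractional smoothness,
  within-section area-measurement error and model-specific variance
  estimators adapted to dropouts are out of scope; after dropouts use
  the model-free estimator.
* `estimate` defaults to m = 1; choose m = 0 deliberately when a flat
  face of the object is parallel to the sections.
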