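# Methods

## Setting and model for the profile evaluations

The object of inference is one focal parameter φ of a larger model
θ = (φ, ψ). The profile log likelihood ℓ^P(φ) = max_ψ ℓ(φ, ψ) is
assumed to be computed only up to Monte Carlo error: the available data
are K paired evaluations (φ_k, ℓ̆_k) with

    ℓ̆_k = ℓ^P(φ_k) + β + ε_k,

where β is a bias constant across the profile (the systematic
downward shift of log-likelihood estimators by Jensen's inequality is
the canonical example) and ε_k are independent, mean-zero,
homoskedastic errors. β is never estimated: it moves every point by
the same amount, so it changes the fitted intercept only and cancels
in every interval computation (this vertical-shift equivariance is
enforced by test). Near the maximum the profile itself is locally
quadratic (the local-asymptotic-normality regime, in which the
curvature of the profile is the marginal Fisher information for φ), so
the evaluations follow a quadratic metamodel a + bφ + cφ² + ε.

Heteroskedastic ε are not modelled; if the noise scale varies strongly
along the profile the residual-based covariance is only approximate.

## The smoother

`loess.py` implements the classical single-predictor local quadratic
regression from scratch, so its behaviour is fully specified by this
package rather than by any host-language implementation:

- neighbourhood: the q = ⌈λK⌉ nearest design points to the evaluation
  point, ties at the boundary all included; λ ∈ (0, 1] is the span,
  default 0.75. q must be at least 4 (three quadratic coefficients
  plus one residual degree of freedom). A warning (not an error) is
  logged when λK < 10, where a local quadratic rests on very few
  points and a larger span is advisable.
- kernel: tricube, w_k = (1 − (d_k/d_max)³)³ with d_max the q-th
  nearest distance. If the evaluation point coincides with at least q
  duplicated design points (d_max = 0) the weights fall back to equal
  weights on the neighbourhood.
- no robustness (iteratively re-weighted) passes; degree is fixed
  at 2. Distances are computed on the raw φ scale — with a single
  predictor, standardization would only rescale all distances.
- the smoother is evaluated exactly at every requested point (batched
  3×3 weighted normal equations, centred at the evaluation point so
  the intercept is the fitted value); no interpolation surface is
  used, so results are reproducible to floating precision.
- `smooth_profile` evaluates on a uniform grid (default 500 points)
  over [min φ_k, max φ_k] and refines the grid argmax by the vertex of
  a parabola through the bracketing triple.

Quadratic reproduction — points lying exactly on a quadratic are
fitted exactly for any admissible span — is the property that makes
the smoother compatible with the cut-off calculus below, and is tested
to 1e−8.

## Error separation and the adjusted cut-off

The metamodel is fitted by weighted least squares with the smoother's
weights at the smoothed maximizer φ̂, evaluated once (not iterated).
Weights are precision weights: scaling them all by a constant changes
nothing. The coefficient covariance is σ̂²(XᵀWX)⁻¹ with
σ̂² = Σ w_k r_k²/(K_eff − 3), K_eff the number of positive-weight
points — standard linear-model practice. For conditioning the
regression is computed on φ centred at its weighted mean and mapped
back exactly; this affects nothing observable. A non-concave fit
(ĉ ≥ 0) is an error instructing the user to widen the profile or add
points; it is never silently patched.

- SE_stat = (−2ĉ)^(−1/2): the curvature −2ĉ estimates the marginal
  Fisher information I, and I^(−1/2) is the statistical standard error
  of the MLE of φ.
- SE_mc = √(gᵀΣg), the delta-method standard error of the metamodel
  maximizer −b̂/(2ĉ), with gradient g = (−1/(2ĉ), b̂/(2ĉ²)) and Σ the
  (b̂, ĉ) covariance block. The gradient is derived from first
  principles and validated against a 10⁴-draw resimulation oracle.
- SE_total² = SE_stat² + SE_mc², and the adjusted cut-off is

      δ = (χ²₁,₁₋α/2) · SE_total²/SE_stat²,

  computed with the χ² quantile at full double precision (1.92 and
  printed values like 2.35 are presentation roundings). δ is strictly
  increasing in SE_mc and in the confidence level and equals
  χ²₁,₁₋α/2 exactly when SE_mc = 0.

The confidence interval is the level set of the smoothed profile δ
below its maximum, with crossings located by linear interpolation
between grid points. If the profile never drops below the threshold
before the domain edge, the endpoint is reported at the edge and
flagged *open* on that side — the data simply do not bound the
interval there; this is a flag, not an error. A smoothed profile that
dips below the threshold between the outermost crossings (a multimodal
profile) is flagged `non_convex_level_set` and the hull is reported.

Known small-sample behaviour: because φ̂ is the argmax of a noisy
curve, the smoothed maximum value overshoots the mean smoothed curve
(a selection effect of order the smoothed-curve noise), which pulls
the level set inward, and the metamodel fitted at the realized argmax
tends to overstate curvature. Both effects shrink as the number of
profile points grows or the per-point noise falls; see the coverage
study below for their measured consequence.

## The lognormal toy model

`toymodel.py` provides a fully controllable instance of the setting:
i.i.d. data Y_n with log Y_n ~ N(φ, 2σ²), generated as
Y_n = exp(X_n + σZ_n), X_n ~ N(φ, σ²), Z_n ~ N(0, 1). The marginal
likelihood is available in closed form — the exact profile over σ at
fixed φ is, with v(φ) = mean((log y_n − φ)²),

    ℓ^P(φ) = −(N/2)·log(2π·v(φ)) − N/2 − Σ log y_n,

maximized at φ̂ = mean(log y), with closed-form cut-off-δ interval
φ̂ ± √(v̂(e^{2δ/N} − 1)) — but the likelihood is deliberately accessed
through a J-draw Monte Carlo integration of the latent variable:

    f̂(y_n; φ, σ) = (1/J) Σ_j f_LN(y_n; φ + σε_nj, σ²),

unbiased for the marginal density on the natural scale and therefore
biased downward on the log scale (Jensen). Defaults are the reference
configuration N = 50, J = 3, φ₀ = 0, σ₀² = 1.

Design choices, stated as this package's decisions where the
construction is open:

- ε-stream layout: one standard-normal block of length J per
  observation, generated once per seed by a counter-based Philox
  generator and reused for every (φ, σ), so the fixed-seed Monte Carlo
  log likelihood is a smooth deterministic function of (φ, σ). Distinct
  seeds give streams that behave like independent sequences. Sharing
  one J-block across all observations was measured to roughly double
  the profile noise and is not used.
- each profile point gets its own seed: seed-fixing removes Monte
  Carlo variability from a single maximization, while the evaluations
  must be independent *across* profile points for the metamodel's
  i.i.d.-error assumption to hold.
- the σ maximization at fixed φ and seed is a bounded scalar search on
  log σ over [log 0.05, log 20] with absolute tolerance 1e−6,
  cross-checked against a dense 1000-point σ-grid oracle. Failed
  maximizations flag the point rather than aborting the profile.
- profile grid: K = 30 equally spaced φ centred on φ̂ = mean(log y)
  with half-width 5·√(v̂/N) (five exact standard errors), covering the
  inferentially relevant region with margin for the smoother. K and
  the half-width are free choices of the experiment, not properties of
  the model.
- data and Monte Carlo randomness use separate seeds, so statistical
  and Monte Carlo error can be toggled independently.

At this configuration the per-point profile noise has standard
deviation of a few log units and an essentially constant downward bias
(measured ≈ 7 log units, flat across the grid) — the regime the
metamodel is designed for.

## The coverage study

`study.py` runs R independent replicates (default 2000, giving a
binomial standard error of about 0.55% on a 95% coverage): simulate a
dataset, build its Monte Carlo profile, run MCAP, build the closed-form
exact-profile interval with the unadjusted 1.92 cut-off, and record
whether each interval covers φ₀ and both widths. Per-replicate seeds
derive deterministically from the master seed before dispatch, so the
result is independent of the worker count. Replicates with a
non-concave metamodel or an interval open at the profile's domain
boundary are flagged and reported separately: primary coverage and
width averages use non-flagged replicates, and a sensitivity coverage
counts every replicate whose interval exists by its actual covering
behaviour. A warning is raised when more than 5% of replicates flag.

Measured behaviour at the default configuration (N = 50, J = 3,
λ = 0.75, K = 30): exact-profile coverage sits at its theoretical
value ≈ 94.6% (computable by direct simulation of the closed form),
while MCAP coverage is depressed to ≈ 86–88% and the mean width excess
of MCAP over exact intervals is ≈ 2–5% rather than the ≈ 12.5%
(= √(δ̄/1.92) − 1 at the typical δ̄ ≈ 2.4–2.5) that the cut-off
inflation alone would give. The cause is the small-sample selection
effects noted above, which at K = 30 and per-point noise ≈ 4 log units
consume most of the cut-off inflation. The effect is a property of the
procedure at this profile-information level, not of this
implementation: applying an independent R implementation of the same
algorithm (R `loess` plus weighted `lm`) to profiles exported from
this package reproduces the same coverage within a fraction of a
percent. Coverage approaches the nominal level as the Monte Carlo
error vanishes (measured ≈ 95% at J = 100) and improves steadily with
more profile points (≈ 91% at K = 100–200).

What the toy study does and does not show: it exercises every part of
the MCAP pipeline under exactly the assumed error model (independent,
nearly homoskedastic noise, constant bias). Real sequential-Monte-
Carlo profiles can violate those assumptions — φ-dependent noise
scale, heavy-tailed likelihood estimates, optimizer failures — so
passing here demonstrates correctness of the procedure, not coverage
guarantees for any particular application.

## Numerical conventions

- All tolerances as stated above; ties in neighbourhood selection are
  broken by inclusion.
- Duplicate φ values are legitimate replicate evaluations and are
  preserved by sorting stably.
- The χ² quantile, interval interpolation and argmax refinement are
  full double precision; reported roundings happen only at display.
- Exit codes in the CLI: 0 success, 1 data error, 2 numerical failure.

## Limitations

- Single focal parameter only; no simultaneous multi-parameter
  regions.
- The Monte Carlo bias β is assumed constant across the profiled
  range; strongly φ-dependent bias (e.g. particle filters collapsing
  far from the MLE) is not corrected.
- No automatic span selection; λ is the user's responsibility, with
  0.75 a reasonable default and larger values advised for short
  profiles.
- Open-ended intervals indicate an under-covering profile range, and
  widening the range is the remedy; the package reports but cannot
  repair them.
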