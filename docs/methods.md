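# Methods

## Population model

Two groups (labelled `referent` and `focal`) of `n = 1,000` respondents
each. Latent variables are multivariate normal with zero means and unit
variances; four structural models connect them:

| model | paths (referent / focal) | latents |
| --- | --- | --- |
| simple | X→Y: 0.22 / 0.22 | X, Y |
| partial | X1→Y: 0.22, X2→Y: 0.37 (both groups); cov(X1,X2)=0 | X1, X2, Y |
| mediation | X→M: 0.22, M→Y: −0.22 (both groups) | X, M, Y |
| moderation | X→Y: 0.47 / 0.18 | X, Y |

Every criterion's residual variance is one minus its explained variance,
so all latent variances are exactly 1. The coefficients are taken from an
empirical nomology of workplace sexual harassment (job-gender context →
harassment → job satisfaction; the moderation pair is that slope estimated
separately in a U.S. and a Turkish sample). Moderation is purely a
group-varying slope — no product term.

One construct per condition (the *target*, in the predictor, mediator or
criterion position) is measured by six three-category items; every other
construct by four five-category auxiliary items.

### Target-construct measurement

Exact referent item parameters for the six-item target scale are not
available from the source material, so the package ships documented
defaults chosen to be representative of questionnaire rating-scale items:
standardized loadings 0.60–0.80 and three-category thresholds near
(−0.8, +0.5) with mild per-item variation (see
`populations.DEFAULT_TARGET_TABLE`), converted to the IRT/theta metric via
`a = λ/√(1−λ²)`, `b_k = τ_k/√(1−λ²)`. The table is a configuration input
(`StudyConfig.target_table`), so an exact parameter table can be dropped
in verbatim. Whether the "true" thresholds were symmetric or skewed is
unknown; results that depend on fine threshold placement (notably the
size, not the sign, of threshold-driven bias) should be read with that
approximation in mind.

### Auxiliary measurement

Per item: standardized loading drawn from N(0.6, 0.1) truncated to
[0.05, 0.95] (a genuinely truncated draw, not clipping, so no mass piles
at the bounds; untruncated draws could imply |λ| ≥ 1), lowest threshold
drawn from N(−1.7, 0.45²), remaining thresholds at +1.2/+2.4/+3.6 above
it. The auxiliary constructs are drawn **once per master seed** and reused
across all conditions and replications — a fixed population design that
varies only what the experiment varies.

### Non-invariance manipulations

Items 2, 4, 6 of the target scale are perturbed in the focal group,
cumulatively by level (level 1 = item 2 only): `loadings` halves the
theta-metric discrimination; `thresholds` lowers the bottom threshold by
0.8 / 1.0 / 1.2 respectively (an acquiescent response style; ordering is
never disturbed because only the bottom threshold moves down); `both`
applies both. The 50% reduction acts on the theta-metric slope because the
target parameters are defined in that metric.

## Data generation

Graded responses follow `y* = a·η + ε`, `ε ~ N(0,1)`; the observed
category (coded 0..K−1) counts thresholds below `y*`. The analytic
marginal `P(y=k) = Φ((b_{k+1}−aμ)/√(a²v+1)) − Φ((b_k−aμ)/√(a²v+1))`
serves as the testing oracle. Replications in which any item lacks an
observed category in either group would have infinite sample thresholds;
they are rejected and redrawn from the next substream, with the count
reported per cell (how the original study handled this is unstated; at
n = 1,000 with these parameters rejections are rare).

Random streams: every replication uses
`SeedSequence(master_seed, spawn_key=(cell_id, rep, attempt))`, so cells
are reproducible independently, in any order, and in parallel
(`jobs > 1` is byte-identical to serial). The auxiliary-parameter draw
uses a reserved spawn key.

## Estimation

**Stage 1 — polychoric summaries.** Thresholds are normal quantiles of
cumulative margins. Pairwise correlations maximize the bivariate
multinomial likelihood with thresholds fixed (two-stage ML). The
production path solves all pairs' score equations jointly by vectorized
Fisher scoring; `polychoric_pair` keeps a bounded-Brent reference
implementation, and the two agree to optimizer tolerance (~1e−7).
Bivariate normal rectangle probabilities use a port of Genz's BVND
Gauss–Legendre quadrature (deterministic, abs. error < 1e−10 over the
usable correlation range). Correlations are clipped at |0.999| with a
logged warning rather than failing a cell.

**Asymptotic covariance.** `Γ̂ = A⁻¹ M A⁻ᵀ` for the stacked
(thresholds, correlations): `M` is the empirical second moment of the
per-observation moment functions (cumulative indicators minus Φ(τ) for
thresholds; pairwise likelihood scores for ρ), and `A` the expected
negative Jacobian, assembled analytically from `∂Φ₂/∂ρ = φ₂` (Plackett)
and `∂Φ₂(h,k)/∂h = φ(h)Φ((k−ρh)/√(1−ρ²))`. The estimator variant used by
the original software is unknowable; this influence-function form is
validated in the tests against a closed-form delta-method case, a
nonparametric bootstrap, and a direct Monte Carlo of the sampling
variance.

**Stage 2 — DWLS fit.** The two-group discrepancy
`F = Σ_g (n_g/N) r_g' diag(Γ̂_g)⁻¹ r_g` is minimized by
Levenberg–Marquardt Gauss–Newton (the problem is weighted least squares
in σ(θ), so GN from truth starts converges in ~5–15 iterations; truth
starts are standard in simulation studies and cut non-convergence).
Convergence requires gradient ∞-norm < 1e−6 within 500 iterations;
non-convergence is a flagged result, never an exception. Jacobians are
complex-step derivatives (step 1e−30, machine-precision, verified against
central differences). Variances are optimized on the log scale;
admissibility is judged on the natural scale (variances above 1e−6,
implied correlations proper) — a boundary solution shows up as a
collapsed variance and is flagged inadmissible, counted separately from
non-convergence.

**Robust corrections.** Parameter covariance is the sandwich
`(Δ'VΔ)⁻¹ Δ'V Cov(s) VΔ (Δ'VΔ)⁻¹` with `V` the DWLS diagonal weights and
`Cov(s)` the full `Γ̂_g/n_g` blocks; SEs for variances are delta-method
through the log transform. The test statistic is the scaled-and-shifted
chi-square `T* = a·T + b` with `a = √(df/tr((UΓ)²))`,
`b = df − a·tr(UΓ)`, `U = V − VΔ(Δ'VΔ)⁻¹Δ'V`, compared at the nominal
df — the mean-and-variance adjustment of the WLSMV family. The precise
adjustment variant in the original software is unknown; calibration is
validated empirically (level-0 cells at 500 replications reject at
0.008/0.020/0.042/0.080 under nominal 0.01/0.02/0.05/0.10).

### Identification

First loading of each construct fixed at its population value in both
groups; latent variances/residual variances free in both groups; latent
means 0 in the referent group, free in the focal group; item residual
variances (theta parameterization) fixed at 1 in the referent group, free
in the focal group. An alternative convention — referent latent
variances/residual variances fixed at their population values instead of
freely estimated — is available as
`analysis_spec(..., referent_unit_variances=True)`. The free-variance
default was kept because it produces the characteristic two-sided
distortion pattern (referent and focal slopes biased in opposite
directions, e.g. pseudo-true +0.19 referent / −0.34 focal in the
moderation-with-non-invariant-criterion cell), whereas the alternative
absorbs nearly all of the distortion into the focal group and leaves the
referent slope essentially unbiased.

Focal latent means are parameterized directly (saturated mean structure)
rather than via intercepts propagated through paths — an equivalent
reparameterization for these recursive models.

Under the "model" strategy the known non-invariant items' manipulated
parameter class(es) are freed in the focal group (no detection/search).
An item whose loading *and* thresholds are both freed keeps its focal
residual variance fixed at 1: with both classes free, `(a_j, θ_j)` enter
the focal moments only through `a_j/√(a_j²ψ + θ_j)`, so a free `θ_j`
would be unidentified (this is the standard identification for fully
freed ordinal items).

## Performance criteria

Per cell, over converged admissible replications (counts always
reported): mean estimate, Monte Carlo SD, relative bias
`(mean − true)/true`, 95% Wald-CI coverage and power (|z| ≥ 1.96, closed
boundary) using robust SEs, and empirical rejection rates of `T*` at
nominal sizes 0.01/0.02/0.05/0.10. `pseudo_true_cell` provides a
deterministic surrogate: the analysis model fitted to population-implied
moments with unit weights, giving the asymptotic distortion (and its
sign pattern) without simulation noise.

## Problem sizes

The full design is 216 cells × 1,000 replications. The package defaults
mirror that (`profile="full"`); the desk-scale profile used by the test
suite and the acceptance script runs single cells at 150–500 and 200
replications respectively with n = 1,000 per group, sizes at which a cell
takes tens of seconds on one CPU and Monte Carlo noise is well inside the
reported tolerances (±0.10 on relative bias, ±0.07 on coverage).

## What the generator does and does not emulate

It emulates: two-group graded responses from a known normal-ogive
measurement model, fixed realistic auxiliary scales, uniform-direction
non-invariance on known items, and multivariate-normal latents. It does
not emulate: non-normal latent distributions, mixed-direction loading
differences, extreme response styles other than acquiescence, missing
data, or sampling variability in the population parameters themselves.
Passing tests therefore demonstrate correct behaviour of the estimator
and harness under the stated generating conditions, not robustness of the
substantive conclusions to violations of those conditions.

## Known limitations

* The target-construct parameter table is a documented approximation
  (see above); magnitudes of threshold-driven bias depend on it, signs
  and the qualitative pattern do not.
* Only two groups; no FIML comparison; no delta parameterization beyond
  the documented metric conversion; no invariance-detection procedures.
* Coverage behaviour under *gross* misspecification depends on the SE
  estimator: the sandwich here stays consistent with the observed Monte
  Carlo SD, so coverage collapse is driven by bias alone. A standardized
  slope at n = 1,000 has an information-bound SE of about
  `√((1−R²)/n) ≈ 0.03`, which bounds how far coverage can collapse for a
  given bias.
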