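# Methods

## Models

**Primary model.** Isothermal survivor curves are assumed log-linear:
`log10 C(t) = log10 C0 − t/D_T`.  `D_T` is estimated as the negative
reciprocal of the OLS slope of `log10 C` vs `t`.  A non-negative slope
means no measurable inactivation and raises an error rather than
returning a meaningless negative D.

**Secondary model.** `log10 D_T = log10 D_Tref + (T_ref − T)/z`.  We
regress `y = log10 D_T` on `x = T_ref − T`, so the slope is `1/z` and the
intercept is `log10 D_Tref` — each reported parameter is a direct
transform of one coefficient.  All logarithms are base 10.

**Interval transforms.** Coefficient CIs are two-sided Student-t
intervals, `t_{α/2, n−2} · se`, with α = 0.05.  They are moved onto the
parameter scales with the first-order error-propagation rule
`δ(f(x)) = |f′(x)| δ(x)`:

- `δ(D_T) = D_T² · δ(1/D_T)`
- `δ(z) = z² · δ(1/z)`
- `δ(D_Tref) = ln(10) · D_Tref · δ(log10 D_Tref)`

These are first-order approximations: for a CI that is a large fraction
of the estimate, the true interval of a reciprocal or power transform is
asymmetric, which this workflow (deliberately, matching field practice)
symmetrizes.

**Regression bands.** For a fit with residual SD `σ_y`, centered sum of
squares `S_xx = Σ(x_i − x̄)²` and `N` points, the half-widths at `x₀` are
`t_{α/2} σ_y √(1/N + (x₀−x̄)²/S_xx)` (confidence band, mean response) and
`t_{α/2} σ_y √(1 + 1/N + (x₀−x̄)²/S_xx)` (prediction band, new
observation).  The prediction band dominates the confidence band
everywhere; both are minimal at `x̄`.

## Discretized-normal sampling

A parameter with mean μ and sigma σ is represented by bins of width 0.5 σ,
the central bin on [μ − 0.25 σ, μ + 0.25 σ], each bin by its midpoint with
the normal mass of the bin (central bin: Φ(0.25) − Φ(−0.25) ≈ 19.7%; one
sigma out: ≈ 12.1%; 2.5 sigma out: ≈ 0.9%).  The grid extends to ±4 σ by
default; the residual tail mass is folded into the outermost bins, which
keeps total mass at 1 and the expectation exactly at μ.  (Whether tails
should be folded or resampled is an open convention; folding is the
package default and the alternative — continuous normal sampling — is a
config switch for stage 2.)  Sampling draws a standard normal deviate and
returns the midpoint of its bin, so empirical frequencies converge to the
bin masses.  Discretization inflates the SD by under 2% (bin-width
variance ≈ (0.5σ)²/12 added in quadrature).

## Nested Monte Carlo

Inputs: a table of per-temperature D values with 95% CI half-widths, and
a config.  Defaults (also the case-study settings): `n_outer = 500`,
`n_inner = 500`, `T_ref = 120 °C`, `ci_to_sigma_factor = 2.0`,
`summary_ci_factor = 2.0`, truncation ±4 σ, stage-2 sampling discretized.

1. **Stage 1.** For each temperature, build the discretized normal with
   μ = D and σ = CI/`ci_to_sigma_factor`; draw `n_outer` joint D sets
   (independent across temperatures); refit the secondary model to each
   set, recording (D_Tref, CI) and (z, CI) per set.
2. **Stage 2.** For each outer fit and each parameter, build a
   discretized normal (μ = estimate, σ = CI/`ci_to_sigma_factor`) and
   draw `n_inner` values; D_Tref and z are sampled independently of each
   other, ignoring their regression correlation — this mirrors the
   procedure being modelled; joint sampling is out of scope.
3. **Pooling.** The `n_outer × n_inner` values per parameter are
   summarized as mean, sample SD (n−1), and 95% CI half-width
   `summary_ci_factor × SD` (a percentile option exists).

**CI ↔ σ conventions.** The package must convert 95% CI half-widths to
normal sigmas and back.  The default factor is 2.0 both ways: the
case-study table's 80 °C entry has CI 45.0 for σ 22.5, i.e. exactly 2 σ,
and the mirrored output convention reproduces the published pooled CIs.
1.96 or t-based factors are config options.  The deterministic regression
CIs themselves always use t(n−2) intervals, which is what reproduces the
published deterministic ±2.3 °C / ±7.3 min on eight temperatures.

**Degenerate draws.** An outer D set whose secondary slope is
non-positive (or that contains a non-positive D, possible when σ is a
large fraction of μ) has no valid z; the default policy rejects and
redraws it with a logged count, aborting if the rejection rate exceeds
20% — at that point the inputs are too noisy for the Bigelow model to be
meaningful.  A strict `error` policy is available.

**Randomness.** One root `SeedSequence` spawns named sub-streams: one per
temperature (stage 1), one per parameter (stage 2), one per size in the
sensitivity analysis.  Identical (table, config, seed) gives bit-identical
results; components are independently reproducible.

**Shape of the pooled distribution.** With narrow input CIs the pooled
samples are close to normal (|skewness| < 0.1, excess kurtosis < 0.3 at
250k draws).  With wide input CIs the pooled sample is a scale mixture of
normals and becomes mildly leptokurtic (excess kurtosis ~0.6–0.85 here);
it remains unimodal and nearly symmetric, so a mean ± 2 SD summary is
still a fair description, but the tails are slightly heavier than normal.

## Synthetic data

`generate_isothermal` produces curves that satisfy the primary model
exactly plus i.i.d. normal noise on `log10 C` (the regression scale);
relative noise on raw concentration is an option.  Where a time grid is
not supplied, the default is 7 evenly spaced points spanning two log10
reductions — a package convention for a quantity that real protocols
choose per experiment.  `dt_sampling_distribution` repeats
generate-then-fit `n_datasets` times and reports the D estimates with
moment diagnostics; at moderate noise (D-value CV ≲ 10%) the estimates
are close to normal, which is the premise of the Monte Carlo input model.
The generator does not emulate heteroscedastic or autocorrelated
measurement error, so passing tests say nothing about such data.

## Problem sizes and numerical choices

The case-study computations are small by construction: 8-point
regressions, ≤ 250,000 pooled draws per Monte Carlo run.  The outer-stage
regressions are evaluated with vectorized closed-form OLS (cross-checked
against the scalar path to 1e-10), so a full 500×500 run takes well under
a second and seed-averaged studies take seconds.  Monte Carlo size
defaults follow the sensitivity analysis: pooled CI half-widths change by
under 5% between 250×250 and 500×500, so 250×250 is a safe working size
and 500×500 is used for reported numbers.  Perfect-line fits yield
exactly zero residual SD and zero-width intervals; zero input sigmas
degenerate every sampler to a point mass, collapsing the Monte Carlo onto
the deterministic fit.

## Limitations

- Bigelow-type (log-linear) models only; Weibull/Gompertz/Baranyi primary
  models and Arrhenius secondary models are outside scope, though the
  two-stage sampler is agnostic to how the per-temperature estimates and
  CIs were obtained.
- Unweighted OLS throughout; no weighting by the input CIs.
- Stage 2 ignores the D_Tref–z correlation (by design, see above), so
  joint statements about both parameters should not be read off the
  pooled samples.
- Delta-method CIs are symmetric first-order approximations.
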