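# Methods

## Demographic model

The demographic individual is the ramet; its state is z = ln(surface area
in m²).  Five vital rates close a one-census-interval projection:

| rate | model | parameters (defaults from the reference set) |
|---|---|---|
| survival | logistic in z | β₀ₛ = 2.790, β₁ₛ = 0.731 |
| growth | Gaussian, mean linear in z, SD σ(z) = σ₀ exp(β_σ z) | β₀g = 0.016, β₁g = 0.898, σ₀ = 0.5, β_σ = −0.175 |
| flowering | logistic in z | β₀pr = 1.021, β₁pr = 1.103 |
| flower count | log-linear conditional mean, Var = φ·mean | β₀rs = 1.664, β₁rs = 0.753, φ = 2.0 |
| recruitment | truncated normal sizes; r_r recruits per flower | μ_rd = −3.103, σ_rd = 1.064, r_r = 0.001 |

σ₀ (the growth residual SD at z = 0, in log m²), φ and r_r are
configuration constants of this package: the model cannot be closed
without them, but they are not identified by the published coefficient
table, so `reference_parameterization()` fixes σ₀ = 0.5, φ = 2.0 and
r_r = 0.001 and documents them as overridable.

The exponential variance function acts on the **SD scale**,
σ(z) = σ₀·exp(β_σ·z), the usual single-exponent convention for
exponentially size-varying spread; a constant-SD variant
(`variance="constant"`) is available and coincides exactly with OLS.

The flower-count regression is fit on flowering ramets only, so
r_s(z) is a conditional-on-flowering mean; the fecundity kernel therefore
multiplies it by the flowering probability.  The mean structure is
estimated by Poisson maximum likelihood — a quasi-ML estimator that is
consistent for any log-linear conditional mean — and the dispersion
φ = Pearson χ²/(n−p) scales the standard errors by √φ.  Zero-truncated
likelihoods are deliberately out of scope.

## Synthetic censuses

`generate_population` draws initial sizes uniformly over the observed
range [−6.04, 3.31] log m² (maximal design spread for parameter
recovery), then simulates each fate from the model above.  Flower counts
for flowering ramets are negative binomial with Var = φ·mean, redrawn
until ≥ 1 so that `flowered = 1 ⇔ n_flowers ≥ 1` holds; recruits number
Poisson(r_r × total flowers) with truncated-normal sizes.

Two features of real censuses are *not* emulated, so green tests say
nothing about them: spatial structure (clonal neighborhoods, map-alignment
error) and temporal variation (a single transition year is simulated).
One known internal tension is documented rather than hidden: redrawing
counts until ≥ 1 raises the realized conditional mean above
exp(β₀rs + β₁rs z) wherever that target falls below (φ−1)/ln φ ≈ 1.44
(i.e. z < −0.53), because no ≥ 1 count variable can have a smaller mean.
Refitting therefore recovers the flower-count coefficients with a small
positive intercept bias (≈ +0.09) and negative slope bias (≈ −0.04) —
within the precision at the study's n = 134 but several SEs at n ≈ 5000.
The recovery tests record this as a known failure of exact coefficient
recovery for that one rate; all other rates are recovered without bias
(verified by 200-replicate coverage simulations at n = 1000, Wald 95%
intervals covering in [0.90, 0.99]).

At study scale (276 ramets) the default r_r = 0.001 yields only ~2.3
expected recruits, so the truncated-normal recruit fit (which needs ≥ 2)
can fail for unlucky seeds; analyses that need reliable recruit samples
should use larger censuses or a higher r_r (the study's 10 recruits imply
r_r ≈ 0.004).

## Ground-truth calibration

Aerial area measurements carry a multiplicative bias (the study's targets
were underestimated by ~12%).  `calibrate_sizes` estimates the correction
as the mean of per-target known/measured ratios (a pooled Σknown/Σmeasured
variant is selectable; the original choice is not documented, and both are
scale-equivariant).  The ratio is applied uniformly to all raw areas
before the log transform.

## Numerical choices

* **Domain.** L = min observed size − 0.8, U = max observed size + 0.8
  (≈ 1.6 generating SDs of padding), overridable; the reference domain is
  [−6.84, 4.11].
* **Discretization.** Midpoint rule, default 100 meshpoints; matrices stay
  density-valued and the bin width h enters explicitly (λ from h·K,
  elasticities integrate to 1 with weight h²).
* **Eviction.** Growth columns are renormalized to unit mass on [L, U] by
  their discrete midpoint sum — so the identity h·ΣᵢP[i,j] = s(z_j) holds
  to machine precision — and the recruit density is truncated to [L, U]
  and renormalized the same way.
* **Eigenanalysis.** λ, w, v come from a dense eigendecomposition;
  a power iteration (relative tolerance 1e-12) re-derives λ as a
  cross-check and the two must agree to 1e-10.  w is normalized to a
  probability density (h·Σw = 1) and v so that h·⟨v, w⟩ = 1, making the
  sensitivity surface the plain outer product v·wᵀ.
* **Mesh convergence.** Rebuilding from 100 to 500 meshpoints in steps of
  50 changes λ by ≲ 1e-9 per step on the reference model, far inside the
  1e-5 band used as the convergence criterion, so 100 meshpoints is the
  default.
* **Growth ML.** Joint (β₀g, β₁g, log σ₀, β_σ) maximum likelihood by BFGS
  with the analytic gradient, started from OLS; SEs from the inverse
  observed information, with the delta method on the log-σ₀ scale.
* **Truncated-normal ML.** Nelder–Mead on (μ, log σ) with tight
  tolerances; σ is floored at 1e-8 and hitting the floor sets a
  `degenerate` flag (e.g. identical recruit sizes).
* **Separation.** Logistic fits reject constant responses and complete
  separation (statsmodels' detection plus a |β| > 30 guard).
* **AIC ties.** Candidates within 2 AIC units of the minimum are resolved
  toward the fewest parameters.  Growth candidates cross the mean ladder
  with constant vs exponential SD; flowering and flower-count rates
  compare intercept vs linear only.  `DemographicIPM` restricts selection
  to forms the linear kernel parameterization can project
  (intercept/linear); quadratic fits remain available through
  `select_by_aic` directly.

## Uncertainty

The bootstrap resamples year-t records and recruit records with
replacement **within their own strata** — the recruit-size fit and the
recruits-per-flower rate come from a different sample than the
regressions — refits every vital rate with the frozen, originally selected
formulas, recomputes r_r from the resampled totals, rebuilds the kernel on
the fixed grid and records λ, e_P, e_F.  Intervals are percentile 95%;
degenerate replicates (e.g. a resample with no deaths) are counted and
excluded rather than retried.  The flower-model perturbation draws
(β₀rs, β₁rs) as independent Gaussians with the quasi-scaled SEs (the joint
covariance is not propagated), rebuilds only the fecundity sub-kernel and
tracks λ; on the reference model the induced interquartile spread of λ is
well under 5% of λ, because e_F is tiny.

## Problem sizes

Recovery experiments use censuses of 5,000 ramets (≈ 5,000 flowering
ramets for the count model, obtained from a 10,900-ramet census) and 2,000
recruit-size draws; coverage checks use 200 replicates at n = 1,000;
nested bootstrap-coverage checks use 20 outer censuses × 150 bootstrap
replicates, and endpoint-stability checks compare 250 vs 1,000 replicates.
These sizes were chosen so each check's Monte-Carlo error is small
relative to the tolerance it asserts.

## Known limitations

* Single-transition model: no temporal stochasticity, density dependence,
  spatial spread or age-from-stage analysis.
* The kernel parameterization is linear in z; quadratic vital-rate fits
  can be selected and inspected but not projected.
* r_r treats flower production as time-invariant (recruits observed at
  t+1 arise from flowers initiated before t); the perturbation analysis
  quantifies how little λ depends on this.
* Percentile bootstrap intervals only; no BCa or jackknife.
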