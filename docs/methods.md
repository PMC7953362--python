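# Methods

## Model

The Rutter–Gatsonis HSROC model treats each study's 2×2 table as two
binomials whose logits are linear in a study cut-point θᵢ and a study
accuracy αᵢ (log diagnostic odds ratio at β = 0), with the shape parameter
β letting accuracy vary along the curve:

```
logit(π₁ᵢ) = (θᵢ + αᵢ/2)·e^{−β/2}       logit(π₀ᵢ) = (θᵢ − αᵢ/2)·e^{+β/2}
θᵢ ~ N(Θ, σ_θ²)                          αᵢ ~ N(Λ, σ_α²)
```

The exact binomial likelihood is used throughout; zero cells need no
continuity correction (a +0.5-per-cell correction appears only in chain
initialization, never in inference).

### Priors

Non-informative by default: improper flat on Θ, Λ and β, Uniform(0, ∞) on
σ_θ and σ_α.  `PriorConfig` optionally truncates both (`sd_upper`,
`hypermean_halfwidth`) for users who want proper priors.  With ≥ 2 studies
and both groups non-empty the posterior is proper despite the improper
flats.  Derived probabilities (sensitivities, specificities, the summary
point) are deterministic transforms of (θ, α, β, Λ) and carry no extra
prior factor; their (0, 1) support is a consequence, not an assumption.

## Sampler

A blocked MCMC scheme on the centered parameterization:

* **(θᵢ, αᵢ) pairs** — random-walk Metropolis with an isotropic 2-D
  proposal per study, proposed and accepted independently across studies
  (conditionally independent given the hyper-parameters), vectorized.
* **Θ, Λ** — exact Gibbs: with a flat prior the full conditional is
  N(mean of the study parameters, σ²/n).
* **σ_θ², σ_α²** — exact Gibbs: a flat prior on the SD makes the
  variance's full conditional InvGamma((n−1)/2, S/2) with
  S = Σ(xᵢ − mean)².  Truncated priors are handled by rejection.
* **β** — scalar random-walk Metropolis, *plus* a likelihood-invariant
  reparameterization move: propose β′ = β + ε and rescale every study pair
  via u′ = u·e^{ε/2}, v′ = v·e^{−ε/2} (u = θ+α/2, v = θ−α/2), which keeps
  all study probabilities exactly fixed.  The map is linear with unit
  Jacobian, so acceptance depends only on the hierarchy terms.  This move
  targets the stiff β–(θ, α) ridge that otherwise dominates the
  autocorrelation time; without it β's effective sample size on the example
  dataset drops from ≈ 370 to ≈ 7.

Proposal scales adapt every 25 recorded iterations during warmup (×1.5 when
acceptance > 45%, ÷1.5 when < 25%) and are frozen afterwards.  Each
recorded iteration performs `sweeps_per_iter` (default 5) full sweeps; the
recorded-draw arithmetic (chains × (iter − warmup)/thin, default
4 × 500 = 2000) is unchanged by this.  Chains are seeded by spawning a
`numpy` `SeedSequence` from the single user seed; identical inputs give
byte-identical draws on one platform.

Initialization uses continuity-corrected empirical logits per study, the
empirical moments for the hyper-parameters (SDs floored at 0.1), β = 0, and
N(0, 0.1²) jitter per chain, retrying until the log posterior is finite.

### Validation

* the log posterior agrees with a term-by-term scalar-math oracle to
  1e−10 relative tolerance on randomized states;
* with the hierarchy clamped away (huge fixed SDs, β = 0) each study's
  TPR/FPR posterior collapses to a flat-prior logit binomial, and the
  sampler's posterior means match 1-D numeric quadrature within
  3 Monte-Carlo standard errors;
* simulate-and-refit at 25 studies × 500 per group recovers the
  hyper-parameters inside their 95% CrIs at roughly the nominal rate.

## Diagnostics

Classic (pre-rank-normalization) estimators, matching RStan-era output:
split-R̂ over 2·chains half-chains, and effective sample size from
chain-averaged autocorrelations with Geyer's initial-positive/monotone
paired-sum truncation.  Both return NaN for constant draws; NaN rows are
excluded from the convergence maximum but reported with a warning.
Quantiles are linearly interpolated order statistics (type 7) on the draws
pooled across chains — the default choice; at 2000 draws the difference
from other quantile types is far below Monte-Carlo noise.  The convergence
rule is the one users are told to apply: every monitored split-R̂ ≤ 1.1,
always including the summary quantity `other_snsp[max]`; the CLI exits
non-zero when it fails.

## Summary points

Fixing specificity s, each retained draw of (Λ, β) maps to
`invlogit(Λ·e^{−β/2} + e^{−β}·logit(1−s))`; fixing sensitivity uses the
exact algebraic inverse.  The headline quantity uses the hyper-mean Λ, not
a predictive draw of a new study's α: a delta-method check against the
published example's moments (sd(Λ) = 0.407 maps to ≈ 0.063 on the
probability scale at the plug-in point, versus the printed 0.0647)
confirms that definition — a predictive interval would be far wider.  The
per-study values substitute each αᵢ for Λ.  Note the reported estimate is
the posterior mean of the transform, which differs from the transform of
the posterior means (Jensen gap: 0.771 vs 0.790 on the example).

## Synthetic data

`simulate_dataset` draws (θᵢ, αᵢ) from the hyper-normals and counts from
the two binomials — exactly the fitted model, with equal group sizes per
study.  It emulates threshold and accuracy heterogeneity; it does *not*
emulate non-exchangeable studies, covariate effects, verification bias, or
unequal/informative group sizes, so green recovery tests establish
correctness of the inference machinery, not robustness to model
misspecification.  Recovery-test defaults (25 studies, 500 per group,
Θ = 0, Λ = 2.5, β = 0.15, σ_θ = 0.6, σ_α = 1.0) mirror a well-powered DTA
meta-analysis with hyper-parameters in the neighbourhood typical of
moderately accurate tests.

## Numerical choices and limitations

* Binomial log-pmfs in the sampler's hot path drop count-only constants;
  the public `log_likelihood` includes them (scipy).
* SD Gibbs draws and truncated-normal draws fall back to the current value
  after 100 rejections (only reachable with very tight truncation).
* Datasets need ≥ 2 studies; with < 5 the hyper-SDs are poorly identified
  and a warning is issued.  Zero cells are allowed and simply widen
  posteriors.
* The upper CrI bound of the summary quantity reproduces the published
  example to ≈ 0.01 on the probability scale; marginal tails of Λ, β and
  the SDs reproduce more closely.  Residual differences at this order are
  expected between samplers/prior-boundary conventions and sit well inside
  the stated Monte-Carlo tolerance.
* The SROC curve itself is deliberately not drawn, and no bivariate-model
  (Reitsma) equivalence is provided; the package's scope is the summary
  point and its supporting diagnostics.
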