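# Methods

## The model

Each planted stand *i* contributes, per ecosystem compartment (AGB, BGB,
soil to 1 m), a buildup ratio `R_i = C_planted,i / mean(C_intact,i)` where
the mean runs over that stand's matched intact reference plots. Within a
stratum (compartment × composition group) the ratios follow a logistic
curve of stand age with a free asymptote,

    R(age) = Rmax · logistic(β₀ + β₁ ln age),
    ln R_i ~ Normal( ln Rmax − ln(1 + exp(−β₀ − β₁ ln age_i)), σ ),

i.e. multiplicative lognormal noise around the curve. The free asymptote
matters: some planted stands never reach intact stocks, others overshoot
them, so `Rmax` is not constrained to 1. The model is a descriptive
chronosequence fit — space substitutes for time, stands are treated as
exchangeable within a stratum, and no site random effects, spatial
autocorrelation, or measurement error in the intact reference are modelled.
Each stratum is fitted independently with identical structure (including
the pooled "all" group per compartment); there is no partial pooling
across strata.

Priors are weakly informative on the unconstrained scale:
`ln Rmax ~ N(0, 2.5)` (≈95% prior mass on Rmax between 0.001 and 148, ≈68%
between 0.08 and 12), `β₀ ~ N(0, 5)` (≈95% mass on log odds at age 1
between −10 and 10), `β₁ ~ N(0, 2.5)` (a unit change of ln age shifts the
log odds by at most ±5 with ≈95% prior probability), and the Jeffreys
prior `p(ln σ) ∝ 1`, realized for the sampler as uniform on
ln σ ∈ [−10, 10]; tests verify posterior insensitivity to widening those
bounds. All logarithms are natural — the closed-form age inversion
`age = exp[(ln(R/(Rmax−R)) − β₀)/β₁]` requires it.

### Age zero

The compilation includes stands observed at the year of planting
(age = 0), where ln(age) is undefined. Ages below `age_floor_yr` (default
0.25 yr, configurable in `FitConfig`) are floored before taking logs, in
both the likelihood and the synthetic generator, so the generative model
and the fitted model agree exactly. Curve *evaluation* at age 0 instead
uses the analytic limit: 0 when β₁ > 0, Rmax·logistic(β₀) when β₁ = 0,
Rmax when β₁ < 0. Net-gain calculations ("stock at horizon minus stock at
planting") use this limit rule; note that for a posterior with substantial
mass on β₁ < 0 the limit at 0⁺ jumps to Rmax, which can make net gains
strongly negative for near-flat curves — a property of the limit
convention, reported as-is.

## Sampling

The posterior is sampled with emcee's affine-invariant ensemble sampler
(32 walkers = 4 pseudo-chains × 8, default 2 000 warmup + 8 000 retained
steps, all seeded through `FitConfig.seed`; runs are bit-reproducible).

Two numerical choices matter:

* **Pivot parameterization.** When the curve saturates over the observed
  age range, `ln Rmax` and `β₀` are individually only prior-identified and
  the posterior is a long curved ridge that defeats stretch moves. The
  sampler therefore works in `(φ, β₀, β₁, ln σ)` where
  `φ = ln Rmax − ln(1+exp(−β₀ − β₁·c))` is the curve's log level at the
  pivot `c = mean(ln effective age)` — the data-identified combination.
  The transform has unit Jacobian; priors are evaluated on the natural
  parameters, and draws are stored in the natural parameterization.
* **Initialization.** With data, walkers start in a Laplace-scaled ball
  around the posterior mode (L-BFGS-B from three fixed starts); with no
  data (prior checks) they are overdispersed across the prior scales,
  including the full flat ln σ band.

Diagnostics treat each walker as a chain: split-R̂ and bulk ESS (arviz)
per natural parameter. A fit fails loudly (`ConvergenceError`, exit code 3
from the CLI) when any R̂ > 1.01 or ESS < 100. Near-flat strata (the
synthetic soil group) sit closest to the gate; the acceptance script runs
those fits longer (3 000 + 16 000 steps) for margin.

Derived quantities are draw-wise: equal-tailed 95% posterior quantiles for
curves and predictions; slope "probability" is the one-sided tail
`min(P(β₁≤0), P(β₁≥0))` by draw counting; Bayesian R² is the draw-averaged
`Var(fitted ln R) / (Var(fitted) + Var(residual))`. The curve/age
inversion identity is exact algebraically; numerically it is meaningful
only away from the asymptote (once `R > Rmax(1−10⁻⁶)` the difference
`Rmax − R` is at float64 resolution), and the tests restrict to that
domain.

## Harmonization and pairing

Soil stocks are computed from profiles as Σ BD × thickness × %C per layer
(the unit product is directly MgC ha⁻¹ when BD is g cm⁻³, thickness cm,
and %C a percentage). Stocks sampled at other depths are rescaled to 1 m
by depth proportionality (stock/depth × 100 cm), the method that tracks
observed 1-m stocks more closely in observed-vs-predicted OLS (observed on
y); the alternative mean-BD × mean-%C × 100 cm reconstruction is retained
for the method comparison and flagged secondary — its description in the
source compilations is terse and our formula assumes the plain product.
Depth-weighted means are used when layers are available. Stocks already
reported at exactly 1 m pass through untouched.

Pairing: all intact stands of the same geomorphic class (delta, estuary,
lagoon, open coast, oceanic island — a closed vocabulary; unknown classes
are validation errors) within 10 km are local references, and the ratio
divides by their compartment-wise mean (missing values ignored, never
zero-filled). Without a local reference the fallback is the nearest intact
site cluster (stands sharing a `site_id`, at their centroid) of the same
geomorphic class in the same climatic band, capped at 400 km. "Climatic
class" has no standard definition in this literature; we bin |latitude|
into 10° bands, configurable. The 400-km cap covers the remote-match
distances reported for this kind of compilation (a few hundred km).
Unmatched planted stands are dropped and counted. Strata with fewer than
30 observations or fewer than 6 contributing studies are excluded before
fitting (both configurable); matching is deterministic with ties broken by
stand id.

## The synthetic generator

`synthetic.simulate_dataset` emulates the structure the analysis assumes:
25 geomorphic sites ≥100 km apart at mangrove latitudes (|lat| ≤ 28°),
each with one geomorphic class, 3 intact stands (lognormal stocks around a
site median; medians centred near literature means for mature stands —
AGB 99, BGB 49, soil 277 MgC ha⁻¹ — with log-SD 0.5–0.6) and 10 planted
stands. Stand scatter within a site is ±2 km so a site is one local
reference pool. Planted ages are log-uniform on (0.25, 40] yr with an 8%
point mass at exactly 0 to exercise the age-floor rule; 25% of planted
soil stocks are reported over 50-cm cores (recoverable exactly by depth
scaling); composition is drawn uniformly over mixed + four genera.
Planted stocks are generated exactly from the model:
`C_planted = mean(site intact) × R(θ, max(age, floor)) × exp(N(0, σ))`.
Default curve truths are Rmax 0.71/0.73/0.75, β₀ −3/−2.5/+2, β₁
1.5/1.5/0.3, σ 0.5/0.5/0.45 for AGB/BGB/soil: biomass compartments rise
over ~20 yr to asymptotes near 0.7, soil sits near 0.75 with a weak,
uncertain slope.

Because the generator *is* the fitted model, passing recovery tests
demonstrates correctness of the pipeline and calibration of the sampler —
not robustness to real-data pathologies (non-lognormal noise,
within-study correlation, biased reference selection, age measurement
error), which the generator deliberately omits. A hidden truth record
(parameters, site memberships, latent ratios) lets tests score every stage
exactly.

`recovery_experiment` repeats simulate → harmonize → pair → fit and
reports bias, RMSE and credible-interval coverage. Coverage in the
acceptance gate is pooled across the four parameters: at desk scale (10
replicates) per-parameter coverage is a 0–10 count too coarse for a
meaningful binomial band, while the pooled 40 indicators give one. Problem
sizes throughout (n = 250 observations per stratum, 10 replicates) were
chosen as the smallest at which these checks are statistically meaningful.

## Known limitations

* Compartment fits are independent; ecosystem-level interval arithmetic
  sums per-compartment interval endpoints and ignores cross-compartment
  posterior correlation (conservative).
* The ratio treats the intact mean as known; reference sampling error
  propagates into σ rather than being modelled.
* The remote-matching centroid rule and the 10° climatic bands are
  reasonable defaults, not estimates; both are exposed in
  `PairingConfig`.
* Near-flat curves leave `Rmax` and `β₀` prior-dominated; their marginals
  should be read as prior-shaped in that regime (the pivot level φ is what
  the data determine).
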