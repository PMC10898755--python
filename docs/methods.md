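# Methods

## Model

Concentrations are strictly positive and span three orders of magnitude from
roadside to reference sites, so the model lives on the natural-log scale.
For element concentration `y_ij` (mg/kg dry weight) at site `i = 1..n`,
tissue sample `j = 1..J_i`:

    log(y_ij) = x_i' beta + alpha_i + eta_i + eps_ij

* `x_i = (1, log d_i, s_i, s_i log d_i)`: log distance-to-road `d_i` (m) and
  a south-side indicator `s_i` with their interaction.  Deposition from road
  dust decays roughly log-linearly with distance; prevailing winds make the
  two sides differ in level and, via the interaction, in decay rate.
* `alpha_i ~ N(0, sigma1^2)` i.i.d. site effects.  Field duplicates at a
  plot share `alpha_i` and `eta_i` and differ only through `eps_ij`; the
  duplicates are what identify the nugget `sigma0^2` separately from
  `sigma1^2`.
* `eta ~ N(0, Sigma)` with `Sigma[i,k] = sigma2^2 exp(-d_ik / theta)`
  (exponential covariance; partial sill `sigma2^2`, range `theta` in m).
  The 10–20 m "autocorrelation" plots give near-zero lags that inform
  `theta`.  Distances are Euclidean on projected planar coordinates; over a
  ~60 km extent the planar approximation is adequate, and inputs are assumed
  already projected.
* `eps_ij ~ N(0, sigma0^2)` measurement error.

Priors are weakly informative: `beta ~ N(0, 100 I)`; Gamma(2, 2) in
shape–rate form on each of `sigma0^2, sigma1^2, sigma2^2` (mean 1 on the
log-concentration variance scale — the priors sit on the variances
themselves, not on standard deviations); Half-Normal(0, 5000) on `theta`,
with 5000 m read as the scale parameter of the underlying Normal (the
conventional Half-Normal parameterization; the alternative
variance-parameter reading would make the prior absurdly tight for a 32 km
road).  Reference sites 42–64 km out enter through the same log-distance
predictor; there is no separate reference term.

Separate models are fit per element (Zn, Pb, Cd) and year (2006, 2017).

## Sampler

The model is linear-Gaussian given
`psi = (log sigma0^2, log sigma1^2, log sigma2^2, log theta)`, so the
sampler collapses everything it can:

1. **Metropolis on psi** — an adaptive random-walk on the 4-dimensional
   log-parameter vector targeting `p(psi | z)` with both `beta` (via its
   Gaussian prior, using the Woodbury/determinant-lemma identities) and the
   latent `(alpha, eta)` integrated out of the Gaussian likelihood
   `z ~ N(X beta, sigma0^2 I + A (sigma1^2 I + Sigma) A')`.  The proposal
   covariance is re-estimated every 50 iterations during burn-in (scaled
   empirical covariance, `2.38^2/4`, plus a `1e-6` regularizer) and frozen
   afterwards, so the retained draws come from a fixed-kernel chain.
   Variances are sampled on the log scale with the Jacobian included.
2. **Exact draw of `beta | psi, z`** from the conjugate Gaussian
   conditional, once per retained iteration.
3. **Exact joint draw of `(alpha, eta) | beta, psi, z`** (optional,
   `include_latent=True`), from the 2n-dimensional Gaussian conditional.
   The conditional covariance Cholesky is cached per accepted `psi`.

Steps 2–3 are exact conditionals, so the scheme targets the full joint
posterior and its mixing is governed only by the 4-dimensional walk.  This
collapsed design is why a 131-observation fit takes under a second per
thousand iterations and why replicate-based calibration experiments are
feasible on one CPU.

Defaults follow the study schedule: 4 chains × 4,000 iterations, first half
discarded, giving 8,000 retained draws.  Starting values: unit variances,
`theta` at the median pairwise site distance (the collapsed scheme needs no
`beta` start).  Convergence is summarized by rank-normalized split-chain
R-hat and bulk ESS (via arviz) with a 1.05 flag threshold; the variance and
range parameters are weakly identified and genuinely need the full schedule,
while `beta` mixes almost immediately.

Numerical choices: `1e-8 * sigma2^2` jitter on the diagonal of every spatial
covariance before factorization (the 10–20 m plot pairs make `Sigma` nearly
singular); Cholesky factorizations throughout; the predictive conditional
covariance retries with escalating jitter only for grid points coincident
with sites.

## Prediction

For each of K (default 200) parent posterior draws sampled uniformly without
replacement, the spatial field at the grid is drawn from its exact Gaussian
conditional given that draw's `eta` at the sites and its
`(sigma2^2, theta)` — jointly across all grid points, so map draws are
spatially coherent and stratum averages inherit the right dependence.  The
joint draw is computed by blocked Cholesky factorization (blocks of ≤ 512
grid points, each conditioned on the sites and all previous blocks), which
is algebraically identical to a single full factorization; the block
partition changes results only at floating-point roundoff (tested at 1e-8).

Original-scale draws are
`yhat^(k)_l = exp(x_l' beta^(k) + eta*^(k)_l + alpha*^(k)_l)`.  A fresh
`alpha* ~ N(0, sigma1^2^(k))` per grid point is included by default because
a grid location is a new, unsampled site; measurement error is never added
(maps show modeled concentrations, not hypothetical lab replicates).  The
`include_new_site_effect` flag exposes the choice.

Quantiles everywhere use linear interpolation of order statistics (the
type-7 convention, numpy's default), frozen for bit-stability.

## Change summaries

Per grid point and per stratum the package reports 2006 and 2017 posterior
summaries, average change, percent change and probability of decrease.  All
are computed draw-wise and only then summarized: percent change is the mean
of `100 (yhat_2017 - yhat_2006) / yhat_2006` over draws, never the ratio of
summary means (the two differ whenever the 2006 draws are dispersed — a
regression test enforces the distinction).  Draw `k` of one year is paired
with draw `k` of the other; the two years' fits are independent, so the
pairing is arbitrary and frozen by seed.  Ties in the probability of
decrease count as no decrease (measure-zero for continuous draws).  Stratum
averages are plain means over the grid points of the stratum (and of the
side-of-road subset for the north/south tables); a structurally empty
stratum-region (stratum 5 north) is flagged by omission rather than raised.

## Synthetic study design

The generator reproduces the monitored network: 12 transects stationed along
a configurable road polyline (default: straight, 32 km; 6 transects per
side, assigned by lot) with plots at 10, 50, 100, 300, 1000, 2000, 4000 m
(11 rather than 12 plots at 2000 and 4000 m, matching the published design
table); one autocorrelation plot per transect offset uniformly 10–20 m from
its 1000/2000/4000 m plot (8/1/3 parent split by default); 6 roadside
tissue-only points at 3 m; 10 reference sites 42–64.2 km south.  Field
duplicates per distance class are chosen so the planned total is exactly 131
tissue samples at 110 locations; a dropout probability (default 0) can
emulate plots with no recoverable tissue.

Default simulation truths use the published posterior-mean regression
coefficients per element × year (e.g. Zn 2006
`beta = (9.165, -0.535, -0.766, 0.059)`) so synthetic data resemble the
study.  The variance components are not published; the defaults
`sigma0^2 = 0.05, sigma1^2 = 0.10, sigma2^2 = 0.30, theta = 3000 m`
correspond to ~25% duplicate CV, ~37% between-site CV, a spatial field
spanning a factor of ~3 across its central 95% range, and spatial
correlation decaying over a few kilometres — typical of moss-tissue metal
surveys.

The prediction grid scatters points uniformly along the road with distances
uniform within each stratum band — 1: (0, 100], 2: (100, 2000],
3: (2000, 4000], 4: (4000, 5000], 5: [30000, 64000] m (south side only) —
at the published per-stratum densities (697, 743, 507, 121, 289; the
north/south split follows the published side tables).  What the generator
does **not** emulate: land-cover-class placement, the real road geometry and
coastline, spatially varying grid density, and any below-detection-limit
censoring.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to the
model misspecification real data would bring.

## Calibration findings and limitations

Replicate experiments at reduced schedules (they are well within the reach
of the collapsed sampler; the reduced sizes are simply sufficient for the
Monte-Carlo tolerances used) show:

* 95% credible intervals for the distance-decay coefficient `beta_1` cover
  the simulation truth at ~95–97% over replicate datasets.
* Pointwise 95% posterior-predictive intervals at held-out locations cover
  the true simulated concentration at ~95% in the interpolation region.
* In a null-change experiment (identical truth both years), stratum
  probabilities of decrease centre exactly on 50% with no year asymmetry.
  Their *spread*, however, is heavier-tailed than uniform in the near-road
  strata: values outside (5%, 95%) occur in ~20% of run × stratum
  combinations rather than the ~10% a uniform distribution would give.
  The excess sits in the corridor strata (strata 1–3); the reference
  stratum, pure interpolation among the reference sites, is calibrated
  (~99% inside).  Part of the corridor excess comes from extrapolation —
  stratum averages are dominated by grid points closer to the road (down to
  ~1 m under the uniform-distance grid) than the closest sampled plots
  (3 m), and flooring grid distances at 10 m recovers roughly half the gap —
  and the remainder reflects that, at n = 131 samples with weakly identified
  `(sigma2^2, theta)`, finite-sample Bayesian intervals for this derived
  exp-scale functional carry no frequentist guarantee.  Practical reading: near-road probability-of-
  decrease values close to 0% or 100% should be treated as "strong
  evidence", not as literal frequencies, when the stratum includes
  locations outside the sampled distance range.

Other known limitations: exponential covariance only (no Matérn/Gaussian
options, no anisotropy); no censored-likelihood support for below-detection
measurements; no model comparison machinery; planar coordinates are assumed,
so inputs in geographic coordinates must be projected first.
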