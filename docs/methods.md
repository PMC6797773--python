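# Methods

## The inverse-calibration model

Seed δ¹⁸O declines roughly linearly with the altitude at which the seed
matured, because the source water and temperature regime change with
elevation. `isoseed` treats the fitted line δ = a + b·A as an empirical
transfer function and inverts it probabilistically: for each dispersed seed
*j*,

- likelihood: δⱼ ~ Normal(a + b·Aⱼ, σ_obs),
- prior: Aⱼ ~ Uniform(A_min, A_max) on the mother-plant altitude,
- derivative parameter: Dⱼ = zⱼ − Aⱼ, the vertical dispersal distance,
  where zⱼ is the recorded deposition altitude (exact subtraction per
  retained draw, so posterior mean/quantiles of D are those of A reflected
  and shifted).

With the line fixed, the seed posteriors are independent truncated normals;
the package still samples them by MCMC because the production path must
also cover the *refit* mode, where (a, b, σ_cal) get uniform priors and are
estimated jointly from reference-seed records, coupling all seeds and
propagating calibration uncertainty into every Dⱼ. The fixed-mode
tractability is exploited the other way round: `grid_posterior_oracle`
integrates the same unnormalised posterior on a ≥10,000-point lattice and
serves as an independent correctness oracle in the tests (sampler vs oracle
agreement within 5 m on posterior means and 10 m on 95% CI endpoints).

### Observation error

σ_obs = √(σ_cal² + σ_meas²) combines the calibration line's residual SD
with the analytical replicate SD in quadrature, treating measurement error
in the dispersed seed's δ and scatter about the line as independent. The
analytical SD defaults to 0.2‰ (replicate reproducibility of the IRMS
protocol). A pure-σ_cal mode (`include_measurement_sd=False`) exists for
sensitivity analysis, since published applications do not always state
whether the analytical term was included.

### Priors and defaults

- `prior_alt_bounds` default (0, 2500) m a.s.l.: the study massif spans
  hilly (400 m) to subalpine (2500 m) zones, and the prior should not
  exclude mothers below or above the survey route. Configurable; widening
  it mainly stretches the tails of extrapolated seeds.
- Calibration constants `ACTINIDIA_OKUTAMA_2013`: slope −0.0024 ‰/m,
  intercept 19.0213 ‰, R² 0.55, altitude support 600–1,280 m, δ support
  15.09–17.73 ‰. The residual SD 0.55 ‰ is a **derived** default: only R²
  was published, and 0.55 ‰ reproduces R² ≈ 0.55 for seeds spread uniformly
  over the 600–1,280 m transect (verified by simulation in the test suite).
- MCMC protocol default: 3 chains × 110,000 iterations, 10,000 burn-in,
  thinning every 50 → 2,000 retained values per chain, 6,000 total;
  convergence threshold R̂ < 1.04. These are the published protocol's
  settings and are configurable; validation tests that need many seeds use
  shorter chains (11,000 iterations, burn-in 1,000, thin 5 — still 6,000
  retained draws) because the per-seed posteriors are low-dimensional and
  mix within hundreds of iterations.

### Sampler

Adaptive random-walk Metropolis within Gibbs. Seed-altitude coordinates
are conditionally independent given the line, so their proposals and
accept/reject decisions are vectorised across seeds and across chains in a
single numpy sweep; line parameters (refit mode) update as scalar
Metropolis steps against the full likelihood. Per-coordinate step sizes
start at 2.4 × the posterior scale σ_obs/|b| and adapt every 50 iterations
during burn-in toward ≈ 0.44 acceptance, then freeze, so the post-burn-in
chain satisfies detailed balance. Chains initialise overdispersed
(uniform over the prior box). Acceptance rates outside (0.05, 0.95) after
burn-in are logged as warnings; a non-finite log-posterior at
initialisation is an error, as is a seed whose δ is unreachable (>12
σ_obs) anywhere inside the prior bounds.

### Diagnostics

`gelman_rubin` implements the classic potential scale reduction factor
√(V̂/W) with V̂ = (n−1)/n·W + (1+1/m)·B/n on retained draws (the variant
contemporary with WinBUGS-era workflows); `split_gelman_rubin` computes the
modern split-chain variant, logged alongside in `diagnostics.json` and
cross-checked against arviz in the tests. Identical constant chains report
R̂ = 1 by convention with a warning. An R̂ above threshold produces a
prominent pipeline warning, never a silent pass.

## Direction classification and summaries

A seed is *downhill* iff the upper bound of the equal-tailed 95% credible
interval of D is < 0, *uphill* iff the lower bound is > 0, otherwise
*neither*; an endpoint exactly at zero is conservatively *neither*.
Equal-tailed percentile intervals (not HPD) match the BUGS-era convention.
Species summaries report the mean ± SE of per-seed posterior-mean
distances — the SE is over seeds, so it reflects between-seed spread, not
posterior width. Under a well-specified zero-displacement null, the
non-*neither* fraction approaches 1 − coverage ≈ 5%, which the test suite
checks via the coverage property below.

## Year gate and lapse-rate adjustment

Calibration intercepts track the maturation-month air temperature, so the
gate compares each collection year's maturation-month mean with the
calibration year's: |ΔT| ≤ 0.2 °C → identical; |ΔT| ≥ 0.5 °C → excluded;
between → retained but flagged. Thresholds are configuration parameters;
the altitude equivalent ΔT/lapse × 100 (0.2 °C ≙ 33.3 m at 0.6 °C/100 m)
is always reported, and `apply_year_offset=True` subtracts it from every
distance and CI endpoint exactly (a rigid shift of the posterior).
Threshold comparisons carry a 1e-9 guard because temperature differences
like 23.8 − 23.3 are not exact in binary floating point.

## Synthetic-data generator

The generator emulates the study's generative structure: mother plants
uniform over a mother-altitude band; per-species Gaussian displacement
kernels (negative mean = downhill), rejection-truncated (cap 1,000 tries
per seed, then a hard error) so deposition stays within the physical
mountain bounds; observed δ = line(mother) + Normal(0, σ_cal) +
Normal(0, σ_meas), plus an optional faecal-sample random effect shared by
the (default 3) seeds of one sample — replication within faeces is
represented by the `faecal_sample_id` grouping, never by averaging.

The default scenario uses the study conditions: bounds 550–1,650 m (the
survey route), σ_meas 0.2 ‰, and four mammal kernels whose means are the
published per-species mean distances (−393.1, −98.5, +4.5, −245.3 m).
Kernel SDs are derived as published SE × √n with n = 30/18/24/48; home
ranges are 3,450 ha (published, bear) and 90/24/590 ha for macaque/raccoon
dog/marten, obtained by inverting the published distance–home-range log
relation at each species' mean — literature-plausible magnitudes, shipped
as defaults only.

**Truncation caveat.** With a bear-scale kernel (mean −393 m, SD ≈ 480 m)
and mothers uniform over a 1,100 m band, the bounds truncate the kernel
hard: the realised mean displacement is biased toward zero by well over
100 m. This is physics, not a bug — a seed cannot be carried below the
mountain foot. Two consequences for validation design: (1) the
"sample mean ≈ kernel mean" property is tested in a tall-massif
configuration (`mother_alt_range` decoupled from `mountain_bounds`) where
truncation is negligible; (2) recovery tests for the inference pipeline
compare estimates against the *realised* ground-truth displacements in the
`TrueEvent` table, which is the correct recovery target under any
truncation regime.

### What passing tests do and do not show

The generator draws mothers from the inference prior and noise from the
inference likelihood, so coverage and recovery results certify internal
consistency of the machinery, not field realism. Real data add: nonuniform
mother distributions (plant density varies with elevation), non-Gaussian
and spatially autocorrelated animal movement, within-faeces correlation of
δ (same mother for all seeds of one fruit), inter-annual intercept shifts,
and calibration extrapolation — the last is flagged per seed
(`extrapolated`) but its bias cannot be corrected from within the model.

## Regressions

`log_regression` fits y on ln(x) by OLS (x = home range, ha > 0);
`linear_regression` fits distance on mother altitude. Both report the
signed Pearson r (and |r|, since figure conventions for the sign vary),
t = r·√((n−2)/(1−r²)) carrying the slope's sign, and the two-sided p on
n−2 df; a constant response returns slope = r = 0 with a warning, perfect
collinearity returns t = ±∞, p = 0. Note a structural caveat the package
inherits from the workflow it implements: regressing D̂ = z − Â on Â shares
the estimation noise of Â between axes, which by itself pushes the slope
toward −1; the per-species altitude regressions should be read as
descriptive of the estimates, not as causal slopes.

## Numerical and interface choices

- Retention rule: post-burn-in iteration *t* (1-based) is kept iff
  t mod thin = 0, giving exactly (iterations − burn-in)/thin draws/chain.
- Reproducibility: every random path flows from one `numpy` SeedSequence;
  identical configs give byte-identical outputs, and all output files embed
  the rng seed and a SHA-256 config hash in `#` comment headers.
- CSV dialect: comma, UTF-8, dot decimal, mandatory header; floats are
  written with `repr` so round-trips are exact.
- Problem sizes in the validation suite — 50 seeds under the full default
  protocol, 20 seeds for oracle equivalence (120,000 retained draws so the
  quantile Monte-Carlo error ~2 m sits inside the 5 m/10 m bands), 200
  seeds/species for four-species recovery, and 1,000 seeds for 95% ± 2%
  CI coverage under shortened chains — were chosen so each check's
  Monte-Carlo error is small against its tolerance while the whole battery
  stays a desk-scale computation.

## Known limitations

- No hierarchical pooling across seeds of a species and no multi-isotope
  model; seeds are conditionally independent given the line.
- The refit mode uses uniform priors with wide fixed boxes; pathological
  calibration data (2–3 points) are accepted with a saturated-design
  warning rather than refused.
- The year gate adjusts intercept-equivalent offsets only; it does not
  model slope changes between years.
- Direction proportions depend on posterior CI width and hence on σ_cal:
  a noisier calibration line reclassifies seeds from downhill/uphill to
  neither without changing mean distances much.
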