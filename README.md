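# isoseed

**Vertical seed-dispersal distances from seed oxygen isotopes, by Bayesian
inverse calibration.**

Frugivorous mammals move fleshy-fruited seeds up and down mountainsides.
Whether that net movement points toward the summit or the foot decides
whether animal-dispersed plants can track a warming climate uphill.
`isoseed` implements the isotope-based workflow used to measure that
movement: because seed δ¹⁸O declines linearly with the altitude at which a
seed matured, the δ¹⁸O of a seed recovered from a faecal sample locates its
mother plant, and the difference between deposition and mother altitude is
the vertical dispersal distance.

It is written for movement ecologists and isotope ecologists who have (a)
dispersed-seed records (deposition altitude, δ¹⁸O, disperser species,
collection year), and (b) either a published calibration line or raw
reference-seed data — plus anyone who wants to test such an analysis
end-to-end on synthetic data with known ground truth.

## The model

For seed *j* with observed isotope ratio δ*ⱼ* (‰ vs V-SMOW), deposited at
altitude *zⱼ* (m a.s.l.):

```
δⱼ ~ Normal(a + b·Aⱼ, σ_obs),   Aⱼ ~ Uniform(A_min, A_max)
σ_obs = √(σ_cal² + σ_meas²)
Dⱼ = zⱼ − Aⱼ                      (derivative parameter, draw by draw)
```

where (*a*, *b*) is the δ¹⁸O–altitude calibration line (*b* < 0), σ_cal its
residual SD, σ_meas the analytical replicate SD (0.2‰), *Aⱼ* the unknown
mother-plant altitude and *Dⱼ* the vertical dispersal distance (negative =
toward the mountain foot). The line can be held at fixed published
coefficients or refit jointly from reference-seed records (uniform priors on
*a*, *b*, σ_cal), in which case calibration uncertainty propagates into every
*Dⱼ*. Sampling is adaptive random-walk Metropolis within Gibbs (3 chains ×
110,000 iterations, 10,000 burn-in, thinning 50 → 6,000 retained draws by
default), checked with the Gelman–Rubin R̂ (< 1.04). A seed is classified
*downhill* when the entire equal-tailed 95% credible interval of *Dⱼ* is
below zero, *uphill* when above, *neither* otherwise. Downstream analyses
regress mean distance on ln(home range) across species and distance on
mother altitude within species.

An inter-annual gate compares the maturation-month mean temperature of each
collection year against the calibration year: |ΔT| ≤ 0.2 °C is treated as
identical, |ΔT| ≥ 0.5 °C excludes the year, anything between is flagged; the
lapse rate (0.6 °C/100 m) converts ΔT to an altitude offset (0.2 °C ≙ 33.3 m)
that can optionally be subtracted from all distances.

## Worked example

Simulate the built-in four-species mountain scenario and run the full
pipeline on it:

```bash
isoseed simulate --outdir sim --seed 7
printf 'year,mean_temp_c\n2010,23.8\n2011,23.5\n2013,23.3\n' > temps.csv
cat > config.yaml <<EOF
seed_csv: sim/seeds.csv
temperature_csv: temps.csv
outdir: out
rng_seed: 7
EOF
isoseed run --config config.yaml
```

which prints (abridged):

```
isoseed v0.1.0 report (rng_seed=7, config_hash=ba6de8346338)
Sign convention: negative distance = seed dispersal toward the mountain foot,
positive = toward the top.
Seeds analysed: 120/120 (after year gate); line mode: fixed; extrapolated seeds: 23.

Vertical seed dispersal summary (negative = toward the mountain foot, positive = toward the top):
  Asian black bear: mean -271.6 ± 65.5 m SE over 30 seeds; 23% downhill, 0% uphill, 77% neither (by 95% credible intervals).
  Japanese macaque: mean -129.9 ± 69.3 m SE over 30 seeds; 23% downhill, 3% uphill, 73% neither (by 95% credible intervals).
  raccoon dog: mean -85.1 ± 54.7 m SE over 30 seeds; 3% downhill, 10% uphill, 87% neither (by 95% credible intervals).
  Japanese marten: mean -279.2 ± 60.2 m SE over 30 seeds; 17% downhill, 0% uphill, 83% neither (by 95% credible intervals).

home_range_log: y = -42.22·ln(x) + 42.89; r = -0.93, t = -3.56, P = 0.071, n = 4
altitude_linear[Asian black bear]: y = -0.85·x + 724.99; r = -0.84, t = -8.30, P = 4.9e-09, n = 30
...
```

Reading this: each species line is the mean ± SE (over seeds) of the
posterior-mean dispersal distance — e.g. bear-dispersed seeds moved on
average ~272 m toward the mountain foot in this simulation — followed by the
share of seeds whose 95% credible interval excludes zero in each direction.
`extrapolated seeds` counts seeds whose δ¹⁸O falls outside the calibration
line's δ support (13.53‰-class values below the 15.09–17.73‰ range), whose
estimates rest on extrapolation. The log regression says species with larger
home ranges carried seeds further downhill; the per-species linear fits say
seeds from higher mothers went further downhill. Machine-readable tables
(`estimates.csv`, `species_summary.csv`, `direction_table.csv`,
`regressions.json`, `diagnostics.json`) land in `out/`, every file stamped
with the rng seed and config hash; reruns are byte-identical.

The same stages are importable directly
(`isoseed.build_model` → `run_mcmc` → `summarize_posterior` → …), and
`isoseed.grid_posterior_oracle` provides an independent dense-integration
check of any fixed-line posterior.

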