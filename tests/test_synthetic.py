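"""Ground-truth generator: determinism, invariants and kernel recovery."""

import dataclasses
import math

import numpy as np
import pytest

from isoseed import (
    DisperserKernel,
    SimulationConfig,
    default_study_config,
    fit_calibration,
    generate_calibration_seeds,
    generate_dispersal_events,
)


class TestCalibrationSeeds:
    def test_line_evaluation_at_1000m(self, line):
        # closed-form check of the line the generator perturbs
        assert line.predict(1000.0) == pytest.approx(16.6213, abs=1e-12)
        assert line.predict(0.0) == pytest.approx(19.0213)

    def test_noiseless_records_lie_on_line(self, line):
        quiet = dataclasses.replace(line, residual_sd=0.0)
        recs = generate_calibration_seeds(quiet, 50, (600, 1280), rng_seed=3)
        for r in recs:
            assert r.delta18O == pytest.approx(quiet.predict(r.altitude), abs=1e-12)
            assert 600 <= r.altitude <= 1280

    def test_reproducible_for_fixed_seed(self, line):
        a = generate_calibration_seeds(line, 20, (600, 1280), rng_seed=9)
        b = generate_calibration_seeds(line, 20, (600, 1280), rng_seed=9)
        assert a == b

    def test_ols_refit_recovers_slope(self, line):
        noisy = dataclasses.replace(line, residual_sd=0.3)
        recs = generate_calibration_seeds(noisy, 200, (600, 1280), rng_seed=21)
        fit = fit_calibration(recs)
        assert fit.slope == pytest.approx(line.slope, abs=5e-4)

    def test_too_few_seeds_rejected(self, line):
        with pytest.raises(ValueError):
            generate_calibration_seeds(line, 2, (600, 1280), rng_seed=0)

    def test_extrapolation_needs_explicit_flag(self, line):
        with pytest.raises(ValueError, match="extrapolation"):
            generate_calibration_seeds(line, 10, (400, 1500), rng_seed=0)
        recs = generate_calibration_seeds(
            line, 10, (400, 1500), rng_seed=0, allow_extrapolation=True
        )
        assert len(recs) == 10


class TestDispersalEvents:
    def test_truth_identity_and_bounds(self, small_study):
        seeds, truth = generate_dispersal_events(small_study)
        lo, hi = small_study.mountain_bounds
        assert len(seeds) == len(truth) == 4 * small_study.n_seeds_per_species
        for s, t in zip(seeds, truth):
            assert s.seed_id == t.seed_id
            assert t.true_displacement == t.deposition_altitude - t.mother_altitude
            assert lo <= t.mother_altitude <= hi
            assert lo <= t.deposition_altitude <= hi

    def test_degenerate_kernel_gives_zero_displacement(self, line):
        cfg = SimulationConfig(
            line=line,
            dispersers=(DisperserKernel("static", 0.0, 1e-9, 100.0),),
            n_seeds_per_species=20,
            rng_seed=1,
        )
        _, truth = generate_dispersal_events(cfg)
        assert all(abs(t.true_displacement) < 1e-6 for t in truth)

    def test_deterministic_output(self, small_study):
        a = generate_dispersal_events(small_study)
        b = generate_dispersal_events(small_study)
        assert a == b

    def test_noiseless_delta_inverts_to_mother_altitude(self, line):
        quiet = dataclasses.replace(line, residual_sd=0.0)
        cfg = SimulationConfig(
            line=quiet,
            dispersers=(DisperserKernel("bear", -200.0, 100.0, 3450.0),),
            n_seeds_per_species=30,
            measurement_sd=0.0,
            rng_seed=13,
        )
        seeds, truth = generate_dispersal_events(cfg)
        for s, t in zip(seeds, truth):
            assert quiet.invert(s.delta18O) == pytest.approx(t.mother_altitude, abs=1e-9)

    def test_kernel_means_recovered_when_bounds_permissive(self, line):
        """On a massif tall enough that truncation is negligible, the
        empirical per-species displacement means land within 3 Monte-Carlo
        SEs of the study-scale kernel means."""
        base = default_study_config()
        cfg = SimulationConfig(
            line=line,
            dispersers=base.dispersers,
            n_seeds_per_species=1500,
            mountain_bounds=(0.0, 6000.0),
            mother_alt_range=(2500.0, 3500.0),
            rng_seed=99,
        )
        _, truth = generate_dispersal_events(cfg)
        for kernel in cfg.dispersers:
            disp = np.array(
                [t.true_displacement for t in truth if t.species == kernel.species]
            )
            se = kernel.sd_displacement / math.sqrt(len(disp))
            assert abs(disp.mean() - kernel.mu_displacement) < 3 * se
            assert disp.std(ddof=1) == pytest.approx(kernel.sd_displacement, rel=0.15)

    def test_sample_effect_shared_within_faecal_sample(self, line):
        quiet = dataclasses.replace(line, residual_sd=0.0)
        cfg = SimulationConfig(
            line=quiet,
            dispersers=(DisperserKernel("bear", 0.0, 50.0, 3450.0),),
            n_seeds_per_species=9,
            measurement_sd=0.0,
            sample_effect_sd=5.0,
            seeds_per_faecal_sample=3,
            rng_seed=2,
        )
        seeds, truth = generate_dispersal_events(cfg)
        # residual of delta vs line(mother) is exactly the shared effect
        effects = {}
        for s, t in zip(seeds, truth):
            effects.setdefault(s.faecal_sample_id, []).append(
                s.delta18O - float(quiet.predict(t.mother_altitude))
            )
        assert len(effects) == 3
        for vals in effects.values():
            assert max(vals) - min(vals) < 1e-9

    def test_impossible_kernel_fails_loudly(self, line):
        cfg = SimulationConfig(
            line=line,
            dispersers=(DisperserKernel("teleporter", -5000.0, 1.0, 10.0),),
            n_seeds_per_species=1,
            rng_seed=0,
        )
        with pytest.raises(RuntimeError, match="inconsistent"):
            generate_dispersal_events(cfg)


class TestDefaultStudyConfig:
    def test_published_constants(self):
        cfg = default_study_config()
        assert cfg.line.slope == pytest.approx(-0.0024)
        assert cfg.line.intercept == pytest.approx(19.0213)
        assert cfg.measurement_sd == pytest.approx(0.2)
        assert cfg.mountain_bounds[0] == 550.0
        assert cfg.mountain_bounds[1] == 1650.0
        assert len(cfg.dispersers) == 4
        mus = {k.species: k.mu_displacement for k in cfg.dispersers}
        assert mus["Asian black bear"] == pytest.approx(-393.1)
        assert mus["raccoon dog"] == pytest.approx(4.5)

    def test_invalid_configs_rejected(self, line):
        kernel = DisperserKernel("bear", 0.0, 10.0, 100.0)
        with pytest.raises(ValueError):
            SimulationConfig(line=line, dispersers=(kernel,), n_seeds_per_species=0)
        with pytest.raises(ValueError):
            SimulationConfig(line=line, dispersers=(kernel,), mountain_bounds=(1650, 550))
        with pytest.raises(ValueError):
            DisperserKernel("bear", 0.0, -1.0, 100.0)
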