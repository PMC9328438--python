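"""Simulator: emission statistics, diffusion law, dark-state kinetics,
determinism, and the dose-response generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fflux.simkit import (DetectionVolume, DoseResponseDataset, PhotonTrace,
                          SimulationConfig, SpeciesSpec,
                          generate_dose_response, simulate_calibration_trace,
                          simulate_dark_trajectory, simulate_trace,
                          simulate_trajectories)

VOL = DetectionVolume(0.2, 5.0)


def small_config(**kw):
    defaults = dict(volume=VOL,
                    species=(SpeciesSpec("2d", 0.2, 20.0, 20_000.0),),
                    duration=0.05, bin_time=1e-4, dt=1e-4, box_scale=5.0,
                    seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDomainTypes:
    def test_detection_volume_invariants(self):
        assert VOL.beam_area == pytest.approx(math.pi * 0.04, rel=1e-15)
        assert VOL.axial_radius == 1.0
        with pytest.raises(ValueError):
            DetectionVolume(-0.1)
        with pytest.raises(ValueError):
            DetectionVolume(0.2, S=0.5)

    @pytest.mark.parametrize("bad", [
        dict(dimensionality="1d", D=1, density=1, epsilon=1),
        dict(dimensionality="2d", D=-1, density=1, epsilon=1),
        dict(dimensionality="2d", D=1, density=-1, epsilon=1),
        dict(dimensionality="2d", D=1, density=1, epsilon=-1),
        dict(dimensionality="2d", D=1, density=1, epsilon=1, T=1.0),
        dict(dimensionality="2d", D=1, density=1, epsilon=1, tau_dark=0),
    ])
    def test_species_invariants(self, bad):
        with pytest.raises(ValueError):
            SpeciesSpec(**bad)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            small_config(duration=1e-5)          # duration < bin_time
        with pytest.raises(ValueError):
            small_config(dt=1e-3)                # dt > bin_time
        with pytest.raises(ValueError):
            small_config(box_scale=2.0)
        with pytest.raises(ValueError):
            small_config(bin_time=1e-4, dt=3e-5)  # not an integer divisor

    def test_trace_length_invariant(self):
        with pytest.raises(ValueError):
            PhotonTrace(np.zeros(10, int), 1e-4, 2e-3)
        with pytest.raises(ValueError):
            PhotonTrace(np.array([1, -1]), 1e-4, 2e-4)

    def test_trace_rebin_conserves_counts(self):
        tr = simulate_trace(small_config())
        rb = tr.rebin(5)
        assert rb.bin_time == pytest.approx(5e-4)
        assert rb.counts.sum() == tr.counts[:rb.n_bins * 5].sum()


class TestSimulateTrace:
    def test_zero_brightness_gives_all_zero_counts(self):
        cfg = small_config(species=(SpeciesSpec("2d", 0.2, 20.0, 0.0),))
        tr = simulate_trace(cfg)
        assert np.all(tr.counts == 0)

    def test_empty_species_zero_background_rejected(self):
        with pytest.raises(ValueError, match="empty species"):
            simulate_trace(small_config(species=()))

    def test_background_only(self):
        cfg = small_config(species=(), background=50_000.0, duration=0.2)
        tr = simulate_trace(cfg)
        total = tr.counts.sum()
        expect = 50_000.0 * 0.2
        assert abs(total - expect) < 4 * math.sqrt(expect)

    def test_unresolved_dark_kinetics_rejected(self):
        sp = SpeciesSpec("2d", 0.2, 20.0, 1e4, T=0.2, tau_dark=1e-6)
        with pytest.raises(ValueError, match="dark-state"):
            simulate_trace(small_config(species=(sp,)))

    def test_seed_determinism(self):
        cfg = small_config()
        t1 = simulate_trace(cfg)
        t2 = simulate_trace(cfg)
        assert np.array_equal(t1.counts, t2.counts)
        t3 = simulate_trace(small_config(seed=8))
        assert not np.array_equal(t1.counts, t3.counts)

    def test_count_conservation_against_rate_oracle(self):
        """Total counts agree with the brute-force sum of per-bin Poisson
        rates within 3σ, and the rate itself matches the analytic
        ε·density·∫MDF mean (2D: π·ω²/2) within particle-number noise."""
        cfg = small_config(duration=12.0, seed=3)
        tr = simulate_trace(cfg, return_rates=True)
        rates = tr.metadata["bin_rates"]
        assert tr.n_bins >= 1e5
        total, expect = tr.counts.sum(), rates.sum()
        assert abs(total - expect) < 3 * math.sqrt(expect)
        analytic = 20.0 * 20_000.0 * math.pi * 0.04 / 2
        # mean rate fluctuates with the Poisson particle number (~320 here)
        assert rates.mean() / 1e-4 == pytest.approx(analytic, rel=0.2)

    def test_3d_mean_rate_analytic(self):
        """3D species: mean rate = ε·c·(π/2)^{3/2}·ω³·S, cross-checked
        against the per-bin rate oracle on the same trajectories.  The
        per-seed rate carries Poisson particle-number and slow axial-
        transit noise, so three seeds are averaged."""
        means = []
        for seed in (11, 12, 13):
            sp = SpeciesSpec("3d", 30.0, 30.0, 50_000.0)
            cfg = small_config(species=(sp,), duration=2.0, bin_time=1e-5,
                               dt=1e-5, seed=seed)
            tr = simulate_trace(cfg, return_rates=True)
            rates = tr.metadata["bin_rates"]
            assert abs(tr.counts.sum() - rates.sum()) < \
                3 * math.sqrt(rates.sum())
            means.append(rates.mean() / 1e-5)
        analytic = 50_000.0 * 30.0 * (math.pi / 2) ** 1.5 * 0.2**3 * 5.0
        assert np.mean(means) == pytest.approx(analytic, rel=0.12)

    @pytest.mark.parametrize("ndim,factor", [(2, 4.0), (3, 6.0)])
    def test_msd_diffusion_law(self, ndim, factor):
        """Mean squared displacement equals 2·ndim·D·t within 5% at
        t = 100·dt, averaged over 2000 particles."""
        D, dt = 0.5, 1e-5
        pos = simulate_trajectories(2000, D, dt, 100, ndim=ndim, seed=5)
        msd = np.mean(np.sum((pos[100] - pos[0]) ** 2, axis=1))
        assert msd == pytest.approx(factor * D * 100 * dt, rel=0.05)

    def test_dark_state_occupancy(self):
        """Long-run dark fraction equals T within 2% (relative) for
        T = 0.2, tau_dark = 5 μs over a 1 s trajectory."""
        dark = simulate_dark_trajectory(T=0.2, tau_dark=5e-6, dt=1e-6,
                                        n_steps=1_000_000, seed=1)
        assert dark.mean() == pytest.approx(0.2, rel=0.02)


class TestCalibrationTrace:
    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration_trace(280.0, VOL, concentration=0.0)

    def test_negative_dref_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration_trace(-1.0, VOL, concentration=1.0)

    def test_metadata_records_reference(self):
        tr = simulate_calibration_trace(280.0, VOL, concentration=1.0,
                                        duration=0.01, bin_time=1e-5,
                                        dt=1e-6, tau_dark=8e-6)
        assert tr.metadata["D_ref"] == 280.0


class TestDoseResponseGenerator:
    CONCS = np.logspace(-10, -6.5, 8)

    def test_half_maximal_at_ec50(self):
        ec50 = 1e-7
        d = generate_dose_response(80.0, 7.0, [ec50 / 100, ec50, ec50 * 100],
                                   0.0, basal=5.0)
        assert d.responses[1, 0] == pytest.approx(5.0 + 40.0, abs=1e-12)

    def test_saturation_limit(self):
        d = generate_dose_response(80.0, 7.0, [1e-9, 1e-7 * 1e6], 0.0,
                                   basal=5.0)
        assert d.responses[-1, 0] == pytest.approx(85.0, rel=1e-4)

    def test_noise_seeded(self):
        d1 = generate_dose_response(100.0, 7.35, self.CONCS, 5.0, seed=3)
        d2 = generate_dose_response(100.0, 7.35, self.CONCS, 5.0, seed=3)
        assert np.array_equal(d1.responses, d2.responses)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_dose_response(1.0, 7.0, [0.0, 1e-7], 0.0)
        with pytest.raises(ValueError):
            generate_dose_response(1.0, 7.0, self.CONCS, -1.0)

    @given(st.floats(min_value=5.0, max_value=9.0))
    @settings(max_examples=20, deadline=None)
    def test_noiseless_response_is_monotone(self, pec50):
        d = generate_dose_response(50.0, pec50, self.CONCS, 0.0)
        assert np.all(np.diff(d.responses[:, 0]) > 0)

    def test_dataset_invariants(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(np.array([1e-7, 1e-8]), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            DoseResponseDataset(np.array([-1e-7, 1e-8]), np.zeros((2, 1)))
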