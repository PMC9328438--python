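"""ACF models: hand-computed evaluations, exact noiseless roundtrips,
calibration arithmetic, and the derived-quantity conversions."""

import math

import numpy as np
import pytest

from fflux import acfmodels
from fflux.acfmodels import (ACFComponent, ACFFitResult, CalibrationResult,
                             TripletParams, acf_eval, derive_density,
                             derive_diffusion, fit_calibration,
                             fit_ligand_acf, fit_membrane_acf)
from fflux.simkit import DetectionVolume

from conftest import make_noiseless_curve

VOL = DetectionVolume(0.2, 5.0)
LAGS = np.logspace(-6, -0.7, 160)


class TestAcfEval:
    def test_half_decay_at_tau_d(self):
        G = acf_eval("membrane", dict(N=1.0, T=0.0, tau_D1=1e-3, f1=1.0,
                                      tau_D2=1.0, f2=0.0), [1e-3])
        assert G[0] == pytest.approx(0.5, abs=1e-12)

    def test_3d_reduces_to_2d_for_large_s(self):
        p3 = dict(N=2.0, T=0.0, tau_D1=5e-4, S=1e6)
        p2 = dict(N=2.0, T=0.0, tau_D1=5e-4, f1=1.0, tau_D2=1.0, f2=0.0)
        assert np.allclose(acf_eval("calibration", p3, LAGS),
                           acf_eval("membrane", p2, LAGS), rtol=1e-6)

    def test_two_component_hand_value(self):
        # f = (0.5, 0.5), tau = (1, 10) ms at tau = 1 ms:
        # G*N = 0.5*(0.5 + 1/1.1) = 0.70455
        G = acf_eval("membrane", dict(N=1.0, T=0.0, tau_D1=1e-3, f1=0.5,
                                      tau_D2=1e-2, f2=0.5), [1e-3])
        assert G[0] == pytest.approx(0.5 * (0.5 + 1 / 1.1), abs=1e-12)

    def test_zero_lag_amplitude_with_triplet(self):
        p = dict(N=4.0, T=0.2, tau_tr=5e-6, tau_D1=1e-3, S=5.0)
        G0 = acf_eval("calibration", p, [0.0])[0]
        assert G0 == pytest.approx((1 / 4.0) * (1 + 0.2 / 0.8), rel=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            acf_eval("membrane", dict(N=1.0, tau_D1=1e-3, f1=0.6,
                                      tau_D2=1e-2, f2=0.6), LAGS)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            acf_eval("exotic", {}, LAGS)


class TestTypes:
    def test_triplet_invariants(self):
        with pytest.raises(ValueError):
            TripletParams(1.0, 1e-6)
        with pytest.raises(ValueError):
            TripletParams(0.1, 0.0)
        assert TripletParams(0.0, 1e-6).factor(LAGS)[0] == 1.0

    def test_component_ordering_enforced(self):
        comps = [ACFComponent("2d", 1e-2, 0.5), ACFComponent("2d", 1e-3, 0.5)]
        with pytest.raises(ValueError, match="sorted"):
            ACFFitResult(N_total=1.0, components=comps,
                         triplet=TripletParams(0, 1e-6), chisq=0.0)

    def test_calibration_result_invariants(self):
        with pytest.raises(ValueError):
            CalibrationResult(tau_D_cal=3.57e-5, omega=0.3,
                              beam_area=math.pi * 0.09, S=5.0, D_ref=280.0)


class TestCalibration:
    PARAMS = dict(N=5.0, T=0.15, tau_tr=4e-6, tau_D1=3.6e-5, S=5.0)

    def test_noiseless_roundtrip_exact(self):
        curve = make_noiseless_curve("calibration", self.PARAMS, LAGS)
        res = fit_calibration(curve, D_ref=280.0, fit_window=(1e-6, 1e-2))
        assert res.tau_D_cal == pytest.approx(3.6e-5, rel=1e-6)
        assert res.S == pytest.approx(5.0, rel=1e-4)
        assert res.N_total == pytest.approx(5.0, rel=1e-5)
        assert res.triplet.T == pytest.approx(0.15, rel=1e-4)

    def test_beam_waist_hand_arithmetic(self):
        # tau_D = 35.7 us at D_ref = 280 um^2/s -> omega = 0.19996 um
        curve = make_noiseless_curve(
            "calibration", dict(self.PARAMS, tau_D1=3.57e-5), LAGS)
        res = fit_calibration(curve, D_ref=280.0, fit_window=(1e-6, 1e-2))
        assert res.omega == pytest.approx(math.sqrt(4 * 3.57e-5 * 280.0),
                                          rel=1e-5)
        assert res.omega == pytest.approx(0.19996, rel=1e-4)
        assert res.beam_area == pytest.approx(0.1256, rel=1e-3)

    def test_short_curve_rejected(self):
        lags = np.logspace(-5, -3.5, 30)
        curve = make_noiseless_curve("calibration", self.PARAMS, lags)
        with pytest.raises(acfmodels.FitError, match="decades"):
            fit_calibration(curve, 280.0)


class TestMembraneFit:
    def test_noiseless_two_component_roundtrip(self):
        params = dict(N=4.0, T=0.1, tau_tr=8e-6, tau_D1=5e-3, f1=0.6,
                      tau_D2=8e-2, f2=0.4)
        curve = make_noiseless_curve("membrane", params, LAGS)
        fit = fit_membrane_acf(curve, VOL)
        assert not fit.degenerate_refit
        assert fit.N_total == pytest.approx(4.0, rel=1e-5)
        taus = [c.tau_D for c in fit.components]
        fracs = [c.fraction for c in fit.components]
        assert taus == sorted(taus)
        assert taus[0] == pytest.approx(5e-3, rel=1e-5)
        assert taus[1] == pytest.approx(8e-2, rel=1e-5)
        assert fracs[0] == pytest.approx(0.6, abs=1e-5)
        assert fit.triplet.T == pytest.approx(0.1, abs=1e-4)

    def test_start_permutation_invariance(self):
        """The multi-start winner does not depend on the order in which
        the starts are tried."""
        params = dict(N=4.0, T=0.0, tau_D1=5e-3, f1=0.6, tau_D2=8e-2, f2=0.4)
        curve = make_noiseless_curve("membrane", params, LAGS)
        starts = [
            {"A1": 0.2, "A2": 0.05, "tau_D2": 1e-3, "ratio": 4.0,
             "T": 0.05, "tau_tr": 5e-6},
            {"A1": 0.01, "A2": 0.3, "tau_D2": 3e-2, "ratio": 20.0,
             "T": 0.2, "tau_tr": 2e-5},
            {"A1": 0.12, "A2": 0.12, "tau_D2": 8e-3, "ratio": 8.0,
             "T": 0.0, "tau_tr": 1e-5},
        ]
        f1 = fit_membrane_acf(curve, VOL, starts=starts)
        f2 = fit_membrane_acf(curve, VOL, starts=starts[::-1])
        assert f1.N_total == pytest.approx(f2.N_total, rel=1e-9)
        assert [c.tau_D for c in f1.components] == \
            pytest.approx([c.tau_D for c in f2.components], rel=1e-9)

    def test_degenerate_pair_collapses_to_single(self):
        """Two dwell times within a factor 2 are not resolvable: the fit
        is flagged and refit with one 2D component."""
        params = dict(N=4.0, T=0.0, tau_D1=5e-2, f1=0.5, tau_D2=7e-2, f2=0.5)
        curve = make_noiseless_curve("membrane", params, LAGS)
        fit = fit_membrane_acf(curve, VOL)
        assert fit.degenerate_refit
        assert len([c for c in fit.components if c.kind == "2d"]) == 1
        # the single component sits between the two generating dwell times
        assert 4e-2 < fit.components[0].tau_D < 9e-2


class TestLigandFit:
    def test_noiseless_three_component_roundtrip(self):
        params = dict(N=2.0, T=0.05, tau_tr=5e-6, tau_D1=1e-4, f1=0.3,
                      tau_D2=7e-3, f2=0.3, tau_D3=7e-2, f3=0.4, S=5.0)
        curve = make_noiseless_curve("ligand", params, LAGS)
        fit = fit_ligand_acf(curve, VOL, tau_D1_fixed=1e-4)
        assert fit.N_total == pytest.approx(2.0, rel=1e-4)
        by_kind = {c.kind: c for c in fit.components if c.kind == "3d"}
        assert by_kind["3d"].tau_D == 1e-4
        taus2d = sorted(c.tau_D for c in fit.components if c.kind == "2d")
        assert taus2d[0] == pytest.approx(7e-3, rel=1e-4)
        assert taus2d[1] == pytest.approx(7e-2, rel=1e-4)

    def test_pure_free_ligand_has_no_membrane_fraction(self):
        """With no membrane species the 2D fractional amplitudes vanish."""
        params = dict(N=2.0, T=0.0, tau_D1=1e-4, S=5.0)
        curve = make_noiseless_curve("calibration", params, LAGS)
        fit = fit_ligand_acf(curve, VOL, tau_D1_fixed=1e-4)
        f2d = sum(c.fraction for c in fit.components if c.kind == "2d")
        assert f2d < 0.05

    def test_invalid_fixed_dwell_rejected(self):
        curve = make_noiseless_curve(
            "calibration", dict(N=2.0, T=0.0, tau_D1=1e-4, S=5.0), LAGS)
        with pytest.raises(ValueError):
            fit_ligand_acf(curve, VOL, tau_D1_fixed=-1.0)


class TestDerivedQuantities:
    def test_diffusion_hand_arithmetic(self):
        # omega = 0.2 um, tau_D = 50 us -> D = 0.04/(4*5e-5) = 200
        assert derive_diffusion(5e-5, VOL) == pytest.approx(200.0, rel=1e-12)

    def test_diffusion_roundtrip_identity(self):
        D = 0.13
        tau = VOL.omega_xy**2 / (4 * D)
        assert derive_diffusion(tau, VOL) == pytest.approx(D, rel=1e-14)

    def test_table_scale_conversion(self):
        assert derive_diffusion(76.9e-3, VOL) == pytest.approx(0.13, rel=1e-2)

    def _fit(self, fraction, n_total=10.0):
        comps = [ACFComponent("2d", 1e-2, fraction),
                 ACFComponent("2d", 1e-1, 1.0 - fraction)]
        return ACFFitResult(N_total=n_total, components=comps,
                            triplet=TripletParams(0.0, 1e-6), chisq=1.0)

    def test_density_hand_arithmetic(self):
        # N = 10, f = 0.5, omega = 0.25 -> 5/0.19635 = 25.46 /um^2
        vol = DetectionVolume(0.25, 5.0)
        comps = [ACFComponent("3d", 1e-4, 0.5), ACFComponent("2d", 1e-2, 0.5)]
        fit = ACFFitResult(N_total=10.0, components=comps,
                           triplet=TripletParams(0.0, 1e-6), chisq=1.0)
        assert derive_density(fit, vol, "sum_2d") == \
            pytest.approx(25.46, rel=1e-3)

    def test_zero_fraction_gives_zero_density(self):
        comps = [ACFComponent("3d", 1e-4, 1.0), ACFComponent("2d", 1e-2, 0.0)]
        fit = ACFFitResult(N_total=10.0, components=comps,
                           triplet=TripletParams(0.0, 1e-6), chisq=1.0)
        assert derive_density(fit, VOL, "slowest_2d") == 0.0

    def test_selector_slowest_vs_sum(self):
        fit = self._fit(0.3)
        area = VOL.beam_area
        assert derive_density(fit, VOL, "sum_2d") == \
            pytest.approx(10.0 / area)
        assert derive_density(fit, VOL, "slowest_2d") == \
            pytest.approx(0.7 * 10.0 / area)

    def test_unconverged_fit_rejected(self):
        fit = self._fit(0.5)
        fit.converged = False
        with pytest.raises(acfmodels.FitError):
            derive_density(fit, VOL)
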