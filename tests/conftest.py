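"""Shared fixtures: simulated traces at the published ground truths.

Heavy Brownian-dynamics simulations are session-scoped and reused by the
unit and acceptance tests.  All seeds are fixed constants so the whole
suite is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np
import pytest

from fflux import acfmodels, correlator, pch, presets, simkit

BASE_SEED = 20260923


def seeds_for(tag: str, n: int) -> list[int]:
    """Deterministic per-purpose seed streams (crc32: stable across runs)."""
    ss = np.random.SeedSequence([BASE_SEED, zlib.crc32(tag.encode())])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


@pytest.fixture(scope="session")
def volume():
    return presets.DEFAULT_VOLUME


def _membrane_set(name, n, tag, factory):
    out = []
    for seed in seeds_for(tag, n):
        trace = simkit.simulate_trace(factory(name, seed=seed))
        curve = correlator.autocorrelate(trace)
        hist = pch.compute_pch(trace, 1e-4)
        out.append((curve, hist))
    return out


@pytest.fixture(scope="session")
def vehicle_set():
    """20 seeded 30 s traces at the GFP-receptor vehicle ground truths."""
    return _membrane_set("gfp_vehicle", 20, "vehicle",
                         presets.membrane_condition)


@pytest.fixture(scope="session")
def bifc_set():
    """20 seeded 30 s traces at the BiFC vehicle ground truths."""
    return _membrane_set("bifc_vehicle", 20, "bifc", presets.bifc_condition)


@pytest.fixture(scope="session")
def vehicle_fits(vehicle_set, volume):
    return [acfmodels.fit_membrane_acf(curve, volume)
            for curve, _ in vehicle_set]


@pytest.fixture(scope="session")
def r6g_calibration(volume):
    """One simulated Rhodamine 6G calibration read and its beam-waist fit."""
    cal = presets.CALIBRATION
    trace = simkit.simulate_calibration_trace(
        D_ref=cal["D_ref"], volume=volume,
        concentration=cal["concentration"], epsilon=cal["epsilon"],
        duration=cal["duration"], seed=seeds_for("r6g", 1)[0], T=cal["T"],
        tau_dark=cal["tau_dark"], bin_time=cal["bin_time"], dt=cal["dt"],
        box_scale=cal["box_scale"])
    curve = correlator.autocorrelate(trace)
    return acfmodels.fit_calibration(curve, cal["D_ref"])


@pytest.fixture(scope="session")
def pch_correction_F(volume):
    """Frozen first-order correction from a 20 nM dye histogram at 20 μs."""
    cal = presets.PCH_CALIBRATION
    trace = simkit.simulate_calibration_trace(
        D_ref=cal["D_ref"], volume=volume,
        concentration=cal["concentration"], epsilon=cal["epsilon"],
        duration=cal["duration"], seed=seeds_for("pch-cal", 1)[0],
        T=cal["T"], tau_dark=cal["tau_dark"], bin_time=cal["bin_time"],
        dt=cal["dt"], box_scale=cal["box_scale"])
    hist = pch.compute_pch(trace, 2e-5)
    return pch.calibrate_pch_correction(hist).F


def make_noiseless_curve(model: str, params: dict,
                         lags: np.ndarray) -> correlator.CorrelationCurve:
    """Exact model curve with uniform weights, for roundtrip fits."""
    G = acfmodels.acf_eval(model, params, lags)
    return correlator.CorrelationCurve(lags, G, np.full(len(lags), 1e6),
                                       mean_rate=float("nan"),
                                       bin_time=lags[0])
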