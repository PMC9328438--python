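"""FCS autocorrelation models, calibration, and derived quantities.

Three model variants are supported, all of the form

    G(τ) = (1/N)·(1 + T/(1−T)·exp(−τ/τ_tr)) · Σ_i f_i·g_i(τ)

with g_2D(τ) = (1 + τ/τ_Di)⁻¹ for membrane species and
g_3D(τ) = (1 + τ/τ_Di)⁻¹·(1 + τ/(S²·τ_Di))^(−1/2) for solution species:

- ``calibration``: one free 3D component plus the dark-state
  (triplet) pre-exponential term, fitted to a reference dye of known D
  to determine the beam waist ω = √(4·τ_D·D_ref) and area A = π·ω².
- ``ligand``: one 3D component with fixed τ_D1 (free fluorescent ligand,
  dwell time taken from a ligand-in-buffer fit) plus two free 2D
  components (receptor-bound ligand) and the triplet term.
- ``membrane``: two free 2D components plus a pre-exponential term for
  fluorophore photophysics (GFP / complemented-YFP dark states).

Dwell times convert to diffusion coefficients via D = ω²/(4·τ_D) and
component particle densities via density = f·N/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .correlator import CorrelationCurve
from .simkit import DetectionVolume

__all__ = [
    "TripletParams", "ACFComponent", "ACFFitResult", "CalibrationResult",
    "FitError", "acf_eval", "fit_calibration", "fit_ligand_acf",
    "fit_membrane_acf", "derive_diffusion", "derive_density",
]

#: default fit window (s): excludes afterpulsing-scale lags and the
#: poorly averaged long-lag tail of a 30 s read
FIT_WINDOW = (4e-6, 0.3)
#: calibration fit window (s): a fast dye's decay is complete well below
#: a millisecond, and longer lags of a short calibration read carry
#: mostly normalization noise
CAL_FIT_WINDOW = (4e-6, 6e-4)
#: upper bound on the photophysics relaxation time (s)
TAU_TR_MAX = 5e-5
#: two 2D dwell times closer than this factor are treated as degenerate
DEGENERACY_RATIO = 2.0


class FitError(RuntimeError):
    """A model fit failed to converge or hit a hard bound."""


@dataclass(frozen=True)
class TripletParams:
    """Dark-state pre-exponential term: fraction T, relaxation time tau_tr."""

    T: float
    tau_tr: float

    def __post_init__(self) -> None:
        if not 0 <= self.T < 1:
            raise ValueError("T must be in [0, 1)")
        if not self.tau_tr > 0:
            raise ValueError("tau_tr must be positive")

    def factor(self, lags: np.ndarray) -> np.ndarray:
        if self.T == 0:
            return np.ones_like(np.asarray(lags, dtype=float))
        return 1.0 + self.T / (1.0 - self.T) * np.exp(-np.asarray(lags) / self.tau_tr)


@dataclass(frozen=True)
class ACFComponent:
    """One diffusing component of an autocorrelation model."""

    kind: str          # "2d" | "3d"
    tau_D: float       # dwell time, s
    fraction: float    # fractional amplitude, 0..1
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("2d", "3d"):
            raise ValueError("kind must be '2d' or '3d'")
        if not self.tau_D > 0:
            raise ValueError("tau_D must be positive")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")

    def g(self, lags: np.ndarray, S: float | None = None) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        g = 1.0 / (1.0 + lags / self.tau_D)
        if self.kind == "3d":
            if S is None:
                raise ValueError("3D component requires a structure parameter")
            g = g / np.sqrt(1.0 + lags / (S * S * self.tau_D))
        return g


@dataclass
class ACFFitResult:
    """Fitted autocorrelation model with derived per-component quantities."""

    N_total: float
    components: list[ACFComponent]
    triplet: TripletParams
    chisq: float
    S: float | None = None
    derived_D: list[float] = field(default_factory=list)
    derived_density: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate_refit: bool = False
    model: str = ""
    offset: float = 0.0  # fitted G(∞) baseline (estimator nuisance)

    def __post_init__(self) -> None:
        if not self.N_total > 0:
            raise ValueError("N_total must be positive")
        taus = [c.tau_D for c in self.components]
        if any(t2 < t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("components must be sorted by increasing tau_D")

    @property
    def dominant_2d(self) -> ACFComponent:
        """The 2D component with the largest fractional amplitude."""
        comps = [c for c in self.components if c.kind == "2d"]
        if not comps:
            raise ValueError("fit has no 2D component")
        return max(comps, key=lambda c: c.fraction)

    def dominant_2d_D(self, volume: DetectionVolume) -> float:
        return derive_diffusion(self.dominant_2d.tau_D, volume)


@dataclass
class CalibrationResult:
    """Beam-waist calibration from a reference dye of known D."""

    tau_D_cal: float
    omega: float
    beam_area: float
    S: float
    D_ref: float
    N_total: float = float("nan")
    triplet: TripletParams | None = None
    chisq: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.omega - math.sqrt(4.0 * self.tau_D_cal * self.D_ref)) > \
                1e-9 * self.omega:
            raise ValueError("omega must equal sqrt(4*tau_D_cal*D_ref)")
        if abs(self.beam_area - math.pi * self.omega**2) > 1e-9 * self.beam_area:
            raise ValueError("beam_area must equal pi*omega^2")

    @property
    def volume(self) -> DetectionVolume:
        return DetectionVolume(self.omega, self.S)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def acf_eval(model: str, params: dict, lags) -> np.ndarray:
    """Evaluate one of the three autocorrelation models at ``lags``.

    ``params`` keys: ``N``, ``T``, ``tau_tr``; per-component ``tau_D<i>``
    and ``f<i>`` (fractions must sum to 1); ``S`` for models with a 3D
    component.  Component 1 is 3D in the calibration and ligand models;
    all others are 2D.
    """
    lags = np.asarray(lags, dtype=float)
    if model == "calibration":
        kinds = ["3d"]
    elif model == "ligand":
        kinds = ["3d", "2d", "2d"]
    elif model == "membrane":
        kinds = ["2d", "2d"]
    else:
        raise ValueError(f"unknown model '{model}'")
    idx = range(1, len(kinds) + 1)
    fracs = [params.get(f"f{i}", 1.0) for i in idx] if len(kinds) > 1 else [1.0]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("component fractions must sum to 1")
    triplet = TripletParams(params.get("T", 0.0), params.get("tau_tr", 1e-6))
    S = params.get("S")
    total = np.zeros_like(lags)
    for kind, i, f in zip(kinds, idx, fracs):
        comp = ACFComponent(kind, params[f"tau_D{i}"], min(max(f, 0.0), 1.0))
        total += f * comp.g(lags, S)
    return triplet.factor(lags) * total / params["N"]


def _decay_curve(model, kinds, lags, p, S):
    """Amplitude-parameterized model: G = triplet · Σ A_i·g_i."""
    T = p["T"]
    tau_tr = p["tau_tr"]
    trip = 1.0 + T / (1.0 - T) * np.exp(-lags / tau_tr) if T > 0 else 1.0
    total = np.zeros_like(lags)
    for i, kind in enumerate(kinds, start=1):
        tau = p[f"tau_D{i}"] if f"tau_D{i}" in p else p["tau_D2"] * p["ratio"]
        g = 1.0 / (1.0 + lags / tau)
        if kind == "3d":
            g = g / np.sqrt(1.0 + lags / (S * S * tau))
        total = total + p[f"A{i}"] * g
    return trip * total


def _fit_window(curve: CorrelationCurve, window=FIT_WINDOW):
    mask = (curve.lags >= window[0]) & (curve.lags <= window[1])
    if mask.sum() < 8:
        raise FitError("fewer than 8 lag points inside the fit window")
    return curve.lags[mask], curve.G[mask], curve.sigma[mask]


def _run_multistart(build_params, starts, residual):
    best = None
    for start in starts:
        params = build_params(start)
        try:
            res = lmfit.minimize(residual, params, method="least_squares",
                                 nan_policy="omit")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitError("no fit start converged")
    return best


def _jittered(base: dict, n_starts: int, rng: np.random.Generator):
    """The base start plus log-jittered copies of every positive entry."""
    starts = [dict(base)]
    for _ in range(n_starts - 1):
        s = {}
        for k, v in base.items():
            if k in ("T",):
                s[k] = min(0.6, max(0.0, v + rng.uniform(-0.05, 0.1)))
            elif v > 0:
                s[k] = v * 10 ** rng.uniform(-0.5, 0.5)
            else:
                s[k] = v
        starts.append(s)
    return starts


def _amp_guess(lags, G):
    """Crude amplitude and half-decay-time guesses from the curve."""
    head = max(3, len(G) // 20)
    amp = float(np.median(G[:head]))
    if not amp > 0:
        amp = max(float(np.max(G)), 1e-3)
    below = np.nonzero(G < amp / 2.0)[0]
    tau = float(lags[below[0]]) if len(below) else float(lags[len(lags) // 2])
    return amp, tau


def fit_calibration(curve: CorrelationCurve, D_ref: float,
                    n_starts: int = 5,
                    starts: list[dict] | None = None,
                    fit_window: tuple[float, float] | None = None,
                    ) -> CalibrationResult:
    """Fit the single-3D-component + triplet calibration model.

    ``D_ref`` is the known diffusion coefficient of the reference dye;
    the fitted dwell time gives ω = √(4·τ_D·D_ref) and A = π·ω².  The
    structure parameter is fitted within [3, 10].
    """
    if curve.lags.max() / curve.lags.min() < 1e3:
        raise FitError("calibration curve must span >= 3 decades of lag")
    lags, G, sigma = _fit_window(curve, fit_window or CAL_FIT_WINDOW)
    amp, tau0 = _amp_guess(lags, G)
    base = {"A1": amp, "tau_D1": tau0, "S": 5.0, "T": 0.15, "tau_tr": 4e-6}
    rng = np.random.Generator(np.random.PCG64(12345))
    starts = starts if starts is not None else _jittered(base, n_starts, rng)

    def build(start):
        p = lmfit.Parameters()
        p.add("A1", value=start["A1"], min=1e-8)
        p.add("tau_D1", value=start["tau_D1"], min=lags[0] / 10,
              max=lags[-1] * 10)
        p.add("S", value=start["S"], min=3.0, max=10.0)
        # dye triplet kinetics are faster than the dwell time of a fast
        # calibration dye; a looser bound lets the pre-exponential term
        # absorb the diffusion decay itself
        p.add("T", value=start["T"], min=0.0, max=0.6)
        p.add("tau_tr", value=start["tau_tr"], min=1e-7, max=2e-5)
        # free baseline absorbs the finite-read normalization bias of the
        # correlation estimator (a small negative G(inf) offset)
        p.add("offset", value=0.0, min=-0.05 * amp, max=0.05 * amp)
        return p

    def residual(p):
        return (_decay_curve("calibration", ["3d"], lags, p, p["S"])
                + p["offset"] - G) / sigma

    res = _run_multistart(build, starts, residual)
    p = res.params
    tau_D = float(p["tau_D1"].value)
    if tau_D <= lags[0] / 9 or tau_D >= lags[-1] * 9:
        raise FitError("calibration dwell time pinned at a bound")
    omega = math.sqrt(4.0 * tau_D * D_ref)
    return CalibrationResult(
        tau_D_cal=tau_D, omega=omega, beam_area=math.pi * omega**2,
        S=float(p["S"].value), D_ref=D_ref, N_total=1.0 / float(p["A1"].value),
        triplet=TripletParams(float(p["T"].value), float(p["tau_tr"].value)),
        chisq=float(res.redchi))


def _fit_decay(model: str, kinds, curve: CorrelationCurve,
               volume: DetectionVolume | None, tau_fixed: float | None,
               n_starts: int, starts, fit_window=None):
    lags, G, sigma = _fit_window(curve, fit_window or FIT_WINDOW)
    S_val = volume.S if volume is not None else None
    amp, tau0 = _amp_guess(lags, G)
    n2d = sum(1 for k in kinds if k == "2d")
    base = {"T": 0.05, "tau_tr": 5e-6, "tau_D2": tau0, "ratio": 8.0}
    if model == "ligand":
        base.update({"A1": amp / 3, "A2": amp / 3, "A3": amp / 3})
    else:
        base.update({"A1": 0.7 * amp, "A2": 0.3 * amp})
    rng = np.random.Generator(np.random.PCG64(6789))
    start_list = starts if starts is not None else _jittered(base, n_starts, rng)

    two2d = n2d == 2

    def build(start):
        p = lmfit.Parameters()
        for i in range(1, len(kinds) + 1):
            p.add(f"A{i}", value=max(start[f"A{i}"], 1e-8), min=0.0)
        if model == "ligand":
            p.add("tau_D1", value=tau_fixed, vary=False)
        # first free 2D dwell time and the >1 ratio to the second
        p.add("tau_D2", value=start["tau_D2"], min=curve.lags[0] / 10,
              max=FIT_WINDOW[1] * 30)
        p.add("ratio", value=max(start["ratio"], 1.01), min=1.0, max=1e4)
        p.add("T", value=start["T"], min=0.0, max=0.8)
        p.add("tau_tr", value=start["tau_tr"], min=1e-7, max=TAU_TR_MAX)
        p.add("offset", value=0.0, min=-0.05 * amp, max=0.05 * amp)
        return p

    # component slots: for the membrane model the two 2D dwell times are
    # (tau_D2, tau_D2*ratio); for the ligand model the 3D slot is tau_D1
    # (fixed) and the 2D slots are tau_D2, tau_D2*ratio.
    def residual(p):
        v = {k: p[k].value for k in p}
        trip = 1.0
        if v["T"] > 0:
            trip = 1.0 + v["T"] / (1.0 - v["T"]) * np.exp(-lags / v["tau_tr"])
        tau2 = v["tau_D2"]
        tau3 = tau2 * v["ratio"]
        total = np.zeros_like(lags)
        slot = 0
        for i, kind in enumerate(kinds, start=1):
            if kind == "3d":
                tau1 = v["tau_D1"]
                g = 1.0 / (1.0 + lags / tau1) / np.sqrt(
                    1.0 + lags / (S_val * S_val * tau1))
            else:
                tau = tau2 if slot == 0 else tau3
                slot += 1
                g = 1.0 / (1.0 + lags / tau)
            total = total + v[f"A{i}"] * g
        return (trip * total + v["offset"] - G) / sigma

    res = _run_multistart(build, start_list, residual)

    # degenerate two-2D solution: dwell times within a factor DEGENERACY_RATIO
    degenerate = two2d and float(res.params["ratio"].value) < DEGENERACY_RATIO
    if degenerate:
        res = _refit_single_2d(model, kinds, lags, G, sigma, S_val, tau_fixed,
                               start_list)
        kinds_eff = [k for k in kinds if k == "3d"] + ["2d"]
    else:
        kinds_eff = list(kinds)

    result = _finalize_components(res, kinds_eff, model, S_val, volume,
                                  tau_fixed)
    result.degenerate_refit = degenerate
    return result


def _refit_single_2d(model, kinds, lags, G, sigma, S_val, tau_fixed,
                     start_list):
    """Collapse the two 2D components into one and refit."""
    has3d = "3d" in kinds
    amp2d = "A2" if has3d else "A1"

    def build(start):
        p = lmfit.Parameters()
        if has3d:
            p.add("A1", value=max(start["A1"], 1e-8), min=0.0)
            p.add("tau_D1", value=tau_fixed, vary=False)
        p.add(amp2d, value=max(start["A2"], 1e-8), min=0.0)
        p.add("tau_D2", value=start["tau_D2"], min=lags[0] / 10,
              max=FIT_WINDOW[1] * 30)
        p.add("T", value=start["T"], min=0.0, max=0.8)
        p.add("tau_tr", value=start["tau_tr"], min=1e-7, max=TAU_TR_MAX)
        amp = max(float(np.max(G)), 1e-3)
        p.add("offset", value=0.0, min=-0.05 * amp, max=0.05 * amp)
        return p

    def residual(p):
        trip = 1.0
        T = p["T"].value
        if T > 0:
            trip = 1.0 + T / (1.0 - T) * np.exp(-lags / p["tau_tr"].value)
        total = p[amp2d].value / (1.0 + lags / p["tau_D2"].value)
        if has3d:
            tau1 = p["tau_D1"].value
            total = total + p["A1"].value / (1.0 + lags / tau1) / np.sqrt(
                1.0 + lags / (S_val * S_val * tau1))
        return (trip * total + p["offset"].value - G) / sigma

    return _run_multistart(build, start_list, residual)


def _finalize_components(res, kinds_eff, model, S_val, volume, tau_fixed):
    p = res.params
    entries = []  # (kind, tau, amplitude, fixed)
    slot2d = 0
    amp_index = 1
    for kind in kinds_eff:
        A = float(p[f"A{amp_index}"].value)
        if kind == "3d":
            entries.append(("3d", float(p["tau_D1"].value), A, True))
        else:
            tau = float(p["tau_D2"].value)
            if slot2d == 1:
                tau *= float(p["ratio"].value)
            entries.append(("2d", tau, A, False))
            slot2d += 1
        amp_index += 1
    total_amp = sum(e[2] for e in entries)
    if not total_amp > 0:
        raise FitError("all component amplitudes collapsed to zero")
    N_total = 1.0 / total_amp
    components = sorted(
        (ACFComponent(k, t, A / total_amp, fx) for k, t, A, fx in entries),
        key=lambda c: c.tau_D)
    triplet = TripletParams(float(p["T"].value), float(p["tau_tr"].value))
    result = ACFFitResult(N_total=N_total, components=components,
                          triplet=triplet, chisq=float(res.redchi),
                          S=S_val, model=model,
                          offset=float(p["offset"].value))
    if volume is not None:
        result.derived_D = [derive_diffusion(c.tau_D, volume)
                            for c in components]
        result.derived_density = [
            c.fraction * N_total / volume.beam_area if c.kind == "2d" else 0.0
            for c in components]
    return result


def fit_ligand_acf(curve: CorrelationCurve, volume: DetectionVolume,
                   tau_D1_fixed: float, n_starts: int = 5,
                   starts: list[dict] | None = None,
                   fit_window: tuple[float, float] | None = None,
                   ) -> ACFFitResult:
    """Fit the fluorescent-ligand model: triplet term, one 3D component
    with fixed dwell time (free ligand) and two free 2D components
    (receptor-bound ligand).  Returns components sorted by τ_D; the
    slowest 2D component carries the bound-ligand signal.
    """
    if not tau_D1_fixed > 0:
        raise ValueError("tau_D1_fixed must be positive")
    return _fit_decay("ligand", ["3d", "2d", "2d"], curve, volume,
                      tau_D1_fixed, n_starts, starts, fit_window)


def fit_membrane_acf(curve: CorrelationCurve, volume: DetectionVolume,
                     n_starts: int = 5,
                     starts: list[dict] | None = None,
                     fit_window: tuple[float, float] | None = None,
                     ) -> ACFFitResult:
    """Fit the membrane-receptor model: two free 2D components plus a
    pre-exponential photophysics term.  If the two dwell times converge
    within a factor of 2 the solution is flagged degenerate and refit
    with a single 2D component.
    """
    return _fit_decay("membrane", ["2d", "2d"], curve, volume, None,
                      n_starts, starts, fit_window)


def derive_diffusion(tau_D: float, volume: DetectionVolume) -> float:
    """Convert a dwell time to a diffusion coefficient, D = ω²/(4·τ_D)."""
    if not tau_D > 0:
        raise ValueError("tau_D must be positive")
    return volume.omega_xy**2 / (4.0 * tau_D)


def derive_density(fit: ACFFitResult, volume: DetectionVolume,
                   component_selector: str = "sum_2d") -> float:
    """Particle density (N/μm²) of the membrane-bound component(s).

    ``component_selector``:

    - ``"sum_2d"`` (membrane/BiFC fits): all 2D fractional amplitudes
      summed, density = Σ f_2D · N_total / A.
    - ``"slowest_2d"`` (ligand fits): the slowest 2D component alone
      represents bound ligand.
    """
    if not fit.converged:
        raise FitError("cannot derive density from an unconverged fit")
    comps = [c for c in fit.components if c.kind == "2d"]
    if not comps:
        return 0.0
    if component_selector == "sum_2d":
        frac = sum(c.fraction for c in comps)
    elif component_selector == "slowest_2d":
        frac = max(comps, key=lambda c: c.tau_D).fraction
    else:
        raise ValueError("selector must be 'sum_2d' or 'slowest_2d'")
    return frac * fit.N_total / volume.beam_area
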