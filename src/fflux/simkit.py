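"""Forward simulation of confocal fluorescence-fluctuation experiments.

Brownian particles (freely diffusing 3D species in solution, 2D species
confined to the focal plane of a membrane) are propagated through a
3D-Gaussian detection volume; per-bin photon counts are drawn from a
Poisson distribution whose rate is the molecular detection function (MDF)
summed over all bright particles.  Reversible dark-state (triplet /
blinking) kinetics are modeled as a two-state telegraph process.

All lengths are in μm, times in seconds, diffusion coefficients in μm²/s,
and brightnesses in detected counts·molecule⁻¹·s⁻¹ at the center of the
detection volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "DetectionVolume",
    "SpeciesSpec",
    "SimulationConfig",
    "PhotonTrace",
    "DoseResponseDataset",
    "simulate_trace",
    "simulate_calibration_trace",
    "simulate_trajectories",
    "simulate_dark_trajectory",
    "generate_dose_response",
]

#: D of Rhodamine 6G in water, μm²/s (2.8e-6 cm²/s), used for 488 nm calibration.
D_RHODAMINE_6G = 280.0
#: D of Cy5 NHS ester in water, μm²/s (3.16e-6 cm²/s), used for 633 nm calibration.
D_CY5 = 316.0


@dataclass(frozen=True)
class DetectionVolume:
    """3D-Gaussian confocal detection volume.

    Parameters
    ----------
    omega_xy:
        Lateral 1/e² beam-waist radius at focus, μm.
    S:
        Structure parameter, the axial-to-lateral ratio of the volume
        (dimensionless, ≥ 1).  The axial 1/e² radius is ``S * omega_xy``.
    """

    omega_xy: float
    S: float = 5.0

    def __post_init__(self) -> None:
        if not self.omega_xy > 0:
            raise ValueError("omega_xy must be positive")
        if not self.S >= 1:
            raise ValueError("structure parameter S must be >= 1")

    @property
    def beam_area(self) -> float:
        """Beam area at the waist, A = π·ω², μm²."""
        return math.pi * self.omega_xy**2

    @property
    def axial_radius(self) -> float:
        """Axial 1/e² radius z₀ = S·ω, μm."""
        return self.S * self.omega_xy

    @property
    def effective_volume(self) -> float:
        """Effective Gaussian volume V_eff = π^{3/2}·ω²·z₀, μm³."""
        return math.pi**1.5 * self.omega_xy**2 * self.axial_radius

    def mdf(self, x, y, z):
        """Molecular detection function exp(−2(x²+y²)/ω² − 2z²/z₀²)."""
        w2 = self.omega_xy**2
        z02 = self.axial_radius**2
        return np.exp(-2.0 * (np.asarray(x) ** 2 + np.asarray(y) ** 2) / w2
                      - 2.0 * np.asarray(z) ** 2 / z02)


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing fluorescent species.

    ``density`` is particles/μm² for 2D (membrane) species and
    particles/μm³ for 3D (solution) species.  ``T`` is the stationary
    dark-state occupancy of the two-state telegraph photophysics and
    ``tau_dark`` its relaxation time.
    """

    dimensionality: str  # "2d" | "3d"
    D: float
    density: float
    epsilon: float
    T: float = 0.0
    tau_dark: float = 5e-6

    def __post_init__(self) -> None:
        if self.dimensionality not in ("2d", "3d"):
            raise ValueError("dimensionality must be '2d' or '3d'")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 <= self.T < 1:
            raise ValueError("dark fraction T must be in [0, 1)")
        if not self.tau_dark > 0:
            raise ValueError("tau_dark must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated photon trace."""

    volume: DetectionVolume
    species: tuple[SpeciesSpec, ...]
    duration: float = 30.0
    bin_time: float = 2e-6
    background: float = 0.0
    box_scale: float = 8.0
    dt: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.bin_time > 0 or self.duration < self.bin_time:
            raise ValueError("require duration >= bin_time > 0")
        if self.dt > self.bin_time:
            raise ValueError("dt must not exceed bin_time")
        if self.box_scale < 5:
            raise ValueError("box_scale must be >= 5")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        steps = self.bin_time / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("bin_time must be an integer multiple of dt")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    @property
    def box_half(self) -> float:
        """Lateral half-width of the periodic simulation box, μm."""
        return self.box_scale * self.volume.omega_xy

    @property
    def z_half(self) -> float:
        """Axial half-width, μm: at least 2.5 axial radii so the slow
        out-of-focus wings of the detection volume are not truncated."""
        return max(self.box_half, 2.5 * self.volume.axial_radius)


@dataclass
class PhotonTrace:
    """Binned photon-count time series, the raw observable of every stage."""

    counts: np.ndarray
    bin_time: float
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.counts) != int(round(self.duration / self.bin_time)):
            raise ValueError("length must equal round(duration / bin_time)")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate, counts/s."""
        return float(self.counts.sum()) / self.duration

    def rebin(self, factor: int) -> "PhotonTrace":
        """Sum counts over ``factor`` consecutive bins (remainder dropped)."""
        if factor < 1 or factor != int(factor):
            raise ValueError("rebin factor must be a positive integer")
        factor = int(factor)
        if factor == 1:
            return self
        n = (self.n_bins // factor) * factor
        counts = self.counts[:n].reshape(-1, factor).sum(axis=1)
        bt = self.bin_time * factor
        return PhotonTrace(counts, bt, len(counts) * bt, dict(self.metadata))


@dataclass
class DoseResponseDataset:
    """Concentration-response data: one row of ``responses`` per replicate.

    ``concentrations`` (molar) are unique and sorted ascending;
    ``responses`` has shape (n_concentrations, replicates).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] == 1 and self.replicates == 1:
            self.responses = self.responses.reshape(-1, 1)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be sorted strictly ascending")
        if self.responses.shape != (len(self.concentrations), self.replicates):
            raise ValueError("responses must have shape (n_conc, replicates)")


# ---------------------------------------------------------------------------
# Brownian-dynamics photon kernel
# ---------------------------------------------------------------------------

@njit(fastmath=True)
def _chunk_kernel(rates, steps, start_step, steps_per_bin, dt,
                  x, y, z, step_std, eps, is2d, has_z,
                  bright, next_flip, log1m_pbd, log1m_pdb, has_dark,
                  box_half, z_half, inv_w2, inv_z02, seed):  # pragma: no cover
    np.random.seed(seed)
    n_chunk = steps.shape[0]
    n = steps.shape[1]
    L = 2.0 * box_half
    Lz = 2.0 * z_half
    for s in range(n_chunk):
        gstep = start_step + s
        b = gstep // steps_per_bin
        rate = 0.0
        for i in range(n):
            xi = x[i] + step_std[i] * steps[s, i, 0]
            yi = y[i] + step_std[i] * steps[s, i, 1]
            if xi > box_half:
                xi -= L
            elif xi < -box_half:
                xi += L
            if yi > box_half:
                yi -= L
            elif yi < -box_half:
                yi += L
            x[i] = xi
            y[i] = yi
            zi = z[i]
            if has_z and not is2d[i]:
                zi = zi + step_std[i] * steps[s, i, 2]
                if zi > z_half:
                    zi -= Lz
                elif zi < -z_half:
                    zi += Lz
                z[i] = zi
            if has_dark and next_flip[i] == gstep:
                # toggle and schedule the next geometric dwell
                if bright[i] == 1:
                    bright[i] = 0
                    lg = log1m_pdb[i]
                else:
                    bright[i] = 1
                    lg = log1m_pbd[i]
                u = np.random.random()
                next_flip[i] = gstep + 1 + int(math.log(1.0 - u) / lg)
            if bright[i] == 1:
                arg = inv_w2 * (xi * xi + yi * yi) + inv_z02 * zi * zi
                if arg < 23.0:  # MDF < 1e-10: negligible
                    rate += eps[i] * math.exp(-arg)
        rates[b] += rate * dt


def _kernel_inputs(config: SimulationConfig, rng: np.random.Generator):
    """Draw per-species particle numbers and assemble flat per-particle arrays."""
    L = 2.0 * config.box_half
    step_std, eps, is2d, p_bd, p_db = [], [], [], [], []
    n_per_species = []
    for sp in config.species:
        measure = L**2 if sp.dimensionality == "2d" else L**2 * 2 * config.z_half
        n_p = int(rng.poisson(sp.density * measure))
        n_per_species.append(n_p)
        if sp.T > 0:
            # discrete telegraph with exact stationary occupancy T and
            # relaxation time tau_dark: per-step flip probabilities sum to
            # q = 1-exp(-dt/tau_dark) and split in the ratio T : (1-T)
            q = -math.expm1(-config.dt / sp.tau_dark)
            pbd = sp.T * q
            pdb = (1.0 - sp.T) * q
        else:
            pbd = pdb = 0.0
        step_std += [math.sqrt(2.0 * sp.D * config.dt)] * n_p
        eps += [sp.epsilon] * n_p
        is2d += [sp.dimensionality == "2d"] * n_p
        p_bd += [pbd] * n_p
        p_db += [pdb] * n_p
    return (np.array(step_std), np.array(eps), np.array(is2d, dtype=np.bool_),
            np.array(p_bd), np.array(p_db), n_per_species)


#: cap on the per-chunk Gaussian step buffer (number of float32 values)
_CHUNK_BUDGET = 24_000_000


def simulate_trace(config: SimulationConfig,
                   return_rates: bool = False) -> PhotonTrace:
    """Simulate one binned photon-count trace.

    Particles are placed uniformly in a periodic box of half-width
    ``box_scale·ω`` (2D species confined to the focal plane z = 0),
    propagated by Gaussian steps of standard deviation √(2·D·dt) per axis,
    toggled through the dark state by a telegraph process (geometric dwell
    schedule, equivalent to per-step Bernoulli flips), and photons are
    drawn per bin from Poisson(background·bin_time + Σ ε·MDF·dt).

    With ``return_rates=True`` the exact per-bin Poisson rates used for
    the draw are attached as ``metadata["bin_rates"]`` (diagnostics).
    Identical configs (same seed) give bit-identical traces.
    """
    if not config.species and config.background == 0:
        raise ValueError(
            "empty species list with zero background: request the all-zero "
            "trace explicitly with a zero-brightness species")
    for sp in config.species:
        if sp.T > 0 and config.dt > sp.tau_dark / 5.0:
            raise ValueError(
                f"dt={config.dt} too coarse to resolve dark-state kinetics "
                f"(tau_dark={sp.tau_dark}); require dt <= tau_dark/5")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    step_std, eps, is2d, p_bd, p_db, n_per_species = _kernel_inputs(config, rng)
    n = len(step_std)
    vol = config.volume
    steps_per_bin = int(round(config.bin_time / config.dt))
    n_steps = config.n_bins * steps_per_bin
    L = 2.0 * config.box_half

    x = rng.uniform(-config.box_half, config.box_half, n)
    y = rng.uniform(-config.box_half, config.box_half, n)
    z = np.where(is2d, 0.0, rng.uniform(-config.z_half, config.z_half, n))
    has_z = bool(np.any(~is2d))
    ndim = 3 if has_z else 2

    has_dark = bool(np.any(p_bd > 0))
    bright = np.ones(n, np.uint8)
    next_flip = np.full(n, -1, np.int64)
    log1m_pbd = np.zeros(n)
    log1m_pdb = np.zeros(n)
    if has_dark:
        dark_mask = p_bd > 0
        T_eff = p_bd / np.where(dark_mask, p_bd + p_db, 1.0)
        start_dark = dark_mask & (rng.random(n) < T_eff)
        bright[start_dark] = 0
        log1m_pbd[dark_mask] = np.log1p(-p_bd[dark_mask])
        log1m_pdb[dark_mask] = np.log1p(-p_db[dark_mask])
        # first flip: geometric dwell in the starting state
        p_leave = np.where(start_dark, p_db, p_bd)
        idx = np.nonzero(dark_mask)[0]
        next_flip[idx] = rng.geometric(p_leave[idx]) - 1

    rates = np.zeros(config.n_bins)
    if n > 0:
        chunk = max(1, min(n_steps, _CHUNK_BUDGET // max(n * ndim, 1)))
        start = 0
        while start < n_steps:
            m = min(chunk, n_steps - start)
            steps = rng.standard_normal((m, n, ndim), dtype=np.float32)
            _chunk_kernel(rates, steps, start, steps_per_bin, config.dt,
                          x, y, z, step_std, eps, is2d, has_z,
                          bright, next_flip, log1m_pbd, log1m_pdb, has_dark,
                          config.box_half, config.z_half,
                          2.0 / vol.omega_xy**2, 2.0 / vol.axial_radius**2,
                          int(rng.integers(0, 2**31 - 1)))
            start += m
    rates += config.background * config.bin_time
    counts = rng.poisson(rates)
    meta = {
        "seed": config.seed,
        "n_particles": n_per_species,
        "omega_xy": vol.omega_xy,
        "S": vol.S,
        "species": [
            {"dimensionality": sp.dimensionality, "D": sp.D,
             "density": sp.density, "epsilon": sp.epsilon,
             "T": sp.T, "tau_dark": sp.tau_dark}
            for sp in config.species
        ],
    }
    if return_rates:
        meta["bin_rates"] = rates
    return PhotonTrace(counts, config.bin_time,
                       config.n_bins * config.bin_time, meta)


def simulate_calibration_trace(D_ref: float,
                               volume: DetectionVolume,
                               concentration: float,
                               epsilon: float = 3e4,
                               duration: float = 2.0,
                               seed: int = 0,
                               T: float = 0.15,
                               tau_dark: float = 4e-6,
                               bin_time: float = 2e-6,
                               dt: float = 5e-7,
                               background: float = 0.0,
                               box_scale: float = 5.0) -> PhotonTrace:
    """Simulate a calibration-dye trace (single 3D species with triplet).

    ``D_ref`` is the reference diffusion coefficient of the dye (μm²/s,
    e.g. 280 for Rhodamine 6G, 316 for Cy5) and ``concentration`` its
    number density in particles/μm³.  ``D_ref`` is recorded in the trace
    metadata for the downstream beam-waist calibration fit.
    """
    if not D_ref > 0:
        raise ValueError("D_ref must be positive")
    if not concentration > 0:
        raise ValueError("calibration dye concentration must be positive")
    species = SpeciesSpec("3d", D_ref, concentration, epsilon, T, tau_dark)
    config = SimulationConfig(volume=volume, species=(species,),
                              duration=duration, bin_time=bin_time,
                              background=background, box_scale=box_scale,
                              dt=dt, seed=seed)
    trace = simulate_trace(config)
    trace.metadata["D_ref"] = D_ref
    return trace


def simulate_trajectories(n_particles: int, D: float, dt: float,
                          n_steps: int, ndim: int = 2,
                          seed: int = 0) -> np.ndarray:
    """Unwrapped Brownian trajectories, shape (n_steps+1, n_particles, ndim).

    Uses the same propagation rule as the photon kernel (independent
    Gaussian steps of std √(2·D·dt) per axis); intended for verifying the
    mean-squared-displacement law of the simulator.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt),
                       size=(n_steps, n_particles, ndim))
    pos = np.zeros((n_steps + 1, n_particles, ndim))
    np.cumsum(steps, axis=0, out=pos[1:])
    return pos


@njit(fastmath=True)
def _telegraph_kernel(n_steps, p_to_dark, p_to_bright, start_dark, seed):
    np.random.seed(seed)
    dark = np.empty(n_steps, np.uint8)
    state = start_dark
    for i in range(n_steps):
        if state == 0:
            if np.random.random() < p_to_dark:
                state = 1
        else:
            if np.random.random() < p_to_bright:
                state = 0
        dark[i] = state
    return dark


def simulate_dark_trajectory(T: float, tau_dark: float, dt: float,
                             n_steps: int, seed: int = 0) -> np.ndarray:
    """Dark-state telegraph trajectory (1 = dark) with the kernel's rates."""
    if dt > tau_dark / 5.0:
        raise ValueError("dt must be <= tau_dark/5")
    q = -math.expm1(-dt / tau_dark)
    p_bd = T * q
    p_db = (1.0 - T) * q
    rng = np.random.Generator(np.random.PCG64(seed))
    start_dark = 1 if rng.random() < T else 0
    return _telegraph_kernel(n_steps, p_bd, p_db, start_dark,
                             int(rng.integers(0, 2**31 - 1)))


def generate_dose_response(emax: float,
                           pec50: float,
                           concentrations: Sequence[float],
                           noise_sd: float = 0.0,
                           basal: float = 0.0,
                           seed: int = 0,
                           replicates: int = 1) -> DoseResponseDataset:
    """Generate responses from the hyperbolic Emax model plus Gaussian noise.

    response = basal + Emax·A/(A + EC50),  EC50 = 10^(−pEC50), A in molar.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = np.sort(conc)
    ec50 = 10.0 ** (-pec50)
    mean = basal + emax * conc / (conc + ec50)
    rng = np.random.Generator(np.random.PCG64(seed))
    responses = mean[:, None] + rng.normal(0.0, noise_sd,
                                           size=(len(conc), replicates))
    if noise_sd == 0.0:
        responses = np.repeat(mean[:, None], replicates, axis=1)
    return DoseResponseDataset(conc, responses, replicates)
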