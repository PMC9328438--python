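"""Photon counting histogram (PCH) molecular-brightness analysis.

The PCH of a stationary trace binned at bin time b is super-Poissonian;
its shape encodes the molecular brightness ε (detected
counts·molecule⁻¹·s⁻¹ at the center of the detection volume) and the
mean particle number N̄.  The single-particle count distribution is
obtained by integrating Poisson(k; ε·b·MDF) over a reference region of
the Gaussian detection profile; because particle numbers are Poisson and
particles independent, the full histogram is the compound-Poisson
(Poisson-weighted self-convolution) of the single-particle distribution,
evaluated here with the exact Panjer recursion.  Species convolve.

The empirical first-order out-of-focus correction F adds an independent
Poisson photon stream carrying a fraction F of the in-focus mean
intensity — to first order, out-of-focus molecules are numerous and
individually so dim that only their summed mean emission matters.  F is
determined once from a calibration-dye histogram and then frozen for all
subsequent fits.

For the 3D Gaussian profile the shape factor is γ = 2^(−3/2) and N̄ is
referred to the effective volume V_eff = π^{3/2}·ω²·z₀; the 2D variant
(particles confined to the focal plane) has γ = 1/2 with N̄ referred to
the beam area A = π·ω².  The modeled mean count per bin is then
Σ_i γ·ε_i·N̄_i·b in either geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import stats

from .simkit import PhotonTrace

__all__ = ["PCHistogram", "PCHComponent", "PCHFitResult", "compute_pch",
           "pch_model", "fit_pch", "calibrate_pch_correction",
           "select_pch_model"]

#: MDF truncation for the reference region (amplitudes below are ignored)
MDF_MIN = 1e-8
#: target tail mass when extending the modeled count range
TAIL_TOL = 1e-12

_T_MAX = -math.log(MDF_MIN)


def gamma_factor(mdf: str) -> float:
    """Shape factor γ = ∫MDF²/∫MDF of the ideal Gaussian profile."""
    return 2.0 ** -1.5 if mdf == "3d" else 0.5


def _ref_scale(mdf: str) -> float:
    """Ratio of the truncated reference region to the effective volume/area."""
    if mdf == "3d":
        return 4.0 / (3.0 * math.sqrt(math.pi)) * (_T_MAX / 2.0) ** 1.5
    return _T_MAX / 2.0


@dataclass
class PCHistogram:
    """Histogram of photon counts per bin, k contiguous from 0."""

    k: np.ndarray
    frequency: np.ndarray
    bin_time: float
    n_bins: int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k)
        self.frequency = np.asarray(self.frequency)
        if not np.array_equal(self.k, np.arange(len(self.k))):
            raise ValueError("k must be contiguous from 0")
        if self.frequency.sum() != self.n_bins:
            raise ValueError("frequencies must sum to n_bins")

    @property
    def mean(self) -> float:
        return float((self.k * self.frequency).sum() / self.n_bins)

    @property
    def variance(self) -> float:
        m = self.mean
        return float((self.frequency * (self.k - m) ** 2).sum() / self.n_bins)


@dataclass(frozen=True)
class PCHComponent:
    """One brightness species: ε in counts·molecule⁻¹·s⁻¹, N̄ the mean
    particle number in the effective Gaussian volume (3D) or beam area (2D)."""

    epsilon: float
    N_bar: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.N_bar > 0:
            raise ValueError("N_bar must be positive")


@dataclass
class PCHFitResult:
    """Fitted PCH model (components sorted by ε ascending)."""

    components: list[PCHComponent]
    F: float
    chisq: float
    bin_time: float
    mdf: str = "3d"
    converged: bool = True
    collapsed: bool = False   # two-component fit with eps2/eps1 < 2

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        eps = [c.epsilon for c in self.components]
        if any(b < a for a, b in zip(eps, eps[1:])):
            raise ValueError("components must be sorted by epsilon ascending")


def compute_pch(trace: PhotonTrace, bin_time: float | None = None) -> PCHistogram:
    """Histogram the trace at ``bin_time`` (integer multiple of the native
    bin width; counts are rebinned by summation first)."""
    if bin_time is None:
        bin_time = trace.bin_time
    factor = bin_time / trace.bin_time
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("bin_time must be an integer multiple of the native "
                         "bin width")
    rebinned = trace.rebin(int(round(factor)))
    counts = np.asarray(rebinned.counts, dtype=np.int64)
    freq = np.bincount(counts)
    return PCHistogram(np.arange(len(freq)), freq, rebinned.bin_time,
                       len(counts))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

_QUAD_CACHE: dict = {}


def _quad_nodes(mdf: str, n_nodes: int = 300):
    """Cached Gauss-Legendre weights and MDF amplitudes over the
    reference region, parameterized by t = −ln MDF."""
    key = (mdf, n_nodes)
    if key not in _QUAD_CACHE:
        if mdf == "3d":
            # substitute t = x²: w(t)dt ∝ x² dx, smooth at the origin
            x, wx = np.polynomial.legendre.leggauss(n_nodes)
            x = (x + 1.0) * 0.5 * math.sqrt(_T_MAX)
            wx = wx * 0.5 * math.sqrt(_T_MAX)
            weights = wx * 3.0 * x**2 / _T_MAX**1.5
            mdf_amp = np.exp(-(x**2))
        else:
            t, wt = np.polynomial.legendre.leggauss(n_nodes)
            t = (t + 1.0) * 0.5 * _T_MAX
            weights = (wt * 0.5 * _T_MAX) / _T_MAX
            mdf_amp = np.exp(-t)
        _QUAD_CACHE[key] = (weights, mdf_amp)
    return _QUAD_CACHE[key]


def _p1(eps_bin: float, k_max: int, mdf: str) -> np.ndarray:
    """Single-particle count distribution over the reference region:
    p1(k) = ∫ w(t)·Poisson(k; ε_b·e^{−t}) dt by Gauss-Legendre quadrature,
    where t = −ln MDF and w(t) is the (dimensionality-dependent) density
    of reference-region volume over MDF amplitude."""
    weights, mdf_amp = _quad_nodes(mdf)
    lam = eps_bin * mdf_amp
    p = np.empty(k_max + 1)
    pmf = np.exp(-lam)
    p[0] = weights @ pmf
    for k in range(1, k_max + 1):
        pmf = pmf * lam / k
        p[k] = weights @ pmf
    return p


def _panjer(n_bar: float, q: np.ndarray) -> np.ndarray:
    """Compound-Poisson distribution P with Poisson(n_bar) particles each
    contributing counts ~ q (Panjer recursion, exact)."""
    k_max = len(q) - 1
    P = np.zeros(k_max + 1)
    P[0] = math.exp(-n_bar * (1.0 - q[0]))
    jq = np.arange(k_max + 1) * q
    for k in range(1, k_max + 1):
        P[k] = (n_bar / k) * float(jq[1:k + 1] @ P[k - 1::-1])
    return P


def _pch_probs(comps, F, bin_time, K, mdf):
    """Exact model probabilities P(0..K).  The Panjer recursion is exact
    at any truncation K (P(k) depends only on q(1..k)), so no tail
    extension is needed when only the first K+1 values are wanted.

    The first-order out-of-focus correction convolves the ideal-profile
    histogram with a Poisson photon stream carrying a fraction F of the
    in-focus mean intensity: to first order the out-of-focus molecules
    are numerous and individually so dim that only their summed mean
    matters, and uncorrelated dim emission is Poisson light.
    """
    P = None
    scale = _ref_scale(mdf)
    gam = gamma_factor(mdf)
    mean_in_focus = 0.0
    for c in comps:
        q = _p1(c.epsilon * bin_time, K, mdf)
        Pc = _panjer(c.N_bar * scale, q)
        P = Pc if P is None else np.convolve(P, Pc)[: K + 1]
        mean_in_focus += gam * c.epsilon * bin_time * c.N_bar
    if F > 0:
        lam = F * mean_in_focus
        k = np.arange(K + 1)
        oof = np.exp(-lam + k * math.log(max(lam, 1e-300))
                     - _gammaln_cache(K)[k])
        P = np.convolve(P, oof)[: K + 1]
    return np.maximum(P, 0.0)


_GAMMALN: dict = {}


def _gammaln_cache(K):
    if K not in _GAMMALN:
        from scipy.special import gammaln
        _GAMMALN[K] = gammaln(np.arange(K + 1) + 1.0)
    return _GAMMALN[K]


def pch_model(components, F: float = 0.0, bin_time: float = 1e-4,
              k_max: int = 30, mdf: str = "3d") -> np.ndarray:
    """Model photon-count probabilities p(0..K), K ≥ k_max.

    ``components`` is a sequence of :class:`PCHComponent` (or
    (epsilon, N_bar) pairs).  The returned array is extended beyond
    ``k_max`` until the un-modeled tail mass is below ``TAIL_TOL``, so it
    always sums to 1 within that tolerance.
    """
    if mdf not in ("2d", "3d"):
        raise ValueError("mdf must be '2d' or '3d'")
    if F < 0:
        raise ValueError("F must be >= 0")
    comps = [c if isinstance(c, PCHComponent) else PCHComponent(*c)
             for c in components]
    gam = gamma_factor(mdf)
    mean = (1.0 + F) * sum(gam * c.epsilon * bin_time * c.N_bar
                           for c in comps)
    # beyond mean + 20σ the true tail is negligible; any residual in
    # 1 - ΣP there is floating-point cancellation, not missing mass
    k_safe = mean + 20.0 * math.sqrt(mean + 1.0) + 64.0
    K = max(k_max, 5)
    while True:
        P = _pch_probs(comps, F, bin_time, K, mdf)
        if 1.0 - P.sum() < TAIL_TOL or K >= k_safe:
            return P
        if K > 65536:
            raise RuntimeError("pch_model failed to converge: tail mass "
                               "did not drop below tolerance")
        K *= 2


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _moment_guess(hist: PCHistogram, mdf: str):
    mu = hist.mean
    q_mandel = max(hist.variance / max(mu, 1e-12) - 1.0, 1e-3)
    gam = gamma_factor(mdf)
    eps_bin = q_mandel / gam
    n_bar = mu / (gam * eps_bin)
    return eps_bin / hist.bin_time, max(n_bar, 1e-3)


def _pch_residual(hist: PCHistogram, mdf: str):
    obs = hist.frequency.astype(float)
    n = hist.n_bins
    k_obs = len(obs) - 1

    def residual(p):
        comps = []
        i = 1
        while f"eps{i}" in p:
            comps.append(PCHComponent(p[f"eps{i}"].value, p[f"N{i}"].value))
            i += 1
        model = _pch_probs(comps, p["F"].value, hist.bin_time, k_obs, mdf)
        expected = n * model[: k_obs + 1]
        sigma = np.sqrt(np.maximum(expected, 1.0))
        return (obs - expected) / sigma

    return residual


def fit_pch(hist: PCHistogram, n_components: int = 1,
            F_fixed: float | None = None, mdf: str = "3d",
            n_starts: int = 4) -> PCHFitResult:
    """Minimum-χ² PCH fit with 1 or 2 brightness components.

    ``F_fixed`` freezes the first-order out-of-focus correction to a
    calibration value; otherwise F is held at 0.  Use
    :func:`calibrate_pch_correction` to fit F itself.  A two-component
    fit whose brightnesses collapse within a factor of 2 is flagged.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if hist.n_bins < 10_000:
        raise ValueError("need >= 1e4 histogrammed bins for stable tails")
    return _fit_pch_impl(hist, n_components, F_fixed, mdf, n_starts,
                         fit_F=False)


def _fit_pch_impl(hist, n_components, F_fixed, mdf, n_starts, fit_F):
    eps0, nbar0 = _moment_guess(hist, mdf)
    residual = _pch_residual(hist, mdf)
    rng = np.random.Generator(np.random.PCG64(424242))

    base_starts = []
    if n_components == 1:
        base_starts.append({"eps1": eps0, "N1": nbar0})
    else:
        base_starts.append({"eps1": eps0 / 4, "N1": nbar0,
                            "eps2": eps0 * 2, "N2": nbar0 / 4})
        base_starts.append({"eps1": eps0 / 8, "N1": 2 * nbar0,
                            "eps2": eps0, "N2": nbar0 / 2})
    starts = []
    for b in base_starts:
        starts.append(b)
        for _ in range(max(0, n_starts - 1)):
            starts.append({k: v * 10 ** rng.uniform(-0.4, 0.4)
                           for k, v in b.items()})

    best = None
    for start in starts:
        p = lmfit.Parameters()
        for i in range(1, n_components + 1):
            p.add(f"eps{i}", value=start[f"eps{i}"], min=1e-2, max=1e9)
            p.add(f"N{i}", value=start[f"N{i}"], min=1e-6, max=1e6)
        if fit_F:
            p.add("F", value=0.3, min=0.0, max=5.0)
        else:
            p.add("F", value=F_fixed if F_fixed is not None else 0.0,
                  vary=False)
        try:
            # cap per-start effort: converged fits need ~100 evaluations,
            # while degenerate (collapsed) solutions crawl a flat valley.
            # A start that exhausts the cap is still a candidate — the
            # best-χ² selection keeps whichever start got furthest.
            res = lmfit.minimize(residual, p, method="least_squares",
                                 nan_policy="omit", max_nfev=1000)
        except Exception:
            continue
        if np.isfinite(res.chisqr) and (best is None or
                                        res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("PCH fit failed to converge from every start")

    comps = sorted(
        (PCHComponent(float(best.params[f"eps{i}"].value),
                      float(best.params[f"N{i}"].value))
         for i in range(1, n_components + 1)),
        key=lambda c: c.epsilon)
    collapsed = (n_components == 2 and
                 comps[1].epsilon < 2.0 * comps[0].epsilon)
    return PCHFitResult(components=comps, F=float(best.params["F"].value),
                        chisq=float(best.redchi), bin_time=hist.bin_time,
                        mdf=mdf, collapsed=collapsed)


def calibrate_pch_correction(hist_calib: PCHistogram,
                             mdf: str = "3d") -> PCHFitResult:
    """One-component fit of a calibration-dye histogram with F free.

    Returns the full fit; ``result.F`` is the first-order correction to
    freeze for all subsequent fits.  F pinned at its upper bound (5)
    signals a bad calibration.
    """
    if hist_calib.n_bins < 10_000:
        raise ValueError("need >= 1e4 histogrammed bins for stable tails")
    result = _fit_pch_impl(hist_calib, 1, None, mdf, 4, fit_F=True)
    if result.F > 4.99:
        raise RuntimeError("first-order correction pinned at its bound: "
                           "bad calibration data")
    return result


def select_pch_model(hist: PCHistogram, F_fixed: float | None = None,
                     mdf: str = "3d", alpha: float = 0.01):
    """Choose 1 vs 2 brightness components by an F-test on the χ² drop.

    Returns ``(n_components, fit1, fit2)``.  The two-component model is
    preferred only when the improvement is significant at ``alpha`` and
    the two brightnesses have not collapsed onto each other.
    """
    fit1 = fit_pch(hist, 1, F_fixed, mdf)
    try:
        fit2 = fit_pch(hist, 2, F_fixed, mdf)
    except RuntimeError:
        return 1, fit1, None
    n_k = len(hist.k)
    dof2 = n_k - 4 - (0 if F_fixed is None else 0)
    if dof2 <= 0 or fit2.collapsed:
        return 1, fit1, fit2
    c1 = fit1.chisq * (n_k - 2)
    c2 = fit2.chisq * dof2
    if c2 <= 0 or c1 <= c2:
        return 1, fit1, fit2
    f_stat = ((c1 - c2) / 2.0) / (c2 / dof2)
    p_val = stats.f.sf(f_stat, 2, dof2)
    return (2 if p_val < alpha else 1), fit1, fit2
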