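"""Multi-tau autocorrelation of binned photon traces.

The normalized fluctuation autocorrelation is defined without the +1
baseline, G(τ) = ⟨δI(t)·δI(t+τ)⟩ / ⟨I⟩² with δI = I − ⟨I⟩, so that
G(∞) = 0 and the zero-lag amplitude of a diffusing species reads 1/N.

``autocorrelate`` implements the standard hardware multi-tau scheme
(m linear lags per octave, counts rebinned ×2 per octave) with symmetric
normalization: at each lag the leading and lagging segments are
normalized by their own means, which removes the rebinning bias at long
lags.  ``autocorrelate_direct`` is the brute-force O(N·k) evaluation of
the definition used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simkit import PhotonTrace

__all__ = ["CorrelationCurve", "autocorrelate", "autocorrelate_direct",
           "average_curves"]


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation on a (quasi-logarithmic) lag grid."""

    lags: np.ndarray          # s, strictly increasing
    G: np.ndarray             # dimensionless amplitude
    npts: np.ndarray          # products averaged per lag
    mean_rate: float          # counts/s
    bin_time: float = 0.0     # native bin width of the source trace, s
    bin_widths: np.ndarray | None = None  # correlator bin width per lag, s

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.npts = np.asarray(self.npts, dtype=float)
        if self.bin_widths is not None:
            self.bin_widths = np.asarray(self.bin_widths, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")
        if np.any(self.npts <= 0):
            raise ValueError("npts must be positive")

    @property
    def sigma(self) -> np.ndarray:
        """Relative uncertainty proxy per lag used for fit weighting.

        The averaging contribution scales as 1/√npts; where the mean
        counts per correlator bin ⟨n⟩ are known the photon (shot-noise)
        contribution inflates it by (1 + 1/⟨n⟩), which down-weights the
        sparsely populated short-lag channels of a multi-tau grid.
        """
        base = 1.0 / np.sqrt(self.npts)
        if self.bin_widths is None or not np.isfinite(self.mean_rate):
            return base
        mean_counts = np.maximum(self.mean_rate * self.bin_widths, 1e-12)
        return base * (1.0 + 1.0 / mean_counts)


def _level_correlation(s: np.ndarray, lags_bins: np.ndarray):
    """Symmetric-normalized G at integer ``lags_bins`` of series ``s``."""
    n = len(s)
    G = np.empty(len(lags_bins))
    npts = np.empty(len(lags_bins), dtype=np.int64)
    for j, k in enumerate(lags_bins):
        lead = s[: n - k]
        lag = s[k:]
        mu_lead = lead.mean()
        mu_lag = lag.mean()
        if mu_lead == 0 or mu_lag == 0:
            raise ValueError("zero segment mean: correlation undefined")
        G[j] = float(lead @ lag) / (len(lead) * mu_lead * mu_lag) - 1.0
        npts[j] = n - k
    return G, npts


def autocorrelate(trace: PhotonTrace, m: int = 16,
                  rebin_factor: int = 1) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon trace.

    Parameters
    ----------
    m:
        Even number of linear lag channels per octave (default 16).  The
        first octave holds lags 1..2m in native bins; each subsequent
        octave rebins the counts ×2 and holds lags m+1..2m.
    rebin_factor:
        Integer pre-rebinning of the trace before correlating, e.g. to
        move from the raw simulation binning to the analysis bin time.
    """
    if m < 2 or m % 2:
        raise ValueError("m must be even and >= 2")
    if rebin_factor != 1:
        trace = trace.rebin(rebin_factor)
    s = np.asarray(trace.counts, dtype=float)
    if len(s) < 4 * m:
        raise ValueError("trace must contain at least 4*m bins")
    if s.sum() == 0:
        raise ValueError("all-zero trace: mean intensity is 0")

    all_lags, all_G, all_npts, all_widths = [], [], [], []
    bin_width = trace.bin_time
    level = 0
    while True:
        if level == 0:
            lags_bins = np.arange(1, 2 * m + 1)
        else:
            lags_bins = np.arange(m + 1, 2 * m + 1)
        if len(s) <= lags_bins[-1] + 1:
            break
        G, npts = _level_correlation(s, lags_bins)
        all_lags.append(lags_bins * bin_width)
        all_G.append(G)
        all_npts.append(npts)
        all_widths.append(np.full(len(lags_bins), bin_width))
        # rebin ×2 for the next octave
        n2 = (len(s) // 2) * 2
        s = s[:n2].reshape(-1, 2).sum(axis=1)
        bin_width *= 2.0
        level += 1
        if len(s) < 2 * m + 2:
            break
    return CorrelationCurve(np.concatenate(all_lags), np.concatenate(all_G),
                            np.concatenate(all_npts), trace.mean_rate,
                            trace.bin_time, np.concatenate(all_widths))


def autocorrelate_direct(trace: PhotonTrace, max_lag_bins: int,
                         normalization: str = "global") -> CorrelationCurve:
    """Brute-force autocorrelation at every integer lag 1..max_lag_bins.

    ``normalization="global"`` evaluates the textbook definition with the
    single whole-trace mean; ``"symmetric"`` normalizes each lag by the
    means of its leading and lagging segments, matching the estimator the
    multi-tau correlator uses (for oracle-equivalence checks).
    """
    s = np.asarray(trace.counts, dtype=float)
    if max_lag_bins >= len(s):
        raise ValueError("max_lag_bins must be smaller than the trace length")
    if s.sum() == 0:
        raise ValueError("all-zero trace: mean intensity is 0")
    lags_bins = np.arange(1, max_lag_bins + 1)
    if normalization == "symmetric":
        G, npts = _level_correlation(s, lags_bins)
    elif normalization == "global":
        mu = s.mean()
        d = s - mu
        n = len(s)
        G = np.empty(max_lag_bins)
        npts = np.empty(max_lag_bins, dtype=np.int64)
        for j, k in enumerate(lags_bins):
            G[j] = float(d[: n - k] @ d[k:]) / ((n - k) * mu * mu)
            npts[j] = n - k
    else:
        raise ValueError("normalization must be 'global' or 'symmetric'")
    return CorrelationCurve(lags_bins * trace.bin_time, G, npts,
                            trace.mean_rate, trace.bin_time,
                            np.full(len(lags_bins), trace.bin_time))


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise average of curves computed on identical lag grids.

    Used to combine the repeated reads taken on each cell: every read is
    correlated separately and the curves are averaged.
    """
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ValueError("curves must share the same lag grid")
    G = np.mean([c.G for c in curves], axis=0)
    npts = np.sum([c.npts for c in curves], axis=0)
    rate = float(np.mean([c.mean_rate for c in curves]))
    return CorrelationCurve(lags, G, npts, rate, curves[0].bin_time,
                            curves[0].bin_widths)
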