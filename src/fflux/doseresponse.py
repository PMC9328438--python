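"""Hyperbolic Emax concentration-response fitting.

Response = basal + Emax·A/(A + EC50) with A the molar agonist
concentration and a Hill slope fixed at 1.  Concentrations are handled
as pEC50 = −log10(EC50) internally for conditioning.  A dataset whose
response is statistically indistinguishable from flat (likelihood-ratio
test of Emax = 0 at α = 0.05) is reported as "no response" rather than
returning a meaningless potency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import stats

from .simkit import DoseResponseDataset

__all__ = ["EmaxFit", "NoResponseError", "fit_emax", "normalize_response"]


class NoResponseError(RuntimeError):
    """The data show no concentration-dependent response (NR)."""


@dataclass
class EmaxFit:
    """Fitted Emax model."""

    emax: float
    ec50: float
    pec50: float
    basal: float = 0.0
    se_pec50: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if abs(self.pec50 + math.log10(self.ec50)) > 1e-9:
            raise ValueError("pec50 must equal -log10(ec50)")

    def predict(self, concentrations) -> np.ndarray:
        a = np.asarray(concentrations, dtype=float)
        return self.basal + self.emax * a / (a + self.ec50)


def _flatten(data: DoseResponseDataset):
    conc = np.repeat(data.concentrations, data.replicates)
    resp = data.responses.reshape(-1)
    return conc, resp


def fit_emax(data: DoseResponseDataset, fit_basal: bool = False,
             alpha_nr: float = 0.05) -> EmaxFit:
    """Nonlinear least-squares fit of the Emax equation.

    Requires ≥ 4 distinct concentrations spanning ≥ 2 log units.  Raises
    :class:`NoResponseError` when Emax is indistinguishable from 0 at
    ``alpha_nr`` by a likelihood-ratio test against the flat model.
    """
    conc = data.concentrations
    if len(conc) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if math.log10(conc[-1] / conc[0]) < 2.0 - 1e-9:
        raise ValueError("concentrations must span at least 2 log units")
    a, y = _flatten(data)
    n = len(y)

    p = lmfit.Parameters()
    p.add("emax", value=float(y.max() - y.min()) or 1.0)
    p.add("pec50", value=float(-np.log10(np.median(conc))),
          min=-np.log10(conc[-1]) - 3, max=-np.log10(conc[0]) + 3)
    p.add("basal", value=float(y.min()), vary=fit_basal)
    if not fit_basal:
        p["basal"].value = 0.0

    def residual(p):
        ec50 = 10.0 ** (-p["pec50"].value)
        return p["basal"].value + p["emax"].value * a / (a + ec50) - y

    res = lmfit.minimize(residual, p, method="least_squares")
    if not res.success:
        raise RuntimeError("Emax fit failed to converge")
    rss1 = float(np.sum(res.residual**2))

    # flat null model (no concentration dependence): constant at the mean
    rss0 = float(np.sum((y - y.mean()) ** 2))
    k_extra = 2  # emax, pec50
    if rss1 <= 0 or rss0 <= rss1:
        lr = math.inf if rss1 < rss0 else 0.0
    else:
        lr = n * math.log(rss0 / rss1)
    p_val = stats.chi2.sf(lr, k_extra) if np.isfinite(lr) else 0.0
    if p_val >= alpha_nr:
        raise NoResponseError(
            f"Emax indistinguishable from 0 (LR p = {p_val:.3g}): no response")

    pec50 = float(res.params["pec50"].value)
    se = res.params["pec50"].stderr
    return EmaxFit(emax=float(res.params["emax"].value),
                   ec50=10.0 ** (-pec50), pec50=pec50,
                   basal=float(res.params["basal"].value),
                   se_pec50=float(se) if se is not None else float("nan"))


def normalize_response(raw, basal_ref: float, max_ref: float) -> np.ndarray:
    """Express responses as percent of a reference window:
    100·(raw − basal_ref)/(max_ref − basal_ref)."""
    if max_ref == basal_ref:
        raise ZeroDivisionError("max_ref must differ from basal_ref")
    return 100.0 * (np.asarray(raw, dtype=float) - basal_ref) / \
        (max_ref - basal_ref)
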