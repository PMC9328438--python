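"""End-to-end experiment orchestration.

Mirrors the acquisition protocol of a confocal FCS session: calibrate
the detection volume with a reference dye (beam-waist ACF fit plus the
PCH first-order correction), then for each cell of each condition
simulate the repeated reads, correlate each read and average the curves,
fit the condition's autocorrelation model, derive per-cell D and
particle density, fit the photon counting histogram at the analysis bin
time, and aggregate per-condition mean ± SEM tables.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import acfmodels, correlator, pch
from .simkit import SimulationConfig, simulate_calibration_trace, simulate_trace
from .presets import CALIBRATION, DEFAULT_VOLUME, PCH_CALIBRATION

__all__ = ["ConditionConfig", "ExperimentConfig", "CellRecord",
           "ConditionSummary", "run_experiment", "summarize",
           "summary_table"]

log = logging.getLogger("fflux.pipeline")


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental condition: a simulation ground truth plus the
    analysis model to apply to its traces."""

    name: str
    sim: SimulationConfig
    model: str = "membrane"            # "membrane" | "ligand"
    pch_components: str | int = 1      # 1, 2 or "auto"
    tau_D1_fixed: float | None = None  # required for the ligand model

    def __post_init__(self) -> None:
        if self.model not in ("membrane", "ligand"):
            raise ValueError("model must be 'membrane' or 'ligand'")
        if self.model == "ligand" and self.tau_D1_fixed is None:
            raise ValueError("the ligand model requires tau_D1_fixed")
        has_3d = any(sp.dimensionality == "3d" for sp in self.sim.species)
        if self.model == "membrane" and has_3d:
            raise ValueError("membrane model is incompatible with 3D species")


@dataclass(frozen=True)
class ExperimentConfig:
    """A full experiment: calibration plus per-condition cell replicates."""

    conditions: tuple[ConditionConfig, ...]
    n_cells: int = 20
    reads_per_cell: int = 2
    seed: int = 0
    analysis_bin_time: float = 1e-4
    pch_bin_time: float = 1e-4
    pch_mdf: str = "2d"
    calibration: dict = field(default_factory=lambda: dict(CALIBRATION))
    pch_calibration: dict = field(
        default_factory=lambda: dict(PCH_CALIBRATION))
    pch_cal_bin_time: float = 2e-5

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.reads_per_cell < 1:
            raise ValueError("reads_per_cell must be >= 1")


@dataclass
class CellRecord:
    """Per-cell analysis outcome (one simulated cell, all reads)."""

    condition: str
    cell: int
    ok: bool
    error: str = ""
    density: float = float("nan")
    D_dominant: float = float("nan")
    N_total: float = float("nan")
    epsilons: tuple[float, ...] = ()
    pch_n_components: int = 0
    degenerate_refit: bool = False


@dataclass
class ConditionSummary:
    """Mean ± SEM over successfully analyzed cells of one condition."""

    condition: str
    n: int
    records: list[CellRecord]
    stats: dict  # quantity -> (mean, sem)
    failures: list[CellRecord]


def summarize(values) -> tuple[float, float | None, int]:
    """Arithmetic mean, SEM = sd/√n (None for n = 1), and n."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no records to summarize")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None, 1
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem, int(arr.size)


def _cell_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _analyze_cell(cond: ConditionConfig, cell_idx: int, seeds,
                  cal: acfmodels.CalibrationResult, F: float,
                  cfg: ExperimentConfig) -> CellRecord:
    volume = cal.volume
    rebin = int(round(cfg.analysis_bin_time / cond.sim.bin_time))
    traces = [simulate_trace(replace(cond.sim, seed=int(s))) for s in seeds]
    curves = [correlator.autocorrelate(t, rebin_factor=max(rebin, 1))
              for t in traces]
    curve = correlator.average_curves(curves)
    if cond.model == "membrane":
        fit = acfmodels.fit_membrane_acf(curve, volume)
        density = acfmodels.derive_density(fit, volume, "sum_2d")
    else:
        fit = acfmodels.fit_ligand_acf(curve, volume, cond.tau_D1_fixed)
        density = acfmodels.derive_density(fit, volume, "slowest_2d")
    D_dom = fit.dominant_2d_D(volume)

    # pool the reads into one histogram at the PCH analysis bin time
    hists = [pch.compute_pch(t, cfg.pch_bin_time) for t in traces]
    kmax = max(len(h.k) for h in hists)
    freq = np.zeros(kmax, dtype=np.int64)
    for h in hists:
        freq[: len(h.k)] += h.frequency
    hist = pch.PCHistogram(np.arange(kmax), freq, cfg.pch_bin_time,
                           int(freq.sum()))
    if cond.pch_components == "auto":
        n_comp, fit1, fit2 = pch.select_pch_model(hist, F, cfg.pch_mdf)
        pfit = fit2 if (n_comp == 2 and fit2 is not None) else fit1
    else:
        n_comp = int(cond.pch_components)
        pfit = pch.fit_pch(hist, n_comp, F, cfg.pch_mdf)
    return CellRecord(
        condition=cond.name, cell=cell_idx, ok=True,
        density=density, D_dominant=D_dom, N_total=fit.N_total,
        epsilons=tuple(c.epsilon for c in pfit.components),
        pch_n_components=n_comp, degenerate_refit=fit.degenerate_refit)


def run_experiment(config: ExperimentConfig) -> dict[str, ConditionSummary]:
    """Run calibration and every condition; aggregate per-condition tables.

    Calibration failure aborts the experiment; per-cell fit failures are
    recorded with their reason and excluded from the summaries.  The whole
    run is reproducible from ``config.seed``.
    """
    t_start = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 + len(config.conditions)) % (2**31 - 1)

    def _cal_trace(calcfg: dict, seed: int):
        kw = dict(calcfg)
        volume_true = kw.pop("volume", DEFAULT_VOLUME)
        return simulate_calibration_trace(
            kw.pop("D_ref"), volume_true, kw.pop("concentration"),
            seed=seed, **kw)

    cal_trace = _cal_trace(config.calibration, int(seeds[0]))
    cal_curve = correlator.autocorrelate(cal_trace)
    cal = acfmodels.fit_calibration(cal_curve, cal_trace.metadata["D_ref"])
    log.info("calibration: omega=%.4f um, S=%.2f", cal.omega, cal.S)

    pch_cal_trace = _cal_trace(config.pch_calibration, int(seeds[1]))
    cal_hist = pch.compute_pch(pch_cal_trace, config.pch_cal_bin_time)
    F = pch.calibrate_pch_correction(cal_hist).F
    log.info("PCH first-order correction F=%.3f (calibration stage %.1f s)",
             F, time.perf_counter() - t_start)

    summaries: dict[str, ConditionSummary] = {}
    for ci, cond in enumerate(config.conditions):
        t_cond = time.perf_counter()
        cell_seed_root = int(seeds[2 + ci])
        all_seeds = _cell_seeds(cell_seed_root,
                                config.n_cells * config.reads_per_cell)
        records, failures = [], []
        for cell in range(config.n_cells):
            s = all_seeds[cell * config.reads_per_cell:
                          (cell + 1) * config.reads_per_cell]
            try:
                rec = _analyze_cell(cond, cell, s, cal, F, config)
                records.append(rec)
            except (acfmodels.FitError, RuntimeError, ValueError) as exc:
                log.warning("condition %s cell %d failed: %s",
                            cond.name, cell, exc)
                failures.append(CellRecord(cond.name, cell, ok=False,
                                           error=str(exc)))
        if not records:
            summaries[cond.name] = ConditionSummary(cond.name, 0, [], {},
                                                    failures)
            continue
        stats = {}
        for quantity in ("density", "D_dominant", "N_total"):
            vals = [getattr(r, quantity) for r in records]
            mean, sem, n = summarize(vals)
            stats[quantity] = (mean, sem)
        max_comp = max(len(r.epsilons) for r in records)
        for j in range(max_comp):
            vals = [r.epsilons[j] for r in records if len(r.epsilons) > j]
            mean, sem, n = summarize(vals)
            stats[f"epsilon{j + 1}"] = (mean, sem)
        summaries[cond.name] = ConditionSummary(cond.name, len(records),
                                                records, stats, failures)
        log.info("condition %s: %d/%d cells fitted in %.1f s", cond.name,
                 len(records), config.n_cells,
                 time.perf_counter() - t_cond)
    return summaries


def load_experiment_yaml(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Schema::

        seed: 1
        n_cells: 20
        reads_per_cell: 2
        conditions:
          - name: vehicle
            preset: gfp_vehicle        # or bifc_vehicle, ...
            duration: 30.0
            pch_components: 1
          - name: custom
            model: membrane
            sim:                       # explicit SimulationConfig fields
              volume: {omega_xy: 0.2, S: 5.0}
              species:
                - {dimensionality: "2d", D: 0.13, density: 36.7,
                   epsilon: 18111.0}
              duration: 30.0
              bin_time: 1.0e-4
              dt: 1.0e-4
              box_scale: 5.0
    """
    import yaml

    from .presets import (BIFC_CONDITIONS, MEMBRANE_CONDITIONS,
                          bifc_condition, membrane_condition)
    from .simkit import DetectionVolume, SpeciesSpec

    with open(path) as f:
        raw = yaml.safe_load(f)
    conditions = []
    for c in raw["conditions"]:
        kwargs = {k: c[k] for k in ("model", "pch_components",
                                    "tau_D1_fixed") if k in c}
        if "preset" in c:
            preset = c["preset"]
            dur = c.get("duration", 30.0)
            if preset in MEMBRANE_CONDITIONS:
                sim = membrane_condition(preset, duration=dur)
            elif preset in BIFC_CONDITIONS:
                sim = bifc_condition(preset, duration=dur)
            else:
                raise ValueError(f"unknown preset '{preset}'")
        else:
            s = dict(c["sim"])
            vol = DetectionVolume(**s.pop("volume"))
            species = tuple(SpeciesSpec(**sp) for sp in s.pop("species"))
            sim = SimulationConfig(volume=vol, species=species, **s)
        conditions.append(ConditionConfig(c["name"], sim, **kwargs))
    exp_kwargs = {k: raw[k] for k in
                  ("n_cells", "reads_per_cell", "seed", "analysis_bin_time",
                   "pch_bin_time", "pch_mdf") if k in raw}
    if "calibration" in raw:
        exp_kwargs["calibration"] = {**CALIBRATION, **raw["calibration"]}
    if "pch_calibration" in raw:
        exp_kwargs["pch_calibration"] = {**PCH_CALIBRATION,
                                         **raw["pch_calibration"]}
    return ExperimentConfig(conditions=tuple(conditions), **exp_kwargs)


def summary_table(summaries: dict[str, ConditionSummary]) -> pd.DataFrame:
    """Condition summary in the layout of the published tables:
    density, diffusion coefficient and brightness as mean ± SEM columns."""
    rows = []
    for name, s in summaries.items():
        row = {"condition": name, "n": s.n}
        for q, label in (("density", "particle_number_per_um2"),
                         ("D_dominant", "diffusion_um2_per_s"),
                         ("epsilon1", "brightness1_cps"),
                         ("epsilon2", "brightness2_cps")):
            if q in s.stats:
                row[f"{label}_mean"], row[f"{label}_sem"] = s.stats[q]
        rows.append(row)
    return pd.DataFrame(rows)
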