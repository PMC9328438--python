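"""Reference simulation conditions for the adenosine A₃ receptor study design.

Each preset encodes the published per-condition ground truths — membrane
particle density (N/μm²), diffusion coefficient (μm²/s) and molecular
brightness (counts·molecule⁻¹·s⁻¹) — for GFP-tagged receptor (one
brightness population) and receptor/β-arrestin2 BiFC complexes (two
brightness populations), under vehicle or 10 μM NECA treatment, plus the
calibration-dye and fluorescent-ligand regimes.

Membrane presets propagate and bin at 100 μs: the slowest kinetics
simulated there are diffusive dwell times of tens of milliseconds, so
sub-μs stepping would add nothing but cost.  The calibration preset
resolves μs-scale triplet kinetics and therefore steps at 1 μs.
"""

from __future__ import annotations

from .simkit import DetectionVolume, SimulationConfig, SpeciesSpec, \
    D_RHODAMINE_6G

__all__ = ["DEFAULT_VOLUME", "membrane_condition", "bifc_condition",
           "MEMBRANE_CONDITIONS", "BIFC_CONDITIONS", "ligand_condition",
           "free_ligand_condition", "CALIBRATION", "PCH_CALIBRATION"]

DEFAULT_VOLUME = DetectionVolume(omega_xy=0.2, S=5.0)

#: GFP-tagged receptor conditions: (density /μm², D μm²/s, ε cps)
MEMBRANE_CONDITIONS = {
    "gfp_vehicle": (36.7, 0.13, 18_111.0),
    "gfp_neca": (64.1, 0.09, 24_027.0),
    "gfp_mutant_vehicle": (43.6, 0.13, 18_152.0),
    "gfp_mutant_neca": (67.1, 0.10, 26_351.0),
}

#: BiFC receptor/β-arrestin2 conditions: (total density /μm², D μm²/s,
#: ε_dim cps, ε_bright cps).  The published density is the total over both
#: brightness populations; the split between them is not reported and is
#: taken as 50/50 here.
BIFC_CONDITIONS = {
    "bifc_vehicle": (7.9, 0.24, 4_383.0, 34_006.0),
    "bifc_neca": (7.5, 0.12, 2_996.0, 44_028.0),
    "bifc_mutant_vehicle": (3.7, 0.25, 3_087.0, 40_618.0),
    "bifc_mutant_neca": (5.3, 0.14, 4_185.0, 43_968.0),
}


def membrane_condition(name: str, duration: float = 30.0, seed: int = 0,
                       volume: DetectionVolume = DEFAULT_VOLUME,
                       ) -> SimulationConfig:
    """Single-population GFP-receptor membrane trace at printed ground truths."""
    density, D, eps = MEMBRANE_CONDITIONS[name]
    species = SpeciesSpec("2d", D=D, density=density, epsilon=eps)
    return SimulationConfig(volume=volume, species=(species,),
                            duration=duration, bin_time=1e-4, dt=1e-4,
                            box_scale=5.0, seed=seed)


def bifc_condition(name: str, duration: float = 30.0, seed: int = 0,
                   volume: DetectionVolume = DEFAULT_VOLUME,
                   ) -> SimulationConfig:
    """Two-brightness-population BiFC membrane trace at printed ground truths."""
    density, D, eps1, eps2 = BIFC_CONDITIONS[name]
    species = (SpeciesSpec("2d", D=D, density=density / 2, epsilon=eps1),
               SpeciesSpec("2d", D=D, density=density / 2, epsilon=eps2))
    return SimulationConfig(volume=volume, species=species,
                            duration=duration, bin_time=1e-4, dt=1e-4,
                            box_scale=5.0, seed=seed)


#: Free fluorescent agonist in solution: D (μm²/s), concentration (/μm³)
#: and brightness are not printed in the study and are assumptions chosen
#: to give a well-conditioned three-component fit.
FREE_LIGAND = dict(D=100.0, concentration=0.8, epsilon=40_000.0)

#: Receptor-bound ligand ground truths: the slow 2D component (bound
#: receptor) diffuses at the published 0.15 μm²/s; the intermediate 2D
#: component and the bound densities are assumptions.
BOUND_LIGAND = dict(D_mid=1.0, density_mid=1.0, D_slow=0.15, density_slow=6.0)


def free_ligand_condition(duration: float = 8.0, seed: int = 0,
                          volume: DetectionVolume = DEFAULT_VOLUME,
                          ) -> SimulationConfig:
    """Fluorescent ligand alone in buffer (for the fixed-τ_D1 calibration)."""
    sp = SpeciesSpec("3d", D=FREE_LIGAND["D"],
                     density=FREE_LIGAND["concentration"],
                     epsilon=FREE_LIGAND["epsilon"])
    return SimulationConfig(volume=volume, species=(sp,), duration=duration,
                            bin_time=1e-5, dt=1e-5, box_scale=5.0, seed=seed)


def ligand_condition(duration: float = 30.0, seed: int = 0,
                     volume: DetectionVolume = DEFAULT_VOLUME,
                     ) -> SimulationConfig:
    """Bound-ligand condition: free 3D ligand plus two 2D bound components."""
    species = (
        SpeciesSpec("3d", D=FREE_LIGAND["D"],
                    density=FREE_LIGAND["concentration"],
                    epsilon=FREE_LIGAND["epsilon"]),
        SpeciesSpec("2d", D=BOUND_LIGAND["D_mid"],
                    density=BOUND_LIGAND["density_mid"],
                    epsilon=FREE_LIGAND["epsilon"]),
        SpeciesSpec("2d", D=BOUND_LIGAND["D_slow"],
                    density=BOUND_LIGAND["density_slow"],
                    epsilon=FREE_LIGAND["epsilon"]),
    )
    # wider box than the receptor presets: the faster bound component
    # needs the periodic-geometry mixing time beyond the fit window
    return SimulationConfig(volume=volume, species=species, duration=duration,
                            bin_time=1e-5, dt=1e-5, box_scale=8.0, seed=seed)


#: Beam-waist (ACF) calibration: dilute, bright Rhodamine 6G (≈1.2 nM,
#: 0.7 particles/μm³) in a wide box, read for 8 s.  Sub-nanomolar-scale
#: occupancy maximizes the correlation amplitude and a wide box keeps the
#: periodic-geometry mixing time well beyond the fitted lag range.
CALIBRATION = dict(D_ref=D_RHODAMINE_6G, concentration=0.7,
                   epsilon=150_000.0, duration=8.0, T=0.15, tau_dark=8e-6,
                   bin_time=1e-6, dt=1e-6, box_scale=12.5)

#: PCH first-order-correction calibration: 20 nM Rhodamine 6G
#: (12.04 particles/μm³) histogrammed at 20 μs bins.
PCH_CALIBRATION = dict(D_ref=D_RHODAMINE_6G, concentration=12.04,
                       epsilon=150_000.0, duration=1.0, T=0.15,
                       tau_dark=8e-6, bin_time=2e-6, dt=1e-6, box_scale=5.0)
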