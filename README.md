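# fflux

Fluorescence fluctuation spectroscopy toolkit for membrane receptor
biophysics: simulation of confocal photon-count traces, multi-tau
autocorrelation, calibrated FCS diffusion-model fitting, photon counting
histogram (PCH) molecular-brightness analysis, Emax concentration-response
fitting, and an end-to-end experiment pipeline.

## The scientific problem

Fluorescence correlation spectroscopy infers the mobility and surface
density of fluorescently tagged membrane receptors from the intensity
fluctuations recorded in a femtoliter confocal volume parked on the upper
plasma membrane of a living cell.  The motivating application is the
adenosine A₃ receptor: quantifying how agonist treatment reorganizes the
receptor (and receptor–β-arrestin2 complexes trapped by bimolecular
fluorescence complementation, BiFC) — slower diffusion, higher particle
density, larger molecular brightness — at the single-cell level.

`fflux` packages the full analysis chain used in such experiments,
together with a forward simulator so that every stage can be validated
against known ground truths without any instrument:

- **`fflux.simkit`** — Brownian-dynamics forward model: 3D solution
  species and 2D membrane species diffusing through a 3D-Gaussian
  detection volume, two-state dark-state (triplet/blinking) kinetics, and
  Poisson photon emission; plus an Emax-shaped concentration-response
  generator.
- **`fflux.correlator`** — multi-tau autocorrelator (m = 16 channels per
  octave, ×2 rebinning, symmetric normalization) with a brute-force
  O(N·k) oracle for verification.
- **`fflux.acfmodels`** — the three standard autocorrelation models
  (calibration dye, fluorescent ligand with fixed free-ligand dwell time,
  two-component membrane receptor), beam-waist calibration
  ω = √(4·τ_D·D_ref), and the conversions D = ω²/(4·τ_D) and
  density = f·N/(π·ω²).
- **`fflux.pch`** — single- and two-component photon counting histogram
  models (exact compound-Poisson evaluation via the Panjer recursion)
  with the first-order out-of-focus correction F, and F-test model
  selection.
- **`fflux.doseresponse`** — Response = Emax·A/(A + EC50) fitting with a
  likelihood-ratio "no response" outcome, and percent-of-window
  normalization.
- **`fflux.pipeline`** — calibration → per-cell reads → condition
  summary tables (mean ± SEM), fully seeded.

The model surface, in the field's notation:

```
G(τ) = (1/N) · (1 + T/(1−T)·e^(−τ/τ_tr)) · Σ_i f_i·g_i(τ)
g_2D(τ) = (1 + τ/τ_Di)⁻¹
g_3D(τ) = (1 + τ/τ_Di)⁻¹ · (1 + τ/(S²·τ_Di))^(−1/2)
ω = √(4·τ_D,cal·D_ref)      A = π·ω²      D = ω²/(4·τ_D)
density (N/μm²) = f_selected · N / A
```

## Worked example

Simulate a 30 s membrane trace at the vehicle-condition ground truths
(36.7 receptors/μm², D = 0.13 μm²/s, ε = 18 111 counts·molecule⁻¹·s⁻¹),
then recover those numbers:

```python
import numpy as np
from fflux import acfmodels, correlator, pch, presets, simkit

volume = presets.DEFAULT_VOLUME            # ω = 0.2 μm, S = 5
config = presets.membrane_condition("gfp_vehicle", seed=1)
trace = simkit.simulate_trace(config)
print(f"mean count rate: {trace.mean_rate:.0f} cps")

curve = correlator.autocorrelate(trace)
fit = acfmodels.fit_membrane_acf(curve, volume)
D = fit.dominant_2d_D(volume)
density = acfmodels.derive_density(fit, volume, "sum_2d")
eps = pch.fit_pch(pch.compute_pch(trace, 1e-4), 1, F_fixed=0.0,
                  mdf="2d").components[0].epsilon
print(f"D = {D:.3f} um^2/s   density = {density:.1f} /um^2   "
      f"epsilon = {eps:.0f} cps")
```

Output from this exact snippet:

```
mean count rate: 46768 cps
D = 0.146 um^2/s   density = 43.4 /um^2   epsilon = 17315 cps
```

A single 30 s read carries real statistical noise (one cell's worth of
data); across 20 seeded cells the medians land on the generating values
within the tolerances quoted below.  The count rate is the product of
brightness, density and the beam-area integral of the detection profile;
D and density come from the autocorrelation decay and amplitude; ε from
the super-Poissonian width of the photon counting histogram.

The same chain is available from the shell:

```sh
fflux simulate --config sim.yaml --seed 1 --out trace.h5
fflux correlate trace.h5 --out curve.csv
fflux fit curve.csv --model membrane --calibration cal.json
fflux pch trace.h5 --bin-time 1e-4 --components auto --mdf 2d
fflux emax dose.csv
fflux run experiment.yaml --out results/   # calibration + cells + summary
```

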