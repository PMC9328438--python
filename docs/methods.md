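# Methods

This note records the models implemented in `fflux`, the assumptions
behind the synthetic-data generator, the numerical choices that matter,
and what the validation suite does and does not demonstrate.

## Forward model

Particles diffuse by independent Gaussian steps of standard deviation
√(2·D·dt) per axis in a periodic box.  Membrane (2D) species are
confined exactly to the focal plane z = 0; membrane curvature and
compartmentalization are not modeled.  Detection follows the
3D-Gaussian molecular detection function

    MDF(x, y, z) = exp(−2(x² + y²)/ω² − 2z²/z₀²),   z₀ = S·ω,

with beam waist ω (lateral 1/e² radius, μm) and structure parameter S.
Photon counts per bin are Poisson with rate background + Σ ε·MDF over
bright particles; ε is an effective detected counts·molecule⁻¹·s⁻¹ at
the beam center, i.e. laser power, quantum yield and detection
efficiency are folded into one number.  Photobleaching, the pre-bleach
step, detector afterpulsing and dead time are not modeled.

Dark-state (triplet/blinking) kinetics are a two-state telegraph
process with stationary dark fraction T and relaxation time τ_dark
(rates T/τ_dark bright→dark and (1−T)/τ_dark dark→bright).  Dwell
times are scheduled as geometric draws in units of dt, which is
distributionally identical to per-step Bernoulli flips; dt must be
≤ τ_dark/5 whenever a species has T > 0.

Particle numbers are grand-canonical: each species' count is a Poisson
draw at density × box measure, so the particle number in the
observation region has the Poisson statistics the FCS amplitude
N = c·πω² (2D) or c·π^{3/2}ω²z₀ (3D) assumes.

### Box geometry and its artifact

The box is periodic with lateral half-width box_scale·ω (default 8;
presets use 5) and axial half-width max(box_scale·ω, 2.5·z₀) — the
axial extension is needed because the detection volume's axial wings
decay much more slowly than the lateral ones, and a cubic box at
box_scale 5 would truncate them at 1 z₀.

A periodic box has a finite mixing time: concentration correlations on
the lowest spatial mode decay as exp(−D(2π/L)²τ), so beyond
τ ≈ 0.3·L²/(4π²D) the simulated autocorrelation falls below the
open-geometry model.  Fit windows are chosen to stay inside the
faithful regime (see below); the calibration preset uses a wide box
(box_scale 12.5) for the same reason, since the calibration dye is the
fastest species simulated.

### Time discretization

The dataclass defaults (dt = 1 μs, bin 2 μs) resolve dye triplet
kinetics.  The membrane-condition presets propagate and bin at 100 μs:
the slowest simulated process there is diffusive transit at
τ_D = ω²/4D ≈ 40–110 ms, resolved by three orders of magnitude, and the
receptor presets carry no dark state, so finer stepping would only add
cost.  The calibration presets step at 1 μs with τ_dark = 8 μs.

### What the generator does not emulate

Real membrane FCS data add photobleaching depletion, membrane
undulation and incomplete dark-state models, cell-to-cell expression
variability, detector artifacts, and out-of-focus fluorescence from the
cytosol.  Passing recovery tests therefore demonstrates that the
analysis chain is a correct estimator for the stated generative model —
not that it is robust to every systematic error of live-cell data.

## Multi-tau correlation

G(τ) = ⟨δI(t)δI(t+τ)⟩/⟨I⟩² with G(∞) = 0, so a single diffusing
species has amplitude 1/N.  The grid is the standard hardware scheme:
m = 16 linear channels covering lags 1..2m at native binning, then
channels m+1..2m per octave with counts rebinned ×2.  Normalization is
symmetric (each lag divides by the means of its leading and lagging
segments).  A brute-force evaluation of the definition at every integer
lag serves as the test oracle; the two agree to 1e-12 when given the
same normalization convention.  (The textbook global-mean normalization
is also available on the oracle and is its default, matching the
hand-computable two-bin example G([0,2], lag 1) = −1, which is undefined
under symmetric normalization.)

Fit weighting uses σ(τ) ∝ (1 + 1/⟨n⟩)/√npts, where npts is the number
of averaged products and ⟨n⟩ the mean counts per correlator bin at that
lag's level.  The 1/⟨n⟩ factor is the shot-noise (Koppel-type)
contribution; without it the sparsely populated microsecond channels
receive the largest weights and the photophysics term can absorb the
diffusion decay.

## Autocorrelation models and fitting

All models share the form
G(τ) = (1/N)(1 + T/(1−T)e^{−τ/τ_tr}) Σ f_i g_i(τ) with
g_2D = (1+τ/τ_D)⁻¹ and g_3D = (1+τ/τ_D)⁻¹(1+τ/(S²τ_D))^{−1/2}:

- **calibration** — one free 3D component plus the triplet term, fitted
  to a dye of known D; ω = √(4·τ_D·D_ref), A = π·ω².
- **ligand** — one 3D component with τ_D1 fixed to the free-ligand
  value plus two free 2D components (receptor-bound ligand) and the
  triplet term; bound ligand is carried by the slowest 2D component.
- **membrane** — two free 2D components plus a pre-exponential term for
  GFP/complemented-YFP photophysics.

Fitting is bounded nonlinear least squares (lmfit/trust-region) in an
amplitude parameterization A_i = f_i/N (positivity is then the only
constraint; N = 1/ΣA_i), with the second 2D dwell time expressed as
τ_D2·ratio, ratio ≥ 1, so ordering is enforced structurally.  Five
jittered starts are tried and the best χ² wins; the winner is invariant
under permutation of the start list.  If the two 2D dwell times end
within a factor of 2 the solution is declared degenerate and refit with
a single 2D component (flagged on the result).

Two estimator-level nuisance choices matter at single-read statistics:

- a free baseline offset G(∞), bounded to ±5% of the curve amplitude.
  The symmetric-normalized estimator of a finite read is biased low by
  a small constant (the estimated means absorb part of the
  fluctuation), which otherwise truncates the tail and biases τ_D
  short by ~10%; the bound covers the ~τ_D/T-scale bias of 30 s reads
  of ~70 ms processes without freeing the baseline enough to swallow a
  genuine slow component;
- fit windows: 4 μs–0.3 s for cell models and 4 μs–0.6 ms for the
  calibration model.  The lower edge excludes afterpulsing-scale lags;
  the upper edges keep the fit inside the well-averaged,
  box-faithful lag range.  In the calibration fit the photophysics term
  is additionally bounded T ≤ 0.6, τ_tr ≤ 20 μs — a calibration dye's
  triplet relaxation is well below its ~36 μs dwell time, and a looser
  bound lets the pre-exponential term ride a degenerate ridge with
  (τ_D, S).

S is fitted within [3, 10] for calibration and then frozen for cell
fits.  Note that S is only weakly identified (its signature lies at
τ ≳ S²τ_D where the curve is nearly decayed), which is the dominant
contribution to the ±7% beam-waist scatter of single calibration
reads.  "Fractional contribution" is implemented as amplitude fraction.
Densities use the summed 2D amplitude fraction for membrane/BiFC fits
and the slowest 2D component for ligand fits.

## Photon counting histogram

The single-particle count distribution over a reference region
(MDF ≥ 1e-8) is p1(k) = ∫ w(t)·Poisson(k; ε_b e^{−t}) dt with
t = −ln MDF and w(t) the volume density over amplitude — ∝ √t for the
3D Gaussian, constant for the 2D (in-plane) profile — evaluated by
300-node Gauss–Legendre quadrature.  Because particle numbers are
Poisson and particles independent, the full histogram is compound
Poisson and is evaluated exactly with the Panjer recursion (the
Poisson-weighted self-convolution in closed recursive form); species
convolve.  Shape factors are γ = 2^{−3/2} (3D) and 1/2 (2D) and N̄ is
referred to the effective volume π^{3/2}ω²z₀ (3D) or beam area πω²
(2D), so the modeled mean is Σ γ·ε_i·N̄_i·b exactly.

**First-order out-of-focus correction.**  F is implemented as an
independent Poisson photon stream with mean F × (in-focus mean
intensity) convolved into the histogram: to first order the
out-of-focus molecules are numerous and individually so dim that only
their summed mean emission matters, and uncorrelated dim emission is
Poisson light.  A multiplicative "(1+F) volume rescaling" of the k ≥ 1
single-particle probabilities was considered and rejected: under the
compound-Poisson structure it is exactly degenerate with N̄ (every
equation depends only on N̄(1+F)), so such an F cannot be estimated
even from perfect data.  F is fitted once on a calibration-dye
histogram (20 μs bins) and frozen for all subsequent fits; for
ideal-Gaussian data it recovers ≈ 0.

Membrane traces are fitted with the 2D-profile PCH by the pipeline:
the simulated membrane species lie exactly in the focal plane, and
fitting the 3D shape to planar data would bias ε by the ratio of shape
factors (≈ 1.4).  The 3D variant remains the default of the standalone
fitting functions, matching common instrument-software behavior on
real (quasi-2D) membranes.

Model selection between one and two brightness components is an F-test
on the χ² reduction at α = 0.01, with a guard that collapsed
two-component fits (ε₂ < 2ε₁) fall back to one component.

## Concentration-response

Response = basal + Emax·A/(A + EC50), Hill slope fixed at 1, fitted on
pEC50 = −log10 EC50 for conditioning.  A likelihood-ratio test against
the flat (constant) model at α = 0.05 declares "no response"; this
mirrors reporting potency only when a concentration-dependent signal
exists.  The basal offset is fittable or fixed at 0.

## Pipeline and aggregation

`run_experiment` mirrors the acquisition protocol: one beam-waist
calibration (dilute bright dye, 8 s read) and one PCH-correction
calibration (20 nM dye, 20 μs bins) per experiment, then per cell two
reads that are correlated separately and averaged before fitting, and a
pooled PCH per cell at 100 μs bins.  Aggregation is per cell
(mean ± SEM, n = successfully fitted cells); failed fits are excluded
and logged with reasons.  All seeds derive from one experiment seed
through `numpy.random.SeedSequence`, making runs byte-reproducible.

## Reference conditions and assumed parameters

The per-condition ground truths (density, D, ε for vehicle and
agonist-treated receptor, and the two BiFC brightness populations) are
the published in-cell values; the generator treats them as inputs and
the suite asks whether the analysis chain returns them.  Values the
source data do not pin down were chosen once as plausible and are
listed here as assumptions:

- calibration dyes: R6G/Cy5 reference D 280/316 μm²/s; triplet
  T = 0.15, τ_dark = 8 μs; ε = 150 kcps; beam-waist calibration at
  ≈1.2 nM (amplitude-optimal), PCH correction calibration at 20 nM;
- free fluorescent agonist: D = 100 μm²/s (τ_D1 = 100 μs at
  ω = 0.2 μm), ≈1.3 nM, ε = 40 kcps; bound-ligand condition: 1 /μm² of
  an intermediate component at 1.0 μm²/s and 6 /μm² of the slow bound
  component at 0.15 μm²/s (nearly a decade apart so both dwell times
  are identifiable), simulated in a wider box (box_scale 8) so the
  intermediate component's mixing time clears the fit window;
- BiFC conditions: the published total density split 50/50 between the
  dim and bright populations;
- membrane receptor photophysics: none (T = 0) — at 100 μs analysis
  bins a μs-scale GFP dark state is unresolvable, and the fitted
  pre-exponential term is retained in the model as a nuisance;
- background count rate: 0 by default, configurable.

Note one consequence of brightness heterogeneity: the FCS amplitude
reads the brightness-weighted apparent particle number
N_app = (Σc_iε_i)²/A·(Σc_iε_i²)⁻¹, so for the two-population BiFC
conditions the recovered density is the apparent (≈0.63× the true
total) value — exactly as it would be for the instrument.

## Problem sizes used in validation

Recovery checks use 20 simulated cells of one 30 s read per membrane
condition (median over cells; tolerances 20% on D and ε, 25% on
density), 5 cells of two averaged 30 s reads for the bound-ligand
condition, and single 8 s calibration reads per dye; the pipeline-level
tests run reduced replicas (1–2 cells, 5–8 s reads) with
correspondingly loose envelopes.  These sizes were chosen to keep the full suite's runtime in
the minutes range; the estimator properties they probe do not change
with longer traces, only the per-cell scatter does.

## Known limitations

- S is nearly unidentifiable from a single calibration read; downstream
  D values inherit ω² scatter of a few percent.
- The two-2D-component fit of truly single-component data correctly
  collapses (degeneracy flag) in most reads, but occasional split
  solutions survive and put the dominant component a few percent fast;
  medians over cells are robust to this.
- The dim BiFC brightness component sits near the identifiability
  limit at 60 s of data per cell; its per-cell scatter is large
  (medians over ≥10 cells are required for the 30% envelope).
- The PCH model assumes particles are static within a bin; for fast
  dyes at 20 μs bins intra-bin diffusion reshapes the histogram, and
  the F fitted on such a calibration trace absorbs that motion artifact
  (≈0.07 here) rather than reading 0.  A spurious F is nearly
  degenerate with a dim brightness component — its Poisson stream looks
  like very dim light — so freezing it biases two-component brightness
  fits; one-component (GFP-type) fits are insensitive.  Closure checks
  on the dim/bright BiFC pair therefore fit with F = 0, the generative
  truth for data that contain no out-of-focus light.
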