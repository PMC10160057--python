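# Methods

This note documents the models and conventions behind each stage of the
pipeline, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Depletion-corrected concentration reconstruction

Interval-sampled assays withdraw an aliquot `V_s` from the receiver
channel (volume `V_c`), measure its concentration `R_t`, and refill with
analyte-free buffer. The raw `R_t` therefore under-report cumulative
transport. Two corrections are implemented and tagged in the output:

* `literal_eq2` — the recursion
  `C_t = C_{t−1} + (R_t·V_c − R_{t−1}·V_s)/V_n` with defaults
  `V_c = 200 μL`, `V_s = 100 μL`, `V_n = 1000 μL`. The 1000 μL divisor is
  a reporting convention, not derivable from the channel and sample
  volumes, and the recursion does not close an exact mass balance; it is
  kept verbatim because published rates in this assay family were
  computed with it. A plausible origin is a dilution step before
  spectrophotometry, but that is not stated anywhere authoritative, so
  both modes are kept.
* `mass_balance` — the exact ledger under fresh-buffer replacement:
  `C_t = R_t + (V_s/V_c)·Σ_{i<t} R_i`, i.e. the current reading plus the
  concentration-equivalent of every aliquot already removed.

The two differ only by a constant factor in the fitted slope
(`V_c/V_n` on the increments, exactly when `V_s/V_c = 1/2` as in the
default protocol), so relative comparisons — fold-changes, efflux ratios,
inhibition percentages — are identical between modes. Absolute
quantities (`P_app`) should use `mass_balance`.

Readings are treated as concentrations (μM) throughout; unit labels
travel as metadata. `C_0 = R_0 = 0` by convention — the receiver contains
no analyte at assay start.

## Rates, apparent permeability, efflux

Transfer rates are ordinary least squares on the corrected course. The
default window is the full series; interval-sampled glucose-style assays
conventionally restrict to 0–3 h (`DEFAULT_GLUCOSE_WINDOW_MIN`), which
keeps the fit in the initial-rate regime. The (0, 0) point is included
and the intercept is free. Fits with r² < 0.8 are emitted with a quality
warning, never suppressed; calibration fits warn below r² = 0.99.
Calibration is OLS of concentration on signal with a free intercept —
blank subtraction is the caller's responsibility.

`P_app = (dC_r/dt)·V_r / (A·C_0)` converted to cm s⁻¹ — the standard
sink-condition form (receiver ≪ donor, donor approximately constant).
The efflux ratio is `slope_{b→a} / slope_{a→b}` from mirrored protocols;
a non-positive absorptive slope yields NaN with an explanatory flag
rather than an infinity. `inhibition% = 100·(1 − slope_inh/slope_ctrl)`.

Shear stress uses the shallow-rectangular-channel estimate
`τ = 6ηQ/(Wh²)` in CGS; η is interpreted in mPa·s (cP), the only reading
that reproduces the conventional 0.06 dyn cm⁻² at 10 μL min⁻¹ in a
1.0 × 0.35 mm channel with 0.7 mPa·s medium.

Reservoir assays (circulating source, e.g. 10 μL aliquots from a 3 mL
jar) are checked for cumulative depletion `n·V_s/V_source`; the
equilibrium assumption is flagged above a configurable 5% threshold.

## TEER processing

Raw four-probe resistances are baseline-subtracted (pre-seeding device
resistance) and multiplied by the membrane area to give Ω·cm². Points
below baseline are kept but flagged, since they usually mean probe
drift.

Smoothing is a zero-phase hard spectral cutoff at `f3dB = 1/(2nΔt)`
(0.167 day⁻¹ at the conventional n = 6, Δt = 0.5 day) applied to the
mean-detrended series with the mean restored. Two boundary treatments
are provided, both *exact orthogonal projections* — hence exactly
idempotent, energy-nonincreasing and mean-preserving:

* `extension='even'` (default): the cutoff is applied in the spectrum of
  the even-symmetric extension (DCT-II basis). A growing TEER curve then
  has no wrap-around discontinuity, so no Gibbs ringing contaminates the
  trace ends — essential for plateau detection near the end of culture.
  The price is imperfect stopband rejection for tones misaligned with
  the boundary (leakage O(1/N), about 12% of the tone amplitude for a
  33-point trace).
* `extension='periodic'`: classical FFT-bin zeroing. Integer-cycle tones
  above the cutoff are annihilated exactly, but trended data ring at the
  edges. Use for genuinely periodic or detrended inputs.

Non-uniform sampling is rejected with an instruction to resample;
`resample_uniform` does linear interpolation onto a Δt grid. Series
shorter than two cutoff periods (2/f3dB) are passed through with a
warning rather than filtered — there is no meaningful passband to keep.

Normalization divides by a reference steady state (default 60 Ω·cm², a
mature RPTEC monolayer); the steady-state summary is the mean ± sample
SD over the last 4 days of culture by default. Smoothing is per chip by
default; averaging across chips before smoothing is equally possible by
passing the mean trace.

Plateau detection is deliberately simple plumbing: maximal runs of
duration ≥ 1 day where the central-difference slope magnitude stays
within 5% of the trace range per day, on smoothed input, both knobs
configurable. Levels are interval means.

## Polarity profiling (Δd)

Profiles are per-channel means over (y, x) at each z-plane, z in μm from
the first plane. Peaks are global maxima after Gaussian smoothing with
σ = 1 z-pitch by default (the profile itself is left untouched); exact
ties break toward the basal-most plane, a documented convention for
noise-free synthetic edge cases.
`Δd = s·(z_peak(marker) − z_peak(DAPI))`, `s = +1` when apical is toward
increasing z. The orientation cannot be inferred from data and is a
required input. Δd is signed internally (positive = apical of nuclei);
summary tables also report the magnitude, which is how such distances
are usually plotted. No background subtraction is applied by default; a
constant-percentile floor is optional.

Known bias: cell-height-like quantities read off z-profiles are
foreshortened when the supporting membrane is not flat, and apical
markers need not sit at the cell apex; no flatness correction is
implemented. Profile-derived distances should be compared within, not
across, imaging configurations.

Morphometry is annotation-table based (protrusion counts, periphery
lengths, villus lengths, cell heights measured manually on TEM
cross-sections); automatic feature extraction from micrographs is out of
scope. Villi density is count/periphery (μm⁻¹). Group summaries are
sample mean ± SD with group sizes. The two-group comparison is a Welch
t-test (unequal variances) at α = 0.05 with stars *, **, ***, **** at
p ≤ 0.05, 0.01, 0.001, 0.0001; two constant identical groups report
p = 1 with a degeneracy warning instead of crashing.

## Synthetic generators

All generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; identical seeds give bit-identical outputs.

**Transport.** Two well-mixed compartments exchange solute across the
membrane: a linear passive leak `P·A·(C_a − C_b)` plus a saturable
carrier `Vmax·C_src/(Km(1 + I/K_i) + C_src)` drawing from its source-side
channel. This Michaelis–Menten-with-competitive-inhibition form is a
deliberate stand-in: it is the simplest mechanism consistent with the
use of competitive inhibitors and with linear initial-rate analysis, and
no kinetic constants are claimed for real tissue. Membrane hindrance and
paracellular leak are folded into the effective `P`. `I = inf` is
supported and makes the carrier term exactly zero, so a fully inhibited
run is bit-identical to a passive-only run at the same seed.

Integration is fixed-step RK4 with ≥ 100 steps per sampling interval; a
negative excursion triggers re-integration at 10× resolution. Sampling
events withdraw `V_s`, record the concentration with multiplicative
Gaussian noise (default CV 2% — a plate-reader-scale placeholder, fully
configurable since real instrument CVs vary), and refill with fresh
buffer (or shrink the working volume when `replacement='none'`). Mass
(channels + withdrawn aliquots) is conserved to float rounding; the
truth record carries the running audit, the analytic initial flux and
the expected initial-flux efflux ratio
`1 + Vmax·C_0/((Km_eff + C_0)·P·A·C_0)` for a basal→apical pump.

Defaults are chosen as realistic chip conditions and then left alone:
`P = 3e-6 cm s⁻¹` (membrane-hindered; donor depletion stays below ~3%
over the default 6 × 1 h protocol so the sink assumption holds),
`C_0 = 2.5 μM`, 200 μL channels, 0.1 cm² membrane.

**TEER.** Sum of one or two logistic components plus Gaussian noise
(σ = 1 Ω·cm²) on a 20-day, Δt = 0.5 day grid; defaults place rise
midpoints at day 3 and 12 with 0.5-day widths and asymptotes 40 + 20
Ω·cm², i.e. a coculture-style double plateau saturating at the 60 Ω·cm²
reference. The truth records the cumulative plateau levels.

**Z-stacks.** Per-channel Gaussian intensity slabs along z (constant
across the scan plane) sampled at the stated pitch (200 nm default),
with Poisson noise whose gain is set so the per-voxel SNR at the profile
peak equals the requested value. The truth records the generating
centres and true Δd separations.

**Morphometry.** Truncated-normal draws per group (counts rounded,
everything floored just above zero).

What the generators deliberately do not emulate: lateral structure
within a z-plane (real stacks have cells, not slabs), spatially resolved
transport or unstirred layers, cell growth or death during an assay,
TEER electrode artifacts beyond additive noise, and instrument-specific
noise spectra. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated models, not robustness to
every failure mode of real data.

## Numerical and interface conventions

* Assay time is minutes internally, TEER time days; conversions happen
  only at the I/O boundary, and units are mandatory in every file
  (column names or explicit unit columns/keys).
* All randomized tests and generators take explicit integer seeds; there
  is no global random state.
* Validation is eager: containers reject impossible field combinations
  at construction, readers reject malformed rows with line numbers, and
  the CLI maps validation failures to exit code 2, computation failures
  to 3.
* Every CLI run writes a YAML manifest (tool version, parameters, input
  SHA-256 checksums, seed, timestamp); primary CSV outputs are
  byte-identical across reruns with identical inputs and seeds.

## Problem sizes used in the acceptance script

The acceptance script uses 1000 random series (length ≤ 20) for the
reconstruction-oracle comparison, 100 seeded replicates for passive
permeability recovery, 100 random parameter sets for the
mass-conservation audit, 100 stacks of shape 51 × 24 × 24 at SNR 10 for
Δd recovery, and a single 41-point TEER trace for the smoothing and
plateau checks — sizes at which every recovery criterion is stable
across seeds while the whole script runs in seconds.
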