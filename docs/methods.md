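# Methods

## Problem and scope

The package compares DFT-computed vibrational spectra of two drug–receptor
binding-site complexes (clopidogrel thiol metabolite H4 + arginine, from the
P2Y12 receptor; aspirin + arginine, from COX-1) with experimental SERS
spectra of platelets, and nominates *joint* normal modes — modes displacing
atoms of both the drug and the receptor residue — as candidate biomarker
bands of drug binding.  Electronic-structure computation, docking and
homology modelling are upstream of this package: its inputs are mode tables
(wavenumber, Raman activity, molecule attribution) and two-column measured
spectra.

## Theoretical spectrum construction

1. **Linear wavenumber scaling.**  ν_ex = ν_th·(a·ν_th + b) with defaults
   a = −0.0000083526 cm and b = 0.98134 (appropriate for B3LYP/6-31G(d)
   harmonic frequencies).  The relation is printed as the ratio
   ν_ex/ν_th = a·ν_th + b; multiplying through by ν_th is the only reading
   consistent with a scaling of wavenumbers.  With these coefficients the
   map is strictly increasing on (0, 4000] (derivative 2aν + b ≥ 0.914
   everywhere in range), so scaling never reorders modes.

2. **Activity → intensity.**
   I_i = f(ν₀−ν_i)⁴A_i / (ν_i·[1−exp(−c₂ν_i/T)]), with c₂ = hc/k computed
   from scipy's CODATA constants (≈ 1.438777 cm·K).  Defaults: ν₀ = 10⁷/532
   cm⁻¹ (the instrument's 532 nm laser line), T = 298.15 K (the measurement
   is at room temperature; the source work does not state a value, so room
   temperature is assumed and configurable).  f defaults to "auto": the
   synthesized spectrum is rescaled so its maximum is 100, matching the
   display convention of the normalized experimental spectra.

3. **Lorentzian broadening.**  Height-normalized Lorentzians,
   L(ν) = I_i·γ²/((ν−ν_i)²+γ²) with γ = FWHM/2 and FWHM = 5 cm⁻¹.  Height
   (not area) normalization keeps printed mode strengths directly comparable
   to stem heights in overlay plots.  The default theory grid is 400–1800
   cm⁻¹ at 0.5 cm⁻¹, fine enough to resolve the 5 cm⁻¹ width.

**Fixture mode.**  The transcribed tables print a "Raman strength" column of
unstated units, and their wavenumbers are recorded as printed (the overlay
figures are captioned "after frequency adjustment", so the tables are
treated as already scaled).  `fixture_spectrum` therefore uses the printed
strengths directly as peak heights, with no intensity conversion and no
re-scaling; full conversion (`synthesize_spectrum`) is for genuine
frequency-job output, where activities are in Å⁴/amu.

## Experimental preprocessing

The fixed grid has centers 400, 405, …, 1800 cm⁻¹ — 281 cells.  "Grid
cells" are realised as nearest-center assignment with a half-step catchment
on each side; a sample exactly halfway between two centers goes to the
lower one (deterministic tie-break).  Bin intensity is the arithmetic mean
of its samples; empty bins stay missing (no interpolation) and are excluded
from detection and matching — the package never invents signal.  Replicate
averaging is a per-bin arithmetic mean, with a bin missing only if missing
in all replicates; averaging happens before normalization by default (the
order is configurable, as the source protocol does not state it).
Normalization multiplies by 100/max and is exactly idempotent.  Baseline
subtraction, smoothing and wavenumber calibration are instrument-side and
out of scope.

## Fragment attribution

The printed tables assign each mode to "Metabolite"/"Aspirin", "Arginine",
or mark it with a dash (joint) without stating a rule.  Table labels are
therefore authoritative and pass through verbatim.  For inputs carrying
per-atom displacements, the package provides the standard surrogate: the
participation fraction of fragment F is Σ_{i∈F} m_i|d_i|² / Σ_i m_i|d_i|²
(mass-weighted squared displacement), and a mode is labelled F when its
fraction reaches a threshold θ (default 0.8, configurable; θ ∈ (0.5, 1] so
at most one fragment can win), otherwise *joint*.  When both sources exist,
table labels win.

## Band detection, matching, biomarker selection

Bands are strict local maxima of the present bins with topographic
prominence ≥ 5% of the spectrum maximum (scipy `find_peaks`).  The 5%
default replaces the by-eye marking of characteristic bands with a low
deterministic threshold; it is exposed in config.

Matching is greedy globally-closest one-to-one pairing within a tolerance
(default 10 cm⁻¹: the known 997↔1001 pair is 4 cm⁻¹ apart and no plausible
pair exceeds ~10), with ties broken toward the lower mode wavenumber then
the lower band — fully deterministic.  Shift sign is experimental −
theoretical, so the phenylalanine case reads +4 cm⁻¹.  An overall spectral
shift is estimated as the median of per-pair shifts (robust to occasional
mispairings among blended peaks).

Biomarker selection: all joint modes inside the region of interest, ordered
by wavenumber.  For the clopidogrel complex this rule reproduces the curated
13-mode list exactly.  The curated aspirin list differs from the joint rule
in four rows (two single-fragment modes included, two joint modes excluded)
and no selection rule for those is stated; the membership is therefore
shipped as an explicit include/exclude override *fixture*
(`aspirin_table3_override.json`), data rather than inferred logic.

## Synthetic data

The generator emulates what the analysis assumes about its inputs, so every
stage is testable without deposited data: mode wavenumbers uniform over
400–1800 cm⁻¹; activities log-uniform over [0.01, 1.5] (the dynamic range of
the printed strengths); joint labels with probability 0.11 (13 of 120
transcribed modes are joint); spectra as Lorentzian peaks (FWHM 5 cm⁻¹) plus
a low-order polynomial baseline (default gentle quadratic at ~10% of peak
height) plus additive zero-mean Gaussian noise with sd 2% of the signal
maximum, the level at which shift recovery is specified to hold.  An
injected wavenumber shift displaces every peak before binning.  All draws
derive from one integer seed.

What the generator does *not* emulate: plasmonic enhancement physics,
cosmic-ray spikes, detector nonlinearity, wavenumber miscalibration, and
correlated (non-white) noise.  A green end-to-end test therefore establishes
that the pipeline recovers shifts under the stated noise model, not under
every instrumental pathology.

The end-to-end recovery surface uses 10 modes per synthetic world: with the
full 120-mode density, 5 cm⁻¹-wide peaks overlap heavily on a 5 cm⁻¹ grid
and band detection is no longer a per-mode operation; ten well-spread modes
mirror the handful of marked characteristic bands per experimental spectrum.
Recovered shifts are quantized by the 5 cm⁻¹ experimental grid, hence the
one-grid-step acceptance band (half a step at zero noise).

## Numerical choices and degenerate inputs

- Duplicate wavenumbers in raw spectra are averaged, not rejected (tolerant
  ingestion of instrument exports); duplicate mode indices are an error.
- Empty mode tables synthesize an all-zero spectrum with a logged warning;
  all-zero or all-missing spectra refuse normalization.
- Mode tables are kept sorted by wavenumber with index as tie-break; two
  modes may share a wavenumber (the transcribed tables do).
- The intensity conversion requires 0 < ν_i < ν₀; violations raise domain
  errors rather than producing negative fourth powers.
- Pipeline outputs carry no timestamps; a manifest records the config echo,
  a config hash, input/output sha256 checksums and the seed, so identical
  inputs reproduce identical bytes.

## Known limitations

- The frequency-log parser targets the conventional three-modes-per-block
  text layout only; other quantum-chemistry output dialects are out of scope.
- The headline overlay figures of the source study are not numerically
  reproducible: neither the raw unscaled frequencies nor the experimental
  spectra are deposited.  The package's quantitative guarantees are the
  worked-example values from the transcribed tables plus property-level
  identities and synthetic parameter recovery.
- Statistical comparison of band intensities between therapy groups is
  deliberately absent (none is defined for this analysis).
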