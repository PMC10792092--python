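"""Synthetic inputs with the statistical structure the analysis assumes.

No raw frequency-job output or experimental spectra are deposited for this
system, so every pipeline stage is exercised against generated data: mode
tables with realistic wavenumber and activity spreads, and SERS-like spectra
built from Lorentzian peaks over a smooth polynomial baseline with additive
Gaussian noise.  A controlled wavenumber shift can be injected into the
generated spectrum to test shift recovery end to end.

Defaults mirror the fixture world: ~120 modes across the 400–1800 cm⁻¹
fingerprint window, activities log-uniform over [0.01, 1.5] (the dynamic
range of the printed Raman strengths), a joint-mode probability of 0.11
(13 of 120 modes in the clopidogrel table are joint), 2% additive noise and
a gentle quadratic baseline.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .errors import PackagingError, SchemaError
from .exp_preprocess import GridSpec
from .spectra_model import lorentzian_sum
from .vib_io import ModeTable, RawSpectrum, VibrationalMode


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world; ``seed`` fixes every draw."""

    n_modes: int = 120
    wavenumber_range: tuple[float, float] = (400.0, 1800.0)
    activity_law: tuple[float, float] = (0.01, 1.5)
    joint_fraction: float = 0.11
    baseline_coeffs: tuple[float, ...] = (0.1, 0.1, -0.05)
    noise_sd: float = 0.02
    injected_shift: float = 0.0
    fwhm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.wavenumber_range
        if not 0 < lo < hi:
            raise SchemaError(f"invalid wavenumber range ({lo}, {hi})")
        alo, ahi = self.activity_law
        if not 0 < alo < ahi:
            raise SchemaError(f"invalid activity law interval ({alo}, {ahi})")
        if not 0 <= self.joint_fraction <= 1:
            raise SchemaError(f"joint_fraction must be in [0, 1], got {self.joint_fraction}")
        if self.n_modes < 1:
            raise SchemaError(f"n_modes must be >= 1, got {self.n_modes}")
        if self.noise_sd < 0:
            raise SchemaError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_mode_table(spec: SyntheticSpec, complex_name: str = "synthetic") -> ModeTable:
    """Draw a reproducible mode table.

    Wavenumbers uniform over the range (sorted ascending), activities
    log-uniform over the activity law interval, fragments joint with
    probability ``joint_fraction`` and otherwise ligand/residue with equal
    probability.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.wavenumber_range
    wavenumbers = np.sort(rng.uniform(lo, hi, spec.n_modes))
    alo, ahi = spec.activity_law
    activities = np.exp(rng.uniform(np.log(alo), np.log(ahi), spec.n_modes))
    u = rng.uniform(size=spec.n_modes)
    side = rng.uniform(size=spec.n_modes)
    modes = []
    for i in range(spec.n_modes):
        if u[i] < spec.joint_fraction:
            fragment = "joint"
        else:
            fragment = "ligand" if side[i] < 0.5 else "residue"
        modes.append(
            VibrationalMode(
                index=i + 1,
                wavenumber=float(wavenumbers[i]),
                raman_activity=float(activities[i]),
                fragment=fragment,
                description="synthetic",
            )
        )
    return ModeTable(complex_name=complex_name, modes=modes, provenance="synthetic")


def generate_sers_spectrum(
    table: ModeTable,
    spec: SyntheticSpec,
    grid: GridSpec = GridSpec(),
) -> RawSpectrum:
    """Emulate a SERS acquisition of the given mode table on a grid.

    Signal = Lorentzian peaks at the mode positions shifted by
    ``injected_shift`` with heights equal to the activities, plus a
    polynomial baseline evaluated on the normalized wavenumber coordinate
    (coefficients in units of the tallest peak), plus zero-mean Gaussian
    noise of standard deviation ``noise_sd`` × the signal maximum.
    """
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the table draw
    w = grid.centers()
    centers = table.wavenumbers() + spec.injected_shift
    heights = table.activities()
    signal = lorentzian_sum(w, centers, heights, spec.fwhm)
    peak = float(signal.max()) if signal.size else 0.0
    if peak > 0 and any(c != 0 for c in spec.baseline_coeffs):
        x = (w - grid.start) / (grid.stop - grid.start)
        baseline = peak * np.polynomial.polynomial.polyval(x, spec.baseline_coeffs)
        signal = signal + np.clip(baseline, 0.0, None)
    if spec.noise_sd > 0 and peak > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd * peak, size=w.shape)
    signal = np.clip(signal, 0.0, None)
    return RawSpectrum(w, signal, label=f"synthetic(seed={spec.seed})")


def recover_injected_shift(
    spec: SyntheticSpec,
    grid: GridSpec = GridSpec(),
    tolerance: float = 10.0,
    prominence_fraction: float = 0.05,
) -> float:
    """End-to-end shift recovery on one synthetic world.

    Generates a mode table and a spectrum with ``spec.injected_shift``, bins
    and normalizes the spectrum, detects bands, matches the *unshifted* mode
    positions against them, and returns the median matched shift.  With the
    5 cm⁻¹ experimental grid the recovered value is quantized to grid steps.
    """
    from .band_matching import detect_bands, estimate_shift, match_modes_to_bands
    from .exp_preprocess import bin_spectrum, normalize_to_100

    table = generate_mode_table(spec)
    raw = generate_sers_spectrum(table, spec, grid)
    binned = normalize_to_100(bin_spectrum(raw, grid))
    bands = detect_bands(binned, prominence_fraction)
    matches = match_modes_to_bands(table.modes, bands, tolerance)
    return estimate_shift(matches)


def make_paper_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Copy the packaged fixture transcriptions into ``out_dir``.

    Every file is verified against its packaged sha256 checksum before and
    after the copy; a mismatch raises :class:`PackagingError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in datasets.FIXTURE_FILES:
        src = datasets.fixture_path(name)  # verifies the packaged checksum
        dst = out_dir / name
        shutil.copyfile(src, dst)
        if datasets.sha256_of(dst) != datasets.sha256_of(src):
            raise PackagingError(f"copy of {name} does not match its source")
        written[name] = dst
    return written
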