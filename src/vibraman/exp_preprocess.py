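"""Fixed-grid preprocessing of experimental SERS spectra.

Mirrors the instrument-side statistical treatment: decompose each spectrum
onto a fixed wavenumber grid covering the fingerprint region (400–1800 cm⁻¹
in 5 cm⁻¹ steps), average replicate acquisitions, and normalize so the
strongest band reads 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GridError, NormalizationError, SchemaError
from .vib_io import RawSpectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Fixed wavenumber grid: centers start, start+step, ..., stop."""

    start: float = 400.0
    stop: float = 1800.0
    step: float = 5.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise GridError(f"grid start {self.start} must be < stop {self.stop}")
        if not self.step > 0:
            raise GridError(f"grid step must be > 0, got {self.step}")
        span = (self.stop - self.start) / self.step
        if abs(span - round(span)) > 1e-9:
            raise GridError(
                f"(stop - start) = {self.stop - self.start} is not divisible by step {self.step}"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def centers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_bins)


@dataclass
class BinnedSpectrum:
    """A spectrum on a fixed grid; NaN intensity marks a missing bin."""

    grid: GridSpec
    intensities: np.ndarray
    n_contributing: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if self.intensities.shape != (self.grid.n_bins,):
            raise SchemaError(
                f"expected {self.grid.n_bins} bins, got {self.intensities.shape}"
            )
        if self.n_contributing.shape != self.intensities.shape:
            raise SchemaError("n_contributing must match the bin count")
        present = ~np.isnan(self.intensities)
        if np.any(self.intensities[present] < -1e-12):
            raise SchemaError("binned intensities must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return self.grid.centers()

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.intensities)


def bin_spectrum(raw: RawSpectrum, grid: GridSpec = GridSpec()) -> BinnedSpectrum:
    """Assign each sample to its nearest bin center and average within bins.

    Catchment is half a step on either side of each center; a sample exactly
    halfway between two centers goes to the lower one.  Samples outside
    [start − step/2, stop + step/2) are dropped (and counted in the log).
    Bins that receive no samples are marked missing (NaN).
    """
    w = raw.wavenumbers
    y = raw.intensities
    in_range = (w >= grid.start - grid.step / 2) & (w < grid.stop + grid.step / 2)
    dropped = int(np.count_nonzero(~in_range))
    if dropped:
        logger.info("bin_spectrum(%s): dropped %d of %d out-of-range samples",
                    raw.label, dropped, w.size)
    w, y = w[in_range], y[in_range]
    if w.size == 0:
        raise GridError(
            f"no samples of {raw.label!r} fall inside [{grid.start}, {grid.stop}] cm^-1"
        )
    # round half-down: ties between two centers go to the lower center
    frac = (w - grid.start) / grid.step
    idx = np.ceil(frac - 0.5).astype(int)
    idx = np.clip(idx, 0, grid.n_bins - 1)  # the inclusive lower range edge maps to bin 0
    sums = np.zeros(grid.n_bins)
    counts = np.zeros(grid.n_bins, dtype=int)
    np.add.at(sums, idx, y)
    np.add.at(counts, idx, 1)
    intensities = np.full(grid.n_bins, np.nan)
    nonzero = counts > 0
    intensities[nonzero] = sums[nonzero] / counts[nonzero]
    return BinnedSpectrum(grid, intensities, counts, label=raw.label)


def average_replicates(spectra: Sequence[BinnedSpectrum], label: str = "") -> BinnedSpectrum:
    """Per-bin arithmetic mean over replicate spectra on identical grids.

    A bin is missing in the output only if it is missing in every replicate;
    otherwise the mean runs over the replicates in which it is present.
    """
    if not spectra:
        raise GridError("average_replicates needs at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridError(f"mixed grids: {s.grid} vs {grid}")
    stack = np.vstack([s.intensities for s in spectra])
    counts = np.vstack([s.n_contributing for s in spectra])
    present = ~np.isnan(stack)
    n_present = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_present > 0, np.nansum(stack, axis=0) / np.maximum(n_present, 1), np.nan)
    n_contributing = np.where(present, counts, 0).sum(axis=0)
    if not label:
        label = spectra[0].label
    return BinnedSpectrum(grid, mean, n_contributing, label=label)


def normalize_to_100(spec: BinnedSpectrum) -> BinnedSpectrum:
    """Scale so the maximum present intensity equals exactly 100. Idempotent."""
    present = spec.present
    if not np.any(present):
        raise NormalizationError(f"{spec.label!r}: all bins missing, cannot normalize")
    peak = np.nanmax(spec.intensities)
    if not peak > 0:
        raise NormalizationError(f"{spec.label!r}: maximum intensity is {peak}, cannot normalize")
    return BinnedSpectrum(
        spec.grid,
        spec.intensities * (100.0 / peak),
        spec.n_contributing.copy(),
        label=spec.label,
    )


def write_binned_tsv(spec: BinnedSpectrum, path: str | Path) -> Path:
    """Write bin_center / intensity / n_contributing columns; missing bins blank."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("bin_center\tintensity\tn_contributing\n")
        for c, y, n in zip(spec.centers, spec.intensities, spec.n_contributing):
            val = "" if math.isnan(y) else f"{y:.6f}"
            fh.write(f"{c:g}\t{val}\t{int(n)}\n")
    return path


def read_binned_tsv(path: str | Path, label: str | None = None) -> BinnedSpectrum:
    path = Path(path)
    centers: list[float] = []
    vals: list[float] = []
    ns: list[int] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            centers.append(float(parts[0]))
            vals.append(float(parts[1]) if parts[1] else np.nan)
            ns.append(int(parts[2]))
    arr = np.asarray(centers)
    step = float(arr[1] - arr[0])
    grid = GridSpec(start=float(arr[0]), stop=float(arr[-1]), step=step)
    return BinnedSpectrum(grid, np.asarray(vals), np.asarray(ns),
                          label=label if label is not None else path.stem)
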