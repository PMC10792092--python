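"""Theoretical Raman spectrum construction.

Three steps turn a table of harmonic normal modes into a continuous
theoretical spectrum:

1. **Wavenumber scaling.**  Harmonic frequencies computed at a given
   functional/basis overestimate observed band positions; an empirical linear
   correction maps the computed wavenumber ν_th onto the expected
   experimental position via the ratio form ν_ex/ν_th = a·ν_th + b, i.e.
   ν_ex = ν_th·(a·ν_th + b).  The default coefficients
   a = −0.0000083526 cm, b = 0.98134 are the published values for the
   B3LYP/6-31G(d) level of theory.

2. **Activity → intensity conversion.**  The computed Raman scattering
   activity A_i of mode i is converted to a relative differential Raman
   intensity

       I_i = f · (ν₀ − ν_i)⁴ · A_i / { ν_i · [1 − exp(−h c ν_i / k T)] }

   where ν₀ is the excitation wavenumber, T the temperature, and f a common
   normalization factor.  The combination h·c/k is the second radiation
   constant c₂ ≈ 1.4388 cm·K.  By default f is chosen so the synthesized
   spectrum maximum equals 100, matching the display convention used for the
   experimental spectra.

3. **Lorentzian broadening.**  Each mode contributes a height-normalized
   Lorentzian of full width at half-maximum 5 cm⁻¹ centred at its (scaled)
   position; the spectrum is the sum over modes.

For transcribed table fixtures whose "Raman strength" column is of unstated
units, :func:`fixture_spectrum` skips step 2 and uses the printed strengths
directly as peak heights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import constants

from .errors import DomainError, SchemaError
from .vib_io import ModeTable, VibrationalMode

logger = logging.getLogger(__name__)

#: Second radiation constant h·c/k in cm·K (CODATA, exact since the 2019 SI).
C2_CM_K: float = 100.0 * constants.h * constants.c / constants.k

#: Published linear scaling coefficients for B3LYP/6-31G(d) harmonic wavenumbers.
SCALING_A: float = -0.0000083526
SCALING_B: float = 0.98134

#: 532 nm excitation expressed as a wavenumber.
DEFAULT_EXCITATION_CM: float = 1.0e7 / 532.0


@dataclass(frozen=True)
class ScalingModel:
    """Coefficients of the linear wavenumber scaling ν_ex/ν_th = a·ν_th + b."""

    a: float = SCALING_A
    b: float = SCALING_B

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise SchemaError(f"scaling coefficient b must be > 0, got {self.b}")
        # a·ν + b must stay positive over the supported range (0, 4000]
        if self.a * 4000.0 + self.b <= 0:
            raise SchemaError(
                f"scaling model (a={self.a}, b={self.b}) is non-positive within (0, 4000] cm^-1"
            )


#: The published scaling model, ready to use.
PAPER_SCALING = ScalingModel()


@dataclass(frozen=True)
class IntensityParams:
    """Parameters of the activity-to-intensity conversion.

    ``f=None`` requests the auto-normalization policy: the common factor is
    chosen per spectrum so the synthesized maximum equals 100.
    """

    nu0: float = DEFAULT_EXCITATION_CM
    temperature: float = 298.15
    f: float | None = None
    c2: float = C2_CM_K

    def __post_init__(self) -> None:
        if not self.nu0 > 0:
            raise SchemaError(f"excitation wavenumber must be > 0, got {self.nu0}")
        if not self.temperature > 0:
            raise SchemaError(f"temperature must be > 0 K, got {self.temperature}")
        if self.f is not None and not self.f > 0:
            raise SchemaError(f"normalization factor must be > 0, got {self.f}")
        if not self.c2 > 0:
            raise SchemaError("second radiation constant must be > 0")


@dataclass(frozen=True)
class LineshapeParams:
    """Lorentzian FWHM and the evaluation grid for synthesized spectra.

    The default grid covers the fingerprint window 400–1800 cm⁻¹ at
    0.5 cm⁻¹, fine enough to resolve the 5 cm⁻¹ FWHM.
    """

    fwhm: float = 5.0
    grid_min: float = 400.0
    grid_max: float = 1800.0
    grid_step: float = 0.5

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise SchemaError(f"FWHM must be > 0, got {self.fwhm}")
        if not self.grid_min < self.grid_max:
            raise SchemaError("grid_min must be < grid_max")
        if not self.grid_step > 0:
            raise SchemaError("grid_step must be > 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return self.grid_min + self.grid_step * np.arange(n + 1)


@dataclass
class Spectrum:
    """A synthesized spectrum: strictly increasing grid plus intensities."""

    grid: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.grid.shape != self.intensities.shape:
            raise SchemaError("grid and intensities must have equal length")
        if not np.all(np.diff(self.grid) > 0):
            raise SchemaError("grid must be strictly increasing")
        if np.any(self.intensities < 0):
            raise SchemaError("intensities must be nonnegative")


def scale_wavenumber(nu_th: float | np.ndarray, model: ScalingModel = PAPER_SCALING):
    """Apply the linear wavenumber scaling: ν_ex = ν_th·(a·ν_th + b).

    Accepts scalars or arrays; raises :class:`DomainError` if any result is
    non-positive (coefficients invalid for that wavenumber).
    """
    nu = np.asarray(nu_th, dtype=float)
    if np.any(nu <= 0):
        raise DomainError("computed wavenumber must be > 0")
    scaled = nu * (model.a * nu + model.b)
    if np.any(scaled <= 0):
        raise DomainError(
            f"scaling model (a={model.a}, b={model.b}) yields non-positive wavenumber"
        )
    return float(scaled) if np.isscalar(nu_th) else scaled


def activity_to_intensity(
    mode: VibrationalMode | float,
    params: IntensityParams = IntensityParams(),
    activity: float | None = None,
) -> float:
    """Convert a Raman activity to a relative Raman intensity.

    ``mode`` may be a :class:`VibrationalMode` or a bare wavenumber (with
    ``activity`` supplied separately).  Uses f = 1 when the params request
    auto-normalization, since the common factor only scales whole spectra.
    """
    if isinstance(mode, VibrationalMode):
        nu, act = mode.wavenumber, mode.raman_activity
    else:
        nu = float(mode)
        if activity is None:
            raise DomainError("activity must be given when mode is a bare wavenumber")
        act = float(activity)
    if nu <= 0:
        raise DomainError(f"mode wavenumber must be > 0, got {nu}")
    if nu >= params.nu0:
        raise DomainError(
            f"mode wavenumber {nu} cm^-1 is not below the excitation {params.nu0} cm^-1"
        )
    f = 1.0 if params.f is None else params.f
    thermal = 1.0 - np.exp(-params.c2 * nu / params.temperature)
    return f * (params.nu0 - nu) ** 4 * act / (nu * thermal)


def lorentzian_sum(
    grid: np.ndarray, centers: np.ndarray, heights: np.ndarray, fwhm: float
) -> np.ndarray:
    """Sum of height-normalized Lorentzians: Σ_i h_i·γ²/((ν−c_i)²+γ²), γ=FWHM/2."""
    gamma = fwhm / 2.0
    grid = np.asarray(grid, dtype=float)
    centers = np.asarray(centers, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if centers.size == 0:
        return np.zeros_like(grid)
    diff = grid[:, None] - centers[None, :]
    return (heights[None, :] * gamma**2 / (diff**2 + gamma**2)).sum(axis=1)


def synthesize_spectrum(
    table: ModeTable,
    scaling: ScalingModel | None = PAPER_SCALING,
    params: IntensityParams = IntensityParams(),
    shape: LineshapeParams = LineshapeParams(),
) -> Spectrum:
    """Full theoretical spectrum: scale positions, convert activities, broaden.

    Peak heights are the converted intensities I_i; a lone mode evaluated at
    its own centre yields exactly I_i (height normalization).  With the
    default ``f=None`` policy the spectrum is rescaled so its maximum is 100.
    """
    grid = shape.grid()
    if len(table) == 0:
        logger.warning("synthesize_spectrum: empty mode table for %r", table.complex_name)
        return Spectrum(grid, np.zeros_like(grid), meta={"complex": table.complex_name,
                                                         "scaled": False, "empty": True})
    positions = table.wavenumbers()
    if scaling is not None:
        positions = scale_wavenumber(positions, scaling)
    heights = np.array(
        [activity_to_intensity(nu, params, activity=act)
         for nu, act in zip(positions, table.activities())]
    )
    intensities = lorentzian_sum(grid, positions, heights, shape.fwhm)
    f_applied: float | None = params.f
    if params.f is None and intensities.max() > 0:
        f_applied = 100.0 / intensities.max()
        intensities = intensities * f_applied
    meta = {
        "complex": table.complex_name,
        "scaled": scaling is not None,
        "scaling": None if scaling is None else (scaling.a, scaling.b),
        "nu0": params.nu0,
        "temperature": params.temperature,
        "f": f_applied,
        "fwhm": shape.fwhm,
        "mode": "eq2",
    }
    return Spectrum(grid, intensities, meta=meta)


def fixture_spectrum(table: ModeTable, shape: LineshapeParams = LineshapeParams()) -> Spectrum:
    """Lorentzian synthesis using the stored activities directly as peak heights.

    Intended for transcribed table fixtures whose "Raman strength" column is
    already a usable peak amplitude; no intensity conversion, no re-scaling
    of positions.
    """
    grid = shape.grid()
    if len(table) == 0:
        logger.warning("fixture_spectrum: empty mode table for %r", table.complex_name)
        return Spectrum(grid, np.zeros_like(grid), meta={"complex": table.complex_name,
                                                         "scaled": False, "empty": True})
    intensities = lorentzian_sum(grid, table.wavenumbers(), table.activities(), shape.fwhm)
    meta = {"complex": table.complex_name, "scaled": False, "fwhm": shape.fwhm,
            "mode": "fixture"}
    return Spectrum(grid, intensities, meta=meta)
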