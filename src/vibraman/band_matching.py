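"""Matching theoretical modes to experimental bands and biomarker selection.

Bands are detected on the fixed-grid experimental spectrum as strict local
maxima of sufficient prominence.  Theoretical modes are paired with detected
bands greedily by global closeness within a tolerance; the signed shift of a
pair is experimental − theoretical, so a mode computed at 997 cm⁻¹ matched to
the 1001 cm⁻¹ phenylalanine band reads +4 cm⁻¹.  Biomarker candidates are,
by default, the joint-attributed modes inside the region of interest, with an
explicit include/exclude override available where curated membership differs
from the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DomainError
from .exp_preprocess import BinnedSpectrum, GridSpec
from .fragment_assign import FragmentAttribution
from .vib_io import ModeTable, VibrationalMode

DEFAULT_TOLERANCE = 10.0
DEFAULT_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class BandMatch:
    mode_index: int
    mode_wavenumber: float
    band_wavenumber: float
    source_label: str = ""

    @property
    def shift(self) -> float:
        """Signed shift, experimental band minus theoretical mode (cm⁻¹)."""
        return self.band_wavenumber - self.mode_wavenumber


@dataclass
class BiomarkerCandidate:
    mode: VibrationalMode
    attribution: FragmentAttribution
    matches: list[BandMatch] = field(default_factory=list)


def detect_bands(
    spec: BinnedSpectrum,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> list[float]:
    """Detect band positions as prominent strict local maxima over present bins.

    Returns bin centers, ascending.  Prominence threshold is
    ``prominence_fraction`` of the global maximum of the present bins.
    """
    if not 0 < prominence_fraction < 1:
        raise DomainError(f"prominence_fraction must be in (0, 1), got {prominence_fraction}")
    present = spec.present
    if np.count_nonzero(present) < 3:
        raise DomainError(f"{spec.label!r}: fewer than 3 present bins, cannot detect bands")
    values = spec.intensities[present]
    centers = spec.centers[present]
    peak = float(values.max())
    if peak <= 0:
        return []
    idx, _ = find_peaks(values, prominence=prominence_fraction * peak)
    return [float(c) for c in centers[idx]]


def match_modes_to_bands(
    modes: Sequence[VibrationalMode],
    bands: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    source_label: str = "",
) -> list[BandMatch]:
    """Greedy globally-closest one-to-one matching within a tolerance.

    Repeatedly pairs the (mode, band) pair with the smallest absolute
    distance ≤ tolerance and removes both.  Ties are broken deterministically
    toward the lower mode wavenumber, then the lower band wavenumber.
    Matches are returned ordered by mode wavenumber.
    """
    if not tolerance > 0:
        raise DomainError(f"tolerance must be > 0, got {tolerance}")
    candidates = []
    for mi, mode in enumerate(modes):
        for bi, band in enumerate(bands):
            d = abs(band - mode.wavenumber)
            if d <= tolerance:
                candidates.append((d, mode.wavenumber, band, mi, bi))
    candidates.sort()
    used_modes: set[int] = set()
    used_bands: set[int] = set()
    matches: list[BandMatch] = []
    for d, mode_w, band, mi, bi in candidates:
        if mi in used_modes or bi in used_bands:
            continue
        used_modes.add(mi)
        used_bands.add(bi)
        matches.append(
            BandMatch(
                mode_index=modes[mi].index,
                mode_wavenumber=modes[mi].wavenumber,
                band_wavenumber=float(band),
                source_label=source_label,
            )
        )
    matches.sort(key=lambda m: (m.mode_wavenumber, m.mode_index))
    return matches


def estimate_shift(matches: Sequence[BandMatch]) -> float:
    """Robust overall spectral shift: the median of the per-pair shifts."""
    if not matches:
        raise DomainError("cannot estimate a shift from zero matches")
    return float(np.median([m.shift for m in matches]))


def select_biomarkers(
    table: ModeTable,
    attributions: Sequence[FragmentAttribution],
    matches: Sequence[BandMatch] = (),
    region: GridSpec = GridSpec(),
    include: Iterable[int] = (),
    exclude: Iterable[int] = (),
) -> list[BiomarkerCandidate]:
    """Select biomarker candidate modes.

    Default rule: every joint-attributed mode with wavenumber inside
    [region.start, region.stop], ordered by wavenumber.  ``include`` forces
    specific mode indices in regardless of attribution; ``exclude`` forces
    them out.  Each candidate carries the matches pointing at its mode.
    """
    label_by_index = {a.mode_index: a for a in attributions}
    missing = [m.index for m in table.modes if m.index not in label_by_index]
    if missing:
        raise DomainError(f"attributions do not cover modes {missing}")
    include = set(include)
    exclude = set(exclude)
    matches_by_index: dict[int, list[BandMatch]] = {}
    for match in matches:
        matches_by_index.setdefault(match.mode_index, []).append(match)
    candidates: list[BiomarkerCandidate] = []
    for mode in table.modes:  # already wavenumber-ascending
        if mode.index in exclude:
            continue
        in_region = region.start <= mode.wavenumber <= region.stop
        attribution = label_by_index[mode.index]
        selected = (attribution.label == "joint" and in_region) or mode.index in include
        if selected:
            candidates.append(
                BiomarkerCandidate(
                    mode=mode,
                    attribution=attribution,
                    matches=matches_by_index.get(mode.index, []),
                )
            )
    return candidates


def overlay_report(
    theoretical: ModeTable,
    experimental: Sequence[BinnedSpectrum],
    candidates: Sequence[BiomarkerCandidate],
) -> pd.DataFrame:
    """Tabular pairing of candidates with per-group experimental intensities.

    One row per candidate with, for each experimental spectrum, the intensity
    at the bin nearest the candidate's wavenumber — the data behind a
    stems-over-spectra overlay with separate left/right intensity scales.
    Candidates outside a spectrum's grid are flagged out-of-range.
    """
    rows = []
    for cand in candidates:
        row: dict[str, object] = {
            "mode_index": cand.mode.index,
            "wavenumber": cand.mode.wavenumber,
            "raman_activity": cand.mode.raman_activity,
            "fragment": cand.attribution.label,
            "description": cand.mode.description,
            "n_matches": len(cand.matches),
            "best_shift": cand.matches[0].shift if cand.matches else np.nan,
        }
        out_of_range = False
        for spec in experimental:
            grid = spec.grid
            if not (grid.start - grid.step / 2 <= cand.mode.wavenumber < grid.stop + grid.step / 2):
                row[f"intensity[{spec.label}]"] = np.nan
                out_of_range = True
                continue
            centers = spec.centers
            nearest = int(np.argmin(np.abs(centers - cand.mode.wavenumber)))
            row[f"intensity[{spec.label}]"] = spec.intensities[nearest]
            row[f"bin[{spec.label}]"] = centers[nearest]
        row["out_of_range"] = out_of_range
        rows.append(row)
    columns = None
    if not rows:
        columns = ["mode_index", "wavenumber", "raman_activity", "fragment",
                   "description", "n_matches", "best_shift", "out_of_range"]
    return pd.DataFrame(rows, columns=columns)
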