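"""Attribution of normal modes to molecular fragments.

A biomarker candidate is a *joint* mode — one whose atomic displacement
involves both the drug/metabolite (ligand) and the receptor residue
(arginine).  When per-atom displacement vectors are available the
attribution uses the standard mass-weighted squared-displacement
participation fraction; when only a transcribed table is available the
table's own molecule labels are passed through verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AttributionError
from .vib_io import ModeTable, VibrationalMode

DEFAULT_THETA = 0.8


@dataclass
class FragmentAttribution:
    mode_index: int
    fractions: dict[str, float] = field(default_factory=dict)
    label: str = "joint"


def attribute_mode(
    mode: VibrationalMode,
    atom_map: Mapping[int, str],
    masses: Sequence[float],
    theta: float = DEFAULT_THETA,
) -> FragmentAttribution:
    """Attribute one mode from its displacement pattern.

    The participation fraction of fragment F is

        p_F = Σ_{i ∈ F} m_i |d_i|² / Σ_i m_i |d_i|²

    with m_i the atomic mass and d_i the Cartesian displacement of atom i.
    The mode is labelled F if p_F ≥ theta for some fragment, else *joint*.
    theta must lie in (0.5, 1] so at most one fragment can win.
    """
    if not 0.5 < theta <= 1.0:
        raise AttributionError(f"theta must be in (0.5, 1], got {theta}")
    if mode.displacements is None:
        raise AttributionError(
            f"mode {mode.index} has no displacements; use attribution_from_table instead"
        )
    disp = mode.displacements
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != disp.shape[0]:
        raise AttributionError(
            f"mode {mode.index}: {masses.shape[0]} masses for {disp.shape[0]} atoms"
        )
    missing = [i for i in range(disp.shape[0]) if i not in atom_map]
    if missing:
        raise AttributionError(f"atoms without fragment label: {missing}")
    weights = masses * (disp**2).sum(axis=1)
    total = weights.sum()
    if total <= 0:
        raise AttributionError(f"mode {mode.index}: zero total displacement")
    fractions: dict[str, float] = {}
    for i, w in enumerate(weights):
        frag = atom_map[i]
        fractions[frag] = fractions.get(frag, 0.0) + float(w / total)
    label = "joint"
    for frag, p in fractions.items():
        if p >= theta:
            label = frag
            break
    return FragmentAttribution(mode_index=mode.index, fractions=fractions, label=label)


def attribution_from_table(table: ModeTable) -> list[FragmentAttribution]:
    """Pass the table's own fragment labels through as attributions.

    Joint rows yield label ``joint`` with unknown (empty) fractions.  An
    ``unknown`` fragment anywhere is an error — such tables need
    displacement-based attribution instead.
    """
    attributions: list[FragmentAttribution] = []
    for mode in table.modes:
        if mode.fragment not in ("ligand", "residue", "joint"):
            raise AttributionError(
                f"mode {mode.index} carries fragment {mode.fragment!r}; "
                "table-based attribution needs explicit labels"
            )
        fractions = {} if mode.fragment == "joint" else {mode.fragment: 1.0}
        attributions.append(
            FragmentAttribution(mode_index=mode.index, fractions=fractions, label=mode.fragment)
        )
    return attributions


def attribute_table(
    table: ModeTable,
    masses: Sequence[float] | None = None,
    theta: float = DEFAULT_THETA,
) -> list[FragmentAttribution]:
    """Attribute every mode of a table.

    Table-provided labels win over displacement-based attribution whenever a
    mode carries an explicit label; displacement attribution is used only for
    ``unknown`` modes (requires ``fragment_atom_map`` and masses).
    """
    out: list[FragmentAttribution] = []
    for mode in table.modes:
        if mode.fragment != "unknown":
            fractions = {} if mode.fragment == "joint" else {mode.fragment: 1.0}
            out.append(FragmentAttribution(mode.index, fractions, mode.fragment))
        else:
            if table.fragment_atom_map is None or masses is None:
                raise AttributionError(
                    f"mode {mode.index} is unlabelled and no atom map/masses are available"
                )
            out.append(attribute_mode(mode, table.fragment_atom_map, masses, theta))
    return out
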