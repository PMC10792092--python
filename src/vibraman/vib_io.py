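"""Readers and writers for vibrational mode tables and experimental spectra.

Two input dialects are supported for mode tables: a tab-separated table
(columns ``index``, ``wavenumber``, ``raman_activity``, ``fragment``,
``description``) and the conventional plain-text frequency block emitted by
quantum-chemistry harmonic frequency jobs (three modes per block, with
``Frequencies --`` / ``Raman Activ --`` rows and an optional per-atom
displacement table).  Experimental spectra arrive as two-column text.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ParseError, SchemaError

FRAGMENT_LABELS = ("ligand", "residue", "joint", "unknown")

#: Accepted spellings of fragment labels.  The printed tables name the
#: molecule ("Metabolite", "Aspirin", "Arginine") and mark modes spanning
#: both molecules with an en-dash; all map onto the canonical vocabulary.
_FRAGMENT_ALIASES: Mapping[str, str] = {
    "ligand": "ligand",
    "residue": "residue",
    "joint": "joint",
    "unknown": "unknown",
    "metabolite": "ligand",
    "aspirin": "ligand",
    "clopidogrel": "ligand",
    "arginine": "residue",
    "–": "joint",
    "—": "joint",
    "-": "joint",
}

_TSV_COLUMNS = ("index", "wavenumber", "raman_activity", "fragment", "description")


def canonical_fragment(label: str) -> str:
    """Map a fragment spelling (molecule name, dash, canonical) to canonical form."""
    key = label.strip().lower()
    if not key:
        return "unknown"
    try:
        return _FRAGMENT_ALIASES[key]
    except KeyError:
        raise SchemaError(f"unknown fragment label: {label!r}") from None


@dataclass
class VibrationalMode:
    """One harmonic normal mode.

    ``raman_activity`` holds the quantum-chemistry Raman scattering activity
    (Å⁴/amu convention); for transcribed table fixtures it holds the printed
    "Raman strength" as-is.  ``displacements`` is an optional ``(n_atoms, 3)``
    array of mass-unweighted Cartesian displacement vectors.
    """

    index: int
    wavenumber: float
    raman_activity: float
    fragment: str = "unknown"
    description: str = ""
    displacements: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise SchemaError(f"mode index must be a positive integer, got {self.index}")
        if not self.wavenumber > 0:
            raise SchemaError(f"mode {self.index}: wavenumber must be > 0, got {self.wavenumber}")
        if self.raman_activity < 0:
            raise SchemaError(
                f"mode {self.index}: raman_activity must be >= 0, got {self.raman_activity}"
            )
        if self.fragment not in FRAGMENT_LABELS:
            self.fragment = canonical_fragment(self.fragment)
        if self.displacements is not None:
            self.displacements = np.asarray(self.displacements, dtype=float)
            if self.displacements.ndim != 2 or self.displacements.shape[1] != 3:
                raise SchemaError(
                    f"mode {self.index}: displacements must have shape (n_atoms, 3)"
                )


@dataclass
class ModeTable:
    """Ordered collection of modes for one molecular complex.

    Modes are stored sorted by wavenumber ascending (ties broken by index);
    indices must be unique.
    """

    complex_name: str
    modes: list[VibrationalMode] = field(default_factory=list)
    fragment_atom_map: dict[int, str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.modes = sorted(self.modes, key=lambda m: (m.wavenumber, m.index))
        indices = [m.index for m in self.modes]
        if len(indices) != len(set(indices)):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise SchemaError(f"duplicate mode indices: {dupes}")

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def wavenumbers(self) -> np.ndarray:
        return np.array([m.wavenumber for m in self.modes], dtype=float)

    def activities(self) -> np.ndarray:
        return np.array([m.raman_activity for m in self.modes], dtype=float)

    def subset(self, fragment: str) -> "ModeTable":
        """Modes carrying the given canonical fragment label."""
        return ModeTable(
            complex_name=self.complex_name,
            modes=[m for m in self.modes if m.fragment == fragment],
            fragment_atom_map=self.fragment_atom_map,
            provenance=self.provenance,
        )


@dataclass
class RawSpectrum:
    """Experimental spectrum as (wavenumber, intensity) pairs, ascending."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise SchemaError("wavenumbers and intensities must be 1-D and equal length")
        if self.wavenumbers.size < 2:
            raise SchemaError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise SchemaError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumbers.size


# ---------------------------------------------------------------------------
# Tab-separated mode tables
# ---------------------------------------------------------------------------

def read_mode_table_tsv(path: str | Path, complex_name: str | None = None) -> ModeTable:
    """Read a tab-separated mode table.

    Header must name the columns ``index``, ``wavenumber``, ``raman_activity``,
    ``fragment``, ``description``.  Fragment spellings "–" and "-" are accepted
    for joint modes; molecule names are accepted and canonicalised.  Rows are
    re-sorted by wavenumber ascending.
    """
    path = Path(path)
    modes: list[VibrationalMode] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        header = [h.strip().lower() for h in header]
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: header missing columns {missing}")
        col = {c: header.index(c) for c in _TSV_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            try:
                index = int(row[col["index"]])
                wavenumber = float(row[col["wavenumber"]].replace(",", "."))
                activity = float(row[col["raman_activity"]].replace(",", "."))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            try:
                mode = VibrationalMode(
                    index=index,
                    wavenumber=wavenumber,
                    raman_activity=activity,
                    fragment=canonical_fragment(row[col["fragment"]]),
                    description=row[col["description"]].strip(),
                )
            except SchemaError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from None
            modes.append(mode)
    name = complex_name if complex_name is not None else path.stem
    return ModeTable(complex_name=name, modes=modes, provenance=str(path))


def write_mode_table_tsv(table: ModeTable, path: str | Path) -> Path:
    """Write a mode table in the canonical TSV dialect (joint spelled out)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for m in table.modes:
            writer.writerow(
                [m.index, _fmt(m.wavenumber), _fmt(m.raman_activity), m.fragment, m.description]
            )
    return path


def _fmt(x: float) -> str:
    # integers print without a trailing .0 so transcribed tables round-trip verbatim
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Frequency-job text logs
# ---------------------------------------------------------------------------

_FREQ_RE = re.compile(r"^\s*Frequencies\s*--\s*(.*)$")
_RAMAN_RE = re.compile(r"^\s*Raman Activ\s*--\s*(.*)$")
_ATOM_HEADER_RE = re.compile(r"^\s*Atom\s+AN(\s+X\s+Y\s+Z)+\s*$")
_ATOM_ROW_RE = re.compile(r"^\s*\d+\s+\d+(\s+-?\d+\.?\d*)+\s*$")


def read_freqjob_log(path: str | Path, complex_name: str | None = None) -> ModeTable:
    """Parse the frequency blocks of a harmonic frequency-job text log.

    Handles the conventional layout only: blocks of up to three modes, each
    with a ``Frequencies --`` line, a ``Raman Activ --`` line, and optionally
    an ``Atom AN X Y Z ...`` displacement table.  Modes are numbered in file
    order; fragment is ``unknown``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8", errors="replace").splitlines()
    modes: list[VibrationalMode] = []
    i = 0
    n = len(lines)
    while i < n:
        m = _FREQ_RE.match(lines[i])
        if not m:
            i += 1
            continue
        freqs = [float(x) for x in m.group(1).split()]
        block_acts: list[float] | None = None
        block_disp: list[list[list[float]]] | None = None
        i += 1
        while i < n and not _FREQ_RE.match(lines[i]):
            rm = _RAMAN_RE.match(lines[i])
            if rm:
                block_acts = [float(x) for x in rm.group(1).split()]
            elif _ATOM_HEADER_RE.match(lines[i]):
                block_disp = [[] for _ in freqs]
                i += 1
                while i < n and _ATOM_ROW_RE.match(lines[i]):
                    parts = lines[i].split()
                    coords = [float(x) for x in parts[2:]]
                    if len(coords) != 3 * len(freqs):
                        raise ParseError(
                            f"{path}:{i + 1}: expected {3 * len(freqs)} displacement "
                            f"components, got {len(coords)}"
                        )
                    for k in range(len(freqs)):
                        block_disp[k].append(coords[3 * k : 3 * k + 3])
                    i += 1
                continue
            i += 1
        if block_acts is None:
            raise ParseError(f"{path}: frequency block lacks a 'Raman Activ' line")
        if len(block_acts) != len(freqs):
            raise ParseError(
                f"{path}: block has {len(freqs)} frequencies but "
                f"{len(block_acts)} Raman activities"
            )
        for k, (nu, act) in enumerate(zip(freqs, block_acts)):
            modes.append(
                VibrationalMode(
                    index=len(modes) + 1,
                    wavenumber=nu,
                    raman_activity=act,
                    fragment="unknown",
                    displacements=np.array(block_disp[k]) if block_disp else None,
                )
            )
    if not modes:
        raise FormatError(f"{path}: no frequency block found")
    name = complex_name if complex_name is not None else path.stem
    return ModeTable(complex_name=name, modes=modes, provenance=str(path))


def write_freqjob_log(table: ModeTable, path: str | Path) -> Path:
    """Emit a minimal frequency-job log in the conventional three-per-block layout.

    Exists so synthetic logs can be generated for testing the parser and for
    pipeline runs that start from log input.
    """
    path = Path(path)
    modes = table.modes
    out: list[str] = [f" Harmonic frequencies (cm**-1), Raman scattering activities (A**4/AMU)"]
    for start in range(0, len(modes), 3):
        chunk = modes[start : start + 3]
        out.append("  " + "                      ".join(str(start + k + 1) for k in range(len(chunk))))
        out.append(" Frequencies --" + "".join(f" {m.wavenumber:20.4f}" for m in chunk))
        out.append(" Raman Activ --" + "".join(f" {m.raman_activity:20.4f}" for m in chunk))
        if all(m.displacements is not None for m in chunk):
            n_atoms = chunk[0].displacements.shape[0]
            out.append("  Atom  AN" + "      X      Y      Z  " * len(chunk))
            for a in range(n_atoms):
                row = f"  {a + 1:4d}   1 "
                for m in chunk:
                    row += "".join(f" {c:6.2f}" for c in m.displacements[a])
                out.append(row)
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Two-column experimental spectra
# ---------------------------------------------------------------------------

def read_spectrum_txt(path: str | Path, label: str | None = None) -> RawSpectrum:
    """Read a two-column (wavenumber, intensity) text spectrum.

    Whitespace- or comma-delimited; ``#`` comment lines ignored; samples are
    sorted ascending and exactly-duplicated wavenumbers are averaged.
    """
    path = Path(path)
    ws: list[float] = []
    ys: list[float] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from None
            ws.append(w)
            ys.append(y)
    if len(ws) < 2:
        raise FormatError(f"{path}: fewer than 2 valid samples")
    w_arr = np.asarray(ws)
    y_arr = np.asarray(ys)
    # average strictly duplicated wavenumbers
    uniq, inverse = np.unique(w_arr, return_inverse=True)
    if uniq.size < w_arr.size:
        sums = np.zeros_like(uniq)
        counts = np.zeros_like(uniq)
        np.add.at(sums, inverse, y_arr)
        np.add.at(counts, inverse, 1.0)
        w_arr, y_arr = uniq, sums / counts
    else:
        order = np.argsort(w_arr)
        w_arr, y_arr = w_arr[order], y_arr[order]
    if w_arr.size < 2:
        raise FormatError(f"{path}: fewer than 2 distinct wavenumbers")
    return RawSpectrum(w_arr, y_arr, label=label if label is not None else path.stem)


def write_spectrum_txt(spectrum: RawSpectrum, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {spectrum.label}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.4f}\t{y:.6f}\n")
    return path
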