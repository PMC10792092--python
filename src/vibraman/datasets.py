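"""Packaged fixture tables: transcriptions of the published mode tables.

Two vibrational mode tables are shipped (clopidogrel-thiol-metabolite +
arginine at the P2Y12 binding site; aspirin + arginine at the COX-1 binding
site), together with the curated biomarker list and the membership override
used for the aspirin complex.  All files are plain text and checksummed.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import PackagingError
from .vib_io import ModeTable, read_mode_table_tsv

FIXTURE_FILES = (
    "table1_clopidogrel_arginine.tsv",
    "table2_aspirin_arginine.tsv",
    "table3_biomarkers.tsv",
    "aspirin_table3_override.json",
)

_CHECKSUM_FILE = "_checksums.json"


def _data_dir():
    return resources.files("vibraman") / "data"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture, after an integrity check."""
    if name not in FIXTURE_FILES:
        raise PackagingError(f"unknown fixture {name!r}; known: {FIXTURE_FILES}")
    path = Path(str(_data_dir() / name))
    verify_checksum(name)
    return path


def sha256_of(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def verify_checksum(name: str) -> None:
    checksums = json.loads((_data_dir() / _CHECKSUM_FILE).read_text())
    actual = sha256_of(Path(str(_data_dir() / name)))
    expected = checksums.get(name)
    if expected != actual:
        raise PackagingError(
            f"packaged fixture {name} failed its checksum "
            f"(expected {expected}, got {actual})"
        )


def load_clopidogrel_table() -> ModeTable:
    """Mode table for the clopidogrel-metabolite/arginine binding site (120 modes)."""
    return read_mode_table_tsv(
        fixture_path("table1_clopidogrel_arginine.tsv"),
        complex_name="clopidogrel-metabolite/arginine",
    )


def load_aspirin_table() -> ModeTable:
    """Mode table for the aspirin/arginine binding site (86 modes)."""
    return read_mode_table_tsv(
        fixture_path("table2_aspirin_arginine.tsv"),
        complex_name="aspirin/arginine",
    )


def load_biomarker_table() -> pd.DataFrame:
    """Curated biomarker candidates for both complexes (columns: mode_index,
    wavenumber, drug, description)."""
    return pd.read_csv(fixture_path("table3_biomarkers.tsv"), sep="\t")


def load_aspirin_override() -> dict[str, list[int]]:
    """Include/exclude mode indices reproducing the curated aspirin membership."""
    data = json.loads(fixture_path("aspirin_table3_override.json").read_text())
    return {"include": list(data["include"]), "exclude": list(data["exclude"])}
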