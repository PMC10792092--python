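import numpy as np
import pytest

from vibraman import datasets
from vibraman.exp_preprocess import GridSpec
from vibraman.vib_io import ModeTable, RawSpectrum, VibrationalMode


@pytest.fixture(scope="session")
def clopidogrel_table():
    return datasets.load_clopidogrel_table()


@pytest.fixture(scope="session")
def aspirin_table():
    return datasets.load_aspirin_table()


@pytest.fixture(scope="session")
def biomarker_table():
    return datasets.load_biomarker_table()


@pytest.fixture(scope="session")
def aspirin_override():
    return datasets.load_aspirin_override()


@pytest.fixture
def toy_table():
    """Three well-separated modes for lineshape arithmetic."""
    modes = [
        VibrationalMode(index=1, wavenumber=600.0, raman_activity=1.0, fragment="ligand"),
        VibrationalMode(index=2, wavenumber=1000.0, raman_activity=2.0, fragment="residue"),
        VibrationalMode(index=3, wavenumber=1400.0, raman_activity=0.5, fragment="joint"),
    ]
    return ModeTable(complex_name="toy", modes=modes)


@pytest.fixture
def default_grid():
    return GridSpec()


def make_raw(wavenumbers, intensities, label="test"):
    return RawSpectrum(np.asarray(wavenumbers, float), np.asarray(intensities, float), label=label)
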