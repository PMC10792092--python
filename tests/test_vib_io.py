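"""Mode-table and spectrum I/O: dialects, round trips, error reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibraman.errors import FormatError, ParseError, SchemaError
from vibraman.vib_io import (
    ModeTable,
    VibrationalMode,
    canonical_fragment,
    read_freqjob_log,
    read_mode_table_tsv,
    read_spectrum_txt,
    write_freqjob_log,
    write_mode_table_tsv,
)

HEADER = "index\twavenumber\traman_activity\tfragment\tdescription\n"


def write_tsv(tmp_path, body, name="modes.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body, encoding="utf-8")
    return path


class TestModeTableTsv:
    def test_paper_fixture_row(self, clopidogrel_table):
        """The transcribed table carries the joint mode at 997 cm-1, strength 0.07."""
        mode = next(m for m in clopidogrel_table if m.index == 93)
        assert mode.wavenumber == 997.0
        assert mode.raman_activity == 0.07
        assert mode.fragment == "joint"

    def test_empty_file_header_only(self, tmp_path):
        table = read_mode_table_tsv(write_tsv(tmp_path, ""))
        assert len(table) == 0

    def test_rows_sorted_by_wavenumber(self, tmp_path):
        body = "2\t1200\t0.5\tligand\tx\n1\t800\t0.3\tresidue\ty\n"
        table = read_mode_table_tsv(write_tsv(tmp_path, body))
        assert [m.wavenumber for m in table] == [800.0, 1200.0]

    @pytest.mark.parametrize("dash", ["–", "-"])
    def test_dash_maps_to_joint(self, tmp_path, dash):
        table = read_mode_table_tsv(write_tsv(tmp_path, f"1\t500\t0.1\t{dash}\tboth\n"))
        assert table.modes[0].fragment == "joint"

    def test_molecule_names_canonicalised(self):
        assert canonical_fragment("Metabolite") == "ligand"
        assert canonical_fragment("Aspirin") == "ligand"
        assert canonical_fragment("Arginine") == "residue"

    def test_malformed_row_names_line(self, tmp_path):
        path = write_tsv(tmp_path, "1\t500\t0.1\tligand\tok\n2\tnot-a-number\t0.1\tligand\tbad\n")
        with pytest.raises(ParseError, match=r":3:"):
            read_mode_table_tsv(path)

    def test_duplicate_index_rejected(self, tmp_path):
        path = write_tsv(tmp_path, "1\t500\t0.1\tligand\ta\n1\t600\t0.1\tligand\tb\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_mode_table_tsv(path)

    def test_negative_wavenumber_rejected(self, tmp_path):
        path = write_tsv(tmp_path, "1\t-500\t0.1\tligand\ta\n")
        with pytest.raises(SchemaError):
            read_mode_table_tsv(path)

    def test_round_trip_table1(self, clopidogrel_table, tmp_path):
        out = write_mode_table_tsv(clopidogrel_table, tmp_path / "t1.tsv")
        again = read_mode_table_tsv(out)
        assert len(again) == len(clopidogrel_table)
        for a, b in zip(again, clopidogrel_table):
            assert (a.index, a.wavenumber, a.raman_activity, a.fragment, a.description) == (
                b.index, b.wavenumber, b.raman_activity, b.fragment, b.description)

    def test_joint_spelled_out_on_write(self, tmp_path):
        table = ModeTable("x", [VibrationalMode(1, 500.0, 0.1, "joint", "both")])
        text = write_mode_table_tsv(table, tmp_path / "o.tsv").read_text()
        assert "\tjoint\t" in text and "–" not in text


@st.composite
def mode_tables(draw):
    n = draw(st.integers(1, 12))
    wavenumbers = draw(st.lists(
        st.floats(10.0, 3900.0, allow_nan=False).map(lambda x: round(x, 3)),
        min_size=n, max_size=n, unique=True))
    modes = [
        VibrationalMode(
            index=i + 1,
            wavenumber=w,
            raman_activity=round(draw(st.floats(0.0, 100.0)), 4),
            fragment=draw(st.sampled_from(["ligand", "residue", "joint", "unknown"])),
            description=draw(st.text(
                alphabet=st.characters(whitelist_categories=("L", "N", "Zs")), max_size=20)).strip(),
        )
        for i, w in enumerate(wavenumbers)
    ]
    return ModeTable("prop", modes)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(table=mode_tables())
def test_tsv_round_trip_property(table, tmp_path_factory):
    """write-then-read is the identity on every stored field."""
    tmp = tmp_path_factory.mktemp("rt")
    again = read_mode_table_tsv(write_mode_table_tsv(table, tmp / "t.tsv"))
    assert [(m.index, m.wavenumber, m.raman_activity, m.fragment, m.description)
            for m in again] == [(m.index, m.wavenumber, m.raman_activity, m.fragment,
                                 m.description) for m in table]


class TestFreqJobLog:
    TOY = (
        " Harmonic frequencies\n"
        "                     1                      2                      3\n"
        " Frequencies --            1000.0000              2000.0000              3000.0000\n"
        " Raman Activ --               1.0000                 2.0000                 3.0000\n"
    )

    def test_toy_log(self, tmp_path):
        path = tmp_path / "toy.log"
        path.write_text(self.TOY)
        table = read_freqjob_log(path)
        assert [m.wavenumber for m in table] == [1000.0, 2000.0, 3000.0]
        assert [m.raman_activity for m in table] == [1.0, 2.0, 3.0]
        assert all(m.fragment == "unknown" for m in table)

    def test_two_blocks_concatenate(self, tmp_path):
        path = tmp_path / "two.log"
        block2 = self.TOY.replace("1000", "1100").replace("2000", "2100").replace("3000", "3100")
        path.write_text(self.TOY + block2)
        table = read_freqjob_log(path)
        assert len(table) == 6
        assert sorted(m.wavenumber for m in table) == [1000, 1100, 2000, 2100, 3000, 3100]

    def test_displacement_norms(self, tmp_path):
        """Per-mode displacement norms recomputed by hand from the fixture text."""
        log = (
            " Frequencies --            1000.0000              2000.0000\n"
            " Raman Activ --               1.0000                 2.0000\n"
            "  Atom  AN      X      Y      Z        X      Y      Z\n"
            "     1   8   0.30   0.00   0.40   0.00   0.00   1.00\n"
            "     2   1   0.00   0.00   0.00   0.60   0.80   0.00\n"
        )
        path = tmp_path / "disp.log"
        path.write_text(log)
        table = read_freqjob_log(path)
        # mode 1: |(0.3,0,0.4)| = 0.5, atom 2 zero -> total norm 0.5
        # mode 2: |(0,0,1)| = 1, |(0.6,0.8,0)| = 1 -> total norm sqrt(2)
        norms = [float(np.linalg.norm(m.displacements)) for m in table]
        assert norms[0] == pytest.approx(0.5)
        assert norms[1] == pytest.approx(np.sqrt(2.0))

    def test_no_block_is_format_error(self, tmp_path):
        path = tmp_path / "empty.log"
        path.write_text("nothing to see here\n")
        with pytest.raises(FormatError):
            read_freqjob_log(path)

    def test_writer_reader_round_trip(self, tmp_path, toy_table):
        """A synthesized log recovers every frequency and activity exactly."""
        rng = np.random.default_rng(7)
        for m in toy_table.modes:
            m.displacements = np.round(rng.normal(size=(4, 3)), 2)
        path = write_freqjob_log(toy_table, tmp_path / "gen.log")
        again = read_freqjob_log(path)
        assert [m.wavenumber for m in again] == [m.wavenumber for m in toy_table]
        assert [m.raman_activity for m in again] == [m.raman_activity for m in toy_table]
        for a, b in zip(again, toy_table):
            np.testing.assert_allclose(a.displacements, b.displacements)


class TestSpectrumTxt:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("400 1.0\n405 2.0\n")
        spec = read_spectrum_txt(path)
        assert len(spec) == 2
        np.testing.assert_array_equal(spec.wavenumbers, [400, 405])

    def test_descending_input_sorted(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("# comment\n500,2.0\n400,1.0\n")
        spec = read_spectrum_txt(path)
        np.testing.assert_array_equal(spec.wavenumbers, [400, 500])
        np.testing.assert_array_equal(spec.intensities, [1.0, 2.0])

    def test_duplicate_wavenumbers_averaged(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("500 1.0\n500 3.0\n600 5.0\n")
        spec = read_spectrum_txt(path)
        np.testing.assert_array_equal(spec.wavenumbers, [500, 600])
        np.testing.assert_array_equal(spec.intensities, [2.0, 5.0])

    def test_too_few_rows(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("400 1.0\n")
        with pytest.raises(FormatError):
            read_spectrum_txt(path)

    def test_non_numeric_names_line(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("400 1.0\n405 oops\n")
        with pytest.raises(ParseError, match=r":2:"):
            read_spectrum_txt(path)
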