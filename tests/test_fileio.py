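"""Structure file I/O: PDB round trips, XYZ, QM deck layout."""

import numpy as np
import pytest

from pepbuild import Peptide, QmJobSpec, read_pdb, write_qm_input
from pepbuild.fileio import FileIOError, fragment_charge, write_file
from pepbuild.geometry import wrap_angle


class TestPdbWriter:
    def test_fixed_width_v33_columns(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        text = path.read_text()
        assert text.endswith("\n")
        lines = text.splitlines()
        atom_lines = [ln for ln in lines if ln.startswith("ATOM")]
        assert len(atom_lines) == glg.n_atoms
        for ln in atom_lines:
            assert len(ln) == 78
            int(ln[6:11])                 # serial
            assert ln[21] == "A"          # chain id
            int(ln[22:26])                # resSeq
            float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
            assert ln[54:60] == "  1.00"  # occupancy
            assert ln[60:66] == "  0.00"  # B factor
            assert ln[76:78].strip() in ("C", "N", "O", "S", "H")
        assert lines[-2].startswith("TER")
        assert lines[-1] == "END"

    def test_methyl_caps_are_ace_nme(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        resnames = {
            ln[17:20].strip()
            for ln in path.read_text().splitlines()
            if ln.startswith("ATOM")
        }
        assert {"ACE", "NME", "GLY", "LEU"} == resnames

    def test_merged_termini(self, tmp_path):
        pep = Peptide("GAG", nterm="charged", cterm="neutral")
        path = tmp_path / "gag.pdb"
        pep.write_pdb(path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln.startswith("ATOM")]
        resnames = {ln[17:20].strip() for ln in lines}
        assert resnames == {"GLY", "ALA"}   # caps merged into residues
        names = [ln[12:16].strip() for ln in lines]
        assert {"H1", "H2", "H3", "OXT", "HXT"} <= set(names)

    def test_coordinate_round_trip(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        coords = []
        for ln in path.read_text().splitlines():
            if ln.startswith("ATOM"):
                coords.append(
                    [float(ln[30:38]), float(ln[38:46]), float(ln[46:54])]
                )
        assert np.allclose(np.array(coords), glg.coords, atol=1e-3)


class TestPdbReader:
    def test_round_trip_sequence_and_resnames(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        model = read_pdb(path)
        assert model.n_residues == 3
        assert model.get_sequence() == "GLG"
        assert [model.get_resname(i) for i in (1, 2, 3)] == [
            "GLY", "LEU", "GLY",
        ]

    def test_torsion_round_trip_within_format_precision(self, tmp_path):
        """Write -> read -> measure reproduces torsions to the precision
        allowed by 3-decimal PDB coordinates (~0.1 deg worst case)."""
        rng = np.random.default_rng(5)
        path = tmp_path / "rt.pdb"
        for _ in range(10):
            pep = Peptide("GLG")
            for res in (1, 2, 3):
                pep.set_bb_angles(res, list(rng.uniform(-180, 180, 2)))
            pep.set_chi_angles(2, list(rng.uniform(-180, 180, 2)))
            pep.write_pdb(path)
            model = read_pdb(path)
            for res in (1, 2, 3):
                for got, want in zip(
                    model.get_bb_angles(res), pep.get_bb_angles(res)
                ):
                    assert abs(wrap_angle(got - want)) < 0.15
            for got, want in zip(
                model.get_chi_angles(2), pep.get_chi_angles(2)
            ):
                assert abs(wrap_angle(got - want)) < 0.15

    def test_first_residue_phi_undefined_without_cap(self, tmp_path):
        pep = Peptide("GAG", nterm="charged", cterm="charged")
        path = tmp_path / "bare.pdb"
        pep.write_pdb(path)
        model = read_pdb(path)
        assert model.get_bb_angles(1)[0] is None      # no preceding C
        assert model.get_bb_angles(3)[1] is None      # no following N

    def test_glycine_has_no_chis(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        assert read_pdb(path).get_chi_angles(1) == []

    def test_water_only_file_rejected(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(FileIOError, match="no amino acid"):
            read_pdb(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileIOError):
            read_pdb(tmp_path / "nope.pdb")

    def test_residue_index_out_of_range(self, glg, tmp_path):
        path = tmp_path / "glg.pdb"
        glg.write_pdb(path)
        with pytest.raises(FileIOError):
            read_pdb(path).get_resname(4)


class TestXyzWriter:
    def test_layout(self, glg, tmp_path):
        path = tmp_path / "glg.xyz"
        glg.write_xyz(path)
        lines = path.read_text().splitlines()
        assert int(lines[0]) == glg.n_atoms
        assert "GLG" in lines[1]
        assert len(lines) == glg.n_atoms + 2
        parts = lines[2].split()
        assert parts[0] == "C"
        assert all("." in p and len(p.split(".")[1]) >= 6 for p in parts[1:])

    def test_atom_count_consistency(self, glg, tmp_path):
        xyz = tmp_path / "a.xyz"
        pdb = tmp_path / "a.pdb"
        glg.write_xyz(xyz)
        glg.write_pdb(pdb)
        n_xyz = int(xyz.read_text().splitlines()[0])
        n_pdb = sum(
            1 for ln in pdb.read_text().splitlines()
            if ln.startswith("ATOM")
        )
        assert n_xyz == n_pdb == glg.n_atoms


class TestQmWriters:
    def test_gaussian_route_and_structure(self, glg, tmp_path):
        path = tmp_path / "opt.com"
        spec = QmJobSpec(job_kind="opt", method="B3LYP/6-31G(d)")
        write_qm_input(glg, spec, "gaussian", path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# B3LYP/6-31G(d)")
        assert "opt" in lines[0]
        assert lines[1] == ""
        assert lines[3] == ""
        assert lines[4] == "0 1"       # methyl caps: neutral singlet
        assert len(lines) == 5 + glg.n_atoms + 1

    def test_default_method_is_pm6(self, glg, tmp_path):
        path = tmp_path / "opt.com"
        write_qm_input(glg, QmJobSpec(job_kind="opt"), "gaussian", path)
        assert "PM6" in path.read_text().splitlines()[0]

    def test_energy_job_has_bare_route(self, glg, tmp_path):
        path = tmp_path / "sp.com"
        write_qm_input(glg, QmJobSpec(job_kind="energy"), "gaussian", path)
        assert path.read_text().splitlines()[0] == "# PM6"

    def test_nmr_keyword(self, glg, tmp_path):
        path = tmp_path / "nmr.com"
        write_qm_input(glg, QmJobSpec(job_kind="nmr"), "gaussian", path)
        assert "NMR" in path.read_text().splitlines()[0]

    def test_charge_from_caps(self, tmp_path):
        cases = {
            ("methyl", "methyl"): 0,
            ("charged", "methyl"): 1,
            ("methyl", "charged"): -1,
            ("charged", "charged"): 0,
            ("neutral", "neutral"): 0,
        }
        for (nt, ct), q in cases.items():
            pep = Peptide("GAG", nterm=nt, cterm=ct)
            assert fragment_charge(pep) == q
            path = tmp_path / "q.com"
            write_qm_input(pep, None, "gaussian", path)
            assert f"{q} 1" in path.read_text().splitlines()

    def test_gamess_groups(self, glg, tmp_path):
        path = tmp_path / "job.inp"
        write_qm_input(glg, QmJobSpec(job_kind="opt"), "gamess", path)
        text = path.read_text()
        assert "$CONTRL" in text and "RUNTYP=OPTIMIZE" in text
        assert "$DATA" in text and "\nC1\n" in text
        assert text.rstrip().endswith("$END")

    def test_invalid_job_kind_and_dialect(self, glg, tmp_path):
        with pytest.raises(FileIOError):
            QmJobSpec(job_kind="hessian")
        with pytest.raises(FileIOError):
            write_qm_input(glg, None, "orca", tmp_path / "x.inp")
        with pytest.raises(FileIOError):
            QmJobSpec(multiplicity=0)


class TestWriteFile:
    def test_native_formats(self, glg, tmp_path):
        for ft, probe in (("xyz", "GLG"), ("pdb", "ATOM"),
                          ("com", "PM6"), ("gamin", "$CONTRL")):
            path = tmp_path / f"out.{ft}"
            write_file(glg, ft, path)
            assert probe in path.read_text()
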