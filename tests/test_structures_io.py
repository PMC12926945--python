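"""Parsing, writing, PTM recognition and residue mapping."""

import copy

import numpy as np
import pytest

from parch import (MappingError, PTMSite, Structure, StructureError,
                   Trajectory, TrajectoryError, formal_net_charge,
                   identify_ptm_sites, map_residues, parse_structure,
                   parse_trajectory, write_structure, write_trajectory)
from parch.structures_io import Atom, Residue, _guess_element

from conftest import TRIPEPTIDE_PDB, make_peptide_with_waters


class TestParseStructure:
    def test_minimal_single_residue(self, minimal_pdb):
        s = parse_structure(minimal_pdb)
        assert len(s.residues) == 1
        assert s.n_atoms == 5
        res = s.residues[0]
        assert res.name == "ALA" and res.key == ("A", 1)
        # PDB Angstrom -> nm
        np.testing.assert_allclose(res.atoms[0].coordinates,
                                   [1.1104, 0.6134, -0.6504], atol=1e-6)

    def test_atom_total_matches_record_count_oracle(self, tripeptide_pdb):
        s = parse_structure(tripeptide_pdb)
        n_records = sum(1 for line in TRIPEPTIDE_PDB.splitlines()
                        if line.startswith(("ATOM", "HETATM")))
        assert s.n_atoms == n_records
        assert len(s.protein_residues) == 3
        assert len(s.water_residues) == 2
        assert all(w.is_solvent for w in s.water_residues)

    def test_waters_and_ions_flagged(self, tmp_path):
        pdb = tmp_path / "sys.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH B   2       5.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    3 NA    NA C   3       9.000   0.000   0.000  1.00  0.00          NA\n"
            "END\n")
        s = parse_structure(pdb)
        assert [r.is_solvent for r in s.residues] == [False, True, False]
        assert [r.is_ion for r in s.residues] == [False, False, True]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            parse_structure(tmp_path / "nope.pdb")

    def test_waters_only_is_empty_structure_error(self, tmp_path):
        pdb = tmp_path / "w.pdb"
        pdb.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n")
        with pytest.raises(StructureError):
            parse_structure(pdb)

    def test_source_numbering_kept_verbatim(self, tmp_path):
        # activation-loop style fragment (synthetic stand-in for a kinase
        # chain): residue numbers far from 1 must survive the parse untouched
        lines = []
        for i, (num, name) in enumerate([(652, "ALA"), (653, "TYR"),
                                         (654, "TYR"), (655, "GLY")]):
            lines.append(
                f"ATOM   {i + 1:4d}  CA  {name} A {num:3d}    "
                f"{4.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        pdb = tmp_path / "fragment.pdb"
        pdb.write_text("\n".join(lines) + "\nEND\n")
        s = parse_structure(pdb)
        assert ("A", 653) in s and ("A", 654) in s
        assert s.residue(("A", 653)).name == "TYR"

    def test_gro_roundtrip(self, tmp_path):
        st = make_peptide_with_waters(3, 10, seed=4)
        path = write_structure(st, tmp_path / "sys.gro")
        back = parse_structure(path)
        assert back.n_atoms == st.n_atoms
        # GRO stores 3 decimals in nm
        np.testing.assert_allclose(back.coordinates(), st.coordinates(),
                                   atol=5e-4)


class TestTrajectory:
    def test_single_frame_identity(self, tmp_path):
        st = make_peptide_with_waters(2, 5, seed=1)
        traj = Trajectory(frame_times=[0.0],
                          frames=st.coordinates()[None, :, :])
        path = write_trajectory(traj, st, tmp_path / "one.xtc")
        back = parse_trajectory(path, st)
        assert back.n_frames == 1
        np.testing.assert_allclose(back.frames[0], st.coordinates(), atol=1e-3)

    def test_multiframe_roundtrip_and_count_oracle(self, tmp_path):
        st = make_peptide_with_waters(2, 8, seed=2)
        rng = np.random.default_rng(0)
        frames = st.coordinates()[None] + rng.normal(0, 0.05, (10, st.n_atoms, 3))
        traj = Trajectory(frame_times=np.arange(10) * 10.0, frames=frames)
        path = write_trajectory(traj, st, tmp_path / "run.xtc")
        back = parse_trajectory(path, st)
        # independent frame-iteration oracle
        import MDAnalysis as mda
        u = mda.Universe.empty(st.n_atoms, trajectory=True)
        u.load_new(str(path))
        assert back.n_frames == len(u.trajectory) == 10
        np.testing.assert_allclose(back.frames, frames, atol=1e-3)
        np.testing.assert_allclose(back.frame_times, traj.frame_times, atol=1e-3)

    def test_atom_count_mismatch_raises(self, tmp_path):
        st = make_peptide_with_waters(2, 8, seed=2)
        traj = Trajectory(frame_times=[0.0, 10.0],
                          frames=np.zeros((2, st.n_atoms, 3)))
        path = write_trajectory(traj, st, tmp_path / "run.xtc")
        smaller = make_peptide_with_waters(2, 3, seed=2)
        with pytest.raises(TrajectoryError):
            parse_trajectory(path, smaller)

    def test_nonmonotonic_times_rejected(self):
        with pytest.raises(TrajectoryError):
            Trajectory(frame_times=[0.0, 20.0, 10.0],
                       frames=np.zeros((3, 4, 3)))

    def test_multimodel_pdb_gets_synthesized_times(self, tmp_path):
        st = make_peptide_with_waters(1, 3, seed=5)
        frames = np.repeat(st.coordinates()[None], 4, axis=0)
        traj = Trajectory(frame_times=np.arange(4) * 50.0, frames=frames)
        path = write_trajectory(traj, st, tmp_path / "multi.pdb")
        back = parse_trajectory(path, st, dt=50.0)
        np.testing.assert_allclose(back.frame_times, traj.frame_times)


class TestPTMRecognition:
    def test_single_phosphoserine(self):
        st = make_peptide_with_waters(3, 0, resnames=["ALA", "SEP", "GLY"])
        # renumber so the site sits at 79, as in a nucleocapsid-style numbering
        st.residues[1].seq_number = 79
        st = Structure(residues=st.residues)
        sites = identify_ptm_sites(st)
        assert sites == [PTMSite("A", 79, "ph", "SEP")]

    def test_canonical_only_gives_empty(self):
        st = make_peptide_with_waters(4, 2, seed=0)
        assert identify_ptm_sites(st) == []

    def test_five_phospho_sites_recognised_at_reported_numbers(self):
        # phospho-variant carrying ph codes at T76, S78, S79, S105, T166
        numbered = {76: "TPO", 78: "SEP", 79: "SEP", 105: "SEP", 166: "TPO"}
        residues = []
        serial = 0
        for i, num in enumerate(sorted(set(list(numbered) + [77, 100, 150]))):
            serial += 1
            residues.append(Residue(
                chain_id="A", seq_number=num, name=numbered.get(num, "GLY"),
                atoms=[Atom(serial=serial, name="CA", element="C",
                            coordinates=np.array([0.5 * i, 0.0, 0.0]))]))
        st = Structure(residues=residues)
        sites = identify_ptm_sites(st)
        assert [s.seq_number for s in sites] == [76, 78, 79, 105, 166]
        assert all(s.mod_type == "ph" for s in sites)

    def test_count_equals_table_membership(self):
        names = ["ALA", "SEP", "TPO", "PTR", "ALY", "MLZ", "GLY", "LYS"]
        st = make_peptide_with_waters(len(names), 0, resnames=names)
        from parch import PTM_RECOGNITION_TABLE
        expected = sum(1 for n in names if n in PTM_RECOGNITION_TABLE)
        assert len(identify_ptm_sites(st)) == expected

    def test_unknown_nonstandard_residue_skipped_with_warning(self, caplog):
        st = make_peptide_with_waters(2, 0, resnames=["ALA", "XYZ"])
        with caplog.at_level("WARNING", logger="parch"):
            sites = identify_ptm_sites(st)
        assert sites == []
        assert any("XYZ" in rec.message for rec in caplog.records)

    def test_inconsistent_site_rejected(self):
        with pytest.raises(StructureError):
            PTMSite("A", 1, "ac", "SEP")


class TestMapResidues:
    def _chain(self, names, start=1):
        residues = []
        for i, name in enumerate(names):
            residues.append(Residue(
                chain_id="A", seq_number=start + i, name=name,
                atoms=[Atom(serial=i + 1, name="CA", element="C",
                            coordinates=np.array([0.4 * i, 0.0, 0.0]))]))
        return Structure(residues=residues)

    def test_identity_mapping(self):
        st = self._chain(["ALA", "SER", "GLY", "LYS", "THR"] * 2)
        mp = map_residues(st, copy.deepcopy(st))
        assert mp.pairs == [(r.key, r.key) for r in st.protein_residues]
        assert mp.unmatched_unmod == [] and mp.unmatched_mod == []

    def test_phospho_residue_pairs_with_parent(self):
        names = ["ALA", "SER", "GLY", "LYS", "THR", "TYR", "VAL", "LEU",
                 "ILE", "PHE"]
        unmod = self._chain(names)
        mod = self._chain([n if i != 1 else "SEP" for i, n in enumerate(names)])
        mp = map_residues(unmod, mod)
        assert (("A", 2), ("A", 2)) in mp.pairs
        assert len(mp.pairs) == len(names)

    def test_nterminal_truncation_listed_unmatched(self):
        names = ["MET", "ALA", "SER", "GLY", "LYS", "THR", "TYR", "VAL",
                 "LEU", "ILE", "PHE", "TRP"]
        unmod = self._chain(names)
        mod = self._chain(names[2:], start=3)
        mp = map_residues(unmod, mod)
        assert set(mp.unmatched_unmod) == {("A", 1), ("A", 2)}
        assert mp.unmatched_mod == []
        # hand-verified alignment of the toy pair: remaining residues line up
        assert mp.pairs == [(("A", i), ("A", i)) for i in range(3, 13)]

    def test_identity_floor_enforced(self):
        unmod = self._chain(["ALA"] * 10)
        mod = self._chain(["ALA"] * 5 + ["TRP"] * 5)
        with pytest.raises(MappingError):
            map_residues(unmod, mod)


class TestChargeAndElements:
    def test_formal_net_charge_bookkeeping(self):
        names = ["ASP", "GLU", "LYS", "ARG", "ALA", "SEP"]
        st = make_peptide_with_waters(len(names), 0, resnames=names)
        # -1 -1 +1 +1 0 -3 = -3
        assert formal_net_charge(st) == -3

    @pytest.mark.parametrize("name,resname,expected", [
        ("CA", "ALA", "C"), ("OW", "SOL", "O"), ("1HG1", "VAL", "H"),
        ("NA", "NA", "Na"), ("CL", "CL", "Cl"), ("N", "GLY", "N"),
    ])
    def test_element_guessing(self, name, resname, expected):
        assert _guess_element(name, resname) == expected
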