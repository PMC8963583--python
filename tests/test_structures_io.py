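import numpy as np
import pytest

from crossflex import (
    ACTIVE_SITE_CYP3A4_RANGES,
    Atom,
    EmptyStructureError,
    FormatError,
    NoCommonAtomsError,
    Selection,
    Structure,
    TopologyError,
    Trajectory,
    apply_selection,
    make_toy_ligand,
    make_toy_protein,
    match_atoms,
    parse_selection,
    read_pdb,
    read_trajectory,
    write_pdb,
    write_trajectory,
)

from conftest import ALTLOC_PDB_TEXT, TOY_PDB_TEXT, random_trajectory


class TestReadPdb:
    def test_toy_backbone_atom_count_and_order(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB_TEXT)
        structure = read_pdb(path)
        assert len(structure) == 12
        assert [a.name for a in structure.atoms[:4]] == ["N", "CA", "C", "O"]
        assert [a.resnum for a in structure.atoms] == [1] * 4 + [2] * 4 + [3] * 4
        np.testing.assert_allclose(structure.atoms[1].coords, [0.0, 0.0, 0.0], atol=1e-6)

    @pytest.mark.parametrize("policy", ["first", "A"])
    def test_altloc_keeps_single_atom(self, tmp_path, policy):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB_TEXT)
        structure = read_pdb(path, altloc_policy=policy)
        ca_atoms = [a for a in structure.atoms if a.name == "CA"]
        assert len(ca_atoms) == 1
        np.testing.assert_allclose(ca_atoms[0].coords, [0.0, 0.0, 0.0], atol=1e-6)

    def test_altloc_policy_b(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB_TEXT)
        structure = read_pdb(path, altloc_policy="B")
        ca_atoms = [a for a in structure.atoms if a.name == "CA"]
        assert len(ca_atoms) == 1
        assert ca_atoms[0].coords[0] == pytest.approx(0.5)

    def test_malformed_record_names_line(self, tmp_path):
        bad = TOY_PDB_TEXT.splitlines(keepends=True)
        bad[2] = bad[2][:30] + "  xx.xxx" + bad[2][38:]
        path = tmp_path / "bad.pdb"
        path.write_text("".join(bad))
        with pytest.raises(FormatError, match="line 3"):
            read_pdb(path)

    def test_no_atoms_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING HERE\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(path)

    def test_hetatm_flagged(self, tmp_path):
        structure = make_toy_protein(2)
        with_ligand = Structure(structure.atoms + make_toy_ligand([5.0, 5.0, 5.0]), id="X")
        path = tmp_path / "lig.pdb"
        write_pdb(with_ligand, path)
        back = read_pdb(path)
        het = [a for a in back.atoms if a.het]
        assert len(het) == 5
        assert {a.resname for a in het} == {"RIT"}


class TestRoundTrip:
    def test_structure_round_trip(self, tmp_path, toy3):
        path = tmp_path / "toy.pdb"
        write_pdb(toy3, path)
        back = read_pdb(path)
        assert [a.key() for a in back.atoms] == [a.key() for a in toy3.atoms]
        np.testing.assert_allclose(back.coords, toy3.coords, atol=1e-3)

    def test_multi_model_round_trip(self, tmp_path, toy3):
        traj = random_trajectory(toy3, sigma=0.4, n_frames=5, seed=7)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, toy3)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)

    def test_dcd_round_trip(self, tmp_path, toy3):
        traj = random_trajectory(toy3, sigma=0.4, n_frames=8, seed=8)
        path = tmp_path / "traj.dcd"
        write_trajectory(traj, path)
        back = read_trajectory(path, toy3)
        np.testing.assert_allclose(back.coords, traj.coords.astype(np.float32), atol=1e-5)

    def test_identical_models_give_equal_frames(self, tmp_path, toy3):
        coords = np.repeat(toy3.coords[None], 5, axis=0)
        path = tmp_path / "const.pdb"
        write_trajectory(Trajectory(toy3, coords), path)
        back = read_trajectory(path, toy3)
        assert back.n_frames == 5
        assert np.all(back.coords == back.coords[0])

    def test_missing_atom_in_model_is_topology_error(self, tmp_path, toy3):
        traj = random_trajectory(toy3, sigma=0.1, n_frames=3, seed=1)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines(keepends=True)
        # drop one ATOM record from the second MODEL block
        model_starts = [i for i, l in enumerate(lines) if l.startswith("MODEL")]
        del lines[model_starts[1] + 3]
        path.write_text("".join(lines))
        with pytest.raises(TopologyError, match="frame 1"):
            read_trajectory(path, toy3)

    def test_atom_count_mismatch_with_topology(self, tmp_path, toy3):
        traj = random_trajectory(toy3, sigma=0.1, n_frames=2, seed=2)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        with pytest.raises(TopologyError):
            read_trajectory(path, make_toy_protein(4))


class TestSelection:
    def test_main_chain_on_toy(self, toy3):
        assert len(apply_selection(toy3, Selection(atom_class="main_chain"))) == 12

    def test_residue_range_count(self):
        structure = make_toy_protein(16)
        renumbered = Structure(
            [Atom(a.serial, a.name, a.element, a.resname, a.resnum + 49, a.chain, a.coords)
             for a in structure.atoms],
            id="T",
        )  # residues 50..65
        idx = apply_selection(
            renumbered,
            Selection(residue_ranges=((54, 60),), atom_class="main_chain"),
        )
        assert len(idx) == 7 * 4

    def test_all_returns_every_atom_once(self, toy3):
        idx = apply_selection(toy3, Selection(atom_class="all"))
        assert sorted(idx) == list(range(12))
        assert len(set(idx)) == 12

    def test_het_excluded_from_protein_classes(self, toy3):
        with_ligand = Structure(toy3.atoms + make_toy_ligand([9.0, 9.0, 9.0]), id="X")
        assert len(apply_selection(with_ligand, Selection(atom_class="heavy"))) == 12
        assert len(apply_selection(with_ligand, Selection(atom_class="all"))) == 17
        by_resname = apply_selection(with_ligand, Selection(resnames=frozenset({"RIT"})))
        assert len(by_resname) == 5

    def test_hydrogen_heuristic_without_element(self, toy3):
        h = Atom(99, "1HB", "", "ALA", 1, "A", [0.0, 0.0, 1.0])
        structure = Structure(toy3.atoms + [h], id="H")
        assert len(apply_selection(structure, Selection(atom_class="heavy"))) == 12

    def test_named_class(self, toy3):
        idx = apply_selection(toy3, Selection(atom_class="named", atom_names=("CA",)))
        assert [toy3.atoms[i].name for i in idx] == ["CA"] * 3

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            Selection(residue_ranges=((60, 54),))

    def test_parse_ranges_and_preset(self):
        selection = parse_selection("A:54-60,A:100-122")
        assert selection.chains == frozenset({"A"})
        assert selection.residue_ranges == ((54, 60), (100, 122))
        preset = parse_selection("active-site-cyp3a4")
        assert preset.residue_ranges == ACTIVE_SITE_CYP3A4_RANGES
        with pytest.raises(ValueError):
            parse_selection("A:zz-60")


class TestMatchAtoms:
    def test_identity_map(self, toy3):
        amap = match_atoms(toy3, toy3)
        assert len(amap) == 12
        assert np.all(amap.idx_a == amap.idx_b)

    def test_offset_residue_overlap(self):
        a = make_toy_protein(10)
        b_atoms = [
            Atom(at.serial, at.name, at.element, at.resname, at.resnum + 2, at.chain, at.coords)
            for at in make_toy_protein(10).atoms
        ]  # residues 3..12
        b = Structure(b_atoms, id="B")
        amap = match_atoms(a, b, Selection(atom_class="main_chain"))
        assert len(amap) == 8 * 4

    def test_symmetric_pair_set(self):
        a = make_toy_protein(6)
        b = make_toy_protein(9)
        forward = {(a.atoms[i].key(), b.atoms[j].key()) for i, j in match_atoms(a, b).pairs}
        backward = {(a.atoms[j].key(), b.atoms[i].key()) for i, j in match_atoms(b, a).pairs}
        assert forward == backward

    def test_no_common_atoms(self, toy3):
        other = Structure(
            [Atom(a.serial, a.name, a.element, a.resname, a.resnum, "B", a.coords)
             for a in make_toy_protein(3).atoms],
            id="B",
        )
        with pytest.raises(NoCommonAtomsError):
            match_atoms(toy3, other)
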