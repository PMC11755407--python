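"""Descriptor families: fingerprints, 2D panel, 3D descriptors, voxel grids."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from pdlscreen import descriptors as D
from pdlscreen._manifest_2d import DESCRIPTOR_2D_NAMES
from pdlscreen.curation import MoleculeRecord
from pdlscreen.descriptors import DescriptorError, GridSpec


def _rotated_copy(conformer, seed=0):
    """Same molecule, coordinates under a random proper rigid motion."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    mol = Chem.Mol(conformer.mol)
    conf = mol.GetConformer()
    xyz = conf.GetPositions() @ rot.T + rng.normal(scale=5.0, size=3)
    for i, p in enumerate(xyz):
        conf.SetAtomPosition(i, p)
    return D.Conformer(conformer.molecule_id + "-moved", mol,
                       conformer.pose_source)


class TestFingerprints:
    def test_family_lengths(self):
        assert len(D.compute_maccs("c1ccccc1")) == 166
        assert len(D.compute_morgan("c1ccccc1")) == 1024
        assert len(D.compute_path_fp("c1ccccc1")) == 2048

    def test_deterministic(self):
        for fn in (D.compute_maccs, D.compute_morgan, D.compute_path_fp):
            assert np.array_equal(fn("c1ccc2ccccc2c1"), fn("c1ccc2ccccc2c1"))

    def test_distinct_structures_differ(self):
        from pdlscreen.clustering import tanimoto
        assert tanimoto(D.compute_morgan("c1ccccc1"),
                        D.compute_morgan("c1ccncc1")) < 1
        assert tanimoto(D.compute_path_fp("c1ccccc1"),
                        D.compute_path_fp("c1ccncc1")) < 1

    def test_methane_maccs_nearly_empty(self):
        assert D.compute_maccs("C").sum() <= 5

    def test_amide_sets_a_specific_key(self):
        # the amide functionality must switch on structural keys that neither
        # the acid nor the amine alone sets
        amide = D.compute_maccs("CC(=O)NC")
        acid = D.compute_maccs("CC(=O)O")
        amine = D.compute_maccs("CCNC")
        only_amide = amide & ~acid & ~amine
        assert only_amide.sum() >= 1

    def test_morgan_popcount_monotone_in_radius(self):
        mol = "CC(=O)Oc1ccccc1C(=O)O"
        counts = [D.compute_morgan(mol, radius=r).sum() for r in (1, 2, 3)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_conformation_independent(self):
        smiles = "CCCCc1ccccc1O"
        fp = D.compute_morgan(smiles)
        for seed in (1, 2):
            conf = D.embed_conformer(smiles, seed=seed)
            assert np.array_equal(D.compute_morgan(conf.mol), fp)


class TestTwoD:
    def test_panel_shape_and_names(self):
        vec = D.compute_2d("CCO")
        assert vec.shape == (242,)
        assert len(DESCRIPTOR_2D_NAMES) == 242
        assert len(set(DESCRIPTOR_2D_NAMES)) == 242

    def test_ethane_formula_mass(self):
        # oracle: 2 x 12.011 + 6 x 1.008
        vec = D.compute_2d("CC")
        idx = DESCRIPTOR_2D_NAMES.index("MolWt")
        assert vec[idx] == pytest.approx(2 * 12.011 + 6 * 1.008, abs=0.01)
        assert vec[DESCRIPTOR_2D_NAMES.index("NumRotatableBonds")] == 0

    def test_hexane_rotatable_bonds(self):
        # oracle: C1-C2..C5-C6 chain has 5 C-C bonds, 3 non-terminal
        vec = D.compute_2d("CCCCCC")
        assert vec[DESCRIPTOR_2D_NAMES.index("NumRotatableBonds")] == 3

    def test_benzene(self):
        vec = D.compute_2d("c1ccccc1")
        assert vec[DESCRIPTOR_2D_NAMES.index("NumAromaticRings")] >= 1
        assert vec[DESCRIPTOR_2D_NAMES.index("NumHDonors")] == 0


class TestThreeD:
    def test_lengths(self):
        conf = D.embed_conformer("CC(=O)Oc1ccccc1C(=O)O", seed=1)
        vec = D.compute_3d(conf)
        assert vec.shape == (80 + 224 + 210 + 114,)
        assert np.all(np.isfinite(vec))

    def test_identical_conformer_identical_vector(self):
        conf = D.embed_conformer("CCO", seed=3)
        assert np.array_equal(D.compute_3d(conf), D.compute_3d(conf))

    def test_rigid_motion_invariance(self):
        conf = D.embed_conformer("Clc1ccc(-c2ccccc2)cc1", seed=5)
        moved = _rotated_copy(conf, seed=9)
        assert np.allclose(D.compute_3d(conf), D.compute_3d(moved), atol=1e-6)

    def test_diatomic_rdf_peak_tracks_distance(self):
        # closed form: the radial distribution of a 2-atom system peaks at
        # the interatomic distance, so stretching the bond moves the argmax
        def rdf_for(dist):
            mol = Chem.RWMol()
            mol.AddAtom(Chem.Atom(6))
            mol.AddAtom(Chem.Atom(6))
            mol.AddBond(0, 1, Chem.BondType.SINGLE)
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            c = Chem.Conformer(2)
            c.SetAtomPosition(0, (0.0, 0.0, 0.0))
            c.SetAtomPosition(1, (dist, 0.0, 0.0))
            m.AddConformer(c)
            vec = D.compute_3d(D.Conformer("diatomic", m))
            return vec[80 + 224: 80 + 224 + 30]  # unweighted RDF block

        assert np.argmax(rdf_for(3.0)) > np.argmax(rdf_for(1.5))


class TestVoxelGrid:
    def test_single_atom_conservation(self):
        conf = D.embed_conformer("C", seed=1)
        grid = D.compute_voxel_grid(conf, GridSpec(property="atomic_number"))
        assert grid.sum() == pytest.approx(6.0, rel=0.01)

    @pytest.mark.parametrize("prop", D.GRID_PROPERTIES)
    def test_conservation_all_properties(self, prop):
        conf = D.embed_conformer("CC(=O)Oc1ccccc1C(=O)O", seed=2)
        grid, clipped = D.compute_voxel_grid(conf, GridSpec(property=prop),
                                             return_clipped=True)
        w = D._atom_weights(conf.mol, prop)
        assert clipped == pytest.approx(0.0, abs=1e-9)
        assert grid.sum() == pytest.approx(w.sum(), abs=1e-6)

    def test_neutral_molecule_charge_grid_sums_to_zero(self):
        conf = D.embed_conformer("CCOCC", seed=4)
        grid = D.compute_voxel_grid(conf, GridSpec(property="gasteiger"))
        assert abs(grid.sum()) < 1e-6

    def test_mirror_symmetry(self):
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom(6))
        mol.AddAtom(Chem.Atom(6))
        mol.AddBond(0, 1, Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        c = Chem.Conformer(2)
        c.SetAtomPosition(0, (-1.4, 0.0, 0.0))
        c.SetAtomPosition(1, (1.4, 0.0, 0.0))
        m.AddConformer(c)
        spec = GridSpec(property="atomic_number")
        grid = D.compute_voxel_grid(D.Conformer("pair", m), spec)
        cube = grid.reshape(11, 11, 11)
        assert np.allclose(cube, cube[::-1, :, :])

    def test_oversized_molecule_reports_clipping(self):
        conf = D.embed_conformer("C" * 30, seed=6)  # ~35 A extended chain
        spec = GridSpec(edge_length=8.0, property="atomic_number")
        grid, clipped = D.compute_voxel_grid(conf, spec, return_clipped=True)
        assert clipped > 0.02
        assert grid.sum() < sum(a.GetAtomicNum()
                                for a in conf.mol.GetAtoms())

    def test_grid_spec_validation(self):
        with pytest.raises(DescriptorError):
            GridSpec(edge_length=-1)
        with pytest.raises(DescriptorError):
            GridSpec(sigma=0.0)
        with pytest.raises(DescriptorError):
            GridSpec(property="colour")
        assert GridSpec(n_per_axis=11).n_voxels == 1331


class TestDockedPose:
    def _conf_pair(self, smiles="CC(=O)Oc1ccccc1C(=O)O"):
        pre = D.embed_conformer(smiles, seed=1).mol
        order = list(range(pre.GetNumAtoms()))[::-1]
        post = Chem.RenumberAtoms(pre, order)
        conf = post.GetConformer()
        for i in range(post.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 2.0, p.y - 1.0, p.z))
        return pre, post

    def test_identity(self):
        pre = D.embed_conformer("CCO", seed=1).mol
        out = D.adopt_docked_pose(pre, pre)
        assert out.pose_source == "docked"
        assert np.allclose(out.mol.GetConformer().GetPositions(),
                           pre.GetConformer().GetPositions())

    def test_permuted_atoms_roundtrip(self):
        pre, post = self._conf_pair()
        out = D.adopt_docked_pose(pre, post)
        expect = pre.GetConformer().GetPositions() + np.array([2.0, -1.0, 0.0])
        assert np.allclose(out.mol.GetConformer().GetPositions(), expect,
                           atol=1e-6)
        # graph is the pre-docking one, coordinates the docked ones
        assert Chem.MolToSmiles(out.mol) == Chem.MolToSmiles(pre)

    def test_different_molecules_rejected(self):
        ethanol = D.embed_conformer("CCO", seed=1).mol
        propanol = D.embed_conformer("CCCO", seed=1).mol
        with pytest.raises(DescriptorError, match="atom-count|InChI"):
            D.adopt_docked_pose(ethanol, propanol)

    def test_isomer_mismatch_rejected(self):
        a = D.embed_conformer("CCCO", seed=1).mol    # 1-propanol
        b = D.embed_conformer("CC(C)O", seed=1).mol  # 2-propanol
        with pytest.raises(DescriptorError, match="InChI"):
            D.adopt_docked_pose(a, b)


class TestAssemble:
    def _records(self, smiles_list):
        return [MoleculeRecord(id=f"m{i}", smiles=s)
                for i, s in enumerate(smiles_list)]

    def test_single_family_shape(self):
        recs = self._records(["CCO", "c1ccccc1", "CC(=O)N"] * 3 + ["CCN"])
        mat = D.assemble_matrix(recs, families=("morgan",))
        assert mat.values.shape == (10, 1024)
        assert set(mat.family_tags.values()) == {"morgan"}

    def test_combined_width_with_3d_and_voxel(self):
        recs = self._records(["CCO", "CC(=O)N"])
        confs = {r.id: D.embed_conformer(r, seed=1) for r in recs}
        mat = D.assemble_matrix(
            recs, confs,
            families=("morgan", "autocorr3d", "morse", "rdf", "whim"),
            grid_specs=(GridSpec(property="mr"),))
        assert mat.values.shape[1] == 1024 + 628 + 1331  # 2983
        assert len(set(mat.column_names)) == mat.values.shape[1]
        fams = {mat.family_tags[c] for c in mat.column_names}
        assert fams == {"morgan", "autocorr3d", "morse", "rdf", "whim", "voxel"}

    def test_empty_records_rejected(self):
        with pytest.raises(DescriptorError, match="empty"):
            D.assemble_matrix([], families=("morgan",))

    def test_missing_conformers_rejected(self):
        recs = self._records(["CCO"])
        with pytest.raises(DescriptorError, match="conformer"):
            D.assemble_matrix(recs, families=("morse",))

    def test_csv_roundtrip(self, tmp_path):
        recs = self._records(["CCO", "CCN"])
        mat = D.assemble_matrix(recs, families=("maccs",))
        mat.to_csv(tmp_path / "m.csv")
        back = D.DescriptorMatrix.from_csv(tmp_path / "m.csv")
        assert back.row_ids == mat.row_ids
        assert np.allclose(back.values, mat.values)
        assert back.family_tags == mat.family_tags
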