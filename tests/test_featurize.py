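"""Voxelization math, channel typing, rotations and ligand features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dockpick.featurize import (
    CHANNELS,
    DescriptorStandardizer,
    assign_channels,
    default_descriptor_names,
    ligand_descriptors,
    ligand_fingerprint,
    random_rotation,
    random_rotation_matrix,
    voxel_contribution,
    voxelize,
)
from dockpick.io import PocketStructure
from dockpick.synthetic import generate_pocket


def brute_force_grid(pocket, edge=24.0, resolution=1.0):
    """Independent per-voxel / per-atom double loop oracle."""
    n = int(edge / resolution)
    origin = pocket.center - edge / 2.0
    values = np.zeros((8, n, n, n))
    for c in range(8):
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    vc = origin + (np.array([i, j, k]) + 0.5) * resolution
                    best = 0.0
                    for a in range(len(pocket)):
                        if pocket.channel_flags[a, c]:
                            r = float(np.linalg.norm(pocket.coords[a] - vc))
                            best = max(best, voxel_contribution(r, pocket.vdw_radii[a]))
                    values[c, i, j, k] = best
    return values


class TestVoxelContribution:
    def test_value_at_vdw_radius(self):
        assert voxel_contribution(1.7, 1.7) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_far_field_vanishes(self):
        assert voxel_contribution(18.0, 1.8) == pytest.approx(1e-12, rel=0.01)

    def test_scalar_example(self):
        assert voxel_contribution(3.6, 1.8) == pytest.approx(1 - np.exp(-(0.5**12)), rel=1e-12)

    def test_zero_distance_is_limit_value(self):
        assert voxel_contribution(0.0, 1.7) == 1.0

    @settings(deadline=None, derandomize=True)
    @given(rvdw=st.floats(0.5, 3.0), r1=st.floats(0.01, 30), r2=st.floats(0.01, 30))
    def test_monotone_decreasing_and_bounded(self, rvdw, r1, r2):
        lo, hi = sorted((r1, r2))
        a, b = voxel_contribution(lo, rvdw), voxel_contribution(hi, rvdw)
        assert 0.0 <= b <= a <= 1.0


class TestVoxelize:
    def test_empty_pocket_all_zero(self):
        pocket = PocketStructure(
            coords=np.empty((0, 3)), vdw_radii=np.empty(0),
            channel_flags=np.empty((0, 8), dtype=bool), center=np.zeros(3),
        )
        grid = voxelize(pocket)
        assert grid.values.shape == (8, 24, 24, 24)
        assert not grid.values.any()

    def test_default_edge_is_24_voxels(self, single_atom_pocket):
        assert voxelize(single_atom_pocket).values.shape == (8, 24, 24, 24)

    def test_non_integral_edge_rejected(self, single_atom_pocket):
        with pytest.raises(ValueError):
            voxelize(single_atom_pocket, edge=24.0, resolution=0.7)

    def test_matches_brute_force_oracle(self):
        pocket = generate_pocket(np.random.default_rng(5), 10)
        fast = voxelize(pocket).values
        slow = brute_force_grid(pocket)
        assert np.abs(fast - slow).max() < 1e-12

    def test_single_center_atom_octahedral_symmetry(self, single_atom_pocket):
        grid = voxelize(single_atom_pocket).values
        hydro = grid[0]
        for axes in ((0, 1), (1, 2), (0, 2)):
            np.testing.assert_array_equal(hydro, np.rot90(hydro, axes=axes))
        # channels 1..6 carry no flagged atom
        assert not grid[1:7].any()
        assert grid[7].any()

    def test_axis_aligned_rotation_permutes_grid_exactly(self):
        pocket = generate_pocket(np.random.default_rng(8), 12)
        base = voxelize(pocket).values
        # rotate 90 degrees about z through the grid center
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rotated = PocketStructure(
            coords=(pocket.coords - pocket.center) @ R.T + pocket.center,
            vdw_radii=pocket.vdw_radii,
            channel_flags=pocket.channel_flags,
            center=pocket.center,
        )
        rot_grid = voxelize(rotated).values
        np.testing.assert_array_equal(rot_grid, np.rot90(base, axes=(1, 2)))

    def test_adding_an_atom_never_decreases_any_voxel(self):
        rng = np.random.default_rng(3)
        pocket = generate_pocket(rng, 8)
        extra = generate_pocket(rng, 9)
        sub = PocketStructure(
            coords=extra.coords[:8], vdw_radii=extra.vdw_radii[:8],
            channel_flags=extra.channel_flags[:8], center=extra.center,
        )
        assert (voxelize(extra).values >= voxelize(sub).values - 1e-15).all()

    def test_atom_outside_grid_still_contributes(self):
        flags = np.zeros((1, 8), dtype=bool)
        flags[0, [0, 7]] = True
        pocket = PocketStructure(
            coords=np.array([[14.0, 0.0, 0.0]]),  # outside the 24 A box
            vdw_radii=np.array([1.7]), channel_flags=flags, center=np.zeros(3),
        )
        grid = voxelize(pocket).values
        assert grid[0].max() > 0


class TestAssignChannels:
    @staticmethod
    def _pocket(element, residue, name):
        flags = np.zeros((1, 8), dtype=bool)
        flags[0, 7] = True
        return PocketStructure(
            coords=np.zeros((1, 3)), vdw_radii=np.array([1.7]),
            channel_flags=flags, center=np.zeros(3),
            elements=[element], residues=[residue], atom_names=[name],
        )

    @pytest.mark.parametrize("element,residue,name,expected", [
        ("ZN", "ZN", "ZN", {"metal"}),
        ("O", "GLY", "O", {"acceptor"}),  # backbone carbonyl
        ("C", "ALA", "CB", {"hydrophobic"}),
        ("N", "LYS", "NZ", {"donor", "positive_ionizable"}),
        ("O", "ASP", "OD1", {"acceptor", "negative_ionizable"}),
        ("C", "PHE", "CZ", {"hydrophobic", "aromatic"}),
        ("C", "XXX", "C99", set()),  # not covered: excluded volume only
    ])
    def test_rule_table(self, element, residue, name, expected):
        pocket = assign_channels(self._pocket(element, residue, name))
        on = {CHANNELS[i] for i in np.flatnonzero(pocket.channel_flags[0])}
        assert on == expected | {"excluded_volume"}


class TestRotation:
    def test_identity_matrix_keeps_coords(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        out = random_rotation(coords, np.zeros(3), None, matrix=np.eye(3))
        np.testing.assert_array_equal(out, coords)

    def test_isometry_about_pivot(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3))
        pivot = np.array([1.0, -2.0, 0.5])
        out = random_rotation(coords, pivot, rng)
        np.testing.assert_allclose(
            np.linalg.norm(out - pivot, axis=1),
            np.linalg.norm(coords - pivot, axis=1), atol=1e-9,
        )
        d0 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            R = random_rotation_matrix(rng)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)


class TestLigandFeatures:
    def test_fingerprint_length_and_determinism(self):
        fp1 = ligand_fingerprint("CCO")
        fp2 = ligand_fingerprint("CCO")
        assert fp1.shape == (1024,)
        assert set(np.unique(fp1)) <= {0, 1}
        np.testing.assert_array_equal(fp1, fp2)

    def test_distinct_molecules_differ(self):
        assert (ligand_fingerprint("CC") != ligand_fingerprint("CCO")).any()

    def test_fingerprint_matches_reference_generator(self):
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        mol = Chem.MolFromSmiles("c1ccccc1O")
        ref = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024).GetFingerprint(mol)
        np.testing.assert_array_equal(
            ligand_fingerprint(mol), np.array([int(ref[i]) for i in range(1024)])
        )

    def test_unparsable_smiles_rejected(self):
        with pytest.raises(ValueError):
            ligand_fingerprint("not-a-smiles")

    def test_descriptor_vector_length_and_determinism(self):
        names = default_descriptor_names()
        assert len(names) == 183
        d1 = ligand_descriptors("CCO")
        d2 = ligand_descriptors("CCO")
        assert d1.shape == (183,)
        np.testing.assert_array_equal(d1, d2)
        assert np.isfinite(d1).all()


class TestStandardizer:
    def test_training_fold_moments(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3.0, 5.0, size=(50, 7))
        std = DescriptorStandardizer().fit(train)
        z = std.transform(train)
        assert np.abs(z.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-8)

    def test_constant_column_maps_to_zero(self):
        train = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        z = DescriptorStandardizer().fit(train).transform(train)
        assert (z[:, 0] == 0).all()

    def test_two_point_zscore(self):
        z = DescriptorStandardizer().fit(np.array([[0.0], [2.0]])).transform(
            np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 1.0])

    def test_validation_uses_training_statistics(self):
        train = np.array([[0.0], [2.0]])
        val = np.array([[4.0]])
        z = DescriptorStandardizer().fit(train).transform(val)
        assert z[0, 0] == pytest.approx(3.0)  # (4 - 1) / 1, not val's own stats

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            DescriptorStandardizer().fit(np.ones((1, 3)))
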