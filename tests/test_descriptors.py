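"""Descriptor correctness against independent brute-force oracles, plus the
geometric invariances (rotation, translation, atom permutation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from zindelta.descriptors import (
    DEFAULT_GRID,
    MoRdfGrid,
    atomic_potential,
    bond_features,
    build_edge_features,
    build_node_features,
    mo_rdf,
    morgan_fingerprint,
    particle_hole_densities,
    population_from_orbital,
)
from zindelta.records import ElectronicRecord


# -- independent oracles -----------------------------------------------------


def potential_oracle(Z, coords):
    n = len(Z)
    phi = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                phi[i] += Z[j] / np.linalg.norm(coords[i] - coords[j])
    return phi


def population_oracle(coeffs, basis_to_atom, n_atoms):
    p = np.zeros(n_atoms)
    for c, a in zip(coeffs, basis_to_atom):
        p[a] += c * c
    return p / sum(c * c for c in coeffs)


def mo_rdf_oracle(coords, w, grid):
    out = np.zeros(grid.n_points)
    n = len(w)
    pref = 1.0 / (grid.sigma * np.sqrt(2 * np.pi))
    for k, r in enumerate(grid.r):
        acc = 0.0
        for i in range(n):
            for j in range(i):
                d = np.linalg.norm(coords[i] - coords[j])
                acc += w[i] * w[j] * pref * np.exp(-((r - d) ** 2) / (2 * grid.sigma**2))
        out[k] = acc
    return out


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# -- atomic potential --------------------------------------------------------


class TestAtomicPotential:
    def test_single_atom_empty_sum(self):
        np.testing.assert_array_equal(atomic_potential([6], [[0, 0, 0]]), [0.0])

    def test_two_unit_charges_at_1A(self):
        phi = atomic_potential([1, 1], [[0, 0, 0], [1.0, 0, 0]])
        np.testing.assert_allclose(phi, [1.0, 1.0], atol=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 9)
            Z = rng.integers(1, 17, n).astype(float)
            coords = rng.uniform(-4, 4, (n, 3))
            np.testing.assert_allclose(
                atomic_potential(Z, coords), potential_oracle(Z, coords), atol=1e-12
            )

    def test_rotation_translation_invariance(self, rng):
        Z = np.array([6.0, 7.0, 8.0, 1.0])
        coords = rng.uniform(-2, 2, (4, 3))
        ref = atomic_potential(Z, coords)
        moved = coords @ random_rotation(rng).T + np.array([5.0, -3.0, 11.0])
        np.testing.assert_allclose(atomic_potential(Z, moved), ref, atol=1e-9)

    def test_coincident_atoms_error_names_pair(self):
        with pytest.raises(ValueError, match="0 and 1"):
            atomic_potential([6, 6], [[0, 0, 0], [0, 0, 1e-8]])


# -- orbital populations -----------------------------------------------------


class TestPopulations:
    def test_localized_orbital(self):
        p = population_from_orbital([0.7, 0.0, 0.0], [0, 1, 2])
        np.testing.assert_allclose(p, [1.0, 0.0, 0.0], atol=1e-15)

    def test_symmetric_split(self):
        p = population_from_orbital([0.5, 0.5], [0, 1])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-15)

    def test_matches_grouping_oracle(self, rng):
        coeffs = rng.normal(size=8)
        mapping = rng.integers(0, 3, 8)
        got = population_from_orbital(coeffs, mapping, n_atoms=3)
        np.testing.assert_allclose(got, population_oracle(coeffs, mapping, 3), atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_orbital_rejected(self):
        with pytest.raises(ValueError):
            population_from_orbital([0.0, 0.0], [0, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        r = np.random.default_rng(seed)
        coeffs = r.normal(size=6) + 0.1
        mapping = r.integers(0, 3, 6)
        perm = r.permutation(3)
        base = population_from_orbital(coeffs, mapping, 3)
        permuted = population_from_orbital(coeffs, perm[mapping], 3)
        np.testing.assert_allclose(permuted[perm], base, atol=1e-12)

    def test_particle_hole_limits(self):
        # charge transfer: hole on atom 0, particle on atom 1
        n_hole, n_elec = particle_hole_densities([1.0, 0.0], [0.0, 1.0], [0, 1])
        np.testing.assert_allclose(n_hole, [1, 0], atol=1e-15)
        np.testing.assert_allclose(n_elec, [0, 1], atol=1e-15)
        # identical pair
        h, e = particle_hole_densities([0.3, 0.4], [0.3, 0.4], [0, 1])
        np.testing.assert_allclose(h, e, atol=1e-15)

    def test_multi_pair_singular_value_weighting(self):
        holes = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        parts = [np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        sv = [2.0, 1.0]  # weights 0.8 / 0.2
        n_hole, n_elec = particle_hole_densities(holes, parts, [0, 1], singular_values=sv)
        np.testing.assert_allclose(n_hole, [0.8, 0.2], atol=1e-15)
        np.testing.assert_allclose(n_elec, [0.2, 0.8], atol=1e-15)
        assert n_hole.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="singular"):
            particle_hole_densities(holes, parts, [0, 1], singular_values=[1.0])


# -- MO-RDF ------------------------------------------------------------------


class TestMoRdf:
    def test_default_grid_length_726(self):
        assert DEFAULT_GRID.n_points == 726
        assert len(mo_rdf(np.zeros((3, 3)) + np.eye(3), np.ones(3))) == 726

    def test_single_atom_zero_vector(self):
        assert not mo_rdf(np.zeros((1, 3)), [1.0]).any()

    def test_two_atom_closed_form(self):
        f = mo_rdf(np.array([[0, 0, 0], [2.0, 0, 0]]), [1.0, 1.0])
        peak = 1.0 / (0.05 * np.sqrt(2 * np.pi))
        assert f.max() == pytest.approx(peak, rel=1e-9)
        assert DEFAULT_GRID.r[f.argmax()] == pytest.approx(2.0, abs=1e-9)
        assert f.sum() * DEFAULT_GRID.step == pytest.approx(1.0, rel=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        grid = MoRdfGrid(r_min=0.5, r_max=6.0, step=0.05, sigma=0.05)
        coords = rng.uniform(0, 3, (5, 3))
        w = rng.uniform(0, 1, 5)
        np.testing.assert_allclose(
            mo_rdf(coords, w, grid), mo_rdf_oracle(coords, w, grid), atol=1e-12
        )

    def test_gaussian_mass_conservation(self, rng):
        # all pair distances well inside the grid: step*sum f == sum_{i>j} w_i w_j
        coords = rng.uniform(0, 4.0, (6, 3)) + np.array([2.0, 0, 0])
        d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        iu = np.triu_indices(6, 1)
        assert d[iu].min() > DEFAULT_GRID.r_min + 5 * DEFAULT_GRID.sigma
        assert d[iu].max() < DEFAULT_GRID.r_max - 5 * DEFAULT_GRID.sigma
        w = rng.uniform(0.1, 1, 6)
        total = (w[:, None] * w[None, :])[iu].sum()
        f = mo_rdf(coords, w)
        assert f.sum() * DEFAULT_GRID.step == pytest.approx(total, rel=1e-6)

    def test_rotation_translation_invariance(self, rng):
        coords = rng.uniform(0, 3, (5, 3))
        w = rng.uniform(0, 1, 5)
        ref = mo_rdf(coords, w)
        moved = coords @ random_rotation(rng).T - np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(mo_rdf(moved, w), ref, atol=1e-9)

    def test_atom_reindexing_invariance(self, rng):
        coords = rng.uniform(0, 3, (6, 3))
        w = rng.uniform(0, 1, 6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(mo_rdf(coords[perm], w[perm]), mo_rdf(coords, w), atol=1e-12)

    def test_negative_weights_flagged(self):
        with pytest.warns(UserWarning, match="negative"):
            mo_rdf(np.array([[0, 0, 0], [1.0, 0, 0]]), [-0.5, 1.0])

    def test_weight_sensitivity_vs_fingerprint_blindness(self):
        """Same graph, different orbital weights: the MO-RDF separates what
        the Morgan fingerprint cannot see."""
        smiles = "c1ccc2ccccc2c1"
        mol = Chem.MolFromSmiles(smiles)
        from rdkit.Chem import AllChem

        m = Chem.Mol(mol)
        p = AllChem.ETKDGv3()
        p.randomSeed = 5
        AllChem.EmbedMolecule(m, p)
        coords = np.array(m.GetConformer().GetPositions())
        w1 = np.ones(10) / 10
        w2 = np.zeros(10)
        w2[:4] = 0.25
        f1, f2 = mo_rdf(coords, w1), mo_rdf(coords, w2)
        assert np.linalg.norm(f1 - f2) > 0
        assert np.array_equal(morgan_fingerprint(smiles), morgan_fingerprint(smiles))


# -- fingerprints and graph features ----------------------------------------


class TestFingerprint:
    def test_width_2048(self):
        assert len(morgan_fingerprint("c1ccccc1")) == 2048

    def test_atom_order_invariance(self):
        a = morgan_fingerprint("c1ccccc1C(=O)O")
        b = morgan_fingerprint("OC(=O)c1ccccc1")
        np.testing.assert_array_equal(a, b)

    def test_distinguishes_methane_from_ethane(self):
        assert not np.array_equal(morgan_fingerprint("C"), morgan_fingerprint("CC"))

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            morgan_fingerprint("not-a-smiles")


class TestGraphFeatures:
    def test_benzene_da_shape(self):
        assert build_node_features("c1ccccc1", mode="DA").shape == (6, 41)

    def test_benzene_da_ea_shape(self):
        elec = ElectronicRecord(
            "bz", 4.0, 0.1,
            np.zeros(6), np.ones(6), np.full(6, 1 / 6), np.full(6, 1 / 6), np.full(6, 1 / 6),
        )
        assert build_node_features("c1ccccc1", elec, mode="DA+EA").shape == (6, 45)

    def test_ea_columns_are_the_inputs_in_order(self):
        mull = np.array([0.1, -0.1])
        pot = np.array([5.0, 7.0])
        ne = np.array([0.4, 0.6])
        nh = np.array([0.5, 0.5])
        elec = ElectronicRecord("eth", 4.0, 0.1, mull, pot, ne, nh, np.array([0.5, 0.5]))
        feats = build_node_features("C=C", elec, mode="DA+EA")
        np.testing.assert_allclose(feats[:, 41], mull)
        np.testing.assert_allclose(feats[:, 42], pot)
        np.testing.assert_allclose(feats[:, 43], ne)
        np.testing.assert_allclose(feats[:, 44], nh)

    def test_ea_without_electronics_is_an_error(self):
        with pytest.raises(ValueError, match="ElectronicRecord"):
            build_node_features("CC", None, mode="DA+EA")

    def test_ethane_bond_is_plain_single(self):
        mol = Chem.MolFromSmiles("CC")
        feats = bond_features(mol.GetBondWithIdx(0))
        assert feats[0] == 1.0  # single one-hot
        assert feats[4] == 0.0  # not conjugated
        assert feats[5] == 0.0  # not in ring

    def test_benzene_bonds_aromatic_in_ring(self):
        _, feats = build_edge_features("c1ccccc1")
        assert feats.shape == (6, 10)
        assert np.all(feats[:, 3] == 1.0)  # aromatic one-hot
        assert np.all(feats[:, 5] == 1.0)  # in ring

    def test_bond_feature_direction_symmetry(self):
        mol = Chem.MolFromSmiles(r"F/C=C/c1ccccc1")
        for bond in mol.GetBonds():
            f = bond_features(bond)
            assert f.shape == (10,)  # single definition serves both directions
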