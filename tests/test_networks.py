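"""Linear baseline, variant grammar, encoder invariances and the
delta-learning residual identity."""

import numpy as np
import pytest

from zindelta.autodiff import Tensor
from zindelta.descriptors import molecular_graph
from zindelta.networks import (
    DeltaNet,
    DenseBlockSpec,
    EncoderSpec,
    GraphBatch,
    LinearBaseline,
    LinearBaselineModel,
    assemble_variant,
    linear_fit,
    linear_predict,
    parse_variant,
    residual_predict,
)


# -- linear baseline ---------------------------------------------------------


def ols_oracle(x, y):
    """Closed-form normal equations."""
    xm, ym = x.mean(), y.mean()
    m = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return m, ym - m * xm


class TestLinearBaseline:
    def test_recovers_noiseless_calibration(self):
        x = np.linspace(1.5, 5.5, 300)
        y = 1.08 * x + 0.52
        base, r = linear_fit(x, y)
        assert base.m == pytest.approx(1.08, abs=1e-10)
        assert base.c == pytest.approx(0.52, abs=1e-10)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_two_points_exact_interpolation(self):
        base, _ = linear_fit([1.0, 3.0], [2.0, 8.0])
        assert base.m == pytest.approx(3.0, abs=1e-12)
        assert base.c == pytest.approx(-1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(1.5, 5.5, 200)
        y = 1.08 * x + 0.52 + rng.normal(0, 0.1, 200)
        base, _ = linear_fit(x, y)
        m, c = ols_oracle(x, y)
        assert base.m == pytest.approx(m, abs=1e-12)
        assert base.c == pytest.approx(c, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "base,e,expected",
        [
            (LinearBaseline(1.08, 0.52), 3.0, 3.76),
            (LinearBaseline(1.0, 0.0), 4.3, 4.3),
        ],
    )
    def test_predict(self, base, e, expected):
        assert linear_predict(base, e) == pytest.approx(expected, abs=1e-12)

    def test_predict_vector_matches_loop(self, rng):
        base = LinearBaseline(1.08, 0.52)
        e = rng.uniform(1, 6, 30)
        np.testing.assert_allclose(
            linear_predict(base, e), [linear_predict(base, v) for v in e], atol=1e-15
        )

    def test_results_summary_reports_fit(self):
        x = np.linspace(1, 5, 50)
        res = LinearBaselineModel(x, 1.08 * x + 0.52).fit()
        assert "1.08" in res.summary()
        assert res.params["c"] == pytest.approx(0.52, abs=1e-10)


# -- variant grammar ---------------------------------------------------------


class TestVariantGrammar:
    @pytest.mark.parametrize(
        "name",
        [
            "Linear(E_ZINDO)",
            "MPNN(DA)",
            "MPNN(DA, EA)",
            "Dense(MPNN(DA), E_ZINDO)",
            "Dense(MPNN(DA, EA), E_ZINDO)",
            "Dense(MPNN(DA, EA), E_ZINDO, MO-RDF)",
            "Dense(MPNN(DA, EA), E_ZINDO, MO-RDF, MFP)",
            "Dense(E_ZINDO, MO-RDF)",
            "Dense(E_ZINDO, MO-RDF, MFP)",
        ],
    )
    def test_name_round_trip(self, name):
        assert parse_variant(name).name == name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            parse_variant("Transformer(DA)")
        with pytest.raises(ValueError):
            parse_variant("Dense(MPNN(DA), E_PM7)")

    def test_channel_counts_follow_mode(self):
        assert parse_variant("MPNN(DA)").node_channels == 41
        assert parse_variant("MPNN(DA, EA)").node_channels == 45

    def test_linear_dispatch(self):
        spec = assemble_variant("Linear(E_ZINDO)")
        assert spec.linear


# -- assembled networks ------------------------------------------------------


def tiny_encoder(node_channels=41):
    return EncoderSpec(node_channels=node_channels, hidden_dim=16, fingerprint_dim=12)


def batch_from_smiles(smiles_list, e_low=None):
    nodes_list, src_list, dst_list, ef, mol_idx = [], [], [], [], []
    off = 0
    for b, smi in enumerate(smiles_list):
        nodes, src, dst, efeat = molecular_graph(smi)
        nodes_list.append(nodes)
        src_list.append(src + off)
        dst_list.append(dst + off)
        ef.append(efeat)
        mol_idx.append(np.full(len(nodes), b))
        off += len(nodes)
    e = np.asarray(e_low if e_low is not None else np.zeros(len(smiles_list)), float)
    return GraphBatch(
        node_x=np.concatenate(nodes_list),
        edge_src=np.concatenate(src_list).astype(int),
        edge_dst=np.concatenate(dst_list).astype(int),
        edge_attr=np.concatenate(ef),
        node_mol=np.concatenate(mol_idx).astype(int),
        n_mols=len(smiles_list),
        e_low=e,
        e_low_z=e[:, None],
        mordf=np.zeros((len(smiles_list), 726)),
        mfp=np.zeros((len(smiles_list), 2048)),
    )


class TestAssembledVariants:
    def test_concat_width_bookkeeping(self):
        net = assemble_variant(
            "Dense(MPNN(DA, EA), E_ZINDO, MO-RDF)", rng=0, encoder_spec=tiny_encoder(45)
        )
        assert net.concat_width == 12 + 1 + 726
        net2 = assemble_variant(
            "Dense(MPNN(DA), E_ZINDO, MO-RDF, MFP)", rng=0, encoder_spec=tiny_encoder(41)
        )
        assert net2.concat_width == 12 + 1 + 726 + 2048

    def test_standalone_mpnn_has_direct_head(self):
        net = assemble_variant("MPNN(DA)", rng=0, encoder_spec=tiny_encoder(41))
        assert net.dense is None and not net.spec.use_e_zindo
        batch = batch_from_smiles(["CCO"], e_low=[3.0])
        net.eval()
        out = net(batch)
        assert out.shape == (1,)

    @pytest.mark.parametrize(
        "name",
        ["Dense(MPNN(DA), E_ZINDO)", "Dense(MPNN(DA, EA), E_ZINDO, MO-RDF)",
         "Dense(E_ZINDO, MO-RDF)"],
    )
    def test_delta_identity_with_zero_head(self, name):
        """Zeroed head weights make every residual variant return the
        low-level energy exactly."""
        nc = parse_variant(name).node_channels
        net = assemble_variant(name, rng=1, encoder_spec=tiny_encoder(nc))
        net.zero_head()
        net.eval()
        e_low = np.array([2.5, 4.0])
        smiles = ["c1ccccc1", "CCO"]
        batch = batch_from_smiles(smiles, e_low=e_low)
        if nc == 45:
            batch.node_x = np.concatenate([batch.node_x, np.zeros((len(batch.node_x), 4))], axis=1)
        np.testing.assert_array_equal(net(batch).data, e_low)

    def test_eval_forward_is_deterministic(self):
        net = assemble_variant("Dense(MPNN(DA), E_ZINDO)", rng=3, encoder_spec=tiny_encoder(41))
        net.eval()
        batch = batch_from_smiles(["c1ccncc1"], e_low=[3.3])
        a = net(batch).data
        b = net(batch).data
        np.testing.assert_array_equal(a, b)

    def test_encoder_permutation_invariance(self):
        """Feeding the same molecule with its atoms renumbered yields the
        same embedding."""
        from rdkit import Chem

        net = assemble_variant("MPNN(DA)", rng=5, encoder_spec=tiny_encoder(41))
        net.eval()
        mol = Chem.MolFromSmiles("Cc1ccc(O)cc1")
        order = list(range(mol.GetNumAtoms()))[::-1]
        renum = Chem.RenumberAtoms(mol, order)
        out1 = net.encoder(batch_from_smiles_mol(mol)).data
        out2 = net.encoder(batch_from_smiles_mol(renum)).data
        np.testing.assert_allclose(out1, out2, atol=1e-5)

    def test_single_atom_molecule_finite(self):
        net = assemble_variant("MPNN(DA)", rng=2, encoder_spec=tiny_encoder(41))
        net.eval()
        batch = batch_from_smiles(["C"], e_low=[3.0])
        out = net(batch).data
        assert np.all(np.isfinite(out)) and out.shape == (1,)

    def test_gradient_reaches_every_branch(self):
        net = assemble_variant(
            "Dense(MPNN(DA), E_ZINDO, MO-RDF, MFP)", rng=4,
            encoder_spec=tiny_encoder(41),
            dense_spec=DenseBlockSpec(layer_sizes=(16, 8), dropout=0.0, batch_norm=False),
        )
        net.train()
        batch = batch_from_smiles(["CCO", "c1ccccc1"], e_low=[3.0, 4.0])
        batch.mordf = np.random.default_rng(0).normal(size=(2, 726))
        batch.mfp = np.random.default_rng(1).integers(0, 2, (2, 2048)).astype(float)
        pred = net(batch, np.random.default_rng(2))
        loss = ((pred - Tensor(np.array([3.5, 4.5]))) ** 2).mean()
        loss.backward()
        grads = [p.grad for p in net.parameters()]
        assert all(g is not None for g in grads)
        assert any(np.abs(g).max() > 0 for g in grads)
        # encoder branch specifically
        assert any(np.abs(p.grad).max() > 0 for p in net.encoder.parameters())

    def test_checkpoint_round_trip(self, tmp_path):
        net = assemble_variant("Dense(MPNN(DA), E_ZINDO)", rng=7, encoder_spec=tiny_encoder(41))
        net.eval()
        batch = batch_from_smiles(["CCO"], e_low=[3.1])
        ref = net(batch).data
        path = tmp_path / "ckpt.json"
        net.save(str(path), scalers={"e_low_mean": 0.0})
        loaded, scalers = DeltaNet.load(str(path), expected_variant="Dense(MPNN(DA), E_ZINDO)")
        loaded.eval()
        np.testing.assert_allclose(loaded(batch).data, ref, atol=1e-12)
        with pytest.raises(ValueError, match="variant"):
            DeltaNet.load(str(path), expected_variant="MPNN(DA)")

    def test_channel_mismatch_rejected(self):
        net = assemble_variant("MPNN(DA)", rng=0, encoder_spec=tiny_encoder(41))
        batch = batch_from_smiles(["CC"])
        batch.node_x = batch.node_x[:, :40]
        with pytest.raises(ValueError, match="channels"):
            net(batch)


def batch_from_smiles_mol(mol):
    from zindelta.descriptors import molecular_graph as mg

    nodes, src, dst, efeat = mg(mol)
    return GraphBatch(
        node_x=nodes, edge_src=src.astype(int), edge_dst=dst.astype(int),
        edge_attr=efeat, node_mol=np.zeros(len(nodes), dtype=int), n_mols=1,
    )


class TestResidualPredict:
    def test_zero_correction_identity(self):
        assert residual_predict(0.0, 3.2) == 3.2

    def test_perfect_correction(self):
        assert residual_predict(0.7, 3.0) == pytest.approx(3.7, abs=1e-15)

    def test_batch_matches_loop(self, rng):
        ml = rng.normal(0, 0.5, 20)
        e = rng.uniform(2, 5, 20)
        np.testing.assert_allclose(
            residual_predict(ml, e), [residual_predict(a, b) for a, b in zip(ml, e)], atol=0
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            residual_predict(np.nan, 1.0)
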