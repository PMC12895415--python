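"""Cross-validation mechanics, fold training contracts and ensemble
averaging."""

import copy

import numpy as np
import pytest

import zindelta as zd
from zindelta.networks import DeltaNet, DenseBlockSpec, EncoderSpec, parse_variant
from zindelta.training import (
    DeltaMLModel,
    FeatureCache,
    FoldEnsemble,
    TrainConfig,
    ensemble_predict,
    kfold_split,
    train_fold,
)

TINY_ENC = EncoderSpec(node_channels=45, hidden_dim=24, fingerprint_dim=16)
TINY_DENSE = DenseBlockSpec(layer_sizes=(32, 16), dropout=0.1)


class TestKFold:
    def test_even_division(self):
        split = kfold_split([f"m{i}" for i in range(100)], k=10, seed=0)
        sizes = [len(split.fold_ids(f)[1]) for f in range(10)]
        assert sizes == [10] * 10
        trn, val = split.fold_ids(0)
        assert len(trn) == 90 and not set(trn) & set(val)

    def test_uneven_division_7602(self):
        split = kfold_split([str(i) for i in range(7602)], k=10, seed=3)
        sizes = sorted(len(split.fold_ids(f)[1]) for f in range(10))
        assert sizes == [760] * 8 + [761] * 2

    def test_deterministic(self):
        ids = [f"m{i}" for i in range(37)]
        a = kfold_split(ids, 5, seed=11).fold_assignments
        b = kfold_split(ids, 5, seed=11).fold_assignments
        assert a == b

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=3)

    def test_folds_partition_ids(self):
        ids = [f"m{i}" for i in range(23)]
        split = kfold_split(ids, 4, seed=5)
        seen = [i for f in range(4) for i in split.fold_ids(f)[1]]
        assert sorted(seen) == sorted(ids)


def _zero_deviation_dataset(n=80, seed=9):
    """Synthetic set where the high-level target equals the low-level input
    exactly, so the residual identity (zero correction) is the optimum."""
    ds = zd.generate_dataset(zd.SyntheticSpec(n_molecules=n, seed=seed, noise_sd=0.0))
    for mid in ds.ids:
        ds.targets[mid].e_s1_high = ds.electronic[mid].e_s1_low
    return ds


class TestTrainFold:
    def test_zero_deviation_converges_to_identity(self):
        ds = _zero_deviation_dataset()
        # deterministic head (no dropout/batch noise): the zero correction is
        # the exact optimum and training should find it quickly
        spec = parse_variant(
            "Dense(MPNN(DA, EA), E_ZINDO)",
            dense=DenseBlockSpec(layer_sizes=(32, 16), dropout=0.0, batch_norm=False),
        )
        cache = FeatureCache(ds, spec)
        ids = ds.ids
        net = DeltaNet(spec, np.random.default_rng(0), TINY_ENC)
        cfg = TrainConfig(k=2, lr=5e-3, batch_size=16, max_epochs=50, base_seed=0)
        net, _, hist = train_fold(net, cache, ids[:60], ids[60:], cfg, fold_seed=0)
        assert hist.val_mae.min() < 0.01

    def test_early_stop_fires_after_patience(self):
        ds = _zero_deviation_dataset(n=30)
        spec = parse_variant("Dense(E_ZINDO)", dense=TINY_DENSE)
        cache = FeatureCache(ds, spec)
        net = DeltaNet(spec, np.random.default_rng(0), None)
        # zero learning rate: validation never improves after the first epoch
        cfg = TrainConfig(k=2, lr=1e-30, batch_size=16, max_epochs=500,
                          patience=3, base_seed=0, cyclical=False)
        _, _, hist = train_fold(net, cache, ds.ids[:20], ds.ids[20:], cfg, fold_seed=0)
        assert hist.epoch.iloc[-1] == 4  # patience + 1, not max_epochs
        assert len(hist) < 500

    def test_fixed_seed_reproduces_history_bitwise(self):
        ds = _zero_deviation_dataset(n=40)
        spec = parse_variant("Dense(MPNN(DA, EA), E_ZINDO)", dense=TINY_DENSE)
        cache = FeatureCache(ds, spec)
        cfg = TrainConfig(k=2, lr=1e-3, batch_size=16, max_epochs=5, base_seed=0)
        hists = []
        for _ in range(2):
            net = DeltaNet(spec, np.random.default_rng(7), TINY_ENC)
            _, _, hist = train_fold(net, cache, ds.ids[:30], ds.ids[30:], cfg, fold_seed=7)
            hists.append(hist)
        assert hists[0].equals(hists[1])

    def test_overlapping_ids_rejected(self):
        ds = _zero_deviation_dataset(n=20)
        spec = parse_variant("Dense(E_ZINDO)", dense=TINY_DENSE)
        cache = FeatureCache(ds, spec)
        net = DeltaNet(spec, np.random.default_rng(0), None)
        with pytest.raises(ValueError, match="leakage"):
            train_fold(net, cache, ds.ids[:10], ds.ids[5:15], TrainConfig(), fold_seed=0)


class TestEnsemble:
    def _fitted(self, small_synthetic, k=2):
        cfg = TrainConfig(k=k, lr=1e-3, batch_size=16, max_epochs=8, base_seed=2)
        model = DeltaMLModel(
            small_synthetic, "Dense(MPNN(DA, EA), E_ZINDO)",
            config=cfg, encoder_spec=TINY_ENC, dense_spec=TINY_DENSE,
        )
        return model.fit()

    def test_prediction_is_fold_mean(self, small_synthetic):
        res = self._fitted(small_synthetic)
        preds = res.predict(small_synthetic)
        for p in preds:
            assert p.e_pred == pytest.approx(np.mean(p.per_fold_preds), abs=1e-12)
            assert len(p.per_fold_preds) == 2

    def test_single_member_ensemble_is_identity(self, small_synthetic):
        res = self._fitted(small_synthetic)
        ens = res.ensemble
        solo = FoldEnsemble(ens.variant, ens.members[:1], ens.scalers[:1], ens.seeds[:1])
        cache = FeatureCache(small_synthetic, ens.members[0].spec)
        ids = small_synthetic.ids[:5]
        solo_preds = ensemble_predict(solo, cache, ids)
        batch, _ = cache.batch(ids, ens.scalers[0])
        direct = ens.members[0](batch).data
        np.testing.assert_allclose([p.e_pred for p in solo_preds], direct, atol=1e-12)

    def test_mean_matches_loop_oracle(self, small_synthetic):
        res = self._fitted(small_synthetic)
        cache = FeatureCache(small_synthetic, res.ensemble.members[0].spec)
        ids = small_synthetic.ids[:8]
        preds = ensemble_predict(res.ensemble, cache, ids)
        for j, p in enumerate(preds):
            acc = []
            for member, sc in zip(res.ensemble.members, res.ensemble.scalers):
                batch, _ = cache.batch(ids, sc)
                acc.append(member(batch).data[j])
            assert p.e_pred == pytest.approx(np.mean(acc), abs=1e-12)

    def test_distinct_seeds_enforced(self, small_synthetic):
        res = self._fitted(small_synthetic)
        ens = res.ensemble
        with pytest.raises(ValueError, match="seeds"):
            FoldEnsemble(ens.variant, ens.members, ens.scalers, [1, 1])

    def test_mismatched_variants_rejected(self, small_synthetic):
        res = self._fitted(small_synthetic)
        other = DeltaNet(parse_variant("Dense(E_ZINDO)", dense=TINY_DENSE),
                         np.random.default_rng(0), None)
        with pytest.raises(ValueError, match="variant"):
            FoldEnsemble("x", [res.ensemble.members[0], other], res.ensemble.scalers[:2], [0, 1])

    def test_summary_lists_folds(self, small_synthetic):
        res = self._fitted(small_synthetic)
        text = res.summary()
        assert "Dense(MPNN(DA, EA), E_ZINDO)" in text
        assert "val MAE" in text


def test_fold_scalers_use_training_portion_only(small_synthetic):
    spec = parse_variant("Dense(MPNN(DA, EA), E_ZINDO)", dense=TINY_DENSE)
    cache = FeatureCache(small_synthetic, spec)
    ids = small_synthetic.ids
    sc = cache.fit_scalers(ids[:30])
    e = np.array([cache.e_low[i] for i in ids[:30]])
    assert sc.e_low_mean == pytest.approx(e.mean())
    sc_other = cache.fit_scalers(ids[30:])
    assert sc.e_low_mean != sc_other.e_low_mean
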