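"""K-fold training and ensemble prediction.

The front door is statsmodels-flavoured::

    model = DeltaMLModel(dataset, variant="Dense(MPNN(DA, EA), E_ZINDO)")
    results = model.fit()
    print(results.summary())
    preds = results.predict(test_dataset)

``fit`` performs k-fold cross-validation: each fold trains one network (its
own weight seed, its own feature-standardisation statistics computed from
that fold's training portion only) and the per-fold validation metrics
estimate the model's uncertainty.  ``predict`` averages the k fold models —
the ensemble prediction — keeping the per-fold values on each record.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .descriptors import DEFAULT_GRID, MoRdfGrid, mo_rdf, molecular_graph, morgan_fingerprint
from .evaluation import EvalReport, regression_metrics
from .networks import (
    DeltaNet,
    DenseBlockSpec,
    EncoderSpec,
    GraphBatch,
    LinearBaselineModel,
    VariantSpec,
    parse_variant,
)
from .nn import Adam, cyclical_lr
from .records import Dataset, DatasetSplit, PredictionRecord

__all__ = [
    "TrainConfig",
    "kfold_split",
    "FeatureCache",
    "FoldScalers",
    "train_fold",
    "ensemble_predict",
    "FoldEnsemble",
    "DeltaMLModel",
    "DeltaMLResults",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.  Defaults are the full-scale settings:
    10 folds, Adam at 1e-4, batch 32, up to 500 epochs with a triangular
    cyclical learning rate (period 20 epochs, bounds [lr/10, lr]) and early
    stopping on validation MAE with patience 50."""

    k: int = 10
    lr: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    cyclical: bool = True
    lr_period: int = 20
    early_stopping: bool = True
    patience: int = 50
    base_seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.lr <= 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


def kfold_split(ids, k: int, seed: int = 0, test_ids=()) -> DatasetSplit:
    """Shuffled partition of ``ids`` into k folds with sizes differing by at
    most one; deterministic for a fixed seed."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds n={len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for pos in chunk:
            assignments[ids[pos]] = fold
    return DatasetSplit(train_ids=ids, test_ids=list(test_ids), fold_assignments=assignments)


# ---------------------------------------------------------------------------
# feature cache + per-fold standardisation
# ---------------------------------------------------------------------------


@dataclass
class FoldScalers:
    """Standardisation statistics frozen from one fold's training portion."""

    ea_mean: np.ndarray | None = None
    ea_std: np.ndarray | None = None
    e_low_mean: float = 0.0
    e_low_std: float = 1.0
    mordf_mean: np.ndarray | None = None
    mordf_std: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "ea_mean": None if self.ea_mean is None else self.ea_mean.tolist(),
            "ea_std": None if self.ea_std is None else self.ea_std.tolist(),
            "e_low_mean": self.e_low_mean,
            "e_low_std": self.e_low_std,
            "mordf_mean": None if self.mordf_mean is None else self.mordf_mean.tolist(),
            "mordf_std": None if self.mordf_std is None else self.mordf_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldScalers":
        conv = lambda v: None if v is None else np.asarray(v, float)
        return cls(
            ea_mean=conv(d.get("ea_mean")), ea_std=conv(d.get("ea_std")),
            e_low_mean=float(d.get("e_low_mean", 0.0)),
            e_low_std=float(d.get("e_low_std", 1.0)),
            mordf_mean=conv(d.get("mordf_mean")), mordf_std=conv(d.get("mordf_std")),
        )


class FeatureCache:
    """Raw (unstandardised) features for every molecule of a dataset,
    computed once; batches are assembled per fold with that fold's
    standardisation statistics."""

    def __init__(self, dataset: Dataset, spec: VariantSpec, grid: MoRdfGrid = DEFAULT_GRID):
        self.spec = spec
        self.grid = grid
        self.graph: dict[str, tuple] = {}
        self.ea_raw: dict[str, np.ndarray] = {}
        self.mordf: dict[str, np.ndarray] = {}
        self.mfp: dict[str, np.ndarray] = {}
        self.e_low: dict[str, float] = {}
        self.e_high: dict[str, float] = {}
        for mid in dataset.ids:
            mol = dataset.molecules[mid]
            elec = dataset.electronic.get(mid)
            targ = dataset.targets.get(mid)
            if elec is None:
                raise ValueError(f"molecule {mid}: electronic record required for featurization")
            self.e_low[mid] = elec.e_s1_low
            if targ is not None:
                self.e_high[mid] = targ.e_s1_high
            if spec.use_encoder:
                nodes, src, dst, efeat = molecular_graph(mol, elec, "DA", None)
                self.graph[mid] = (nodes, src, dst, efeat)
                if spec.ea:
                    self.ea_raw[mid] = np.stack(
                        [elec.mulliken, elec.potential, elec.n_elec, elec.n_hole], axis=1
                    )
            if spec.use_mordf:
                w = np.asarray(elec.w_homo, float)
                s = w.sum()
                if s > 0:
                    w = w / s  # size-comparable MO-RDF across molecules
                self.mordf[mid] = mo_rdf(mol.coords, w, grid)
            if spec.use_mfp:
                self.mfp[mid] = morgan_fingerprint(mol).astype(float)

    def fit_scalers(self, ids) -> FoldScalers:
        sc = FoldScalers()
        e = np.array([self.e_low[i] for i in ids])
        sc.e_low_mean = float(e.mean())
        sc.e_low_std = float(e.std()) or 1.0
        if self.spec.ea:
            allrows = np.concatenate([self.ea_raw[i] for i in ids], axis=0)
            sc.ea_mean = allrows.mean(axis=0)
            sc.ea_std = allrows.std(axis=0)
            sc.ea_std[sc.ea_std < 1e-12] = 1.0
        if self.spec.use_mordf:
            m = np.stack([self.mordf[i] for i in ids])
            sc.mordf_mean = m.mean(axis=0)
            sc.mordf_std = m.std(axis=0)
            sc.mordf_std[sc.mordf_std < 1e-12] = 1.0
        return sc

    def batch(self, ids, scalers: FoldScalers) -> tuple[GraphBatch, np.ndarray | None]:
        """(GraphBatch, high-level targets or None) for the given ids."""
        ids = list(ids)
        if self.spec.use_encoder:
            nodes_list, src_list, dst_list, ef_list, mol_idx = [], [], [], [], []
            offset = 0
            for b, mid in enumerate(ids):
                nodes, src, dst, efeat = self.graph[mid]
                if self.spec.ea:
                    ea = (self.ea_raw[mid] - scalers.ea_mean) / scalers.ea_std
                    nodes = np.concatenate([nodes, ea], axis=1)
                nodes_list.append(nodes)
                src_list.append(src + offset)
                dst_list.append(dst + offset)
                ef_list.append(efeat)
                mol_idx.append(np.full(len(nodes), b))
                offset += len(nodes)
            node_x = np.concatenate(nodes_list, axis=0)
            edge_src = np.concatenate(src_list)
            edge_dst = np.concatenate(dst_list)
            edge_attr = np.concatenate(ef_list, axis=0)
            node_mol = np.concatenate(mol_idx)
        else:
            node_x = np.zeros((0, 1))
            edge_src = edge_dst = np.zeros(0, dtype=int)
            edge_attr = np.zeros((0, 1))
            node_mol = np.zeros(0, dtype=int)
        e_low = np.array([self.e_low[i] for i in ids])
        batch = GraphBatch(
            node_x=node_x, edge_src=edge_src.astype(int), edge_dst=edge_dst.astype(int),
            edge_attr=edge_attr, node_mol=node_mol.astype(int), n_mols=len(ids),
            e_low=e_low,
            e_low_z=((e_low - scalers.e_low_mean) / scalers.e_low_std)[:, None],
            mordf=(
                np.stack([(self.mordf[i] - scalers.mordf_mean) / scalers.mordf_std for i in ids])
                if self.spec.use_mordf else None
            ),
            mfp=np.stack([self.mfp[i] for i in ids]) if self.spec.use_mfp else None,
        )
        y = None
        if all(i in self.e_high for i in ids):
            y = np.array([self.e_high[i] for i in ids])
        return batch, y


# ---------------------------------------------------------------------------
# single-fold training
# ---------------------------------------------------------------------------


def train_fold(
    model: DeltaNet,
    cache: FeatureCache,
    train_ids,
    val_ids,
    config: TrainConfig,
    fold_seed: int = 0,
    scalers: FoldScalers | None = None,
) -> tuple[DeltaNet, FoldScalers, pd.DataFrame]:
    """Minimise MSE on the high-level energy over ``train_ids``; early-stop
    on validation MAE; return the best-validation checkpoint and the
    per-epoch history (epoch, train_loss, val_mae, lr)."""
    train_ids, val_ids = list(train_ids), list(val_ids)
    if not train_ids or not val_ids:
        raise ValueError("train and validation id lists must be nonempty")
    if set(train_ids) & set(val_ids):
        raise ValueError("train/validation leakage: id sets overlap")
    rng = np.random.default_rng(fold_seed)
    if scalers is None:
        scalers = cache.fit_scalers(train_ids)
    val_batch, val_y = cache.batch(val_ids, scalers)
    if val_y is None:
        raise ValueError("validation molecules lack high-level targets")
    opt = Adam(model.parameters(), lr=config.lr)
    history = []
    best_mae = np.inf
    best_weights = [w.copy() for w in model.state_arrays()]
    best_epoch = -1
    n = len(train_ids)
    for epoch in range(config.max_epochs):
        lr = cyclical_lr(epoch, config.lr, config.lr_period) if config.cyclical else config.lr
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            ids = [train_ids[i] for i in order[start : start + config.batch_size]]
            batch, y = cache.batch(ids, scalers)
            pred = model(batch, rng)
            loss = ((pred - Tensor(y)) ** 2).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    "reduce the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_pred = model(val_batch).data
        val_mae = float(np.mean(np.abs(val_pred - val_y)))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_mae": val_mae, "lr": lr}
        )
        if val_mae < best_mae - 1e-12:
            best_mae = val_mae
            best_epoch = epoch
            best_weights = [w.copy() for w in model.state_arrays()]
        elif config.early_stopping and epoch - best_epoch > config.patience:
            break
    model.load_state_arrays(best_weights)
    model.eval()
    return model, scalers, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class FoldEnsemble:
    """k trained fold models with their scalers, seeds and validation
    metrics."""

    variant: str
    members: list[DeltaNet]
    scalers: list[FoldScalers]
    seeds: list[int]
    val_reports: list[EvalReport] = field(default_factory=list)

    def __post_init__(self):
        names = {m.spec.name for m in self.members}
        if len(names) > 1:
            raise ValueError(f"ensemble members disagree on variant: {names}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("fold seeds must be distinct")


def ensemble_predict(ensemble: FoldEnsemble, cache: FeatureCache, ids) -> list[PredictionRecord]:
    """Average the fold models' predictions per molecule, retaining the
    per-fold values."""
    ids = list(ids)
    per_fold = []
    for model, sc in zip(ensemble.members, ensemble.scalers):
        batch, _ = cache.batch(ids, sc)
        model.eval()
        per_fold.append(model(batch).data)
    per_fold = np.stack(per_fold)  # (k, n)
    mean = per_fold.mean(axis=0)
    return [
        PredictionRecord(
            molecule_id=mid,
            e_pred=float(mean[j]),
            delta_pred=float(mean[j] - cache.e_low[mid]),
            per_fold_preds=per_fold[:, j].tolist(),
        )
        for j, mid in enumerate(ids)
    ]


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------


class DeltaMLModel:
    """A delta-learning regression of high-level S1 energies from low-level
    electronic data, trained as a k-fold ensemble.

    Parameters
    ----------
    dataset : Dataset with molecule, electronic and target records.
    variant : canonical variant name, e.g. ``"Dense(MPNN(DA, EA), E_ZINDO)"``;
        ``"Linear(E_ZINDO)"`` dispatches to the closed-form baseline.
    config : TrainConfig (defaults to the full-scale hyperparameters).
    encoder_spec / dense_spec : architecture overrides.
    """

    def __init__(
        self,
        dataset: Dataset,
        variant: str = "Dense(MPNN(DA, EA), E_ZINDO)",
        config: TrainConfig | None = None,
        encoder_spec: EncoderSpec | None = None,
        dense_spec: DenseBlockSpec | None = None,
        grid: MoRdfGrid = DEFAULT_GRID,
    ):
        self.dataset = dataset
        self.variant_name = variant
        self.spec = parse_variant(variant, dense=dense_spec)
        self.config = config or TrainConfig()
        self.encoder_spec = encoder_spec or EncoderSpec(node_channels=self.spec.node_channels)
        self.grid = grid
        ids, dropped = dataset.complete_ids()
        if dropped:
            raise ValueError(f"dataset has incomplete records: {dropped}")
        self.ids = ids

    @classmethod
    def from_dataset_dir(cls, path: str, **kwargs) -> "DeltaMLModel":
        from .records import read_dataset
        import os

        ds, _ = read_dataset(
            os.path.join(path, "molecules.sdf"),
            os.path.join(path, "electronic.json"),
            os.path.join(path, "targets.json"),
        )
        return cls(ds, **kwargs)

    def fit(self, verbose: bool = False) -> "DeltaMLResults":
        if self.spec.linear:
            frame = self.dataset.subset(self.ids).to_frame()
            lin = LinearBaselineModel.from_dataframe(frame).fit()
            return DeltaMLResults(model=self, linear_results=lin)
        cache = FeatureCache(self.dataset.subset(self.ids), self.spec, self.grid)
        split = kfold_split(self.ids, self.config.k, seed=self.config.base_seed)
        members, scalers, seeds, histories, val_reports = [], [], [], [], []
        for fold in range(self.config.k):
            t0 = time.time()
            trn, val = split.fold_ids(fold)
            seed = self.config.base_seed + fold  # distinct weight seeds per fold
            net = DeltaNet(self.spec, np.random.default_rng(seed), self.encoder_spec)
            net, sc, hist = train_fold(net, cache, trn, val, self.config, fold_seed=seed)
            val_batch, val_y = cache.batch(val, sc)
            report = regression_metrics(net(val_batch).data, val_y)
            members.append(net)
            scalers.append(sc)
            seeds.append(seed)
            histories.append(hist)
            val_reports.append(report)
            if verbose:
                print(
                    f"fold {fold}: val MAE {report.mae:.4f} eV, r {report.pearson_r:.4f} "
                    f"({time.time() - t0:.1f} s, {len(hist)} epochs)"
                )
        ensemble = FoldEnsemble(
            variant=self.variant_name, members=members, scalers=scalers,
            seeds=seeds, val_reports=val_reports,
        )
        return DeltaMLResults(
            model=self, ensemble=ensemble, split=split, histories=histories, cache=cache
        )


@dataclass
class DeltaMLResults:
    """Fitted ensemble: per-fold validation metrics, training histories and
    ensemble prediction on new data."""

    model: DeltaMLModel
    ensemble: FoldEnsemble | None = None
    split: DatasetSplit | None = None
    histories: list[pd.DataFrame] = field(default_factory=list)
    cache: FeatureCache | None = None
    linear_results: object = None

    @property
    def is_linear(self) -> bool:
        return self.linear_results is not None

    def predict(self, dataset: Dataset, ids=None) -> list[PredictionRecord]:
        ids = list(ids) if ids is not None else dataset.ids
        if self.is_linear:
            out = []
            for mid in ids:
                e_low = dataset.electronic[mid].e_s1_low
                e = float(self.linear_results.predict(e_low))
                out.append(PredictionRecord(mid, e, e - e_low, [e]))
            return out
        cache = FeatureCache(dataset.subset(ids), self.model.spec, self.model.grid)
        return ensemble_predict(self.ensemble, cache, ids)

    def evaluate(self, dataset: Dataset, ids=None) -> EvalReport:
        ids = list(ids) if ids is not None else dataset.ids
        preds = self.predict(dataset, ids)
        y_pred = np.array([p.e_pred for p in preds])
        y_true = np.array([dataset.targets[i].e_s1_high for i in ids])
        return regression_metrics(y_pred, y_true)

    @property
    def validation_mae(self) -> float:
        if self.is_linear:
            raise AttributeError("linear baseline has no fold validation")
        return float(np.mean([r.mae for r in self.ensemble.val_reports]))

    @property
    def validation_r(self) -> float:
        if self.is_linear:
            raise AttributeError("linear baseline has no fold validation")
        return float(np.mean([r.pearson_r for r in self.ensemble.val_reports]))

    def summary(self) -> str:
        if self.is_linear:
            return self.linear_results.summary()
        lines = [
            f"Delta-ML ensemble: {self.model.variant_name}",
            "=" * 56,
            f"n molecules        {len(self.model.ids)}",
            f"folds (k)          {self.model.config.k}",
            f"epochs run         {[len(h) for h in self.histories]}",
            "",
            "fold   val MAE (eV)   val RMSE (eV)   val r",
        ]
        for i, r in enumerate(self.ensemble.val_reports):
            lines.append(f"{i:4d}   {r.mae:11.4f}   {r.rmse:12.4f}   {r.pearson_r:.4f}")
        lines.append("-" * 56)
        lines.append(
            f"mean   {self.validation_mae:11.4f}   "
            f"{np.mean([r.rmse for r in self.ensemble.val_reports]):12.4f}   "
            f"{self.validation_r:.4f}"
        )
        return "\n".join(lines)
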