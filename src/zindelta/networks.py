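"""Model components and the variant assembler.

A *variant* names which inputs feed the final regression head, using the
``component(descriptor)`` convention, e.g.::

    Linear(E_ZINDO)                      ordinary least-squares baseline
    MPNN(DA)                             stand-alone graph encoder, 41 channels
    MPNN(DA, EA)                         encoder with electronic atom features
    Dense(MPNN(DA, EA), E_ZINDO, MO-RDF) encoder fingerprint + scalar ZINDO
                                         energy + MO-RDF through a dense block

Whenever the low-level S1 energy (E_ZINDO) is among the inputs it is also
routed around the network through a residual connection, so the network head
learns only the low→high deviation ΔE and a zero-weight head reproduces the
low-level energy exactly (the delta-learning identity).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import nn
from .autodiff import Tensor, concatenate, segment_softmax, segment_sum

__all__ = [
    "LinearBaseline",
    "linear_fit",
    "linear_predict",
    "LinearBaselineModel",
    "LinearBaselineResults",
    "DenseBlockSpec",
    "EncoderSpec",
    "VariantSpec",
    "parse_variant",
    "GraphBatch",
    "AttentiveEncoder",
    "DeltaNet",
    "assemble_variant",
    "residual_predict",
    "MORDF_DIM",
    "MFP_DIM",
]

MORDF_DIM = 726
MFP_DIM = 2048


# ---------------------------------------------------------------------------
# linear baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearBaseline:
    """E_high ≈ m·E_low + c (slope dimensionless, intercept in eV)."""

    m: float
    c: float


def linear_fit(e_low, e_high) -> tuple[LinearBaseline, float]:
    """Ordinary least-squares fit of high-level onto low-level S1 energies;
    returns the baseline and the Pearson correlation of the inputs."""
    e_low = np.asarray(e_low, dtype=float)
    e_high = np.asarray(e_high, dtype=float)
    if e_low.size < 2 or e_low.size != e_high.size:
        raise ValueError("linear_fit requires two equal-length series of n >= 2")
    if np.ptp(e_low) == 0:
        raise ValueError("low-level energies are constant; slope undefined")
    res = stats.linregress(e_low, e_high)
    return LinearBaseline(float(res.slope), float(res.intercept)), float(res.rvalue)


def linear_predict(baseline: LinearBaseline, e_low):
    e_low = np.asarray(e_low, dtype=float)
    out = baseline.m * e_low + baseline.c
    return float(out) if out.ndim == 0 else out


class LinearBaselineModel:
    """Least-squares calibration of low-level onto high-level energies."""

    def __init__(self, e_low, e_high):
        self.e_low = np.asarray(e_low, dtype=float)
        self.e_high = np.asarray(e_high, dtype=float)

    @classmethod
    def from_dataframe(cls, frame, low_col: str = "e_s1_low", high_col: str = "e_s1_high"):
        sub = frame[[low_col, high_col]].dropna()
        return cls(sub[low_col].to_numpy(), sub[high_col].to_numpy())

    def fit(self) -> "LinearBaselineResults":
        baseline, r = linear_fit(self.e_low, self.e_high)
        res = stats.linregress(self.e_low, self.e_high)
        return LinearBaselineResults(
            model=self,
            baseline=baseline,
            rvalue=r,
            stderr=float(res.stderr),
            intercept_stderr=float(res.intercept_stderr),
        )


@dataclass
class LinearBaselineResults:
    model: LinearBaselineModel
    baseline: LinearBaseline
    rvalue: float
    stderr: float
    intercept_stderr: float

    @property
    def params(self) -> dict[str, float]:
        return {"m": self.baseline.m, "c": self.baseline.c}

    def predict(self, e_low):
        return linear_predict(self.baseline, e_low)

    def summary(self) -> str:
        lines = [
            "Linear(E_ZINDO) baseline",
            "=" * 40,
            f"n observations     {self.model.e_low.size}",
            f"slope m            {self.baseline.m:.6f} (se {self.stderr:.6f})",
            f"intercept c (eV)   {self.baseline.c:.6f} (se {self.intercept_stderr:.6f})",
            f"Pearson r          {self.rvalue:.6f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenseBlockSpec:
    layer_sizes: tuple[int, ...] = (512, 256, 32)
    dropout: float = 0.20
    batch_norm: bool = True
    activation: str = "softplus"

    def __post_init__(self):
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class EncoderSpec:
    node_channels: int = 41
    edge_channels: int = 10
    hidden_dim: int = 200
    fingerprint_dim: int = 256
    atom_steps: int = 2
    mol_steps: int = 2


@dataclass(frozen=True)
class VariantSpec:
    """Which components and descriptors compose a named model variant."""

    use_encoder: bool = False
    ea: bool = False
    use_e_zindo: bool = False
    use_mordf: bool = False
    use_mfp: bool = False
    linear: bool = False
    dense: DenseBlockSpec | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (self.use_encoder or self.use_e_zindo or self.use_mordf
                or self.use_mfp or self.linear):
            raise ValueError("variant enables no input source")
        if self.ea and not self.use_encoder:
            raise ValueError("EA features require the graph encoder")

    @property
    def name(self) -> str:
        if self.linear:
            return "Linear(E_ZINDO)"
        mpnn = "MPNN(DA, EA)" if self.ea else "MPNN(DA)"
        if self.use_encoder and not (self.use_e_zindo or self.use_mordf or self.use_mfp):
            return mpnn
        parts = []
        if self.use_encoder:
            parts.append(mpnn)
        if self.use_e_zindo:
            parts.append("E_ZINDO")
        if self.use_mordf:
            parts.append("MO-RDF")
        if self.use_mfp:
            parts.append("MFP")
        return f"Dense({', '.join(parts)})"

    @property
    def node_channels(self) -> int:
        return 45 if self.ea else 41

    @property
    def featurization_mode(self) -> str:
        return "DA+EA" if self.ea else "DA"


def _split_top(args: str) -> list[str]:
    out, depth, cur = [], 0, []
    for ch in args:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            out.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur).strip())
    return out


def parse_variant(name: str, dense: DenseBlockSpec | None = None) -> VariantSpec:
    """Parse a canonical variant name; round-trips through ``.name``."""
    s = name.strip()
    m = re.fullmatch(r"(Linear|MPNN|Dense)\s*\((.*)\)", s, flags=re.DOTALL)
    if m is None:
        raise ValueError(f"cannot parse variant name {name!r}")
    comp, args = m.group(1), m.group(2).strip()
    if comp == "Linear":
        if args != "E_ZINDO":
            raise ValueError(f"unknown linear variant {name!r}")
        return VariantSpec(linear=True)
    if comp == "MPNN":
        toks = [t.strip() for t in args.split(",")]
        if toks == ["DA"]:
            return VariantSpec(use_encoder=True)
        if toks == ["DA", "EA"]:
            return VariantSpec(use_encoder=True, ea=True)
        raise ValueError(f"unknown MPNN descriptor set {args!r}")
    use_encoder = ea = use_e_zindo = use_mordf = use_mfp = False
    for tok in _split_top(args):
        if tok.startswith("MPNN"):
            inner = parse_variant(tok)
            use_encoder, ea = True, inner.ea
        elif tok == "E_ZINDO":
            use_e_zindo = True
        elif tok in ("MO-RDF", "MORDF"):
            use_mordf = True
        elif tok == "MFP":
            use_mfp = True
        else:
            raise ValueError(f"unknown descriptor token {tok!r} in {name!r}")
    return VariantSpec(
        use_encoder=use_encoder, ea=ea, use_e_zindo=use_e_zindo,
        use_mordf=use_mordf, use_mfp=use_mfp,
        dense=dense or DenseBlockSpec(),
    )


# ---------------------------------------------------------------------------
# batched molecular graphs
# ---------------------------------------------------------------------------


@dataclass
class GraphBatch:
    """Block-diagonal batch of molecular graphs plus molecule-level inputs.

    ``node_mol`` maps each atom row to its molecule index; edges are
    directed (both orientations of every bond present).
    """

    node_x: np.ndarray          # (n_atoms, node_channels)
    edge_src: np.ndarray        # (n_edges,)
    edge_dst: np.ndarray        # (n_edges,)
    edge_attr: np.ndarray       # (n_edges, edge_channels)
    node_mol: np.ndarray        # (n_atoms,)
    n_mols: int
    e_low: np.ndarray | None = None      # (B,) raw eV
    e_low_z: np.ndarray | None = None    # (B, 1) standardized copy
    mordf: np.ndarray | None = None      # (B, 726) standardized
    mfp: np.ndarray | None = None        # (B, 2048)


# ---------------------------------------------------------------------------
# graph-attention message-passing encoder
# ---------------------------------------------------------------------------


class _AtomStep(nn.Module):
    def __init__(self, hidden: int, edge: int, rng):
        self.align = nn.Linear(2 * hidden + edge, 1, rng)
        self.msg = nn.Linear(hidden, hidden, rng)
        self.gru = nn.GRUCell(hidden, hidden, rng)

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        if len(batch.edge_src) == 0:
            # no bonds: state update with a zero context
            ctx = Tensor(np.zeros(h.shape))
            return self.gru(ctx, h)
        h_src = h[batch.edge_src]
        h_dst = h[batch.edge_dst]
        pair = concatenate([h_dst, h_src, Tensor(batch.edge_attr)], axis=1)
        logits = self.align(pair).leaky_relu()
        att = segment_softmax(logits, batch.edge_dst, h.shape[0])
        msgs = self.msg(h_src).elu()
        ctx = segment_sum(att * msgs, batch.edge_dst, h.shape[0])
        return self.gru(ctx, h)


class _MolStep(nn.Module):
    def __init__(self, hidden: int, rng):
        self.align = nn.Linear(2 * hidden, 1, rng)
        self.msg = nn.Linear(hidden, hidden, rng)
        self.gru = nn.GRUCell(hidden, hidden, rng)

    def __call__(self, m: Tensor, h: Tensor, batch: GraphBatch) -> Tensor:
        pair = concatenate([m[batch.node_mol], h], axis=1)
        logits = self.align(pair).leaky_relu()
        att = segment_softmax(logits, batch.node_mol, batch.n_mols)
        msgs = self.msg(h).elu()
        ctx = segment_sum(att * msgs, batch.node_mol, batch.n_mols)
        return self.gru(ctx, m)


class AttentiveEncoder(nn.Module):
    """Attention-weighted message passing producing a fixed-length molecular
    embedding (a "neural fingerprint").

    ``atom_steps`` rounds of neighbour attention with GRU state updates
    propagate local environments; ``mol_steps`` rounds of attention from a
    virtual super-node aggregate the atom states into a molecule state,
    which a final linear layer maps to ``fingerprint_dim``.  All
    aggregations are segment sums/softmaxes, so the embedding is invariant
    to atom ordering.
    """

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.embed = nn.Linear(spec.node_channels, spec.hidden_dim, rng)
        self.atom_layers = [
            _AtomStep(spec.hidden_dim, spec.edge_channels, rng) for _ in range(spec.atom_steps)
        ]
        self.mol_layers = [_MolStep(spec.hidden_dim, rng) for _ in range(spec.mol_steps)]
        self.readout = nn.Linear(spec.hidden_dim, spec.fingerprint_dim, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        if batch.node_x.shape[1] != self.spec.node_channels:
            raise ValueError(
                f"encoder expects {self.spec.node_channels} node channels, "
                f"got {batch.node_x.shape[1]}"
            )
        h = self.embed(Tensor(batch.node_x)).leaky_relu()
        for layer in self.atom_layers:
            h = layer(h, batch)
        m = segment_sum(h, batch.node_mol, batch.n_mols)
        for layer in self.mol_layers:
            m = layer(m, h, batch)
        return self.readout(m)


# ---------------------------------------------------------------------------
# assembled variant
# ---------------------------------------------------------------------------


def residual_predict(ml_out, e_low):
    """Delta-learning residual connection: e_pred = ml_out + e_low."""
    if isinstance(ml_out, Tensor) or isinstance(e_low, Tensor):
        a = ml_out if isinstance(ml_out, Tensor) else Tensor(ml_out)
        b = e_low if isinstance(e_low, Tensor) else Tensor(e_low)
        return a + b
    ml_out = np.asarray(ml_out, dtype=float)
    e_low = np.asarray(e_low, dtype=float)
    if not (np.all(np.isfinite(ml_out)) and np.all(np.isfinite(e_low))):
        raise ValueError("residual_predict requires finite inputs")
    out = ml_out + e_low
    return float(out) if out.ndim == 0 else out


class DeltaNet(nn.Module):
    """A neural variant assembled from a :class:`VariantSpec`.

    Enabled inputs (neural fingerprint | standardized E_ZINDO | MO-RDF |
    Morgan bits) are concatenated into the final dense block with a scalar
    head; when E_ZINDO is enabled its raw value is added back via the
    residual connection.
    """

    def __init__(
        self,
        spec: VariantSpec,
        rng: np.random.Generator,
        encoder_spec: EncoderSpec | None = None,
    ):
        if spec.linear:
            raise ValueError("Linear(E_ZINDO) is a closed-form baseline, not a network")
        self.spec = spec
        if encoder_spec is None:
            encoder_spec = EncoderSpec(node_channels=spec.node_channels)
        if spec.use_encoder and encoder_spec.node_channels != spec.node_channels:
            raise ValueError(
                f"encoder node_channels {encoder_spec.node_channels} does not match "
                f"variant mode {spec.featurization_mode} ({spec.node_channels})"
            )
        self.encoder_spec = encoder_spec
        self.encoder = AttentiveEncoder(encoder_spec, rng) if spec.use_encoder else None
        width = self.concat_width
        standalone = spec.use_encoder and not (spec.use_e_zindo or spec.use_mordf or spec.use_mfp)
        if standalone:
            self.dense = None
            self.head = nn.Linear(encoder_spec.fingerprint_dim, 1, rng)
        else:
            dspec = spec.dense or DenseBlockSpec()
            self.dense = nn.DenseBlock(
                width, rng,
                layer_sizes=dspec.layer_sizes, dropout=dspec.dropout,
                batch_norm=dspec.batch_norm, activation=dspec.activation,
            )
            self.head = nn.Linear(dspec.layer_sizes[-1], 1, rng)

    @property
    def concat_width(self) -> int:
        width = 0
        if self.spec.use_encoder:
            width += self.encoder_spec.fingerprint_dim
        if self.spec.use_e_zindo:
            width += 1
        if self.spec.use_mordf:
            width += MORDF_DIM
        if self.spec.use_mfp:
            width += MFP_DIM
        return width

    def forward(self, batch: GraphBatch, rng: np.random.Generator | None = None) -> Tensor:
        parts: list[Tensor] = []
        if self.encoder is not None:
            parts.append(self.encoder(batch))
        if self.spec.use_e_zindo:
            if batch.e_low_z is None:
                raise ValueError("variant uses E_ZINDO but batch has no standardized energies")
            parts.append(Tensor(batch.e_low_z))
        if self.spec.use_mordf:
            if batch.mordf is None:
                raise ValueError("variant uses MO-RDF but batch carries none")
            parts.append(Tensor(batch.mordf))
        if self.spec.use_mfp:
            if batch.mfp is None:
                raise ValueError("variant uses MFP but batch carries none")
            parts.append(Tensor(batch.mfp))
        x = parts[0] if len(parts) == 1 else concatenate(parts, axis=1)
        if self.dense is not None:
            x = self.dense(x, rng)
        out = self.head(x).reshape(-1)
        if self.spec.use_e_zindo:
            if batch.e_low is None:
                raise ValueError("residual connection requires raw e_low in the batch")
            out = residual_predict(out, Tensor(batch.e_low))
        return out

    __call__ = forward

    def zero_head(self) -> None:
        """Zero the scalar head so the net predicts a zero correction."""
        self.head.weight.data[:] = 0.0
        self.head.bias.data[:] = 0.0

    # -- checkpointing ---------------------------------------------------------
    def save(self, path: str, scalers: dict | None = None) -> None:
        doc = {
            "variant": self.spec.name,
            "encoder_spec": asdict(self.encoder_spec),
            "dense_spec": asdict(self.spec.dense) if self.spec.dense else None,
            "scalers": scalers or {},
            "weights": [w.tolist() for w in self.state_arrays()],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str, expected_variant: str | None = None):
        with open(path) as fh:
            doc = json.load(fh)
        if expected_variant is not None and doc["variant"] != expected_variant:
            raise ValueError(
                f"checkpoint holds variant {doc['variant']!r}, expected {expected_variant!r}"
            )
        dense = DenseBlockSpec(**{**doc["dense_spec"],
                                  "layer_sizes": tuple(doc["dense_spec"]["layer_sizes"])}) \
            if doc["dense_spec"] else None
        spec = parse_variant(doc["variant"], dense=dense)
        model = cls(spec, np.random.default_rng(0), EncoderSpec(**doc["encoder_spec"]))
        model.load_state_arrays([np.asarray(w) for w in doc["weights"]])
        return model, doc.get("scalers", {})


def assemble_variant(
    spec: VariantSpec | str,
    rng: np.random.Generator | int | None = None,
    encoder_spec: EncoderSpec | None = None,
    dense_spec: DenseBlockSpec | None = None,
):
    """Build a model from a :class:`VariantSpec` or a canonical name.

    ``Linear(E_ZINDO)`` returns a :class:`LinearBaselineModel` factory
    marker (the baseline is fitted closed-form); every other name returns a
    :class:`DeltaNet`.
    """
    if isinstance(spec, str):
        spec = parse_variant(spec, dense=dense_spec)
    if spec.linear:
        return spec
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if dense_spec is not None and spec.dense != dense_spec:
        spec = VariantSpec(
            use_encoder=spec.use_encoder, ea=spec.ea, use_e_zindo=spec.use_e_zindo,
            use_mordf=spec.use_mordf, use_mfp=spec.use_mfp, dense=dense_spec,
        )
    return DeltaNet(spec, rng, encoder_spec)
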