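"""Neural-network building blocks: linear layers, batch normalisation,
dropout, GRU cells, dense blocks and the Adam optimiser with an optional
triangular cyclical learning-rate schedule.

All layers operate on :class:`zindelta.autodiff.Tensor` and expose
``parameters()`` for the optimiser.  Weight initialisation draws from a
caller-supplied :class:`numpy.random.Generator`, so a fixed seed gives a
bitwise-reproducible model.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "BatchNorm1d",
    "Dropout",
    "GRUCell",
    "DenseBlock",
    "Adam",
    "cyclical_lr",
    "ACTIVATIONS",
]

# smooth rectifiers and friends usable inside DenseBlock
ACTIVATIONS = {
    "softplus": lambda t: t.softplus(),
    "elu": lambda t: t.elu(),
    "leaky_relu": lambda t: t.leaky_relu(),
    "tanh": lambda t: t.tanh(),
}


class Module:
    """Tiny container base class: child modules/parameters are discovered
    from instance attributes."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch on load")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"Linear expected width {self.in_dim}, got {x.shape[-1]}")
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred**2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = centred * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a Generator must be supplied in training mode so that
    runs are reproducible."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class GRUCell(Module):
    """Gated recurrent unit used for the node- and molecule-state updates in
    the message-passing encoder."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.w_x = Tensor(_glorot(rng, input_dim, 3 * hidden_dim), requires_grad=True)
        self.w_h = Tensor(_glorot(rng, hidden_dim, 3 * hidden_dim), requires_grad=True)
        self.b_x = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)
        self.b_h = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_dim
        gx = x @ self.w_x + self.b_x
        gh = h @ self.w_h + self.b_h
        r = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
        z = (gx[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gx[:, 2 * H : 3 * H] + r * gh[:, 2 * H : 3 * H]).tanh()
        return (1.0 - z) * n + z * h


class DenseBlock(Module):
    """Stack of affine -> batch-norm -> activation -> dropout layers.

    Default geometry is three layers of 512, 256 and 32 units with 20%
    dropout, batch normalisation on and a softplus activation.
    """

    def __init__(
        self,
        in_dim: int,
        rng: np.random.Generator,
        layer_sizes: tuple[int, ...] = (512, 256, 32),
        dropout: float = 0.20,
        batch_norm: bool = True,
        activation: str = "softplus",
    ):
        if any(s <= 0 for s in layer_sizes):
            raise ValueError("layer sizes must be positive")
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.in_dim = in_dim
        self.out_dim = layer_sizes[-1]
        self.layer_sizes = tuple(layer_sizes)
        self.activation = activation
        self.linears: list[Linear] = []
        self.norms: list[BatchNorm1d | None] = []
        prev = in_dim
        for size in layer_sizes:
            self.linears.append(Linear(prev, size, rng))
            self.norms.append(BatchNorm1d(size) if batch_norm else None)
            prev = size
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        act = ACTIVATIONS[self.activation]
        for lin, norm in zip(self.linears, self.norms):
            x = lin(x)
            if norm is not None:
                x = norm(x)
            x = act(x)
            x = self.drop(x, rng)
        return x


class Adam:
    """Adaptive-moment gradient descent (Kingma & Ba)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def cyclical_lr(epoch: int, base_lr: float, period: int = 20) -> float:
    """Triangular schedule bouncing between ``base_lr/10`` and ``base_lr``."""
    lo, hi = base_lr / 10.0, base_lr
    half = period / 2.0
    phase = epoch % period
    frac = phase / half if phase < half else (period - phase) / half
    return lo + (hi - lo) * frac
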