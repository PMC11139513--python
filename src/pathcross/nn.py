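"""Neural-network building blocks on top of :mod:`pathcross.autodiff`.

Contains the generic layers (dense, layer norm, dropout), the mask-constrained
sparse linear layer used for the gene-to-pathway projection, a weighted
cross-entropy loss, and an Adam optimizer.  Randomness (initialization,
dropout) is always drawn from an explicit ``numpy.random.Generator`` so that
training is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Linear", "SparseLinear", "LayerNorm", "Dropout",
    "cross_entropy", "Adam",
]


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        params = list(self._params.values())
        for m in self._modules.values():
            params.extend(m.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class SparseLinear(Module):
    """Linear map whose weight support is fixed by a binary mask.

    Used as the pathway-projection layer: ``mask`` is the (n_in, n_out)
    gene-by-pathway membership matrix, and weights outside the support are
    exactly zero at initialization and are re-projected to zero after every
    optimizer step (see :meth:`Adam.step`).
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator,
                 per_output_bias_dim: int | None = None):
        super().__init__()
        mask = np.asarray(mask, dtype=np.float64)
        if mask.ndim != 2 or not np.isin(mask, (0.0, 1.0)).all():
            raise ValueError("mask must be a binary 2-D array")
        self.mask = mask
        # scaled uniform init on the support only: positive weights near the
        # member-mean pooling operator (1/|pathway| each), with uniform
        # jitter to break symmetry.  A sign-symmetric init would start the
        # projection at a point where member contributions cancel.
        fan_in = np.maximum(mask.sum(axis=0), 1.0)
        w = rng.uniform(0.5, 1.5, size=mask.shape) / fan_in[None, :]
        self.weight = Tensor(w * mask, requires_grad=True)
        if per_output_bias_dim is None:
            self.bias = Tensor(np.zeros(mask.shape[1]), requires_grad=True)
        else:
            self.bias = Tensor(np.zeros((mask.shape[1], per_output_bias_dim)),
                               requires_grad=True)
        self._scalar_bias = per_output_bias_dim is None

    def __call__(self, x: Tensor) -> Tensor:
        """x: (..., n_in, d) -> (..., n_out, d), computed as W^T x + B."""
        w = self.weight * self.mask  # masking inside the graph: exact gradient zeros
        out = w.T @ x
        if self._scalar_bias:
            return out + self.bias.reshape(-1, 1)
        return out + self.bias

    def project_(self) -> None:
        """Force masked weights to exactly zero (called after optimizer steps)."""
        self.weight.data *= self.mask


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        norm = (x - mu) / ((var + self.eps) ** 0.5)
        return norm * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted multinomial cross-entropy.

    logits: (n, k); labels: int array (n,).  Per-sample losses are weighted by
    ``class_weights[label]`` and normalized by the total weight, matching the
    usual class-balanced formulation.
    """
    labels = np.asarray(labels)
    n, k = logits.shape
    logp = logits - logits.logsumexp(axis=-1, keepdims=True)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    nll = -(logp * onehot).sum(axis=-1)
    return (nll * w).sum() * (1.0 / w.sum())


class Adam:
    """Adam with an optional post-step sparsity projection.

    ``sparse_modules`` are :class:`SparseLinear` layers whose masked entries
    are forced back to exact zero after each update; since their gradients are
    identically zero outside the mask this is a no-op in exact arithmetic and
    a safeguard against accumulated floating-point drift.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 sparse_modules: list[SparseLinear] | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.sparse_modules = list(sparse_modules or [])

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled
        for mod in self.sparse_modules:
            mod.project_()

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
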