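"""The end-to-end classifier: sparse pathway projection, criss-cross
encoder, pooling, and the fully connected classification head.

Model modes mirror the ablation family:

- ``pathformer``  — full model: projection + biased criss-cross encoder;
- ``cc_attention``— criss-cross encoder without the crosstalk bias;
- ``transformer`` — col-attention only, no bias, no row-attention;
- ``psnn``        — pathway embedding straight into the classifier;
- ``nn``          — gene embedding straight into the classifier.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad
from .embedding import SparseProjection
from .nn import Dropout, Linear, Module
from .pathways import GenePathwayMask
from .transformer import AttentionConfig, CCEncoder

__all__ = ["ClassifierHead", "PathwayClassifier", "pool_embedding",
           "MODEL_MODES"]

MODEL_MODES = ("pathformer", "cc_attention", "transformer", "psnn", "nn")
POOLING_MODES = ("mean_over_dims", "flatten", "max_over_dims")


def pool_embedding(ep, mode: str = "mean_over_dims"):
    """Pool an (..., Np, Dp) embedding into the classifier input vector.

    mean_over_dims (default) and max_over_dims reduce the embedding axis,
    yielding one scalar per pathway; flatten concatenates everything.
    Accepts a Tensor (differentiable) or ndarray.
    """
    is_tensor = isinstance(ep, Tensor)
    if mode == "mean_over_dims":
        return ep.mean(axis=-1)
    if mode == "max_over_dims":
        return ep.max(axis=-1)
    if mode == "flatten":
        shape = ep.shape[:-2] + (ep.shape[-2] * ep.shape[-1],)
        return ep.reshape(shape) if is_tensor else ep.reshape(shape)
    raise ValueError(f"unknown pooling mode {mode!r}")


class ClassifierHead(Module):
    """Three ReLU layers of 300, 200 and 100 neurons, then class logits."""

    WIDTHS = (300, 200, 100)

    def __init__(self, n_in: int, n_classes: int, dropout_c: float,
                 rng: np.random.Generator):
        super().__init__()
        widths = (n_in,) + self.WIDTHS
        for i in range(3):
            setattr(self, f"fc{i}", Linear(widths[i], widths[i + 1], rng))
            setattr(self, f"drop{i}", Dropout(dropout_c, rng))
        self.out = Linear(self.WIDTHS[-1], n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(3):
            x = getattr(self, f"drop{i}")(getattr(self, f"fc{i}")(x).relu())
        return self.out(x)


class PathwayClassifier(Module):
    """Full multi-omics pathway classifier.

    Parameters
    ----------
    mask : gene-by-pathway membership mask fixing the sparse projection.
    p0 : initial crosstalk matrix (Np, Np); required for mode 'pathformer'.
    dg : gene-embedding width Dg (number of indicator columns).
    n_classes : number of class labels.
    cfg : encoder architecture; ignored for modes 'psnn' and 'nn'.
    mode : one of MODEL_MODES.
    pooling : classifier input pooling, see :func:`pool_embedding`.
    dropout_c : classifier dropout probability.
    seed : initialization/dropout seed; a fixed seed makes training runs
        bit-reproducible.
    """

    def __init__(self, mask: GenePathwayMask, p0: np.ndarray | None, dg: int,
                 n_classes: int, cfg: AttentionConfig | None = None,
                 mode: str = "pathformer", pooling: str = "mean_over_dims",
                 dropout_c: float = 0.3, seed: int = 0,
                 bias_per_dim: bool = True):
        super().__init__()
        if mode not in MODEL_MODES:
            raise ValueError(f"unknown model mode {mode!r}")
        if pooling not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {pooling!r}")
        self.mode = mode
        self.pooling = pooling
        self.mask = mask
        self.dg = dg
        self.n_classes = n_classes
        self.cfg = cfg if cfg is not None else AttentionConfig()
        self.p0 = None if p0 is None else np.asarray(p0, dtype=float)
        rng = np.random.default_rng(seed)
        n_pathways = mask.matrix.shape[1]
        n_genes = mask.matrix.shape[0]

        if mode != "nn":
            self.projection = SparseProjection(mask, dg, rng,
                                               bias_per_dim=bias_per_dim)
            self._register_projection()
        if mode in ("pathformer", "cc_attention", "transformer"):
            if mode == "pathformer" and self.p0 is None:
                raise ValueError("mode 'pathformer' requires an initial "
                                 "crosstalk network p0")
            self.encoder = CCEncoder(
                n_pathways, dg, self.cfg, rng,
                use_bias=(mode == "pathformer"),
                use_row_attention=(mode != "transformer"))

        n_units = n_genes if mode == "nn" else n_pathways
        head_in = n_units * dg if pooling == "flatten" else n_units
        self.head = ClassifierHead(head_in, n_classes, dropout_c, rng)

    def _register_projection(self):
        # SparseProjection is a plain wrapper; register its layer for
        # parameter collection
        self.proj_layer = self.projection.layer

    def sparse_modules(self):
        return [] if self.mode == "nn" else [self.projection.layer]

    # ------------------------------------------------------------- forward
    def forward_full(self, eg: np.ndarray | Tensor) -> dict:
        """Forward pass returning intermediates for interpretation.

        eg: normalized gene embedding, (S, Ng, Dg).  Returns dict with
        'logits' and, depending on mode, 'ep0', 'ep_final', 'p_final',
        'attention_maps', 'pooled'.
        """
        x = eg if isinstance(eg, Tensor) else Tensor(np.asarray(eg, float))
        out: dict = {}
        if self.mode == "nn":
            pooled = pool_embedding(x, self.pooling)
        else:
            ep0 = self.projection(x)
            out["ep0"] = ep0
            if self.mode in ("pathformer", "cc_attention", "transformer"):
                ep_final, p_final, maps = self.encoder(ep0, self.p0)
                out["ep_final"] = ep_final
                out["p_final"] = p_final
                out["attention_maps"] = maps
            else:
                ep_final = ep0
                out["ep_final"] = ep_final
            pooled = pool_embedding(ep_final, self.pooling)
        out["pooled"] = pooled
        out["logits"] = self.head(pooled)
        return out

    def __call__(self, eg) -> Tensor:
        return self.forward_full(eg)["logits"]

    def predict_proba(self, eg: np.ndarray, batch_size: int = 256
                      ) -> np.ndarray:
        """Class probabilities in evaluation mode (dropout off, no graph)."""
        was_training = self.training
        self.eval()
        try:
            probs = []
            with no_grad():
                for start in range(0, eg.shape[0], batch_size):
                    logits = self(eg[start:start + batch_size])
                    probs.append(logits.softmax(axis=-1).data)
            return np.concatenate(probs, axis=0)
        finally:
            self.train(was_training)

    def predict(self, eg: np.ndarray) -> np.ndarray:
        return self.predict_proba(eg).argmax(axis=1)

    def head_proba(self, pooled: np.ndarray) -> np.ndarray:
        """Class probabilities from an already pooled classifier input."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                return self.head(Tensor(np.asarray(pooled, float))) \
                    .softmax(axis=-1).data
        finally:
            self.train(was_training)

    # --------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Save parameters and architecture to an .npz archive."""
        import json
        arch = {"mode": self.mode, "pooling": self.pooling, "dg": self.dg,
                "n_classes": self.n_classes, "cfg": vars(self.cfg)}
        state = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez(path, arch=json.dumps(arch), mask=self.mask.matrix,
                 p0=(self.p0 if self.p0 is not None else np.zeros(0)),
                 genes="\t".join(self.mask.gene_universe),
                 pathway_ids="\t".join(self.mask.pathway_ids), **state)

    @classmethod
    def load(cls, path) -> "PathwayClassifier":
        import json
        with np.load(path, allow_pickle=False) as z:
            arch = json.loads(str(z["arch"]))
            mask = GenePathwayMask(
                matrix=z["mask"],
                gene_universe=str(z["genes"]).split("\t"),
                pathway_ids=str(z["pathway_ids"]).split("\t"))
            p0 = z["p0"] if z["p0"].size else None
            cfg = AttentionConfig(**arch["cfg"])
            model = cls(mask, p0, arch["dg"], arch["n_classes"], cfg,
                        mode=arch["mode"], pooling=arch["pooling"])
            state = {k[len("param/"):]: z[k] for k in z.files
                     if k.startswith("param/")}
            model.load_state_dict(state)
        return model
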