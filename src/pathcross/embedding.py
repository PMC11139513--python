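"""Gene embedding from heterogeneous omics modalities, and the sparse
gene-to-pathway projection.

Each modality arrives as a feature-by-sample matrix at nucleotide, fragment or
gene resolution together with a feature-to-gene mapping.  Sub-gene features
are summarized to one value per gene per statistical indicator (count, min,
max, mean, entropy, weighted means); gene-level modalities pass through as-is.
Concatenating the per-modality summaries yields the compacted per-gene
multi-modal vector; stacking genes gives the gene embedding E_G of shape
(samples, Ng, Dg).  A mask-constrained linear layer then projects gene
embeddings to pathway embeddings E_P = W_sparse^T E_G + B, where the support
of W_sparse is the gene-pathway membership mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import SparseLinear
from .pathways import GenePathwayMask

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityInput", "EmbeddingConfig", "GeneEmbedding", "SparseProjection",
    "INDICATORS", "apply_indicator", "build_modal_features",
    "assemble_gene_embedding", "ZScoreNormalizer", "psnn_forward",
]

#: indicator kinds: statistic summarizing a gene's sub-gene feature values
INDICATORS = ("gene_level_score", "count", "min", "max", "mean", "entropy",
              "weighted_mean_gene", "weighted_mean_window")


@dataclass
class ModalityInput:
    """One omics modality: values plus its feature-to-gene mapping.

    ``values`` is a features-by-samples DataFrame (index = feature ids).
    ``feature_to_gene`` maps feature id -> gene id (identity for gene-level
    modalities; may be omitted in that case).  Optional positive
    ``feature_weights`` and integer ``feature_position`` (coordinate within
    the gene) enable the weighted-mean indicators.
    """

    name: str
    level: str  # 'nucleotide' | 'fragment' | 'gene'
    values: pd.DataFrame
    feature_to_gene: dict[str, str] | None = None
    feature_weights: dict[str, float] | None = None
    feature_position: dict[str, int] | None = None
    #: variance-stabilizing transform applied before summarization;
    #: 'log1p' is the standard choice for counts-like expression data
    transform: str = "none"

    def __post_init__(self):
        if self.level not in ("nucleotide", "fragment", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.transform not in ("none", "log1p", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.feature_to_gene is None:
            if self.level != "gene":
                raise ValueError(f"modality {self.name!r}: sub-gene levels "
                                 "require a feature_to_gene mapping")
            self.feature_to_gene = {f: f for f in self.values.index}
        if self.feature_weights is not None:
            w = np.array(list(self.feature_weights.values()), dtype=float)
            if not (np.isfinite(w).all() and (w > 0).all()):
                raise ValueError(f"modality {self.name!r}: feature weights "
                                 "must be positive and finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EmbeddingConfig:
    """Indicator menu per modality.

    Defaults: gene-level modalities use only the gene-level score; sub-gene
    modalities use count, min, max, mean and entropy.  ``window_size`` is the
    fixed window width (in position units) for the windowed weighted mean.
    """

    indicators: dict[str, list[str]] = field(default_factory=dict)
    window_size: int = 5

    def for_modality(self, mi: ModalityInput) -> list[str]:
        if mi.name in self.indicators:
            kinds = self.indicators[mi.name]
        elif mi.level == "gene":
            kinds = ["gene_level_score"]
        else:
            kinds = ["count", "min", "max", "mean", "entropy"]
        for k in kinds:
            if k not in INDICATORS:
                raise ValueError(f"unknown indicator {k!r}")
        if mi.level == "gene" and kinds != ["gene_level_score"]:
            raise ValueError(f"gene-level modality {mi.name!r} supports only "
                             "the gene_level_score indicator")
        if not kinds:
            raise ValueError(f"no indicators configured for {mi.name!r}")
        return kinds


@dataclass
class GeneEmbedding:
    """Compacted multi-modal gene embedding, (samples, Ng, Dg).

    ``layout`` names the modality and indicator of each of the Dg columns, in
    modality order then indicator order.
    """

    tensor: np.ndarray
    gene_universe: list[str]
    sample_ids: list[str]
    layout: list[tuple[str, str]]

    @property
    def dg(self) -> int:
        return self.tensor.shape[2]

    def modality_dims(self) -> dict[str, list[int]]:
        """Column indices belonging to each modality."""
        dims: dict[str, list[int]] = {}
        for j, (mod, _) in enumerate(self.layout):
            dims.setdefault(mod, []).append(j)
        return dims

    def slice_modality(self, name: str) -> np.ndarray:
        cols = self.modality_dims()[name]
        return self.tensor[:, :, cols]


def apply_indicator(values, kind: str, weights=None, positions=None,
                    window_size: int = 5) -> float:
    """Apply one statistical indicator to a gene's feature values.

    Returns NaN for an empty feature set; the caller substitutes the
    modality's fill value (zero after z-scoring).
    """
    v = np.asarray(values, dtype=float)
    if kind == "count":
        return float(v.size)
    if v.size == 0:
        return float("nan")
    if kind == "gene_level_score":
        if v.size != 1:
            raise ValueError("gene_level_score expects exactly one value")
        return float(v[0])
    if kind == "min":
        return float(v.min())
    if kind == "max":
        return float(v.max())
    if kind == "mean":
        return float(v.mean())
    if kind == "entropy":
        if (v < 0).any():
            raise ValueError("entropy requires non-negative values")
        total = v.sum()
        if total == 0:
            return 0.0
        p = v / total
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())
    if kind == "weighted_mean_gene":
        if weights is None:
            raise ValueError("weighted_mean_gene requires feature weights")
        w = np.asarray(weights, dtype=float)
        if w.sum() == 0:
            raise ValueError("weighted mean undefined for all-zero weights")
        return float((w * v).sum() / w.sum())
    if kind == "weighted_mean_window":
        if positions is None:
            raise ValueError("weighted_mean_window requires feature positions")
        pos = np.asarray(positions, dtype=int)
        w = (np.asarray(weights, dtype=float) if weights is not None
             else np.ones_like(v))
        bins = pos // int(window_size)
        means = [float((w[bins == b] * v[bins == b]).sum() / w[bins == b].sum())
                 for b in np.unique(bins)]
        return float(np.mean(means))
    raise ValueError(f"unknown indicator {kind!r}")


def build_modal_features(mi: ModalityInput, cfg: EmbeddingConfig,
                         universe: list[str]) -> np.ndarray:
    """Summarize one modality to (samples, Ng, e_i) raw indicator values.

    Genes with no mapped features are NaN (filled after normalization).
    Features mapped to genes outside the universe are dropped with a log
    message; if every feature is unmapped this is an error.
    """
    kinds = cfg.for_modality(mi)
    uni_index = {g: i for i, g in enumerate(universe)}
    by_gene: dict[int, list[str]] = {}
    n_unmapped = 0
    for feat in mi.values.index:
        gene = mi.feature_to_gene.get(feat)
        gi = uni_index.get(gene)
        if gi is None:
            n_unmapped += 1
            continue
        by_gene.setdefault(gi, []).append(feat)
    n_feat = len(mi.values.index)
    if n_feat and n_unmapped == n_feat:
        raise ValueError(f"modality {mi.name!r}: no feature maps to a gene "
                         "in the universe")
    if n_unmapped > 0.5 * n_feat:
        logger.warning("modality %r: %d/%d features unmapped",
                       mi.name, n_unmapped, n_feat)
    elif n_unmapped:
        logger.info("modality %r: dropped %d unmapped features",
                    mi.name, n_unmapped)

    n_samples = mi.values.shape[1]
    out = np.full((n_samples, len(universe), len(kinds)), np.nan)

    def _transformed() -> np.ndarray:
        v = mi.values.to_numpy(dtype=float)
        if mi.transform == "log1p":
            return np.log1p(v)
        if mi.transform == "log":
            return np.log(v)
        return v

    fast_gene_level = (mi.level == "gene" and kinds == ["gene_level_score"])
    if fast_gene_level:
        vals = _transformed()
        row_of = {f: r for r, f in enumerate(mi.values.index)}
        for gi, feats in by_gene.items():
            if len(feats) != 1:
                raise ValueError(f"gene-level modality {mi.name!r}: gene "
                                 f"{universe[gi]!r} has {len(feats)} features")
            out[:, gi, 0] = vals[row_of[feats[0]], :]
        return out

    vals = _transformed()
    row_of = {f: r for r, f in enumerate(mi.values.index)}
    for gi, feats in by_gene.items():
        rows = [row_of[f] for f in feats]
        w = (np.array([mi.feature_weights[f] for f in feats])
             if mi.feature_weights is not None else None)
        pos = (np.array([mi.feature_position[f] for f in feats])
               if mi.feature_position is not None else None)
        sub = vals[rows, :]  # (n_feats, n_samples)
        for k, kind in enumerate(kinds):
            for s in range(n_samples):
                out[s, gi, k] = apply_indicator(
                    sub[:, s], kind, weights=w, positions=pos,
                    window_size=cfg.window_size)
    return out


def assemble_gene_embedding(parts: list[np.ndarray],
                            modalities: list[ModalityInput],
                            cfg: EmbeddingConfig,
                            universe: list[str]) -> GeneEmbedding:
    """Concatenate per-modality feature blocks along the indicator axis."""
    if len(parts) != len(modalities):
        raise ValueError("one feature block per modality required")
    shapes = {p.shape[:2] for p in parts}
    if len(shapes) > 1:
        raise ValueError(f"mismatched (samples, genes) shapes: {shapes}")
    layout: list[tuple[str, str]] = []
    for mi in modalities:
        layout.extend((mi.name, k) for k in cfg.for_modality(mi))
    sample_sets = {tuple(mi.sample_ids) for mi in modalities}
    if len(sample_sets) > 1:
        raise ValueError("modalities disagree on sample ids/order")
    tensor = np.concatenate(parts, axis=2)
    if tensor.shape[2] != len(layout):
        raise ValueError("indicator count does not match layout")
    return GeneEmbedding(tensor=tensor, gene_universe=list(universe),
                         sample_ids=modalities[0].sample_ids, layout=layout)


def embed_modalities(modalities: list[ModalityInput], cfg: EmbeddingConfig,
                     universe: list[str]) -> GeneEmbedding:
    """Convenience: build and assemble raw (unnormalized) gene embeddings."""
    parts = [build_modal_features(mi, cfg, universe) for mi in modalities]
    return assemble_gene_embedding(parts, modalities, cfg, universe)


class ZScoreNormalizer:
    """Per-(gene, indicator) z-scoring across samples.

    Fit on training samples only, then applied to any split; NaN entries
    (genes with no features) become 0 — the population mean — after scaling.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, tensor: np.ndarray,
            sample_idx: np.ndarray | None = None) -> "ZScoreNormalizer":
        sub = tensor if sample_idx is None else tensor[sample_idx]
        with np.errstate(invalid="ignore"):
            self.mean_ = np.nanmean(sub, axis=0)
            self.std_ = np.nanstd(sub, axis=0)
        self.mean_ = np.nan_to_num(self.mean_, nan=0.0)
        self.std_ = np.nan_to_num(self.std_, nan=0.0)
        return self

    def transform(self, tensor: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        std = np.where(self.std_ > 0, self.std_, 1.0)
        out = (tensor - self.mean_) / std
        return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)

    def fit_transform(self, tensor: np.ndarray,
                      sample_idx: np.ndarray | None = None) -> np.ndarray:
        return self.fit(tensor, sample_idx).transform(tensor)


class SparseProjection:
    """Gene-to-pathway projection through the membership mask.

    Thin wrapper around :class:`pathcross.nn.SparseLinear` keeping the mask's
    gene/pathway labels; ``bias_per_dim`` selects a per-pathway-per-dimension
    bias (default) or a per-pathway scalar.
    """

    def __init__(self, mask: GenePathwayMask, dg: int,
                 rng: np.random.Generator, bias_per_dim: bool = True):
        self.mask = mask
        self.layer = SparseLinear(mask.matrix, rng,
                                  per_output_bias_dim=dg if bias_per_dim else None)
        self.dg = dg

    def __call__(self, eg: Tensor) -> Tensor:
        return self.layer(eg)


def psnn_forward(eg: GeneEmbedding | np.ndarray | Tensor,
                 proj: SparseProjection) -> Tensor:
    """Project gene embeddings to pathway embeddings, E_P = W^T E_G + B."""
    if isinstance(eg, GeneEmbedding):
        x = Tensor(eg.tensor)
    elif isinstance(eg, Tensor):
        x = eg
    else:
        x = Tensor(np.asarray(eg, dtype=float))
    if x.shape[-2] != proj.mask.matrix.shape[0]:
        raise ValueError(f"gene axis {x.shape[-2]} does not match mask rows "
                         f"{proj.mask.matrix.shape[0]}")
    out = proj(x)
    if not np.isfinite(out.data).all():
        bad = np.argwhere(~np.isfinite(out.data))[0]
        raise FloatingPointError(
            f"non-finite pathway embedding at pathway index {bad[-2]}")
    return out
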