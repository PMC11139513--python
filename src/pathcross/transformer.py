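"""Criss-cross attention encoder with pathway crosstalk bias.

Each of the (default 3) blocks applies, in order:

1. *col-attention* — multi-head self-attention along the pathway axis, with
   the pathway crosstalk matrix P added to the attention logits so that prior
   inter-pathway association steers information flow;
2. a gated multi-head merge with residual, layer norm, GELU feed-forward;
3. *row-attention* — plain multi-head self-attention along the embedding
   (modality/indicator) axis, exchanging information between modalities;
4. a gated merge whose residual is scaled by the constant beta;
5. a network update replacing P with the correlation structure of the updated
   pathway embeddings (or, optionally, the self-product P P^T / Np).

All head weights are stored stacked, shape (H, in, d), so one batched matmul
evaluates every head; the per-head views used by the reference tests are just
slices of these stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Dropout, LayerNorm, Module

__all__ = ["AttentionConfig", "EncoderBlock", "CCEncoder",
           "col_attention", "merge_col", "row_attention", "merge_row",
           "update_network"]


@dataclass
class AttentionConfig:
    """Architecture knobs for the criss-cross encoder.

    head_dim is the per-head attention dimension d; hidden is the width o of
    the position-wise feed-forward; row_residual_coeff is the constant beta
    scaling the row-attention branch before its residual.  logit_scale
    selects division of attention logits by sqrt(d) (default) or by d;
    network_update selects the per-block crosstalk update rule and
    update_denominator its normalizer.
    """

    n_blocks: int = 3
    n_heads: int = 8
    head_dim: int = 8
    hidden: int = 32
    row_residual_coeff: float = 0.3
    dropout_p: float = 0.2
    logit_scale: str = "sqrt_d"          # 'sqrt_d' | 'd'
    #: 'embedding_correlation' (cosine of batch-mean pathway embeddings,
    #: bounded in [-1, 1]) | 'embedding_inner_product' | 'printed_formula'
    network_update: str = "embedding_correlation"
    update_denominator: str = "Dp"       # 'Dp' | 'Np'

    def __post_init__(self):
        if min(self.n_blocks, self.n_heads, self.head_dim, self.hidden) < 1:
            raise ValueError("block/head/dim sizes must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.logit_scale not in ("sqrt_d", "d"):
            raise ValueError(f"unknown logit_scale {self.logit_scale!r}")
        if self.network_update not in ("embedding_correlation",
                                       "embedding_inner_product",
                                       "printed_formula"):
            raise ValueError(f"unknown network_update {self.network_update!r}")
        if self.update_denominator not in ("Dp", "Np"):
            raise ValueError(
                f"unknown update_denominator {self.update_denominator!r}")

    def scale(self) -> float:
        d = float(self.head_dim)
        return np.sqrt(d) if self.logit_scale == "sqrt_d" else d


def _stacked(rng: np.random.Generator, h: int, n_in: int, n_out: int):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(h, n_in, n_out)),
                  requires_grad=True)


def _dense(rng: np.random.Generator, n_in: int, n_out: int):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                  requires_grad=True)


class EncoderBlock(Module):
    """Parameters and sub-layers of one criss-cross block."""

    def __init__(self, n_pathways: int, dp: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        h, d, o = cfg.n_heads, cfg.head_dim, cfg.hidden
        # The output projections of both branches (w_u*, w_o*2) start at
        # zero, so every block is exactly the identity at initialization and
        # attention capacity is introduced only as gradients warrant it —
        # on small cohorts this keeps the deep model from starting worse
        # than its own pathway-projection baseline.
        # pathway-axis (col) attention: inputs are rows of E_P, width Dp
        self.w_q1 = _stacked(rng, h, dp, d)
        self.w_k1 = _stacked(rng, h, dp, d)
        self.w_v1 = _stacked(rng, h, dp, d)
        self.w_g1 = _stacked(rng, h, dp, d)
        self.w_u1 = Tensor(np.zeros((h, d, dp)), requires_grad=True)
        self.w_o11 = _dense(rng, dp, o)
        self.w_o12 = Tensor(np.zeros((o, dp)), requires_grad=True)
        self.ln1 = LayerNorm(dp)
        # embedding-axis (row) attention: inputs are rows of E_P^T, width Np
        self.w_q2 = _stacked(rng, h, n_pathways, d)
        self.w_k2 = _stacked(rng, h, n_pathways, d)
        self.w_v2 = _stacked(rng, h, n_pathways, d)
        self.w_g2 = _stacked(rng, h, n_pathways, d)
        self.w_u2 = Tensor(np.zeros((h, d, n_pathways)), requires_grad=True)
        self.w_o21 = _dense(rng, n_pathways, o)
        self.w_o22 = Tensor(np.zeros((o, n_pathways)), requires_grad=True)
        self.ln2 = LayerNorm(n_pathways)
        self.drop_attn1 = Dropout(cfg.dropout_p, rng)
        self.drop_ff1 = Dropout(cfg.dropout_p, rng)
        self.drop_attn2 = Dropout(cfg.dropout_p, rng)
        self.drop_ff2 = Dropout(cfg.dropout_p, rng)


def _stacked_reshape(x: Tensor) -> Tensor:
    """(S, n, m) -> (S, 1, n, m) so head-stacked weights broadcast."""
    s, n, m = x.shape
    return x.reshape(s, 1, n, m)


def col_attention(ep: Tensor, p_net: Tensor | np.ndarray,
                  block: EncoderBlock, cfg: AttentionConfig
                  ) -> tuple[Tensor, Tensor]:
    """Pathway-axis attention with the crosstalk matrix as logit bias.

    ep: (S, Np, Dp).  Returns (A_col, weights): A_col is (S, H, Np, d) and
    weights the post-softmax attention, (S, H, Np, Np).
    """
    x = _stacked_reshape(ep)
    q = x @ block.w_q1
    k = x @ block.w_k1
    v = x @ block.w_v1
    logits = (q @ k.T) * (1.0 / cfg.scale())
    if p_net is not None:
        bias = (p_net if isinstance(p_net, Tensor)
                else Tensor(np.asarray(p_net, dtype=float)))
        if bias.ndim == 3:  # per-sample networks: broadcast over heads
            s, n_p, _ = bias.shape
            bias = bias.reshape(s, 1, n_p, n_p)
        logits = logits + bias
    if not np.isfinite(logits.data).all():
        raise FloatingPointError("non-finite attention logits (col)")
    weights = logits.softmax(axis=-1)
    a_col = block.drop_attn1(weights) @ v
    return a_col, weights


def merge_col(ep: Tensor, a_col: Tensor, block: EncoderBlock,
              cfg: AttentionConfig) -> Tensor:
    """Gated multi-head merge, residual, and feed-forward for col-attention."""
    x = _stacked_reshape(ep)
    gate = (x @ block.w_g1).sigmoid()
    u1 = ((gate * a_col) @ block.w_u1).sum(axis=1)  # (S, Np, Dp)
    u1p = u1 + ep
    ff = block.drop_ff1((block.ln1(u1p) @ block.w_o11).gelu()) @ block.w_o12
    return ff + u1p


def row_attention(o1: Tensor, block: EncoderBlock, cfg: AttentionConfig
                  ) -> tuple[Tensor, Tensor]:
    """Embedding-axis attention (no bias) on the transposed embedding.

    o1: (S, Np, Dp), transposed internally to (S, Dp, Np).  Returns
    (A_row (S, H, Dp, d), weights (S, H, Dp, Dp)).
    """
    x = _stacked_reshape(o1.swapaxes(-1, -2))
    q = x @ block.w_q2
    k = x @ block.w_k2
    v = x @ block.w_v2
    logits = (q @ k.T) * (1.0 / cfg.scale())
    if not np.isfinite(logits.data).all():
        raise FloatingPointError("non-finite attention logits (row)")
    weights = logits.softmax(axis=-1)
    a_row = block.drop_attn2(weights) @ v
    return a_row, weights


def merge_row(o1: Tensor, a_row: Tensor, block: EncoderBlock,
              cfg: AttentionConfig) -> Tensor:
    """Gated merge with beta-scaled residual; returns (S, Np, Dp)."""
    xt = o1.swapaxes(-1, -2)  # (S, Dp, Np)
    x = _stacked_reshape(xt)
    gate = (x @ block.w_g2).sigmoid()
    u2 = ((gate * a_row) @ block.w_u2).sum(axis=1)  # (S, Dp, Np)
    u2p = u2 * cfg.row_residual_coeff + xt
    ff = block.drop_ff2((block.ln2(u2p) @ block.w_o21).gelu()) @ block.w_o22
    o2 = ff + u2p
    return o2.swapaxes(-1, -2)


def update_network(p_net: Tensor | np.ndarray, o2: Tensor,
                   cfg: AttentionConfig, clip: float = 1e6) -> Tensor:
    """Per-block crosstalk update.

    embedding_correlation (default): cosine similarity between each sample's
    updated pathway embedding vectors — normalized correlation, so entries
    stay in [-1, 1] and the bias remains on the logit scale across blocks.
    Computed per sample (o2 of shape (S, Np, Dp) yields (S, Np, Np)), so the
    result is independent of batch composition; a 2-D o2 is treated as a
    single sample.  embedding_inner_product: raw (E E^T) / denom, denom Dp
    (default) or Np.  printed_formula: P' = P P^T / Np, which does not read
    the embedding at all.  The result is symmetrized and clipped to a finite
    range.
    """
    if cfg.network_update == "printed_formula":
        p = p_net if isinstance(p_net, Tensor) else Tensor(np.asarray(p_net))
        n_p = p.shape[-1]
        out = (p @ p.T) * (1.0 / n_p)
    elif cfg.network_update == "embedding_inner_product":
        denom = float(o2.shape[-1] if cfg.update_denominator == "Dp"
                      else o2.shape[-2])
        out = (o2 @ o2.T) * (1.0 / denom)
    else:
        norm = ((o2 * o2).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        unit = o2 / norm
        out = unit @ unit.T
    out = (out + out.T) * 0.5
    return out.clip(-clip, clip)


class CCEncoder(Module):
    """Stack of criss-cross blocks with per-block network update.

    use_bias=False drops the crosstalk bias and the network update (the
    'CC-attention' ablation); use_row_attention=False additionally reduces
    each block to col-attention + merge (the 'Transformer' ablation takes
    both flags False).
    """

    def __init__(self, n_pathways: int, dp: int, cfg: AttentionConfig,
                 rng: np.random.Generator, use_bias: bool = True,
                 use_row_attention: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_bias = use_bias
        self.use_row_attention = use_row_attention
        self.blocks: list[EncoderBlock] = []
        for b in range(cfg.n_blocks):
            blk = EncoderBlock(n_pathways, dp, cfg, rng)
            setattr(self, f"block{b}", blk)
            self.blocks.append(blk)

    def __call__(self, ep0: Tensor, p0: np.ndarray | None
                 ) -> tuple[Tensor, Tensor | None, list[dict]]:
        """Returns (ep_final, p_final, attention_maps).

        attention_maps is a list of dicts per block with detached numpy
        'col' (S, H, Np, Np) and, when row-attention is on, 'row'
        (S, H, Dp, Dp) post-softmax weights.
        """
        ep = ep0
        if self.use_bias and p0 is None:
            raise ValueError("crosstalk bias enabled but no initial network")
        p_net: Tensor | np.ndarray | None
        p_net = p0 if self.use_bias else None
        maps: list[dict] = []
        for blk in self.blocks:
            a_col, w_col = col_attention(ep, p_net, blk, self.cfg)
            o1 = merge_col(ep, a_col, blk, self.cfg)
            entry = {"col": w_col.data.copy()}
            if self.use_row_attention:
                a_row, w_row = row_attention(o1, blk, self.cfg)
                o2 = merge_row(o1, a_row, blk, self.cfg)
                entry["row"] = w_row.data.copy()
            else:
                o2 = o1
            if self.use_bias:
                p_net = update_network(p_net, o2, self.cfg)
            maps.append(entry)
            ep = o2
        p_final = p_net if isinstance(p_net, Tensor) else None
        return ep, p_final, maps
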