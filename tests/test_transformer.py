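"""Criss-cross attention blocks against an independently written,
loop-based straight-line evaluation, plus structural properties."""

import numpy as np
import pytest

import pathcross as pc
from pathcross.autodiff import Tensor
from pathcross.transformer import (EncoderBlock, col_attention, merge_col,
                                   merge_row, row_attention, update_network)


def softmax_np(x, axis=-1):
    z = np.exp(x - x.max(axis=axis, keepdims=True))
    return z / z.sum(axis=axis, keepdims=True)


def sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-x))


def gelu_np(x):
    from scipy.special import ndtr
    return x * ndtr(x)


def layernorm_np(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def straight_line_block(ep, p_net, blk, cfg, beta):
    """Loop-per-head reference of one block (eval mode, no dropout)."""
    s, n_p, dp = ep.shape
    h = cfg.n_heads
    scale = cfg.scale()
    o1 = np.empty_like(ep)
    for si in range(s):
        x = ep[si]  # (Np, Dp)
        u1 = np.zeros((n_p, dp))
        for hi in range(h):
            q = x @ blk.w_q1.data[hi]
            k = x @ blk.w_k1.data[hi]
            v = x @ blk.w_v1.data[hi]
            logits = q @ k.T / scale
            if p_net is not None:
                logits = logits + (p_net[si] if p_net.ndim == 3 else p_net)
            a_col = softmax_np(logits) @ v
            gate = sigmoid_np(x @ blk.w_g1.data[hi])
            u1 += (gate * a_col) @ blk.w_u1.data[hi]
        u1p = u1 + x
        ff = gelu_np(layernorm_np(u1p, blk.ln1.gamma.data, blk.ln1.beta.data)
                     @ blk.w_o11.data) @ blk.w_o12.data
        o1[si] = ff + u1p
    o2 = np.empty_like(ep)
    for si in range(s):
        xt = o1[si].T  # (Dp, Np)
        u2 = np.zeros((dp, n_p))
        for hi in range(h):
            q = xt @ blk.w_q2.data[hi]
            k = xt @ blk.w_k2.data[hi]
            v = xt @ blk.w_v2.data[hi]
            a_row = softmax_np(q @ k.T / scale) @ v
            gate = sigmoid_np(xt @ blk.w_g2.data[hi])
            u2 += (gate * a_row) @ blk.w_u2.data[hi]
        u2p = beta * u2 + xt
        ff = gelu_np(layernorm_np(u2p, blk.ln2.gamma.data, blk.ln2.beta.data)
                     @ blk.w_o21.data) @ blk.w_o22.data
        o2[si] = (ff + u2p).T
    return o1, o2


@pytest.fixture
def setup_block():
    cfg = pc.AttentionConfig(n_blocks=1, n_heads=3, head_dim=5, hidden=6,
                             dropout_p=0.0, row_residual_coeff=0.7)
    rng = np.random.default_rng(0)
    blk = EncoderBlock(n_pathways=4, dp=6, cfg=cfg, rng=rng)
    # the identity-init projections are randomized here so the reference
    # exercises every term of the block
    for w in (blk.w_u1, blk.w_o12, blk.w_u2, blk.w_o22):
        w.data[:] = rng.normal(scale=0.3, size=w.data.shape)
    blk.eval()
    ep = rng.normal(size=(2, 4, 6))
    p_net = rng.normal(size=(4, 4))
    p_net = (p_net + p_net.T) / 2
    np.fill_diagonal(p_net, 0)
    return cfg, blk, ep, p_net


class TestOracleEquivalence:
    def test_full_block_matches_straight_line_reference(self, setup_block):
        cfg, blk, ep, p_net = setup_block
        ep_t = Tensor(ep)
        a_col, _ = col_attention(ep_t, p_net, blk, cfg)
        o1 = merge_col(ep_t, a_col, blk, cfg)
        a_row, _ = row_attention(o1, blk, cfg)
        o2 = merge_row(o1, a_row, blk, cfg)
        ref_o1, ref_o2 = straight_line_block(ep, p_net, blk, cfg,
                                             cfg.row_residual_coeff)
        assert np.abs(o1.data - ref_o1).max() < 1e-5
        assert np.abs(o2.data - ref_o2).max() < 1e-5

    def test_zero_bias_equals_standard_dot_product_attention(self, setup_block):
        cfg, blk, ep, _ = setup_block
        a_col, w = col_attention(Tensor(ep), None, blk, cfg)
        for hi in range(cfg.n_heads):
            q = ep @ blk.w_q1.data[hi]
            k = ep @ blk.w_k1.data[hi]
            v = ep @ blk.w_v1.data[hi]
            expected = softmax_np(q @ np.swapaxes(k, -1, -2) / cfg.scale()) @ v
            assert np.abs(a_col.data[:, hi] - expected).max() < 1e-10

    def test_strong_negative_offdiagonal_bias_gives_identity_attention(
            self, setup_block):
        cfg, blk, ep, _ = setup_block
        bias = np.full((4, 4), -1e9)
        np.fill_diagonal(bias, 0.0)
        a_col, w = col_attention(Tensor(ep), bias, blk, cfg)
        assert np.allclose(w.data, np.eye(4), atol=1e-12)
        for hi in range(cfg.n_heads):
            v = ep @ blk.w_v1.data[hi]
            assert np.allclose(a_col.data[:, hi], v)

    def test_dp_equal_one_row_attention_is_value_passthrough(self):
        cfg = pc.AttentionConfig(n_blocks=1, n_heads=2, head_dim=3, hidden=4,
                                 dropout_p=0.0)
        rng = np.random.default_rng(1)
        blk = EncoderBlock(n_pathways=5, dp=1, cfg=cfg, rng=rng).eval()
        o1 = Tensor(rng.normal(size=(2, 5, 1)))
        a_row, w = row_attention(o1, blk, cfg)
        assert np.allclose(w.data, 1.0)  # 1x1 attention matrices
        xt = np.swapaxes(o1.data, -1, -2)
        for hi in range(2):
            assert np.allclose(a_row.data[:, hi], xt @ blk.w_q2.data[hi] * 0
                               + xt @ blk.w_v2.data[hi])


class TestStructuralProperties:
    def test_attention_rows_sum_to_one(self, setup_block):
        cfg, blk, ep, p_net = setup_block
        _, w_col = col_attention(Tensor(ep), p_net, blk, cfg)
        assert np.allclose(w_col.data.sum(axis=-1), 1.0, atol=1e-6)
        _, w_row = row_attention(Tensor(ep), blk, cfg)
        assert np.allclose(w_row.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_bias_monotonicity(self, setup_block):
        """Raising one crosstalk entry never lowers that attention weight."""
        cfg, blk, ep, p_net = setup_block
        _, w0 = col_attention(Tensor(ep), p_net, blk, cfg)
        bumped = p_net.copy()
        bumped[1, 2] += 1.0
        _, w1 = col_attention(Tensor(ep), bumped, blk, cfg)
        assert np.all(w1.data[:, :, 1, 2] >= w0.data[:, :, 1, 2])

    def test_row_attention_permutation_equivariance(self, setup_block):
        cfg, blk, ep, _ = setup_block
        perm = np.array([2, 0, 3, 1])
        _, w = row_attention(Tensor(ep), blk, cfg)
        blk2_w = [blk.w_q2.data[:, perm, :], blk.w_k2.data[:, perm, :]]
        blk.w_q2.data[:] = blk2_w[0]
        blk.w_k2.data[:] = blk2_w[1]
        _, w_p = row_attention(Tensor(ep[:, perm, :]), blk, cfg)
        assert np.abs(w.data - w_p.data).max() < 1e-10

    def test_beta_zero_disables_row_branch(self):
        cfg = pc.AttentionConfig(n_blocks=1, n_heads=2, head_dim=3, hidden=4,
                                 dropout_p=0.0, row_residual_coeff=0.0)
        rng = np.random.default_rng(2)
        blk = EncoderBlock(n_pathways=3, dp=4, cfg=cfg, rng=rng).eval()
        blk.w_o22.data[:] = 0.0
        o1 = Tensor(rng.normal(size=(2, 3, 4)))
        a_row, _ = row_attention(o1, blk, cfg)
        o2 = merge_row(o1, a_row, blk, cfg)
        assert np.allclose(o2.data, o1.data)

    def test_pure_residual_when_projections_zero(self):
        cfg = pc.AttentionConfig(n_blocks=1, n_heads=2, head_dim=3, hidden=4,
                                 dropout_p=0.0)
        rng = np.random.default_rng(3)
        blk = EncoderBlock(n_pathways=3, dp=4, cfg=cfg, rng=rng).eval()
        # w_u1 and w_o12 are zero at init, so merge_col is the identity
        ep = Tensor(rng.normal(size=(2, 3, 4)))
        a_col, _ = col_attention(ep, None, blk, cfg)
        assert np.allclose(merge_col(ep, a_col, blk, cfg).data, ep.data)


class TestNetworkUpdate:
    def test_printed_formula_identity_case(self):
        cfg = pc.AttentionConfig(network_update="printed_formula")
        out = update_network(np.eye(2), Tensor(np.zeros((1, 2, 3))), cfg)
        assert np.allclose(out.data, np.eye(2) / 2)

    def test_correlation_symmetric_any_input(self):
        cfg = pc.AttentionConfig()
        rng = np.random.default_rng(4)
        o2 = Tensor(rng.normal(size=(3, 5, 4)))
        out = update_network(None, o2, cfg).data
        assert np.allclose(out, np.swapaxes(out, -1, -2))

    def test_correlation_orthogonal_embeddings_zero_offdiagonal(self):
        cfg = pc.AttentionConfig()
        o2 = Tensor(np.eye(4)[None, :, :] * 2.5)  # orthogonal pathway rows
        out = update_network(None, o2, cfg).data[0]
        off = out - np.diag(np.diag(out))
        assert np.allclose(off, 0.0)

    def test_inner_product_mode_denominator(self):
        cfg = pc.AttentionConfig(network_update="embedding_inner_product")
        o2 = Tensor(np.ones((1, 2, 4)))
        out = update_network(None, o2, cfg).data[0]
        assert np.allclose(out, 1.0)  # (1*1*4)/Dp=4


class TestEncoder:
    def _encoder(self, **kw):
        cfg = pc.AttentionConfig(n_blocks=kw.pop("n_blocks", 3), n_heads=2,
                                 head_dim=3, hidden=4, dropout_p=0.2)
        rng = np.random.default_rng(5)
        return pc.CCEncoder(4, 5, cfg, rng, **kw), cfg

    def test_single_block_equals_manual_application(self):
        enc, cfg = self._encoder(n_blocks=1)
        enc.eval()
        rng = np.random.default_rng(6)
        ep = Tensor(rng.normal(size=(2, 4, 5)))
        p0 = np.zeros((4, 4))
        out, _, _ = enc(ep, p0)
        blk = enc.blocks[0]
        a_col, _ = col_attention(ep, p0, blk, cfg)
        o1 = merge_col(ep, a_col, blk, cfg)
        a_row, _ = row_attention(o1, blk, cfg)
        o2 = merge_row(o1, a_row, blk, cfg)
        assert np.allclose(out.data, o2.data)

    def test_attention_map_inventory(self):
        enc, cfg = self._encoder()
        enc.eval()
        ep = Tensor(np.random.default_rng(7).normal(size=(2, 4, 5)))
        _, _, maps = enc(ep, np.zeros((4, 4)))
        assert len(maps) == 3
        for m in maps:
            assert m["row"].shape == (2, 2, 5, 5)  # (S, H, Dp, Dp)
            assert m["col"].shape == (2, 2, 4, 4)

    def test_eval_mode_deterministic(self):
        enc, _ = self._encoder()
        enc.eval()
        ep = np.random.default_rng(8).normal(size=(2, 4, 5))
        a, _, _ = enc(Tensor(ep), np.zeros((4, 4)))
        b, _, _ = enc(Tensor(ep), np.zeros((4, 4)))
        assert np.array_equal(a.data, b.data)

    def test_network_stays_symmetric_across_blocks(self, small_embedded):
        data, eg, mask, net = small_embedded
        egn = pc.ZScoreNormalizer().fit_transform(eg.tensor)
        model = pc.PathwayClassifier(mask, net.matrix, eg.dg, 2,
                                     mode="pathformer", seed=0)
        from pathcross.cli import collect_updated_networks
        for n in collect_updated_networks(model, egn[:16]):
            assert np.allclose(n, n.T, atol=1e-10)
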