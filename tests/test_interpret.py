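"""Attention-based modality contributions, Shapley attribution (exact and
sampled), core-modality assignment, pathway scores, and sub-network
discovery."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pathcross as pc
from pathcross.interpret import (core_modality, modality_contributions,
                                 pathway_scores, subnetwork_scores)
from pathcross.shapley import exact_shapley, permutation_shapley


def brute_force_shapley(f, x, baseline):
    """Textbook Shapley by direct 2^d coalition enumeration (oracle)."""
    d = len(x)
    phi = np.zeros(d)
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for r in range(d):
            for subset in itertools.combinations(others, r):
                w = (math.factorial(r) * math.factorial(d - r - 1)
                     / math.factorial(d))
                with_i = baseline.copy()
                without = baseline.copy()
                for j in subset:
                    with_i[j] = x[j]
                    without[j] = x[j]
                with_i[i] = x[i]
                phi[i] += w * (f(with_i[None])[0] - f(without[None])[0])
    return phi


def random_stochastic_maps(rng, n, dp):
    logits = rng.normal(size=(n, dp, dp))
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


class TestModalityContributions:
    def test_single_modality_gets_everything(self):
        rng = np.random.default_rng(0)
        maps = [random_stochastic_maps(rng, 4, 3)]
        layout = [("rna", "a"), ("rna", "b"), ("rna", "c")]
        contrib = modality_contributions(maps, layout)
        assert contrib.weights["rna"] == pytest.approx(1.0)

    def test_identity_maps_weight_by_dimension_count(self):
        maps = [np.broadcast_to(np.eye(4), (5, 4, 4)).copy()]
        layout = [("a", "x"), ("a", "y"), ("a", "z"), ("b", "w")]
        contrib = modality_contributions(maps, layout)
        assert contrib.weights["a"] == pytest.approx(3 / 4)
        assert contrib.weights["b"] == pytest.approx(1 / 4)

    def test_weights_sum_to_one_for_random_maps(self):
        rng = np.random.default_rng(1)
        maps = [random_stochastic_maps(rng, 3, 6) for _ in range(4)]
        layout = [("m1", "a")] * 2 + [("m2", "b")] * 3 + [("m3", "c")]
        contrib = modality_contributions(maps, layout)
        assert sum(contrib.weights.values()) == pytest.approx(1.0, abs=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        maps = random_stochastic_maps(rng, 6, 4)
        layout = [("a", "x")] * 4
        c1 = modality_contributions([maps], layout)
        c2 = modality_contributions([maps[::-1]], layout)
        assert c1.weights["a"] == pytest.approx(c2.weights["a"])

    def test_layout_mismatch_errors(self):
        maps = [np.broadcast_to(np.eye(3), (1, 3, 3))]
        with pytest.raises(ValueError, match="layout"):
            modality_contributions(maps, [("a", "x")])


class TestShapley:
    def _surrogate(self, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=8)
        v = rng.normal(size=8)

        def f(batch):
            return np.tanh(batch @ w) + 0.5 * (batch @ v) ** 2

        return f, rng

    def test_exact_matches_brute_force_enumeration(self):
        f, rng = self._surrogate()
        x = rng.normal(size=8)
        baseline = rng.normal(size=8) * 0.2
        got = exact_shapley(f, x, baseline)
        want = brute_force_shapley(f, x, baseline)
        assert np.abs(got - want).max() < 1e-10

    def test_exact_additivity_axiom(self):
        f, rng = self._surrogate(1)
        x = rng.normal(size=8)
        baseline = np.zeros(8)
        phi = exact_shapley(f, x, baseline)
        assert phi.sum() == pytest.approx(
            f(x[None])[0] - f(baseline[None])[0], abs=1e-10)

    def test_permutation_sampling_additivity_is_exact(self):
        f, rng = self._surrogate(2)
        x = rng.normal(size=8)
        baseline = np.zeros(8)
        phi = permutation_shapley(f, x, baseline, n_permutations=8,
                                  rng=np.random.default_rng(0))
        assert phi.sum() == pytest.approx(
            f(x[None])[0] - f(baseline[None])[0], abs=1e-10)

    def test_permutation_sampling_approximates_exact(self):
        f, rng = self._surrogate(3)
        x = rng.normal(size=8)
        baseline = np.zeros(8)
        want = exact_shapley(f, x, baseline)
        got = permutation_shapley(f, x, baseline, n_permutations=400,
                                  rng=np.random.default_rng(1))
        assert np.abs(got - want).max() < 0.15

    def test_ignored_feature_gets_zero(self):
        def f(batch):
            return batch[:, 0] * 2.0  # feature 1 never read

        phi = exact_shapley(f, np.array([1.0, 5.0]), np.zeros(2))
        assert phi[1] == 0.0
        assert phi[0] == pytest.approx(2.0)

    def test_exact_limit_enforced(self):
        with pytest.raises(ValueError, match="sampling"):
            exact_shapley(lambda b: b.sum(axis=1), np.ones(13), np.zeros(13))


class TestModelLevelShap:
    def test_pathway_attribution_finds_planted_signal(self, small_embedded):
        data, eg, mask, net = small_embedded
        egn = pc.ZScoreNormalizer().fit_transform(eg.tensor)
        cfg = pc.TrainConfig(epochs=15, patience=15, seed=0,
                             model_mode="psnn", val_fraction=0.0)
        model, _ = pc.train_model(egn, data.labels, mask, None, cfg)
        table = pc.shap_importance(model, egn, egn[:20], level="pathway",
                                   top=4, seed=0, n_permutations=20)
        assert set(table.columns) >= {"entity", "shap", "signed_mean", "rank"}
        top = set(table["entity"])
        assert top & set(data.truth.planted_pathways)

    def test_gene_attribution_restricted_to_members(self, small_embedded):
        data, eg, mask, net = small_embedded
        egn = pc.ZScoreNormalizer().fit_transform(eg.tensor)
        cfg = pc.TrainConfig(epochs=8, patience=8, seed=0, model_mode="psnn",
                             val_fraction=0.0)
        model, _ = pc.train_model(egn, data.labels, mask, None, cfg)
        pid = data.truth.planted_pathways[0]
        table = pc.shap_importance(model, egn, egn[:4], level="gene",
                                   pathway_id=pid, top=5, seed=0,
                                   n_permutations=6)
        members = data.collection[pid].genes
        assert set(table["entity"]) <= members
        assert len(table) == 5

    def test_background_size_enforced(self, small_embedded):
        data, eg, mask, net = small_embedded
        egn = pc.ZScoreNormalizer().fit_transform(eg.tensor)
        cfg = pc.TrainConfig(epochs=2, patience=2, seed=0, model_mode="psnn",
                             val_fraction=0.0)
        model, _ = pc.train_model(egn, data.labels, mask, None, cfg)
        with pytest.raises(ValueError, match="background"):
            pc.shap_importance(model, egn[:3], egn[:2], level="pathway")


class TestCoreModality:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["entity", "shap"]).assign(
            kind="modality-of-gene", signed_mean=0.0, rank=0)

    def test_dominating_modality_selected(self):
        t = self._table([("g1|rna", 0.9), ("g1|cnv", 0.1)])
        out = core_modality(t, ["rna", "cnv"])
        assert out.loc[0, "core_modality"] == "rna"

    def test_single_modality_gene(self):
        t = self._table([("g1|meth", 0.2)])
        out = core_modality(t, ["rna", "meth"])
        assert out.loc[0, "core_modality"] == "meth"

    def test_exact_tie_goes_to_configured_order(self):
        t = self._table([("g1|cnv", 0.5), ("g1|rna", 0.5)])
        out = core_modality(t, ["rna", "cnv"])
        assert out.loc[0, "core_modality"] == "rna"


class TestPathwayScores:
    def test_single_dimension_identity(self):
        ep = np.arange(8, dtype=float).reshape(2, 4, 1)
        assert np.allclose(pathway_scores(ep), ep[:, :, 0])

    def test_constant_embedding(self):
        assert np.allclose(pathway_scores(np.full((1, 3, 5), 2.2)), 2.2)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        ep = rng.normal(size=(2, 3, 4))
        assert np.allclose(pathway_scores(3.0 * ep), 3.0 * pathway_scores(ep))


def exhaustive_best_subnetwork(adj, shap_vec, max_size=6):
    """Oracle: enumerate every connected subgraph up to max_size and return
    the best-scoring member set."""
    g = nx.from_numpy_array(adj)
    best, best_score = None, -np.inf
    nodes = list(g.nodes)
    for r in range(1, max_size + 1):
        for cand in itertools.combinations(nodes, r):
            sub = g.subgraph(cand)
            if not nx.is_connected(sub):
                continue
            denom = max(len(cand) - 1, 1)
            score = sum(shap_vec[i] * (1 + sub.degree(i) / denom)
                        for i in cand)
            if score > best_score:
                best, best_score = set(cand), score
    return best, best_score


class TestSubnetworks:
    def test_star_hub_with_all_mass_wins(self):
        n = 6
        adj = np.zeros((n, n))
        for i in range(1, n):
            adj[0, i] = adj[i, 0] = 0.9
        ids = [f"P{i}" for i in range(n)]
        shap = {pid: 0.0 for pid in ids}
        shap["P0"] = 1.0
        out = subnetwork_scores([adj], shap, ids, prune_quantile=0.5)
        assert "P0" in out[0].members

    def test_prune_everything_returns_empty(self):
        adj = np.random.default_rng(0).uniform(size=(4, 4))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        ids = list("abcd")
        out = subnetwork_scores([adj], {i: 1.0 for i in ids}, ids,
                                prune_quantile=1.0)
        assert out == []

    def test_two_cliques_top_subnetwork_matches_exhaustive_oracle(self):
        # two disconnected triangles; SHAP mass split 80/20
        adj = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 0.8
        ids = [f"P{i}" for i in range(6)]
        shap_vec = np.array([0.3, 0.3, 0.2, 0.08, 0.07, 0.05])
        shap = dict(zip(ids, shap_vec))
        out = subnetwork_scores([adj], shap, ids, prune_quantile=0.1)
        want_members, want_score = exhaustive_best_subnetwork(
            (adj > 0.1).astype(float) * adj, shap_vec)
        assert set(out[0].members) == {ids[i] for i in want_members}
        assert out[0].score == pytest.approx(want_score)

    def test_averages_networks_across_blocks(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0  # present in one block only
        ids = list("xyz")
        out = subnetwork_scores([a, b], {"x": 1.0, "y": 0.5, "z": 0.0}, ids,
                                prune_quantile=0.0)
        edges = {frozenset(e[:2]) for r in out for e in r.edges}
        assert frozenset(("x", "y")) in edges
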