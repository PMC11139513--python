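"""Model interpretation: modality contributions from attention maps,
Shapley-based pathway/gene importance, core modality assignment, per-sample
pathway scores, and crosstalk sub-network discovery.

The attribution level matters: pathway importance is computed at the pooled
classifier input (one scalar per pathway), which is cheap because only the
classification head is re-evaluated per coalition; gene importance re-runs
the full model with a gene's embedding replaced by the background mean, and
is restricted to one pathway's member genes at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import PathwayClassifier
from .shapley import EXACT_LIMIT, exact_shapley, permutation_shapley

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityContribution", "SubnetworkResult", "modality_contributions",
    "shap_importance", "core_modality", "pathway_scores",
    "subnetwork_scores",
]


@dataclass
class ModalityContribution:
    """Per-modality attention weight; weights are non-negative and sum to 1."""

    weights: dict[str, float]
    per_dimension: np.ndarray

    def __post_init__(self):
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"contributions sum to {total}, expected 1")


@dataclass
class SubnetworkResult:
    """A connected high-importance region of the averaged crosstalk network."""

    members: list[str]
    score: float
    edges: list[tuple[str, str, float]] = field(default_factory=list)


def _collect_row_maps(attention_maps) -> list[np.ndarray]:
    """Accept encoder map dicts or raw arrays; return list of (.., Dp, Dp)."""
    rows = []
    for m in attention_maps:
        if isinstance(m, dict):
            if "row" in m:
                rows.append(np.asarray(m["row"], float))
        else:
            rows.append(np.asarray(m, float))
    if not rows:
        raise ValueError("no row-attention maps found (row-attention may be "
                         "disabled in this model mode)")
    return rows


def modality_contributions(attention_maps,
                           layout: list[tuple[str, str]]
                           ) -> ModalityContribution:
    """Attention-derived contribution of each modality.

    All row-attention maps (across blocks, heads and samples) are averaged
    element-wise into one Dp x Dp matrix; its column means give per-dimension
    weights (summing to 1 since every row is a softmax), and a modality's
    contribution is the sum over its columns in the embedding ``layout``.
    """
    rows = _collect_row_maps(attention_maps)
    dp = rows[0].shape[-1]
    if len(layout) != dp:
        raise ValueError(f"layout covers {len(layout)} dimensions, "
                         f"attention maps have {dp}")
    flat = [r.reshape(-1, dp, dp) for r in rows]
    avg = np.concatenate(flat, axis=0).mean(axis=0)
    per_dim = avg.mean(axis=0)  # column means of the averaged matrix
    weights: dict[str, float] = {}
    for j, (mod, _) in enumerate(layout):
        weights[mod] = weights.get(mod, 0.0) + float(per_dim[j])
    return ModalityContribution(weights=weights, per_dimension=per_dim)


def _pooled_inputs(model: PathwayClassifier, eg: np.ndarray) -> np.ndarray:
    out = []
    from .autodiff import no_grad
    model.eval()
    with no_grad():
        for start in range(0, eg.shape[0], 256):
            out.append(model.forward_full(eg[start:start + 256])
                       ["pooled"].data)
    return np.concatenate(out, axis=0)


def shap_importance(model: PathwayClassifier, eg_background: np.ndarray,
                    eg_eval: np.ndarray, level: str = "pathway",
                    pathway_id: str | None = None, target_class: int = 1,
                    top: int | None = None, n_permutations: int = 30,
                    seed: int = 0) -> pd.DataFrame:
    """Mean |Shapley| importance table at a chosen attribution level.

    level='pathway': attributes the target-class probability to the pooled
    per-pathway classifier inputs (top 15 by default).
    level='gene': attributes the full-model output to the member genes of
    ``pathway_id``, masking a gene by replacing its embedding row with the
    background mean (top 5 by default).
    level='gene-modality': per-(gene, modality-block) attribution for the
    member genes of ``pathway_id``.

    Returns a DataFrame with entity, kind, shap (mean |value|), signed_mean
    (direction: positive means the feature pushes toward the target class),
    and rank.
    """
    if eg_background.shape[0] < 10:
        raise ValueError("need >= 10 background samples")
    rng = np.random.default_rng(seed)
    mean_gene_embedding = eg_background.mean(axis=0)  # (Ng, Dg)

    if level == "pathway":
        pooled_bg = _pooled_inputs(model, eg_background)
        pooled_ev = _pooled_inputs(model, eg_eval)
        baseline = pooled_bg.mean(axis=0)
        entities = list(model.mask.pathway_ids)
        if model.pooling == "flatten":
            raise ValueError("pathway-level attribution requires per-pathway "
                             "pooling (mean_over_dims or max_over_dims)")

        def f(batch):
            return model.head_proba(batch)[:, target_class]

        rows_x = pooled_ev
        default_top = 15
    elif level in ("gene", "gene-modality"):
        if pathway_id is None:
            raise ValueError(f"level={level!r} requires a pathway_id")
        col = model.mask.pathway_ids.index(pathway_id)
        member_idx = np.nonzero(model.mask.matrix[:, col])[0]
        genes = [model.mask.gene_universe[g] for g in member_idx]
        all_cols = np.arange(eg_eval.shape[2])
        if level == "gene":
            entities = genes
            blocks = [(int(g), all_cols) for g in member_idx]
        else:
            layout = getattr(model, "embedding_layout", None)
            if layout is None:
                raise ValueError("gene-modality attribution requires "
                                 "model.embedding_layout (modality of each "
                                 "embedding column)")
            mod_cols: dict[str, list[int]] = {}
            for j, (mod, _) in enumerate(layout):
                mod_cols.setdefault(mod, []).append(j)
            entities, blocks = [], []
            for g, gene in zip(member_idx, genes):
                for mod, cols in mod_cols.items():
                    entities.append(f"{gene}|{mod}")
                    blocks.append((int(g), np.array(cols)))

        current_sample = [None]  # set per eval sample in the loop below

        def f(batch):
            # batch: (n, n_entities) coalition membership vectors
            n = batch.shape[0]
            eg_batch = np.repeat(current_sample[0][None], n, axis=0)
            for e, (g, cols) in enumerate(blocks):
                off = np.nonzero(batch[:, e] == 0)[0]
                if off.size:
                    eg_batch[off[:, None], g, cols[None, :]] = \
                        mean_gene_embedding[g, cols]
            return model.predict_proba(eg_batch)[:, target_class]

        rows_x = np.ones((eg_eval.shape[0], len(entities)))
        default_top = 5
    else:
        raise ValueError(f"unknown attribution level {level!r}")

    n_entities = len(entities)
    shap_sum = np.zeros(n_entities)
    signed_sum = np.zeros(n_entities)
    for s in range(rows_x.shape[0]):
        if level == "pathway":
            x, baseline_s = rows_x[s], baseline
        else:
            current_sample[0] = eg_eval[s]
            x, baseline_s = rows_x[s], np.zeros(n_entities)
        if n_entities <= EXACT_LIMIT:
            phi = exact_shapley(f, x, baseline_s)
        else:
            phi = permutation_shapley(f, x, baseline_s,
                                      n_permutations=n_permutations, rng=rng)
        shap_sum += np.abs(phi)
        signed_sum += phi
    n_eval = rows_x.shape[0]
    kind = {"pathway": "pathway", "gene": "gene",
            "gene-modality": "modality-of-gene"}[level]
    df = pd.DataFrame({"entity": entities, "kind": kind,
                       "shap": shap_sum / n_eval,
                       "signed_mean": signed_sum / n_eval})
    df = df.sort_values("shap", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    top = default_top if top is None else top
    return df.head(top).reset_index(drop=True)


def core_modality(gene_modality_table: pd.DataFrame,
                  modality_order: list[str]) -> pd.DataFrame:
    """Assign each gene the modality with its best (smallest) SHAP rank.

    Expects a gene-modality importance table whose entities are
    ``gene|modality``; exact ties go to the first modality in
    ``modality_order`` (logged).
    """
    parts = gene_modality_table["entity"].str.rsplit("|", n=1, expand=True)
    df = gene_modality_table.assign(gene=parts[0], modality=parts[1])
    rows = []
    order = {m: i for i, m in enumerate(modality_order)}
    for gene, sub in df.groupby("gene", sort=False):
        best = sub["shap"].max()
        tied = sub[np.isclose(sub["shap"], best)]
        if len(tied) > 1:
            logger.info("gene %s: SHAP tie across %d modalities, taking "
                        "first in configured order", gene, len(tied))
        winner = min(tied["modality"], key=lambda m: order.get(m, len(order)))
        rows.append({"gene": gene, "core_modality": winner,
                     "shap": float(best)})
    return pd.DataFrame(rows)


def pathway_scores(ep_final: np.ndarray) -> np.ndarray:
    """Per-sample pathway activity: mean over the embedding dimensions."""
    ep = np.asarray(ep_final, float)
    return ep.mean(axis=-1)


def subnetwork_scores(networks: list[np.ndarray], pathway_shap: dict[str, float],
                      pathway_ids: list[str], prune_quantile: float = 0.9,
                      max_size: int = 20, n_seeds: int = 5,
                      merge_jaccard: float = 0.5) -> list[SubnetworkResult]:
    """Find high-importance sub-networks of the updated crosstalk network.

    Four steps: (1) element-wise average of the per-block updated networks;
    (2) prune edges whose |weight| is not above the ``prune_quantile`` of all
    off-diagonal |weights|; (3) from each of the ``n_seeds`` top-SHAP seed
    pathways, greedily add the neighbor with the strongest edge to the
    current set while the score improves, up to ``max_size`` members;
    (4) score = sum of member SHAP x (1 + degree within the sub-network,
    normalized by its maximum possible value).  Overlapping results
    (Jaccard > ``merge_jaccard``) are merged; output is sorted by score.
    """
    if not networks:
        raise ValueError("need at least one updated network")
    avg = np.mean([np.asarray(n, float) for n in networks], axis=0)
    n_path = avg.shape[0]
    tri = np.triu_indices(n_path, k=1)
    weights = np.abs(avg[tri])
    threshold = np.quantile(weights, prune_quantile)
    graph = nx.Graph()
    graph.add_nodes_from(range(n_path))
    for i, j, w in zip(*tri, np.abs(avg[tri])):
        if w > threshold:
            graph.add_edge(int(i), int(j), weight=float(w))
    if graph.number_of_edges() == 0:
        logger.warning("crosstalk network fully pruned at quantile %.2f",
                       prune_quantile)
        return []

    shap_vec = np.array([pathway_shap.get(p, 0.0) for p in pathway_ids])

    def score(members: set[int]) -> float:
        if not members:
            return 0.0
        sub = graph.subgraph(members)
        denom = max(len(members) - 1, 1)
        return float(sum(shap_vec[i] * (1.0 + sub.degree(i) / denom)
                         for i in members))

    seeds = [i for i in np.argsort(-shap_vec)[:n_seeds]
             if graph.degree(i) > 0]
    results: list[tuple[set[int], float]] = []
    for seed in seeds:
        members = {int(seed)}
        current = score(members)
        while len(members) < max_size:
            neighbors = {}
            for m in members:
                for nb, data in graph[m].items():
                    if nb not in members:
                        neighbors[nb] = max(neighbors.get(nb, 0.0),
                                            data["weight"])
            if not neighbors:
                break
            best_nb = max(neighbors, key=lambda n: (neighbors[n], -n))
            trial = score(members | {best_nb})
            if trial > current:
                members.add(best_nb)
                current = trial
            else:
                break
        results.append((members, current))

    # merge heavily overlapping sub-networks
    merged: list[set[int]] = []
    for members, _ in sorted(results, key=lambda r: -r[1]):
        for existing in merged:
            jac = len(members & existing) / len(members | existing)
            if jac > merge_jaccard:
                existing |= members
                break
        else:
            merged.append(set(members))

    out = []
    for members in merged:
        sub = graph.subgraph(members)
        edges = [(pathway_ids[u], pathway_ids[v], d["weight"])
                 for u, v, d in sub.edges(data=True)]
        out.append(SubnetworkResult(
            members=[pathway_ids[i] for i in sorted(members)],
            score=score(members), edges=edges))
    out.sort(key=lambda r: -r.score)
    return out
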