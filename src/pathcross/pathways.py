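"""Pathway gene sets: loading, filtering, the gene-pathway mask, and the
initial pathway crosstalk network.

A *pathway collection* fixes the canonical ordering used by every downstream
matrix: rows of the gene-pathway mask follow ``gene_universe`` (sorted union
of member genes), columns follow pathway order.  The crosstalk network is an
``Np x Np`` non-negative matrix whose entries encode the significance of the
inter-pathway association and which later biases pathway-axis attention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Pathway", "PathwayCollection", "GenePathwayMask", "CrosstalkNetwork",
    "load_gmt", "overlap_ratio", "count_subsets", "filter_pathways",
    "build_mask", "build_crosstalk",
]


@dataclass(frozen=True)
class Pathway:
    """A named gene set from a pathway database."""

    id: str
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    """Ordered pathways plus the sorted union of their genes."""

    pathways: list[Pathway]
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")
        if not self.gene_universe:
            self.gene_universe = sorted(set().union(
                *(p.genes for p in self.pathways)) if self.pathways else set())
        self._gene_index = {g: i for i, g in enumerate(self.gene_universe)}
        self._id_index = {p.id: i for i, p in enumerate(self.pathways)}

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[self._id_index[pathway_id]]

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]


@dataclass
class GenePathwayMask:
    """Binary Ng x Np membership matrix in collection order."""

    matrix: np.ndarray
    gene_universe: list[str]
    pathway_ids: list[str]


@dataclass
class CrosstalkNetwork:
    """Symmetric non-negative Np x Np pathway association matrix."""

    matrix: np.ndarray
    pathway_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("crosstalk matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError("crosstalk matrix has non-finite entries")


def load_gmt(path: str | Path) -> PathwayCollection:
    """Read pathways from a GMT file (name, description, tab-separated genes).

    The description field is kept as the pathway ``source``.  Duplicate gene
    tokens within a line are deduplicated with a warning; duplicate pathway
    names raise.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >=3 tab-separated fields, got {len(fields)})")
            name, source, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate gene tokens in pathway %r "
                               "deduplicated", path, lineno, name)
            pathways.append(Pathway(id=name, name=name, source=source,
                                    genes=frozenset(genes)))
    if not pathways:
        raise ValueError(f"no pathways found in {path}")
    return PathwayCollection(pathways)


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in coll.pathways:
            fh.write("\t".join([p.id, p.source, *sorted(p.genes)]) + "\n")


def overlap_ratio(p: Pathway, coll: PathwayCollection) -> float:
    """Fraction of ``p``'s genes found in at least one other pathway."""
    if len(coll) < 2:
        raise ValueError("overlap ratio undefined for a singleton collection")
    others: set[str] = set()
    for q in coll.pathways:
        if q.id != p.id:
            others.update(q.genes)
    return len(p.genes & others) / len(p.genes)


def count_subsets(p: Pathway, coll: PathwayCollection) -> int:
    """Number of other pathways whose gene set is contained in ``p``'s."""
    return sum(1 for q in coll.pathways
               if q.id != p.id and q.genes <= p.genes)


def filter_pathways(coll: PathwayCollection, min_genes: int = 15,
                    max_genes: int = 100, max_overlap: float = 1.0,
                    max_subsets: int = 5) -> PathwayCollection:
    """Keep pathways of moderate size or low redundancy.

    A pathway with n genes survives iff
      (min_genes <= n <= max_genes), or
      (n > min_genes and overlap ratio < max_overlap), or
      (n > min_genes and subset count < max_subsets),
    with overlap and subset statistics computed against the *unfiltered*
    collection.  Survivor order is preserved and the gene universe recomputed.
    """
    if min_genes <= 0 or max_genes <= 0:
        raise ValueError("size thresholds must be positive")
    kept: list[Pathway] = []
    for p in coll.pathways:
        n = len(p)
        if min_genes <= n <= max_genes:
            kept.append(p)
        elif n > min_genes and overlap_ratio(p, coll) < max_overlap:
            kept.append(p)
        elif n > min_genes and count_subsets(p, coll) < max_subsets:
            kept.append(p)
    if not kept:
        raise ValueError("all pathways filtered out; relax min_genes/"
                         "max_genes/max_overlap/max_subsets thresholds")
    logger.info("pathway filter kept %d of %d pathways", len(kept), len(coll))
    return PathwayCollection(kept)


def build_mask(coll: PathwayCollection) -> GenePathwayMask:
    """Binary gene-by-pathway membership matrix in collection order."""
    if not coll.pathways:
        raise ValueError("empty pathway collection")
    ng, npath = coll.n_genes, len(coll)
    m = np.zeros((ng, npath))
    for j, p in enumerate(coll.pathways):
        for g in p.genes:
            m[coll.gene_index(g), j] = 1.0
    return GenePathwayMask(matrix=m, gene_universe=list(coll.gene_universe),
                           pathway_ids=coll.ids())


def _inter_set_pairs(a: frozenset, b: frozenset) -> int:
    """Number of unordered node pairs {u, v}, u != v, with u in a and v in b."""
    k = len(a & b)
    return len(a) * len(b) - k - math.comb(k, 2)


def build_crosstalk(coll: PathwayCollection,
                    gene_network: list[tuple[str, str]] | None = None,
                    alpha: float = 0.05) -> CrosstalkNetwork:
    """Score pairwise pathway crosstalk by a connectivity enrichment test.

    With a background gene network, the observed number of inter-set edges for
    each pathway pair is tested against a binomial null whose success
    probability is the network's global edge density.  Without a network, a
    hypergeometric test on the shared-gene count over the gene universe is
    used.  P-values are Benjamini-Hochberg adjusted across all pairs; matrix
    entry = 1 - adjusted p for pairs significant at ``alpha``, else 0.
    """
    n_path = len(coll)
    universe = set(coll.gene_universe)
    for p in coll.pathways:
        if not (p.genes & universe):
            raise ValueError(f"pathway {p.id!r} has no genes in the universe")

    pairs = [(i, j) for i in range(n_path) for j in range(i + 1, n_path)]
    pvals = np.ones(len(pairs))

    if gene_network is not None:
        edges = {frozenset(e) for e in gene_network
                 if e[0] != e[1] and e[0] in universe and e[1] in universe}
        n_nodes = len(universe)
        possible = math.comb(n_nodes, 2)
        density = len(edges) / possible if possible else 0.0
        adjacency: dict[str, set[str]] = {}
        for e in edges:
            u, v = tuple(e)
            adjacency.setdefault(u, set()).add(v)
            adjacency.setdefault(v, set()).add(u)
        for idx, (i, j) in enumerate(pairs):
            a, b = coll.pathways[i].genes, coll.pathways[j].genes
            m = _inter_set_pairs(a, b)
            if m == 0 or density == 0.0:
                pvals[idx] = 1.0
                continue
            # count each unordered inter-set edge once (pairs with both
            # endpoints in both sets would otherwise be counted twice)
            obs = sum(1 for u in a for v in adjacency.get(u, ())
                      if v in b and (u not in b or v not in a or u < v))
            pvals[idx] = stats.binom.sf(obs - 1, m, density)
        meta = {"method": "binomial_connectivity", "alpha": alpha,
                "edge_density": density, "n_edges": len(edges)}
    else:
        n_universe = len(universe)
        for idx, (i, j) in enumerate(pairs):
            a = coll.pathways[i].genes & universe
            b = coll.pathways[j].genes & universe
            k = len(a & b)
            # P[X >= k], X ~ Hypergeom(N=n_universe, K=|a|, n=|b|)
            pvals[idx] = stats.hypergeom.sf(k - 1, n_universe, len(a), len(b))
        meta = {"method": "hypergeometric_overlap", "alpha": alpha,
                "n_universe": n_universe}

    padj = _benjamini_hochberg(pvals)
    mat = np.zeros((n_path, n_path))
    for idx, (i, j) in enumerate(pairs):
        if padj[idx] < alpha:
            mat[i, j] = mat[j, i] = 1.0 - padj[idx]
    return CrosstalkNetwork(matrix=mat, pathway_ids=coll.ids(), metadata=meta)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
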