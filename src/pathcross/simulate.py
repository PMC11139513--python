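"""Synthetic multi-omics data with planted pathway-level signal.

The generator emulates the input structure the pipeline consumes: gene-level
expression, fragment-level methylation fractions mapped many-to-one onto
genes, gene-level copy-number states, and binary labels driven by the
activity of a small set of *planted* pathways.

Generative model.  Every gene g carries a per-sample latent activity
s_gs ~ N(0, 1).  The three modalities are views of this activity:

- expression:   x_gs = exp(mu_g + s_gs)      (log-normal; the log-residual
                                              *is* the activity),
- methylation:  3-10 sites per gene, site value ~ Beta with mean
                sigmoid(b_site + kappa * s_gs),
- CNV:          state in {0..4}, round(2 + lambda * s_gs + noise) clipped.

The label logit is z_s = effect_size * mean over planted pathways of the
*standardized* member-gene mean activity (the member mean scaled by
sqrt(|pathway|), so each pathway activity has unit variance and effect_size
is in units of the label-logit standard deviation), and
y_s = 1{ z_s + label_noise * eta_s > 0 } with eta_s ~ Logistic(0, 1) — i.e.
P(y=1 | z) = sigmoid(z / label_noise), a logistic function of
planted-pathway activity with temperature label_noise.  At label_noise = 0
labels are an exact threshold of z, so the stored truth reconstructs them
from the written files alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import ModalityInput
from .pathways import Pathway, PathwayCollection, write_gmt

__all__ = ["SimConfig", "SimTruth", "SimData", "generate_pathways",
           "generate_dataset", "write_dataset", "reconstruct_labels"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int
    n_samples: int = 300
    n_genes: int = 200
    n_pathways: int = 20
    genes_per_pathway: tuple[int, int] = (15, 40)
    overlap: float = 0.3
    sites_per_gene: tuple[int, int] = (3, 10)
    planted_pathways: int | list[str] = 3
    effect_size: float = 2.0
    label_noise: float = 0.05
    methylation_coupling: float = 1.0
    cnv_coupling: float = 0.8

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if self.n_genes < self.genes_per_pathway[1]:
            raise ValueError("n_genes must be >= max genes_per_pathway")


@dataclass
class SimTruth:
    """Ground truth sufficient to reconstruct labels at label_noise=0."""

    planted_pathways: list[str]
    gene_effect: np.ndarray          # per-gene weight in the label logit
    expression_log_mean: np.ndarray  # mu_g, to recover activity from files
    gene_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids,
                             "effect": self.gene_effect,
                             "expression_log_mean": self.expression_log_mean})


@dataclass
class SimData:
    collection: PathwayCollection
    modalities: list[ModalityInput]
    labels: np.ndarray
    sample_ids: list[str]
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def generate_pathways(cfg: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> PathwayCollection:
    """Random gene sets with controlled overlap, deterministic per seed.

    ``cfg.overlap`` is the target fraction of each pathway's genes drawn from
    genes already used by earlier pathways; at 0 pathways are disjoint (which
    requires enough genes to go around).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.genes_per_pathway
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    if cfg.overlap == 0.0 and sizes.sum() > cfg.n_genes:
        raise ValueError(f"disjoint pathways need {sizes.sum()} genes but "
                         f"only {cfg.n_genes} exist; raise n_genes or overlap")
    used: list[str] = []
    unused = list(genes)
    pathways = []
    for j, size in enumerate(sizes):
        n_shared = min(int(round(cfg.overlap * size)), len(used))
        n_fresh = int(size) - n_shared
        if n_fresh > len(unused):
            n_fresh = len(unused)
            n_shared = int(size) - n_fresh
        members = []
        if n_shared:
            members += list(rng.choice(used, size=n_shared, replace=False))
        if n_fresh:
            fresh = list(rng.choice(unused, size=n_fresh, replace=False))
            members += fresh
            for g in fresh:
                unused.remove(g)
                used.append(g)
        pathways.append(Pathway(id=f"PW{j:02d}", name=f"PW{j:02d}",
                                source="synthetic", genes=frozenset(members)))
    return PathwayCollection(pathways)


def generate_dataset(cfg: SimConfig) -> SimData:
    """Generate modalities, labels and ground truth for one seed."""
    rng = np.random.default_rng(cfg.seed)
    coll = generate_pathways(cfg, rng)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    gene_index = {g: i for i, g in enumerate(genes)}

    activity = rng.normal(size=(cfg.n_genes, cfg.n_samples))  # s_gs

    # --- expression (gene level, log-normal) ------------------------------
    mu = rng.normal(2.0, 1.0, size=cfg.n_genes)
    expression = np.exp(mu[:, None] + activity)
    expr_df = pd.DataFrame(expression, index=genes, columns=samples)

    # --- methylation (fragment level, Beta fractions) ---------------------
    lo, hi = cfg.sites_per_gene
    n_sites = rng.integers(lo, hi + 1, size=cfg.n_genes)
    site_ids, site_gene, site_pos, site_rows = [], {}, {}, []
    for gi, g in enumerate(genes):
        base = rng.normal(0.0, 1.0, size=n_sites[gi])
        for k in range(n_sites[gi]):
            logit = base[k] + cfg.methylation_coupling * activity[gi]
            mean = 1.0 / (1.0 + np.exp(-logit))
            nu = 10.0
            vals = rng.beta(np.maximum(mean * nu, 1e-3),
                            np.maximum((1.0 - mean) * nu, 1e-3))
            fid = f"cg_{g}_{k}"
            site_ids.append(fid)
            site_gene[fid] = g
            site_pos[fid] = k
            site_rows.append(vals)
    meth_df = pd.DataFrame(np.vstack(site_rows), index=site_ids,
                           columns=samples)

    # --- CNV (gene level, integer states 0..4) ----------------------------
    cnv = np.clip(np.round(2.0 + cfg.cnv_coupling * activity
                           + rng.normal(0.0, 0.6, size=activity.shape)),
                  0, 4)
    cnv_df = pd.DataFrame(cnv, index=genes, columns=samples)

    # --- planted pathways and labels --------------------------------------
    if isinstance(cfg.planted_pathways, int):
        planted = list(rng.choice(coll.ids(), size=cfg.planted_pathways,
                                  replace=False))
    else:
        planted = list(cfg.planted_pathways)
        unknown = set(planted) - set(coll.ids())
        if unknown:
            raise ValueError(f"planted pathways not generated: {unknown}")
    w = np.zeros(cfg.n_genes)
    for pid in planted:
        members = sorted(coll[pid].genes)
        # standardized pathway activity: member mean x sqrt(|p|) has unit
        # variance, so effect_size is on the label-logit SD scale
        for g in members:
            w[gene_index[g]] += cfg.effect_size / (len(planted)
                                                   * np.sqrt(len(members)))
    z = w @ activity  # (n_samples,)
    if cfg.label_noise > 0:
        noise = rng.logistic(0.0, 1.0, size=cfg.n_samples)
        labels = (z + cfg.label_noise * noise > 0).astype(int)
    else:
        if cfg.effect_size == 0:
            raise ValueError("effect_size=0 with label_noise=0 produces a "
                             "single-class dataset")
        labels = (z > 0).astype(int)

    truth = SimTruth(planted_pathways=planted, gene_effect=w,
                     expression_log_mean=mu, gene_ids=genes)
    modalities = [
        ModalityInput(name="expression", level="gene", values=expr_df,
                      transform="log1p"),
        ModalityInput(name="methylation", level="fragment", values=meth_df,
                      feature_to_gene=site_gene, feature_position=site_pos),
        ModalityInput(name="cnv", level="gene", values=cnv_df),
    ]
    return SimData(collection=coll, modalities=modalities, labels=labels,
                   sample_ids=samples, truth=truth, config=cfg)


def reconstruct_labels(data: SimData) -> np.ndarray:
    """Oracle labels from the generated expression matrix and SimTruth.

    Exact when label_noise=0: the label logit is recomputed from the
    expression log-residuals, which equal the latent activity by
    construction.
    """
    expr = data.modalities[0].values.to_numpy(dtype=float)
    s = np.log(expr) - data.truth.expression_log_mean[:, None]
    z = data.truth.gene_effect @ s
    return (z > 0).astype(int)


def write_dataset(data: SimData, outdir: str | Path,
                  float_format: str = "%.8g") -> dict[str, Path]:
    """Write all artifacts as TSV/GMT; byte-identical given the same seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for mi in data.modalities:
        p = outdir / f"{mi.name}.tsv"
        mi.values.rename_axis("feature").to_csv(p, sep="\t",
                                                float_format=float_format)
        paths[mi.name] = p
        if mi.level != "gene":
            mp = outdir / f"{mi.name}_mapping.tsv"
            rows = [{"feature": f, "gene": mi.feature_to_gene[f],
                     **({"position": mi.feature_position[f]}
                        if mi.feature_position else {})}
                    for f in mi.values.index]
            pd.DataFrame(rows).to_csv(mp, sep="\t", index=False)
            paths[f"{mi.name}_mapping"] = mp

    lp = outdir / "labels.tsv"
    pd.DataFrame({"sample": data.sample_ids, "label": data.labels}) \
        .to_csv(lp, sep="\t", index=False)
    paths["labels"] = lp

    gp = outdir / "pathways.gmt"
    write_gmt(data.collection, gp)
    paths["pathways"] = gp

    tp = outdir / "truth.tsv"
    data.truth.to_frame().to_csv(tp, sep="\t", index=False,
                                 float_format=float_format)
    paths["truth"] = tp
    pp = outdir / "planted_pathways.txt"
    pp.write_text("\n".join(data.truth.planted_pathways) + "\n")
    paths["planted"] = pp
    return paths
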