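"""Shared fixtures: small pathway collections and synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

import pathcross as pc


@pytest.fixture
def toy_collection() -> pc.PathwayCollection:
    """Three overlapping pathways over genes A..F."""
    mk = lambda i, genes: pc.Pathway(id=f"P{i}", name=f"P{i}", source="toy",
                                     genes=frozenset(genes))
    return pc.PathwayCollection([
        mk(1, "ABC"), mk(2, "BCD"), mk(3, "EF"),
    ])


@pytest.fixture
def small_sim() -> pc.SimData:
    """An 80-sample, 60-gene dataset with planted signal (fast fixture)."""
    cfg = pc.SimConfig(seed=7, n_samples=80, n_genes=60, n_pathways=8,
                       genes_per_pathway=(8, 15), planted_pathways=2,
                       effect_size=2.0)
    return pc.generate_dataset(cfg)


@pytest.fixture
def small_embedded(small_sim):
    """(data, gene embedding, mask, crosstalk) for the small dataset."""
    eg = pc.embed_modalities(small_sim.modalities, pc.EmbeddingConfig(),
                             small_sim.collection.gene_universe)
    mask = pc.build_mask(small_sim.collection)
    net = pc.build_crosstalk(small_sim.collection)
    return small_sim, eg, mask, net


@pytest.fixture
def gmt_file(tmp_path):
    p = tmp_path / "toy.gmt"
    p.write_text("setA\tsrc\tA\tB\tC\nsetB\tsrc\tB\tC\tD\n")
    return p
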