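"""Curate pathway gene sets and build the initial crosstalk network.

Generates a small synthetic pathway collection, applies the three-clause
size/overlap/subset filter, builds the gene-pathway membership mask, and
scores pairwise crosstalk with the shared-gene hypergeometric test.
"""

import numpy as np

import pathcross as pc

cfg = pc.SimConfig(seed=0, n_genes=150, n_pathways=12,
                   genes_per_pathway=(15, 40), overlap=0.7)
coll = pc.generate_pathways(cfg)
print(f"{len(coll)} pathways over {coll.n_genes} genes")

kept = pc.filter_pathways(coll, min_genes=15, max_genes=100)
print(f"filter kept {len(kept)}/{len(coll)} "
      "(moderate size, or low overlap, or few subsets)")

mask = pc.build_mask(kept)
print(f"gene-pathway mask: {mask.matrix.shape}, "
      f"{int(mask.matrix.sum())} memberships "
      "(the support of the learnable sparse projection)")

net = pc.build_crosstalk(kept, alpha=0.05)
pairs = int((np.triu(net.matrix, 1) > 0).sum())
print(f"crosstalk network: {pairs} significant pathway pairs "
      f"({net.metadata['method']}); entries are 1 - adjusted p, "
      "used later as the attention bias")
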