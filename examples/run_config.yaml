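# Example pipeline configuration for `pathcross train / evaluate / interpret`.
# Paths point at the output of `pathcross simulate --config run_config.yaml
# --out data/` run from this directory.
seed: 7
gmt: data/pathways.gmt
labels: data/labels.tsv
modalities:
  - name: expression
    level: gene
    path: data/expression.tsv
    transform: log1p        # counts-like data: log before z-scoring
  - name: methylation
    level: fragment
    path: data/methylation.tsv
    mapping: data/methylation_mapping.tsv
  - name: cnv
    level: gene
    path: data/cnv.tsv
sim:                         # used only by `pathcross simulate`
  seed: 7
  n_samples: 150
  n_genes: 120
  n_pathways: 12
  genes_per_pathway: [12, 25]
  planted_pathways: 2
  effect_size: 2.0
train:
  model_mode: pathformer     # pathformer | cc_attention | transformer | psnn | nn
  lr: 3.0e-3
  dropout_c: 0.3
  epochs: 80
  patience: 15
  seed: 7
attention:
  n_blocks: 3
  n_heads: 8
  head_dim: 8
  row_residual_coeff: 0.3
cv:
  k: 5
  repeats: 2
  seed: 7
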