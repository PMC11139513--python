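# pathcross

Pathway-informed criss-cross attention networks for multi-modal omics
classification.

Disease classification from omics data — cancer staging, survival risk,
liquid-biopsy screening — increasingly draws on several data types at once:
RNA expression at the gene level, DNA methylation measured at many CpG
sites per gene, copy-number states, and further RNA-derived modalities.
`pathcross` is for computational biologists who want to integrate such
modalities *through prior pathway knowledge* rather than through a flat
feature matrix, and to read back which modalities, pathways, genes and
pathway-pathway interactions carried the decision.

## The model

Let `M_1..M_m` be modality matrices at gene, fragment or nucleotide
resolution. Each modality is summarized to one vector per gene by
statistical indicators (count, min, max, mean, entropy, weighted means);
concatenation gives the gene embedding `E_G ∈ R^(Ng×Dg)` per sample. A
sparse layer maps genes to Np curated pathways,

    E_P = (W ∘ M)^T E_G + B,

where `M` is the binary gene-pathway membership mask: weights exist only
where a gene belongs to a pathway, so the projection is interpretable and
immune to feature-selection bias. A 3-block criss-cross transformer then
alternates **col-attention** across pathways — with a pathway crosstalk
matrix `P` added to the attention logits, so prior knowledge of
inter-pathway regulation steers information flow — and **row-attention**
across embedding dimensions (modalities), with gated multi-head merges and
a residual scaled by a constant β. After each block, `P` is refreshed from
the correlation structure of the updated pathway embeddings. A 300/200/100
fully connected head classifies; macro-averaged F1 is the primary metric,
with AUC and sensitivity at 99% specificity (the screening operating
point) alongside.

Interpretation comes from the model itself: row-attention maps quantify
each modality's contribution (weights summing to 1); Shapley values —
exact for ≤12 entities, permutation-sampled beyond — rank pathways (top
15) and, per pathway, genes (top 5); and a pruned, SHAP-seeded search over
the block-averaged updated crosstalk network extracts the "hub module" of
interacting pathways behind the prediction.

The network stack (reverse-mode autodiff, attention, Adam) is implemented
in NumPy inside the package; there is no deep-learning framework
dependency.

## A worked example

A synthetic cohort with a known answer (from
`examples/02_embed_and_classify.py`; the package's generator plants a
label signal inside chosen pathways of a 3-modality dataset):

```python
import pathcross as pc

cfg = pc.SimConfig(seed=3, n_samples=150, n_genes=120, n_pathways=12,
                   genes_per_pathway=(12, 25), planted_pathways=2,
                   effect_size=2.0)
data = pc.generate_dataset(cfg)
eg = pc.embed_modalities(data.modalities, pc.EmbeddingConfig(),
                         data.collection.gene_universe)
mask = pc.build_mask(data.collection)
net = pc.build_crosstalk(data.collection)
report = pc.cross_validate(eg.tensor, data.labels, mask, net.matrix,
                           pc.CVPlan(k=5, repeats=2, seed=3),
                           pc.TrainConfig(seed=0, model_mode="pathformer"))
```

Output:

```
planted pathways: PW04, PW05
gene embedding: samples x genes x indicators = (150, 120, 7)
CV macro_f1: 0.822 +/- 0.059
CV auc: 0.902 +/- 0.059
```

The 7 indicator columns are expression (1), methylation site statistics
(5) and CNV (1). The cross-validated macro-F1 of 0.82 and AUC of 0.90 —
against a chance level of 0.5 — say the classifier recovered the signal
planted in the two pathways from 150 samples, with feature scaling and
early stopping fitted inside each training fold. Running
`examples/03_interpret_model.py` on a similar cohort ranks the three
planted pathways 1-2-3 by Shapley value and attributes most of the
decision to the methylation modality.

The command-line interface mirrors the same stages for shell pipelines:

```bash
pathcross simulate --config sim.yaml --out data/
pathcross pathways filter --gmt data/pathways.gmt --out kept.gmt
pathcross pathways crosstalk --gmt kept.gmt --out net.tsv
pathcross train --config run.yaml --out fit/
pathcross interpret --config run.yaml --checkpoint fit/ --out interp/
```

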