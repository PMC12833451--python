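# spallm

Spatial domain identification for spatial transcriptomics, fusing two
complementary views of each spot:

1. a **spatial stream** `H_ST` — latent embeddings from a graph-convolutional
   autoencoder trained on the normalized expression matrix over a
   Gaussian-kernel spatial proximity graph, and
2. a **functional stream** `H_LLM = X · F` — each spot's expression-weighted
   sum of per-gene *description-embedding* vectors (a precomputed lookup
   table of text embeddings of gene summaries, e.g. GenePT-style vectors of
   NCBI gene descriptions).

The functional stream is PCA-aligned to the spatial width and the two are
combined as a weighted sum

```
Z = α · H_ST + β · H_LLM_PCA        (default α = β = 0.5)
```

after per-column standardization, then clustered (k-means, Louvain, or a
Gaussian mixture) into spatial domains. Agreement with ground-truth
annotations is scored with the adjusted Rand index (ARI). A
quality-degradation simulator (randomly zeroing 50 / 75 / 87.5 / 93.75 % of
the non-zero expression entries, tiers Q1–Q4) and a benchmark harness over
integration strategies make the robustness of each stream measurable, and a
synthetic-tissue generator makes the whole system testable offline.

Intended users: computational biologists analyzing sequencing-based (Visium)
or imaging-based (osmFISH-like) spatial transcriptomics who want to inject
gene-level functional knowledge into domain segmentation, and methods
developers who need a controlled testbed for degradation studies.

## Model summary

* Spatial graph: `A_ij = exp(−‖c_i − c_j‖² / 2σ²)` for `‖c_i − c_j‖ ≤ τ`,
  else 0; symmetrically normalized `Â = D^{−1/2} A D^{−1/2}`. By default
  `τ = 1.05 ×` mean distance to the 6th nearest neighbor and `σ = τ/2`.
* Graph convolution: `H^(l+1) = act(Â H^(l) W^(l))`; a 2-layer encoder to
  width `d_ST = 32` with a mirrored decoder, trained full-batch with Adam
  against the mean-squared reconstruction error of the normalized expression.
* Expression normalization: per-spot scaling to the median library, `log1p`,
  top-3000 genes by dispersion.
* ARI: pair-counting `(RI − E[RI]) / (max RI − E[RI])` via the contingency
  table; 1 for identical partitions, ≈0 for random ones.

## Worked example

Generate a synthetic 40×40 tissue (5 horizontal domains, 200 genes, 20-gene
programs per domain) with a program-coherent embedding table, then run the
fused pipeline:

```bash
spallm synth --out demo --seed 11
spallm run --dataset demo/default.h5ad --table demo/gene_embeddings.csv \
           --out demo/run --epochs 100 --seed 11
# ARI = 0.9953
```

`demo/run/` then contains `labels.csv` (spot → domain), `embedding.csv`
(the fused `Z`), and `report.json` with the run parameters and score:

```
{'sigma': 0.7727, 'tau': 1.5455, 'ari': 0.9953, 'K': 5, 'functional_stream': 'enabled'}
```

An ARI of 0.995 means the predicted partition is in near-perfect agreement
with the generating five-band ground truth. Setting `--alpha 1 --beta 0`
reproduces the expression-only pipeline exactly; `--alpha 0 --beta 1` the
functional-only one. `spallm benchmark` runs the full quality grid (Q0–Q4)
× four integration strategies (expression-only, functional-only,
concatenation, weighted) with mean ± std ARI over repeated runs, and
`spallm mask` / `spallm eval` expose the degradation simulator and the
metric on their own.

The same workflow is available as a library:

```python
import spallm as sp
ds  = sp.make_tissue(sp.TissueSpec(seed=11))
tab = sp.make_embedding_table(sp.EmbeddingSpec(seed=11),
                              sp.gene_programs(sp.TissueSpec()))
res = sp.run_spallm(ds, tab, sp.EncoderConfig(epochs=100))
print(sp.adjusted_rand_index(res.labels, ds.truth))
```

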