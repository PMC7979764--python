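# spotlineage

Integration of single-cell and spatial transcriptomics for developing
tissue: per-spot cell-type mapping, cell-type proximity statistics, and
spatial projection of differentiation pseudotime.

Barcoded spatial transcriptomics (e.g. 10x Visium) measures whole
transcriptomes at 55 µm spots, but each spot mixes the mRNA of 10–20
cells. Given a dissociated single-cell reference of the same tissue,
`spotlineage` deconvolves that mixture with anchor-based label transfer
and then builds the spatial statistics this enables:

- **Prediction scores** — a spots × cell-types weight matrix (rows sum
  to 1). Anchors are mutual nearest neighbours between cells and spots
  in a joint canonical-correlation embedding of the shared highly
  variable genes, scored by neighbourhood overlap and filtered for
  gene-space consistency; a Gaussian kernel over each spot's nearest
  anchors averages the anchors' one-hot type labels.
- **Max-label maps** — each spot labelled by its highest-scoring type.
- **Heterogeneity** — the number of types per spot with score > 5%.
- **Colocalization / proximity maps** — a symmetric type × type pair-count
  matrix over each spot's top-4 predicted types (the matrix behind
  chord diagrams of cell-type proximity).
- **Regional composition and markers** — mean scores per anatomical
  region and one-vs-rest Wilcoxon differential expression.
- **Similarity map and spot pseudotime** — transferring *individual cell
  identities* instead of type labels gives a sparse spots × cells
  similarity map; a lineage's diffusion-potential pseudotime (first
  embedding coordinate, sign-anchored by developmental stage) is then
  projected onto tissue as the mean pseudotime of each spot's
  nonzero-similarity cells. Collapsing the similarity map by cell type
  reproduces the prediction scores exactly — a consistency theorem the
  test suite asserts.

A synthetic generator simulates the whole study — negative-binomial
single-cell reference with lineage-structured latent differentiation
time, and a layered Visium-like tissue whose spots are exact sums of
hidden constituent cells — with complete ground truth, so every stage
has a parameter-recovery test and no external download is needed.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

```python
from spotlineage.pipeline import run_pipeline

res = run_pipeline(seed=0)   # default study: 2000 cells, 8 types, 400 spots
for k, v in res.metrics.items():
    print(f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}")
```

prints

```
n_cells_kept: 2000
n_spots: 400
clustering_ari: 0.993
label_accuracy_cells: 0.997
median_spot_composition_pearson: 0.902
composition_mae_per_type: 0.062
max_label_accuracy: 0.835
median_heterogeneity: 5.000
spot_pseudotime_spearman: 0.630
lineage_pseudotime_spearman: 0.913
```

Reading these numbers: the reference cells cluster back into the eight
planted types almost perfectly (adjusted Rand index 0.993) and are
annotated by marker panels at 99.7% accuracy. Per spot, the predicted
cell-type weights correlate with the true hidden composition at a
median Pearson r of 0.90 with a mean absolute error of 0.06 per type,
and 84% of spots are max-labelled with their true dominant type. The
median spot mixes five types at the >5% level. Epicardial-lineage
pseudotime recovers the planted differentiation time at Spearman 0.91;
its spot projection follows the tissue's outer-to-inner maturation
gradient (the correlation rises to ~0.9 when the study is simulated for
a single lineage, where spot-level lineage pseudotime is well defined —
see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
spotlineage --seed 0 simulate --out data/        # 10x triplets + truth CSVs
spotlineage --seed 0 run-all --out results/      # full analysis, tables + metrics
spotlineage --seed 0 integrate --ref data/cells --query data/spots \
    --labels labels.csv --out results/           # individual stages
```

`read_10x_counts` / `write_10x_counts` handle Matrix Market triplet
directories (plain or gzipped), so real Cell Ranger / Space Ranger
outputs drop in wherever the synthetic data is used.

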