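# Methods

`spotlineage` re-implements, as a tested pipeline, the integration of a
dissociated single-cell RNA-seq reference with barcoded spatial
transcriptomics spots: per-spot cell-type prediction scores by
anchor-based label transfer, spot-level colocalization and heterogeneity
statistics, regional differential expression, and projection of
differentiation pseudotime from cells onto tissue via a cell–spot
similarity map. A synthetic layered-tissue generator supplies every
stage with ground truth, so each operation has a parameter-recovery
test.

## Synthetic study generator

The generator emulates a developing-ventricle study that profiles both
dissociated cells and Visium-style spots (55 µm spots at 110 µm pitch,
each capturing 10–20 cells).

**Cells.** Each cell has a type (default 8 of a 15-type template spanning
myocardial, endocardial, epicardial, and immune lineages), a
developmental stage (4 stages), and a latent differentiation time in
[0, 1]. Cells are drawn per stage with stage-shifted type proportions
and latent-time windows, so earlier stages are enriched for progenitor
types and early latent times. Counts are negative binomial
(dispersion θ = 2) around a per-gene mean

    log µ_gc = base_g + marker_g,type(c) + slope_g,lineage(c) · (z_c − 0.5) + log ℓ_c

with lognormal library factors ℓ_c (σ = 0.3). Marker genes (10 per type)
are boosted by 3 natural-log units in their type — the scale of canonical
markers, which are near-silent off-type; this is what makes the planted
types recoverable by clustering (adjusted Rand index ≥ 0.9 under default
conditions). Each lineage carries a 60-gene "maturity program" whose
log-mean shifts linearly with latent time (slope ±2.5), making
differentiation the dominant continuous structure *within* a lineage —
the property a trajectory method needs to order cells by developmental
state. Mitochondrial genes (5% of genes, `MT-` name prefix) have an
elevated baseline giving healthy cells a ~7–10% mitochondrial fraction.
The baseline expression level is calibrated so that healthy cells detect
well over 200 genes at the default 1000-gene panel; a configurable
fraction of cells is deliberately corrupted (fewer than 200 detected
genes, or >20% mitochondrial counts) so QC filtering has an exact
planted truth.

**Tissue.** Spots sit on a square lattice (the hexagonal offset of the
real array is cosmetic for every statistic computed here; pitch is
recorded in µm for plotting only). Concentric depth bands assign layers:
epicardium at the border, then compact myocardium, trabecular
myocardium, endocardium, with the valve at the lattice centre. Each
layer has a lineage budget (its hallmark lineage dominant — myocardium
mostly cardiomyocytes, the chamber lining endocardial, valves
fibroblastic) distributed within a lineage by each type's affinity to
the layer's latent-time target, which rises from the epicardial border
(0.15) inward (endocardium 0.80). Epicardial-derived mesenchyme is
present in the compact wall at mid latent, mirroring EMT-driven
migration. Every spot draws 10–20 constituent cells (uniform count — the
within-range distribution is not reported anywhere, so the simplest
choice is used) by multinomial type sampling and latent-affinity cell
sampling (with replacement across spots); the spot count vector is the
**exact integer sum** of its constituents' counts, optionally followed by
binomial thinning at a stated capture rate. The hidden per-cell types
and latent times, per-spot compositions, layers, mean latent times, and
constituent lists are all returned as a `TruthBundle`.

**What the generator does not model:** doublets, ambient RNA, segmentation
of H&E images, batch effects (available via `batch_effect_sd` but 0 by
default), spatial bleed between adjacent spots, and read-level
sequencing noise. Passing recovery tests therefore demonstrates that the
algorithms are implemented correctly and behave as designed under the
stated noise model — not that they are robust to every artifact of real
tissue data.

## Preprocessing

- **QC**: keep cells with ≥ 200 detected genes *and* ≤ 20% mitochondrial
  counts. The boundaries are kept because the filter criteria are
  "fewer than 200" and "more than 20 percent". Idempotent.
- **Normalization**: counts per cell scaled to 10⁶ and natural-log
  transformed, `ln(count/total · 10⁶ + 1)`; zeros stay zero.
- **HVG selection (vst)**: lowess trend of log₁₀ variance on log₁₀ mean of
  the raw counts, per-gene standardization by the trend-predicted sd,
  clipping at √N, ranking by the variance of the clipped values; top
  2000 by default (all nonzero-variance genes if fewer, with a warning).
  The trend smoother is statsmodels lowess (local linear) rather than R
  loess (local quadratic, span 0.3); on the simulated data the rankings
  agree with an independent reimplementation exactly.
- **PCA**: genes centred, unit-scaled, clipped at ±10; exact SVD; top 20
  components; deterministic sign (largest-magnitude loading positive).
- **Clustering**: kNN graph in PC space → Jaccard-weighted shared-nearest-
  neighbor edges (pruned below 1/15) → Louvain modularity optimization
  (networkx, seeded). Spots use k = 30, resolution 0.5; cells default to
  k = 20, resolution 0.8 (the conventional single-cell defaults — the
  cell-side parameters are not printed in the source study). Labels are
  contiguous integers ordered by decreasing cluster size.
- **Annotation**: each cluster receives the type whose marker panel has
  the highest mean z-scored expression in the cluster (ties: margin to
  the runner-up, then lexicographic; scores rounded to 9 decimals so
  float noise cannot break exact ties). One-vs-rest Wilcoxon rank-sum
  marker tables accompany the mapping (two-sided; exact for small
  untied samples, tie-corrected normal otherwise; Bonferroni-adjusted by
  default, configurable).

## Anchor integration

Both datasets are restricted to the shared HVG set and per-gene
standardized; the top-d (default 20) singular vectors of X'Y give paired
embeddings, L2-normalized per observation (cosine-equivalent distances,
needed for stable mutual-nearest-neighbor behaviour) with a
deterministic sign convention.

Anchors are mutual nearest neighbours across datasets (k_anchor = 5).
A gene-space consistency filter removes anchors whose reference cell is
not among the spot's k_filter = 200 nearest reference cells; for this
filter the query is standardized with the **reference's** gene statistics,
because per-dataset standardization would re-centre a query concentrated
on one biological state onto the whole reference. Surviving anchors are
scored by the overlap of the two observations' 30-neighbourhoods in the
joint embedding, min-max rescaled with 1st/90th-percentile capping.

Transfer uses a Gaussian kernel over each spot's k_weight = 50 nearest
anchors; distances are normalized by the spot's k-th anchor distance
(locally adaptive bandwidth) and scaled by sd = 1, multiplied by anchor
scores, and normalized to sum 1. One-hot type labels yield the
prediction-score matrix (rows sum to 1 — per-spot scores are treated as
a normalized weighted mix, which the >5% heterogeneity rule presumes);
one-hot individual cell identities yield the sparse spots × cells
similarity map. Because both transfers share one weight kernel,
collapsing the similarity map by cell type reproduces the prediction
scores exactly; the suite asserts this consistency numerically. Spots
whose kernel weights all vanish fall back to uniform weights and are
flagged rather than dropped, keeping spot sets aligned with geometry
tables. The kernel defaults follow the published defaults of the
anchor-transfer method; k_weight is worth reducing on small studies
(few hundred anchors), where 50 anchors span too much of the embedding.

## Spot statistics

- **Max-label map**: argmax of each score row; exact ties take the
  lexicographically smallest type and raise a flag.
- **Heterogeneity**: number of types with score strictly greater than 5%
  (strict reading of "greater than").
- **Colocalization / proximity map**: for each spot, every unordered pair
  among its top-4 nonzero-score types (ties at the cutoff broken by
  score then name) increments a symmetric type × type matrix by 1.
  Counting presence rather than weight is the default because the
  source phrasing ("counting pair abundances") is ambiguous; a weighted
  variant (increment = min of the pair's scores) sits behind a flag, and
  a row-normalized copy is exported alongside the raw counts since the
  published chord diagrams do not state their normalization.
- **Regional composition**: arithmetic mean of score rows per region
  (rows still sum to 1). Regions come from spot clustering plus a
  user-supplied cluster→region mapping, or directly from truth in
  synthetic studies — manual anatomical annotation is out of
  computational scope.
- **Regional markers**: one-vs-rest two-sided Wilcoxon rank-sum per gene
  per region (≥ 3 spots), log₂ fold change of mean normalized
  expression (pseudocount 10⁻⁹), adjusted p, and a significance flag at
  |log₂FC| > 0.5 and adjusted p < 10⁻⁵ by default.

## Trajectory

The diffusion-potential embedding is a faithful-but-simplified
reimplementation of the heat-diffusion affinity embedding family, kept
deliberately small because only one contract must hold: the first
coordinate orders cells by developmental state.

1. Adaptive-bandwidth alpha-decay kernel `exp(−(d/σ_i)^α)` (α = 10,
   σ_i = distance to the 15th neighbour), symmetrized by averaging,
   row-normalized to a diffusion operator P (row-stochastic at every
   power; asserted).
2. Diffusion time t: knee of the von Neumann entropy of the spectrum
   over t = 1..100, located as the point farthest below the chord of the
   entropy curve; t is then doubled (up to 1024) until every entry of
   P^t exceeds the log floor. The second step matters: if P^t still has
   entries below the floor, potential distances between far cells
   saturate at −log ε and the leading coordinate loses the global
   ordering (observed directly on a 1-D gradient, where the coordinate
   is exactly monotone once P^t has full support). Entropy is computed
   in log space because singular values underflow at large t.
3. Potential U = −log(P^t + ε), ε = 10⁻⁷; classical (Torgerson) MDS of
   potential distances; deterministic sign convention. No random
   initialization anywhere, so the embedding is exactly reproducible.

**Pseudotime** is the first coordinate, sign-flipped if the earliest
stage's mean exceeds the latest stage's (the developmental stages anchor
the direction), then min-max rescaled to [0, 1]; the raw coordinate is
kept alongside. **Spot pseudotime** for a lineage is the unweighted
arithmetic mean of pseudotime over the cells with nonzero similarity
weight for the spot, after restricting similarity columns to the lineage
(a literal reading of the projection definition); a similarity-weighted
mean is available behind a flag. Spots with empty support are flagged
undefined rather than imputed. The projection accepts any per-cell
pseudotime vector, so orderings from other tools can be plugged in.
**Gene trends**: per-gene Spearman correlation with pseudotime,
two-sided permutation p (seeded, add-one corrected) and
Benjamini–Hochberg q.

## Problem sizes and determinism

The default synthetic study is desk-scale: 2000 cells × 1000 genes,
a 20 × 20 spot lattice (400 spots), 8 types. Pseudotime recovery is
evaluated on a single-lineage study (4 epicardial types, n = 1000
cells) on a monotone four-layer tissue, matching the setting in which a
one-dimensional developmental ordering and its outer-to-inner tissue
gradient are well defined; in the mixed-tissue study the epicardial
constituents of interior layers are a small minority per spot, which
bounds any projector's attainable rank correlation with the all-cell
spot latent mean (the valve, which breaks the monotone gradient by
construction, sits at the centre). All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); clustering is
seeded; SVD/eigendecompositions use deterministic sign conventions.

## Known limitations

- The anchor machinery assumes the reference covers the query's states;
  spots dominated by a type missing from the reference receive smeared
  scores rather than an "unknown" call.
- Batch correction is intentionally absent (stage is carried as
  metadata); the generator's batch effect defaults to zero.
- Max-label accuracy against the realized dominant type saturates near
  0.8 on the default mixed tissue because many spots' top two types are
  within multinomial sampling noise of each other; where the true
  dominant leads by ≥ 0.15, accuracy is ~0.9.
- The embedding's boundary cells (adaptive bandwidth widens at the ends
  of a 1-D manifold) can swap with their immediate neighbours; interior
  ordering is exact on noiseless gradients.
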