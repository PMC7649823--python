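# Methods

## The model

DiffGE scores *groups* of co-expressed genes, rather than individual
genes, for differential activity across the cells (or cell types) of a
single-cell RNA-seq experiment. The premise is that genes acting in one
pathway co-vary, so pooling their signal over the pathway's
protein-interaction scaffold suppresses the per-gene technical noise that
dominates scRNA-seq.

The pipeline has three stages.

1. **Gene clustering.** Filtered genes are partitioned into K clusters by
   expectation-maximization fitting of a Gaussian mixture to the gene
   expression profiles (cells as features), with diagonal covariances and
   k-means++ initialization. Genes are hard-assigned by maximum posterior
   responsibility; empty components are compacted away, so the effective
   K can be below the requested one.

2. **PPI matching.** Each cluster is intersected with an undirected
   protein-interaction network (STRING links dialect, combined scores
   0–1000). An interaction is kept iff both endpoints belong to the same
   cluster; cross-cluster edges are discarded, and genes absent from the
   network remain cluster members with no incident edges. Each undirected
   edge is counted once; counting both directions multiplies all
   activities by 2 uniformly, which provably leaves shares and entropies
   unchanged (asserted in the tests).

3. **Network entropy.** With expression normalized per sample to relative
   abundances e_si (each sample's vector sums to 1), an edge (i, j) gets
   weight W_ijs = e_si·e_sj, interpretable as the probability that both
   products are present together. Cluster k's activity in sample s is
   W_ks = Σ_(i,j)∈E_k W_ijs / n_k with n_k the member count. Activities
   become shares P_ks and each cluster is scored by the Shannon entropy
   E_k = −Σ_s P_ks ln P_ks (natural log, 0·ln 0 := 0). Clusters are
   ranked by descending E_k (ties: larger total activity, then lower
   index) and the top ⌈fraction·K⌉ (default fraction 0.10, minimum one
   cluster) are reported; every member gene of a selected cluster is a
   detected differential gene and carries its cluster's entropy as a
   per-gene score.

### The two normalization modes

The share definition P_ks = W_ks / Σ_k' W_k's normalizes **across
clusters within a sample** while the entropy sums **across samples**, so
Σ_s P_ks ≠ 1 in general. Both readings are implemented:

- `per_cell` (default): column normalization as written above. E_k then
  grows with both the evenness and the overall magnitude of the cluster's
  activity share; it is bounded by S/e rather than ln S.
- `per_cluster`: row normalization P_ks = W_ks / Σ_s' W_ks', making
  P_k· a probability distribution over samples with 0 ≤ E_k ≤ ln S,
  equality at uniform activity.

Neither mode is mathematically privileged here; the default follows the
share definition literally, and the alternative gives a proper
distribution with a clean entropy bound. Both are exposed as
`--entropy-mode`.

### A known limitation: the direction of the entropy signal

Selecting the *highest* entropy presumes differential groups are
high-entropy. In `per_cluster` mode the opposite holds by construction:
a cluster active uniformly across samples attains the ln S maximum,
whereas a cluster whose activity concentrates in one cell population has
a peaked distribution and strictly lower entropy. On planted-signal
simulations the differential block is therefore separated *at the bottom*
of the per_cluster ranking (a perfect, but inverted, signal), and
descending-top selection cannot recover it; the regression test
`TestPlantedSignalDirection` documents this behavior. In `per_cell` mode
the coupling across clusters makes the ranking track mean activity share,
which recovers strongly expressed differential blocks only when baseline
levels are comparable across groups. Users screening for
population-specific groups should inspect the full ranked table (the
bottom of the per_cluster ranking is the concentrated, population-specific
end) rather than relying on the top slice alone.

## Preprocessing

Raw TPM values are transformed to log2(TPM + 1); the log base and unit
pseudocount are configurable but fixed defaults. A gene is *expressed* in
a cell iff its value exceeds a threshold (default 0, i.e. any non-zero
read). Three filters run on exact fractions, never rounded percentages:

| filter | rule | default |
|---|---|---|
| zero | expressed in no cell | always |
| rare | expressed in < v% of cells (strict) | v = 10 |
| ubiquitous | expressed in ≥ (100−v)% of cells | v = 10 |

Filtering commutes with the log transform at threshold 0 (log2(x+1) > 0
iff x > 0; asserted in tests) and is idempotent.

## Key parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `v` | rare/ubiquitous percentage | 10 | standard informativeness cut for scRNA-seq |
| `expressed_threshold` | "expressed" cut (same units as matrix) | 0 | zero read = not expressed |
| `n_clusters` (K) | mixture components | max(2, n_genes/100) | top-10% selection then yields gene-group granularity of a few groups |
| `seed` | all EM randomness | 0 | full determinism |
| `tol`, `max_iter` | EM stopping | 1e-4, 300 | library defaults; non-convergence is flagged, not fatal |
| `min_score` | STRING confidence cut | 400 | STRING "medium confidence" |
| `entropy_mode` | share normalization axis | per_cell | literal reading of the share definition |
| `top_fraction` | selected share of clusters | 0.10 | ceil, minimum 1, so small K still selects |

Zero-activity samples (per_cell) or clusters (per_cluster) are excluded
from their normalization with a warning instead of erroring — dropout
makes them routine; an all-zero activity matrix is an error.

## Evaluation protocol

`precision_recall` compares a subset detection DE_subset against the
full-data detection DE_full: precision = |∩|/|DE_subset| (recorded as
missing when the subset detects nothing), recall = |∩|/|DE_full|.
`subset_experiment` runs the detector on all cells, then on seeded random
subsets of 10/30/50/70/90% of cells, 10 repeats each; subsampling is
stratified by cell type when labels are given (so a 10% subset cannot
lose a whole population; `stratify=False` disables this). Missing
precisions are excluded from per-fraction means and counted. Each
(fraction, repeat) draws from an independent, repeat-indexed seed stream,
so reports are exactly reproducible from one master seed.

`roc_auc` sweeps distinct score values descending (equal scores move as
one step, producing a diagonal segment), computes TPR/FPR against a
validation set within a gene universe, and integrates by the trapezoidal
rule; this equals the normalized Mann–Whitney U statistic, which the
tests verify by exhaustive pair counting. Per-gene scores for the ROC
are the gene's cluster entropy.

## Synthetic data

The generator plants exactly the structure the method assumes: genes in
co-expression blocks, cells in discrete types, differential blocks whose
mean shifts by `block_mean_shift` in one cell type (round-robin over
types), constant blocks with one mean everywhere, values max(0, mean +
Gaussian noise) on the log2-TPM scale directly, uniform random dropout
zeroing, and a PPI graph with dense within-block (0.3) and sparse
background (0.01) edges, all scored 900. Defaults: 5 blocks × 40 genes,
2 types × 60 cells, baseline means drawn U(1.5, 3.5) log2-TPM per block,
shift 2.0 (four noise SDs), noise SD 0.5, dropout 0.2. Everything is
drawn from one seed, bitwise-reproducibly.

What it does *not* emulate: negative-binomial count noise, library-size
variation, expression-dependent dropout, overlapping pathways, or hub
structure in the PPI graph. Passing tests therefore show the pipeline's
stages behave as specified on idealized block data, not that detection
rates transfer to real scRNA-seq experiments.

## Numerical choices

- Natural log throughout the entropy; −0.0 entropies are clamped to 0.
- Shares for zero-total rows/columns are 0, never NaN.
- Responsibility ties in EM break to the lowest component index;
  entropy-ranking ties break by larger total activity, then lower index.
- The TSV writers use a fixed `%.10g` float format, which is what makes
  repeated runs byte-identical.
- Pipeline refuses to run when under 1% of expression gene IDs occur in
  the PPI network (almost certainly an identifier-namespace mismatch).

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
200-gene × 120-cell simulations (GMM fits take milliseconds); the
stability protocol is 5 datasets × 51 pipeline runs. These sizes give
repeat-averaged metrics stable to a few percent while keeping the whole
suite fast.
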