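# Methods

`pvrsig` implements the computational arm of a fibrotic-membrane
transcriptomics study: building a ranked disease signature from bulk
RNA-seq of proliferative vitreoretinopathy (PVR) membranes versus
control tissue, screening a drug catalog for agents whose transcriptional
effects oppose that signature, scoring cell-type gene sets per sample,
and phenotyping imaging-mass-cytometry (IMC) single cells. This note
records the models, parameter choices, numerical conventions and known
limitations.

## Disease signature

**Differential expression.** The internal DE routine is a deliberately
simple two-group stand-in, not a negative-binomial GLM. Counts are
normalized by median-of-ratios size factors (per-sample median of
count-to-geometric-mean ratios over genes observed in every sample; if
no such gene exists the routine falls back to library-size scaling). The
reported effect is

    log2FC = log2((mean_norm_disease + 0.5) / (mean_norm_control + 0.5)),

with a 0.5 pseudocount so fold changes stay finite at zero means.
Significance comes from a Welch (unequal-variance) t-test on
`log2(normalized + 1)`, with Benjamini-Hochberg adjustment across the
genes actually tested. Genes with zero counts in all samples are
excluded from testing and carry `log2FC = 0`, `p = padj = 1`. This
approximation is adequate for the moderate-to-large planted effects the
synthetic benchmarks use; it has less power than a count-model fit for
small effects at low counts, and shrinkage of fold changes is not
implemented. Externally computed DE tables are accepted everywhere.

**DEG thresholds.** Differentially expressed genes require
`|log2FC| > 2` and `padj < 0.05`, with strict inequalities — boundary
values are excluded. Both thresholds are parameters.

**Ranking.** The signature orders all expressed genes ("expressed" =
nonzero count in at least one sample) by descending log2FC; score ties
break lexicographically by gene id so the ranking is independent of
input file order.

**Over-representation.** Gene-set over-representation uses the
upper-tail hypergeometric probability `P(X >= overlap)` with the
user-supplied universe; annotation collections are flat GMT inputs, and
no ontology-graph handling is attempted.

## Network filter

Signature genes are retained only with at least `min_degree` (default 1)
interactions *within the signature*: degree is computed on the subgraph
induced by the signature genes, since the screen asks which disease
genes corroborate each other, not how connected a gene is genome-wide.
Edges come from a STRING-style scored edge list; the default
`combined_score` threshold is 400 (STRING's "medium confidence"), both
configurable. Identifier matching is exact string equality — mapping
between symbol spaces is the caller's responsibility.

## Connectivity screen

**Statistic.** For a drug with downregulated gene set S and a ranking of
N genes with scores s_i, the running sum adds
`|s_i|^p / sum_{hits} |s|^p` at members and subtracts `1/(N - |S|)` at
non-members; the enrichment score ES is the signed maximal deviation.
The weight exponent p defaults to 1 (classic weighted GSEA); p = 0 gives
the unweighted form, whose |ES| equals the two-sample Kolmogorov-Smirnov
distance between hit and miss rank distributions (verified by an oracle
test). If all hit scores are exactly zero the weights degenerate and the
unweighted form is used. When the positive and negative extrema tie in
magnitude the positive one is reported; the tie is judged at 1e-9 so
float summation order cannot flip the sign (exact ties do occur, e.g.
when the miss step divides the hit weights evenly). The leading edge
contains members at or before the extremum for positive ES, after it for
negative ES.

**Null and calibration.** Because the screen has a single fixed ranking,
the null is gene-set permutation: ES values for `n_perm` (default 1000)
uniform random sets of the same size drawn from the ranked genes,
computed vectorized across permutations (the extremum is attained at a
hit, or just before one, so only those 2k candidates are evaluated per
permutation). The one-sided p-value counts same-sign null ES values at
least as extreme, with the +1 correction, so `p >= 1/(n_perm + 1)`.
NES = ES / mean(|null ES| of matching sign); this sign-split
normalization keeps NES comparable across set sizes. If no null ES of
the matching sign exists (never observed at default settings) the NES is
NaN. Down-set genes absent from the ranking are dropped silently and
`set_size` records the intersection; an empty intersection flags the
drug unscorable and excludes it from ranking.

**Ranking drugs.** p-values are BH-adjusted across all scorable drugs;
the table sorts by NES descending, ties by adjusted p then name. Only
downregulated drug sets are scored by default — the screen asks whether
drug-suppressed genes sit atop the disease ranking.

## Cell-type enrichment

Per-sample scores use the ssGSEA integral: rank the sample's genes by
expression (ties lexicographic), weight member genes at position i from
the top by `(N - i + 1)^alpha` (alpha default 0.25) normalized over
members, and sum `P_hit(i) - P_miss(i)` over all positions, where
P_miss is the uniform ECDF of non-members. The score depends only on
within-sample ranks, so it is invariant under monotone transformations
of expression. No cross-sample rescaling is applied; scores are pure
per-sample functions. The published 64-signature cell-type compendium,
per-type aggregation over multiple signatures, calibration curves and
spillover compensation of the xCell method are *not* reproduced —
signatures are user-supplied GMT sets, so absolute score magnitudes are
not comparable to published xCell scores.

Group comparison is a two-sided Mann-Whitney U test. With at most eight
samples per group the test enumerates all C(n1+n2, n1) group
assignments, handles ties by midranks, and defines the two-sided p-value
as the null probability of a U at least as far from n1·n2/2 as observed;
larger groups use the tie-corrected normal approximation.

## IMC phenotyping

**Normalization.** Each marker is divided by its 99th percentile
(configurable) across all cells and clipped to [0, 1]; all-zero markers
pass through with a warning. This is scale-invariant per marker.

**Clustering.** A PhenoGraph-style procedure: Euclidean k-nearest
neighbours (k default 15) on the normalized intensities, a graph over
all pairs of cells whose neighbourhoods overlap, edge weight =
sqrt(Jaccard overlap of the two neighbourhoods), then seeded Leiden
modularity optimization (resolution default 1.0). Two choices here were
made deliberately after examining the modularity landscape: restricting
edges to kNN pairs, or weighting by the raw Jaccard coefficient, leaves
a strong within-population geometric gradient in the graph, and
modularity maximization then shreds a single tight population into
spatial fragments (a measured 6-way split of two planted blobs scored
Q = 0.61 versus 0.50 for the true partition). The shared-neighbour edge
set plus the concave weight transform flatten that gradient, and planted
populations are then recovered exactly across seeds and noise levels.
Neighbour ties are broken by cell index after a seeded shuffle, so a
fixed seed yields one assignment regardless of input order; cluster ids
are relabelled 1..K by first appearance. The shared-neighbour graph is
denser than a kNN graph (O(n·k²) candidate edges), which is comfortable
at the cell counts this package targets (10³–10⁴ cells).

An arcsinh pre-transform is not applied for clustering; percentile
normalization already bounds the dynamic range, and the cofactor-based
transform in the source workflow belongs to its embedding step, which is
out of scope.

**Profiles, composition, gating.** Cluster profiles report per-cluster
marker means and z-scores of those means across clusters (z = 0 when the
across-cluster deviation is zero). Composition counts cells per
(cluster, entity), averages counts over each entity's samples, and
attributes a cluster to an entity when >= 80% (configurable) of its
cells carry that label, else "shared". Gating calls a cell positive when
its normalized intensity exceeds a threshold (default 0.5, a required
and logged parameter — the underlying study does not state its gating
rule); co-expression percentages are reported within the gated
population, and co-marker expressions support single markers and
AND/OR combinations judged at the same threshold.

## Synthetic data

The generators define the benchmark conditions:

- **Bulk counts.** Negative binomial with `var = mu + alpha·mu²`;
  baseline means log-uniform on [1, 1e4]; dispersion default 0.1 in the
  benchmarks (typical for bulk RNA-seq of tissue); a planted fraction of
  genes (10% in the benchmarks) has the disease-group mean multiplied by
  `2^effect` with a common effect (3.0), yielding up-regulated DEGs; two
  groups of 8 samples mirror a small clinical series.
- **Drug catalog.** One planted drug whose down-set holds
  `planted_overlap` (30) genes from the top 50 of the signature, plus 20
  decoys with uniform random down-sets of the same size; the planted
  drug always passes the organism/known-action/approved filters, a
  quarter of the decoys fail one filter each, and decoy targets are
  drawn from the top tenth of the ranking so decoys survive target
  mapping and exercise the screen.
- **Network.** Erdős–Rényi over non-orphan genes (edge probability 0.10
  over ~200 signature genes gives every non-orphan a degree ≫ 1);
  designated orphans have degree 0; scores uniform on [400, 1000).
- **Cells.** Gaussian populations around distinct marker-mean vectors,
  truncated at zero; noise SD 0.05 on a [0, 1]-normalized scale in the
  benchmarks (means differ by ~0.8–0.9, i.e. well-separated populations).

All generators are pure functions of (arguments, seed). What they do
*not* emulate: library-size and GC biases, batch effects, correlated
genes, dispersion trends, drug down-sets derived from real perturbation
profiles, scale-free interaction topology, or spatial structure and
marker spillover in IMC images. Passing benchmarks therefore demonstrate
correctness of the statistics and the plumbing under the stated models,
not performance on real tissue data.

## Reported study values

The source study's headline numbers (DEG counts of 3194/2639, xCell
score medians, NES values 1.58/1.37/1.31/1.27, IMC co-expression
percentages, 23 clusters) depend on external databases and raw data not
shipped here and on unstated algorithm variants; they are treated as
illustrative. The published NES values appear in one test only as inputs
to the drug-ranking order, never as expected outputs of this
implementation.

## Problem sizes

The shipped benchmarks use 2000 genes × 16 samples, 21 drugs × 1000
permutations, 100 screen replicates, 250–500 calibration runs and 200
cells — sizes chosen so the whole suite runs in well under a minute per
component on a single CPU while keeping Monte-Carlo bands tight enough
for the stated tolerances.
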