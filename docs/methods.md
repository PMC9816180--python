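# Methods

## Disease-gene scoring

Evidence sub-sources are binary gene memberships grouped into three
categories: genetics (gene-level GWAS associations by genomic proximity, eQTL
mapping, and per-cell-type functional-genomics hits), expression (per-cell
differential expression), and literature (curated disease gene sets).  Per
(gene, cell type) the category indicator is the logical OR over the
sub-sources applicable to that cell: expression and functional-genomics
sources are cell-specific, genetics (proximity/eQTL) and literature apply to
every cell type in which the gene is admissible.

The final score is `category_sum + diversification` with `diversification =
1 − G(indicator)` and `G` the unbiased Gini estimator
`G = [Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄)] · n/(n−1)`.  On 0/1 3-vectors this gives
diversification 0 / 0.5 / 1 for one / two / three categories, hence final
scores 1, 2.5 and 4 — a gene carried by several independent lines of evidence
outranks one hit many times within a single line.  The Gini vector is the
3-element per-category binary indicator, not per-sub-source counts; this is
the simplest reading consistent with summing 0/1 subcomponents, and a
count-based variant would only matter for genes hit by many sub-sources of
one category.  Genes whose only evidence anywhere is the proximity-only
genetics source are flagged `is_AD_gene = False`: genomic risk loci contain
several genes under linkage disequilibrium, and locus membership without
functional support does not identify the causal gene.  Functional-genomics
genetics evidence alone does confer the genetics category.  An all-zero
indicator makes the Gini undefined; callers treat the diversification as 0.
Ranking ties break lexicographically by gene symbol for reproducibility.

## Network assembly

Interaction sources carry per-edge confidence scores with source-specific
thresholds: PBA keeps PBS scores strictly below 1, the IntAct family keeps MI
scores strictly above 0.45, HIPPIE keeps scores at or above 0.73.  The
synaptic IntAct source enters only the excitatory and inhibitory neuron
networks.  A gene is expressed when at least two cells of the type have more
than one count; the admissible set is `expressed_disease ∪
(expressed_control ∩ DEG_down)`, so genes silenced by the disease remain
visible to the network.  PPI and TF→gene edges merge into one simple graph
per cell type over admissible genes only; self-loops are removed, parallel
edges collapse with concatenated source labels, and GRN direction is retained
purely as metadata — all community detection and distance computations treat
the graph as undirected.  Isolated admissible genes are dropped (they cannot
contribute to modules or distances), and no largest-component extraction is
performed: all components are modularized.

## Module detection

Walktrap (random-walk agglomerative clustering, walk length 4 — the
algorithm's standard default) is cut at maximum modularity.  Modules larger
than 500 genes are re-clustered on their induced subgraph, recursively;
children are named `parent_i` with 1-based indices ordered by descending
size.  An oversized module for which walktrap returns a single community is
kept as indivisible with a logged warning rather than force-split.
Enrichment in disease genes uses the one-sided Fisher exact test
(hypergeometric upper tail) with the network's own node set as universe, and
BH correction across the modules of each cell network separately (each
network is an independent analysis; a pooled variant would only tighten
thresholds uniformly).  Adjusted p < 0.05 defines a disease module.

## Multicellular graph and core modules

Each significant ligand–receptor pair contributes one edge between the module
containing the ligand in the producing cell and the module containing the
receptor in the receiving cell; a partner outside every disease module
(including genes absent from the network) maps to the cell's "other" node,
and pairs with neither partner in a disease module are dropped.  Parallel
pairs between the same node pair merge into one undirected edge whose weight
counts them (direction of signaling is collapsed).  Closeness is the classic
per-component form `CC(v) = (n_reachable−1)/Σ d(v,u)` on hop distances —
edge weights are annotation, not resistance; isolated nodes get 0.  Core
modules are disease modules with closeness at or above a quantile (default
0.5) of the disease-module closeness distribution *and* adjusted enrichment p
below 0.05 — a quantile rule rather than fixed cutoffs, since "high
centrality, high enrichment" is a quadrant, not a number.  The ≥-comparison
makes a lone disease module its own core.  Cell-type specificity of a gene is
its mean expression in one cell type divided by the sum across cell types
(rows sum to 1), computed from the disease-condition summaries.

## Drug modules and the proximity screen

A drug's signature is the union of the top 100 most up- and top 100 most
down-regulated genes.  The drug module is the target, the signature genes
present in the cell network, and the interior nodes of one shortest path from
each signature gene to the target (breadth-first, ties broken by the
lexicographically smallest path — a minimal, fully reproducible reading of
"connecting genes"; a Steiner-tree connector would be smaller but
non-unique).  Unreachable signature genes are dropped with a logged count;
modules under 10 genes are not screened.

Proximity to a core disease module T combines the average closest distance
`d_c(S,T) = mean_{s∈S'} min_{t∈T} d(s,t)` (S' = members with a reachable
target; empty S' skips the pair) with the best-match-average GO-BP similarity
`sim = [Σ_s max_t J + Σ_t max_s J]/(|S|+|T|)` over Jaccard similarities of
annotation sets (unannotated genes excluded; set-based Jaccard rather than
ontology-graph semantic similarity — a pluggable hook exists).  A plain sum
of the two is ill-posed (small distance is good, small similarity is bad), so
both are z-standardized against a shared null and combined as
`combined_z = z_distance + z_dissimilarity`; raw components are always
reported for audit.  The null draws random gene sets matched to the drug
module's degree sequence via log2-degree bins (bins under 10 candidates merge
with a neighbor) without replacement within a draw — degree matching avoids
the hub bias of uniform sampling.  Significance is the add-one empirical
p-value `(1 + #{null ≤ observed})/(n_perm + 1)` at α = 0.05 per (drug, core
module) pair; an optional BH across drugs is off by default.  With the
distance-to-T reduced to a per-node lookup vector the permutations are
vectorized, so 1000 permutations per pair cost milliseconds.

Tissue filtering removes candidates whose target carries one of the four HPA
specificity categories (Tissue/Group enriched/enhanced) for a non-brain
tissue; microglia candidates additionally tolerate lymphoid tissue, blood,
bone marrow and gallbladder, microglia being the brain's resident immune
population.  A candidate significant in both microglia and other networks is
judged under the more permissive microglia rule.

## Synthetic study conditions

The generator plants a stochastic block model per cell type: 300 genes in 5
blocks, within-block edge probability 0.25, between 0.01 — within-degree ≈ 15
versus between ≈ 2.4, comfortably above the community-detectability threshold
yet far from clique-like.  Two blocks are disease-enriched; their *member
genes are shared across cell types* while the other blocks are shuffled
independently.  This departs from fully independent assignments deliberately:
genetics and literature evidence apply to all cell types, so with independent
disease blocks nearly every gene would be "disease" in some cell type and the
global evidence sources would carry no enrichment signal; shared disease
blocks keep cross-cell evidence, ligand–receptor wiring and planted-drug
proximity coherent.  Evidence sub-sources (including a proximity-only
genetics source to exercise the exclusion rule) hit disease genes at rate
0.6 versus background 0.05 — strong but noisy enrichment.  Sixty
ligand–receptor pairs wire the disease blocks across all cell-type pairs
(one sixth of them to genes outside any disease module, populating the
"other" nodes).  Positive drugs (10) target disease-block genes, with 40
ranked signature genes per direction drawn 75% from the target's block and
25% from its one-hop halo; decoy drugs (90) target and modulate uniform
random genes.  GO annotations give each (cell, block) a 4-term pool from a
150-term vocabulary, each gene drawing 2 pool terms per cell type plus one
noise term, so co-module genes share terms above chance.  Confidence scores
are drawn inside the passing range of each source, with an extra 10% of edges
emitted below threshold (plus synaptic edges for non-neuron cells) so the
filters do real work.  Expression summaries mark six genes per cell type as
control-only, half of them downregulated DEGs, exercising both branches of
the admissibility rule; positive-drug targets receive brain-compatible
tissue categories, other genes a fixed category mix including non-brain- and
immune-specific labels.

What the generator does **not** emulate: realistic count distributions,
correlated evidence sources, hub-dominated scale-free interactomes,
direction-of-effect in drug signatures, or overlapping communities.  Passing
tests therefore demonstrate correctness and calibration of the pipeline's
logic under planted truth, not performance on real snRNA-seq-derived inputs.
A consequence of uniform decoy targeting is that decoys landing inside a
disease block are genuinely proximal and legitimately significant; discrimination
is measured by ranking (AUROC), and null calibration is measured separately on
degree-matched random modules, which are exact draws from the null.

## Numerical choices and limitations

Hop distances come from a cached all-pairs shortest-path matrix per network;
unreachable pairs are infinite and excluded per the rules above.  A null
component with zero variance yields z = 0 with a warning.  All randomness
flows from one integer seed (per-pair permutation seeds are derived
deterministically), and a run manifest with SHA-256 checksums of every output
table makes byte-reproducibility checkable.  Default problem sizes (300
genes × 6 cell types, 100 drugs, 1000 permutations) complete in about half a
minute on one CPU; they are the package's reference study conditions, and all
recovery and calibration claims in the test suite are made under them.
Known limitations: walktrap module numbering is size-ordered, not stable
across perturbed inputs; the GO similarity ignores the ontology graph; and
the screen reports association, not direction of effect (a significant drug
may mimic rather than revert the disease module).
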