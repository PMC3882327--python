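# Methods

This note records the models, the tunable parameters, the numerical
choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Differential calling

**Expression.** Input is a probe × sample matrix of signed log₂
tumour/normal ratios with a total probe→gene map.  Genes represented
by several probes are collapsed to the per-sample median
(missing-aware).  The default significance rule is mean-based: a
gene is significant when the mean of its collapsed values is ≥ +1.4
or ≤ −1.4 (inclusive; 2^1.4 ≈ 2.64-fold).  Per-sample screening
variants (`mode="any"`/`"all"`) are provided, but the mean rule is
the default because single-sample excursions at realistic noise
levels (σ ≈ 0.5 on the log₂ scale) would otherwise dominate the
calls.  The reported `log2_summary` is always the mean over all
non-missing samples.

**Methylation.** Input is a β-value matrix (fraction methylated,
[0,1]) with normal/disease labels.  Probe rows mapping to one gene
are collapsed by keeping the probe with the largest |Δβ|
(tie-breaks: smaller Mann–Whitney p, then lexicographic probe ID;
each choice is logged).  Δβ = mean(disease) − mean(normal), so
positive Δβ means tumour-elevated methylation; genes with fewer than
2 non-missing values in either group are excluded and logged.
Missing values are never imputed.

The per-gene test is the two-sided Mann–Whitney U: exact enumeration
when both groups have ≤ 8 values and the pooled sample is tie-free,
otherwise the normal approximation with tie and continuity
correction (both via `scipy.stats.mannwhitneyu`).  The permutation
test reuses one set of `n_perm = 1000` label permutations across all
genes, measures extremeness two-sidedly on |U − n₁n₂/2|, and applies
the add-one rule `perm_p = (1 + #extreme) / (1 + n_perm)` so p never
reaches 0.  Rows with missing values fall back to per-row
permutations on their non-missing samples.

**FDR.** q-values are Benjamini–Hochberg by default; a Storey
variant (π₀ at λ = 0.5) is available by flag.  `fdr_threshold`
returns the largest p whose q ≤ FDR (0.0 sentinel when nothing
qualifies).  One numerical subtlety matters at small samples: the U
statistic is discrete, so at n = 10+10 every maximally separated
gene carries the *same* most extreme p — which is then exactly the
returned cutoff.  A strict `p < cutoff` rule would discard the
entire passing set, so the comparison is inclusive when the cutoff
came from the internal q-value analysis (those genes satisfy q ≤ FDR
by construction) and strict when a cutoff is supplied externally.

Hyper/hypo classification intersects the FDR rule with the effect
filter: Δβ ≥ +0.25 (hyper) or ≤ −0.25 (hypo), boundaries inclusive.
The FDR analysis runs on all tested genes before the Δβ filter, so
the cutoff does not depend on effect direction.

## Annotation

The CpG flag is a manifest pass-through (unannotated genes are FALSE
with a warning).  The promoter window is −1500/+500 bp around the
TSS on the + strand and reflected ([tss−500, tss+1500]) on the −
strand, endpoints inclusive; the probe position falling inside the
window is the promoter criterion.  Coordinates stay 1-based
inclusive end to end — the only coordinate arithmetic in scope is
this inclusive window test, and a half-open internal representation
would add conversions with no consumer.  Transcription-factor status
propagates along is\_a ancestors only: a gene annotated to the
configured TF term or any of its descendants is a TF.

**Pathway significance score.**  Pathways carry one of three
classes with ranks s: lung cancer (3), other cancer (2), other (1).
For a gene, the highest-rank class containing it is chosen; with f =
pathways of that class containing the gene and F = pathways in the
class,

    PSS = ( log10( (f/F) · 100 · F^s ) )^s

clamped to 0 when f = 0 or the log argument ≤ 1.  The formula is
deliberately exposed as one small replaceable function: it preserves
monotonicity in f at fixed F and s, and the rank exponent makes
lung-cancer membership dominate.  PSS is min-max normalized across
each stage network's nodes (not globally across stages) before it
enters the node strength.

## Stage networks

The stage network holds every interaction incident to a significant
methylated gene: methylated–methylated, methylated–expressed, and
*missing links* to genes significant in neither way (the partner is
a *novel gene* and its significance is looked up in the other
stages).  Expressed–expressed edges are included by default
(`include_expr_edges`) to keep the expression context connected;
they can be dropped to restrict the network to the three methylated
categories.  Isolated significant genes remain as nodes.

Node strength is the mean of three features, each min-max normalized
within the stage network: betweenness centrality (pair-dependency
sum over unordered pairs, scaled by 2/((n−1)(n−2))), the local
clustering coefficient, and PSS.  A feature that is constant across
the network contributes 0 to every node.  Edge strength is a Wang
graph-based semantic similarity: each term's ancestor profile
carries S-values decaying by 0.8 per is\_a step (best path), term
similarity is the shared-profile mass over the total, and gene
similarity is the best-match average over the two term sets,
restricted to the biological\_process namespace by default.  A gene
with no term in the namespace contributes similarity 0.

## Subnetworks

A subnetwork is a connected gene set with ≥ 1 significant methylated
gene in which every edge used has edge strength ≥ the similarity
threshold (default 0.60).  The "every edge used" reading — rather
than all pairwise gene combinations — matches the growth algorithm,
which qualifies edges as it adds genes; an all-pairs rule would make
most subnetworks infeasible.  The score is

    strength = ( Σ node strength + Σ edge strength ) / k

with the edge sum over k−1 spanning edges: the recorded growth edges
for grown subnetworks, and the maximum-edge-strength spanning tree
of the induced qualifying subgraph for enumerated ones (Kruskal with
deterministic (−strength, sorted pair) ordering).

Greedy growth (`seed_and_expand`) starts from significant methylated
seeds in descending |Δβ| and repeatedly admits the qualifying-edge
neighbour with the highest node strength, entering over its
strongest qualifying edge to the current set.  Ties everywhere break
by higher Δβ for methylated candidates, then lexicographic gene ID,
so all outputs are deterministic.  Enumeration uses an ESU-style
search that produces every connected qualifying set exactly once
(sizes 2..5 by default; counts grow sharply past size 4).  Ranking
is by descending strength, ties by larger size then sorted gene
list.

**Cross-stage conservation.**  Per stage, the top-10 size-4
subnetworks are each extended greedily while their strength does not
decrease (cap 12 genes); the conserved set is the intersection of
the best extended subnetwork per stage.  "While strength does not
decrease" is this package's concrete stopping rule for
score-guided propagation; it can occasionally leave one low-strength
core member behind in a stage (the benchmark recovers the full
planted core in roughly 85-90% of seeded replicates), so
conserved-set recall is reported over seeds rather than asserted per
run.

**Hub profiles.**  A subnetwork's hub is its member with the highest
full-network degree (ties lexicographic).  Neighbour and member
counts are reported in four categories — lung cancer, other cancer,
signaling, metabolic+other — with each gene assigned once by
priority (lung > other cancer > signaling > rest).  Because the
pathway table carries only three classes, a class-`other` gene
counts as "signaling" when any of its pathway ids contains the token
"signaling"; this keeps the four-way profile computable from the
3-class vocabulary.

## Cross-stage comparison

Venn regions are exact exclusive intersections of 2–3 named gene
sets (counts always sum to the union).  Pattern strings record each
gene's per-stage state (`hyper/hypo/hyper` marks the mid-course
switch behaviour).  Cross-source network overlap defaults to Jaccard
× 100 per node class (methylation / expression / merged); because
published overlap tables rarely state their denominator, `first` and
`second` conventions are also available.

## Synthetic data generator

The generator emulates a staged 27k-style methylation cohort:

* β-values drawn from Beta(μ·φ, (1−μ)·φ) with concentration φ = 50
  and a bimodal baseline (low 0.1 / high 0.8) mimicking array
  bimodality; planted hyper (hypo) genes shift the disease mean by
  +δ (−δ), δ = 0.4 by default so planted effects clear the 0.25
  filter by ~5 standard errors at n = 10+10.
* 30 hyper + 15 hypo genes planted per stage, 10 stage-switch genes
  (baseline 0.5; hyper/hypo/hyper across three stages), and a
  conserved core of 7 genes hypermethylated in every stage.
* Expression log₂ ratios are N(0, 0.5) with 50 genes per stage at
  ±2; ten genes carry two probes to exercise collapse.
* The interaction set is a Barabási–Albert graph (attachment 2) over
  all 500 genes plus the core wired as a clique; a second
  "signaling" source tag covers the core, 40% of the remaining
  edges, and extra signaling-only edges, so cross-source overlap is
  exercised.
* The mini-ontology gives each core gene a shared leaf plus an own
  sibling leaf in a dedicated shallow subtree, which fixes pairwise
  core Wang similarity at ≈ 0.795 (≥ the 0.60 threshold);
  background genes draw 1–2 leaves from ten other subtrees, giving
  cross-subtree similarity ≈ 0.26 and same-subtree sibling
  similarity ≈ 0.59 — just below threshold, so the qualifying graph
  is sparse outside the core.  A molecular\_function branch holds
  the TF term used for TF flagging.
* Core genes sit in 3 of 5 lung-cancer pathways (maximal PSS);
  background genes populate other-cancer, signaling-named and
  metabolic pathways.

All files are written in the package's documented dialects — no
in-memory shortcut — and the same seed yields a byte-identical
bundle.

**What the benchmark shows and does not show.**  Passing the
recovery suite demonstrates that the pipeline's statistics and the
seed-and-expand machinery behave correctly under the generator's
assumptions: clean group labels, independent genes, beta-distributed
noise, a similarity-coherent planted module.  Real cohorts add
unequal and tiny group sizes per stage (as few as 2 normals),
probe-level artefacts, batch effects, correlated genes and
annotation incompleteness; none of these are modelled, so benchmark
sensitivity/FDR numbers do not transfer to real data.  The
stage-I-like small-sample regime is partially covered by the exact
U test and the permutation machinery, but at n = 2 vs 6 no gene can
reach q ≤ 0.01, mirroring the empty stage-IV result such cohorts
produce.

## Problem sizes and numerical notes

Default analyses run at 500 genes × 3 stages × 20 samples; the
recovery benchmark uses 10 seeded replicates and the null suite 20.
Betweenness is exact (no sampling).  Semantic similarities are
cached per ontology instance.  Subnetwork enumeration is exponential
in principle but runs on the sparse qualifying graph; the default
cap is size 4 for ranking and 5 for counting.  Degenerate inputs:
empty methylated lists yield an empty network with a warning; a
stage without size-4 subnetworks empties the conserved set with a
warning; constant genes give p = 1; all-missing genes are dropped
and logged.
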