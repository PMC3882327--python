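# epistage

Stage-wise differential DNA methylation and epigenetic subnetwork
analysis for tumour cohorts.

## The problem

In lung adenocarcinoma (and other staged cancers), promoter
methylation changes from clinical stage to stage: genes
hypermethylated early can flip to hypomethylation mid-course and
back, and the affected genes rarely act alone — they sit inside
protein-interaction neighbourhoods whose other members are
differentially expressed or silently co-regulated.  `epistage`
implements a systems-level workflow for this setting: it calls
significant methylation and expression changes per stage, embeds the
calls in stage-specific interaction networks, scores genes and
interactions with combined topological/biological features, mines
high-scoring subnetworks, and compares stages to find conserved
epigenetic modules.  It is written for computational biologists who
want the full workflow reproducible offline: a synthetic-data
generator with known ground truth stands in for cohort downloads.

## Method

Per stage, with normal and tumour groups:

* **Expression** (log₂ tumour/normal ratios): multi-probe genes are
  collapsed by the per-sample median; a gene is *significant
  expressed* when its mean ratio satisfies |log₂| ≥ 1.4 (fold change
  ≈ 2.6).
* **Methylation** (β-values in [0,1]): Δβ = mean β(tumour) − mean
  β(normal); a two-sided Mann–Whitney U test (exact for small
  groups) gives per-gene p, permutation resampling (1000 label
  shuffles) gives resampling p, and Benjamini–Hochberg q-values at
  1% FDR fix the p cutoff.  *Hypermethylated*: Δβ ≥ +0.25 with
  significant p; *hypomethylated*: Δβ ≤ −0.25.
* **Annotation**: CpG-island flag, promoter window −1500/+500 bp
  around the TSS (strand-reflected), transcription-factor status via
  GO is\_a ancestor propagation, chromosome profiles, and a pathway
  significance score
  `PSS = (log₁₀((f/F)·100·Fˢ))ˢ` with class rank s = 3 for lung
  cancer pathways, 2 for other cancer, 1 otherwise.
* **Network scoring**: the stage network contains every interaction
  incident to a significant methylated gene — including *missing
  links* to genes significant neither way, whose partners are
  flagged *novel genes* and followed across stages.  Node strength
  is the mean of min-max-normalized betweenness, clustering
  coefficient and PSS; edge strength is the Wang GO semantic
  similarity of the endpoints.
* **Subnetworks**: a subnetwork is a connected gene set with ≥ 1
  methylated gene whose edges all have semantic similarity ≥ 0.60,
  scored `(Σ node strength + Σ edge strength) / k` over its k genes
  and k−1 spanning edges.  Greedy seed-and-expand growth starts from
  top-|Δβ| methylated seeds; exhaustive enumeration covers sizes
  ≤ 5.  The top size-4 subnetworks of each stage are propagated
  (grown while their score does not decrease) and intersected across
  stages to yield the *conserved* module.

## Worked example

`examples/03_conserved_subnetwork.py` simulates a default cohort
(3 stages, 500 genes, 10 normal + 10 tumour samples per stage,
planted Δβ = 0.4 effects and a 7-gene conserved interaction core),
runs the full pipeline and prints:

```
stage  normal_samples  disease_samples  significant_genes  methylated_genes  hyper  hypo  novel_genes
    I              10               10                 50                62     47    15           77
   II              10               10                 50                62     37    25          109
  III              10               10                 50                62     47    15           94

top-ranked size-4 subnetwork per stage (score = (sum node strengths + sum edge strengths) / k):
  stage I: G0039,G0170,G0208,G0249  strength=1.317
  stage II: G0029,G0170,G0275,G0281  strength=1.088
  stage III: G0170,G0249,G0275,G0281  strength=1.093

conserved gene set across stages: ['G0029', 'G0039', 'G0170', 'G0208', 'G0249', 'G0275', 'G0281']
planted conserved core:            ['G0029', 'G0039', 'G0170', 'G0208', 'G0249', 'G0275', 'G0281']
```

Each stage's 62 methylated calls are the 47 + 15 (stage II: 37 + 25)
hyper/hypo split after the Δβ and FDR filters; the "novel genes" are
interaction partners significant in neither way in that stage.  The
conserved set — the intersection of the best propagated subnetwork
per stage — recovers the planted core exactly.

The other examples cover differential calling
(`01_simulate_and_call.py`), network scoring
(`02_score_stage_network.py`) and cross-stage Venn/pattern analysis
(`04_stage_patterns.py`).  A thin CLI mirrors the library:
`epistage simulate`, `epistage run --config run.yaml`,
`epistage report --out-dir out/`.

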