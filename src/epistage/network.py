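"""Per-stage interaction networks with node and edge scores.

A stage network contains every interaction incident to the stage's
significant methylated genes -- methylated-methylated edges,
methylated-expressed edges and "missing links" from a methylated
gene to a partner that is significant neither way (the partner is a
*novel gene* and is followed up across the other stages) -- plus,
optionally, expressed-expressed edges.

Node score ("node strength") is the mean of three per-stage min-max
normalized features: betweenness centrality (pair-dependency sum
over unordered pairs, normalized by 2/((n-1)(n-2)) for n >= 3),
local clustering coefficient, and the pathway significance score.
Edge score ("edge strength") is the Wang GO semantic similarity of
the endpoint genes, in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .datatypes import (
    InteractionSet,
    OntologyBundle,
    SignificantGeneRecord,
    StageCalls,
    normalize_pair,
)
from .annotation import PathwayScore, pathway_scores
from .semsim import DEFAULT_NAMESPACE, SemanticSimilarity

log = logging.getLogger(__name__)

ROLE_METHYLATED = "methylated"
ROLE_EXPRESSED = "expressed"
ROLE_NOVEL = "novel"

CAT_METH_METH = "meth-meth"
CAT_METH_EXPR = "meth-expr"
CAT_MISSING_LINK = "missing_link"
CAT_EXPR_EXPR = "expr-expr"


@dataclass
class NovelGeneRecord:
    """A gene pulled into a stage network only through missing links."""

    gene: str
    stage: str
    partners: set[str] = field(default_factory=set)  # methylated partners
    significant_in: set[str] = field(default_factory=set)  # other stages


@dataclass
class StageNetwork:
    """Scored undirected simple graph for one stage.

    Node attributes: ``role``, ``delta_beta`` (methylated nodes),
    ``betweenness``, ``clustering``, ``pss``, ``pss_norm``,
    ``node_strength``.  Edge attributes: ``category``,
    ``edge_strength``.
    """

    stage: str
    graph: nx.Graph

    @property
    def methylated(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_METHYLATED}

    @property
    def expressed(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_EXPRESSED}

    @property
    def novel(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_NOVEL}

    def node_strength(self, gene: str) -> float:
        return self.graph.nodes[gene]["node_strength"]

    def edge_strength(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["edge_strength"]

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": n,
                "role": d["role"],
                "betweenness": d.get("betweenness"),
                "clustering": d.get("clustering"),
                "pss_norm": d.get("pss_norm"),
                "node_strength": d.get("node_strength"),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["gene", "role", "betweenness", "clustering", "pss_norm", "node_strength"]
        )

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "geneA": a,
                "geneB": b,
                "category": d["category"],
                "edge_strength": d.get("edge_strength"),
            }
            for (a, b), d in sorted(
                (normalize_pair(a, b), d) for a, b, d in self.graph.edges(data=True)
            )
        ]
        return pd.DataFrame(rows, columns=["geneA", "geneB", "category", "edge_strength"])


def build_stage_network(
    calls: StageCalls,
    interactions: InteractionSet,
    include_expr_edges: bool = True,
) -> tuple[StageNetwork, list[NovelGeneRecord]]:
    """Induce the stage network from the interaction set.

    Edge categories: two significant methylated endpoints
    (meth-meth); methylated with significant expressed (meth-expr);
    methylated with a gene significant neither way (missing_link,
    the partner node gets the ``novel`` role).  Expressed-expressed
    edges are kept only when ``include_expr_edges``.  All
    significant genes appear as nodes even when isolated.
    """
    meth = calls.methylated_genes
    expr = calls.expressed_genes - meth
    db = calls.delta_beta_map()
    if not meth:
        log.warning("stage %s has no significant methylated genes", calls.stage)
    g = nx.Graph()
    for gene in sorted(meth):
        g.add_node(gene, role=ROLE_METHYLATED, delta_beta=db.get(gene))
    for gene in sorted(expr):
        g.add_node(gene, role=ROLE_EXPRESSED)
    novel: dict[str, NovelGeneRecord] = {}
    for a, b in interactions.edges:
        in_meth = (a in meth, b in meth)
        in_expr = (a in expr, b in expr)
        if all(in_meth):
            g.add_edge(a, b, category=CAT_METH_METH)
        elif any(in_meth) and any(in_expr):
            g.add_edge(a, b, category=CAT_METH_EXPR)
        elif any(in_meth):
            m, other = (a, b) if in_meth[0] else (b, a)
            if other not in g:
                g.add_node(other, role=ROLE_NOVEL)
            g.add_edge(m, other, category=CAT_MISSING_LINK)
            novel.setdefault(other, NovelGeneRecord(gene=other, stage=calls.stage))
            novel[other].partners.add(m)
        elif all(in_expr) and include_expr_edges:
            g.add_edge(a, b, category=CAT_EXPR_EXPR)
    return StageNetwork(stage=calls.stage, graph=g), [novel[k] for k in sorted(novel)]


def novel_gene_cross_stage(
    novel: Iterable[NovelGeneRecord], all_stage_calls: Mapping[str, StageCalls]
) -> pd.DataFrame:
    """For each novel gene, the other stages where it is significant."""
    rows = []
    for rec in novel:
        hits = {
            stage
            for stage, calls in all_stage_calls.items()
            if stage != rec.stage
            and (rec.gene in calls.methylated_genes or rec.gene in calls.expressed_genes)
        }
        rec.significant_in = hits
        rows.append(
            {
                "gene": rec.gene,
                "stage": rec.stage,
                "partners": ",".join(sorted(rec.partners)),
                "significant_in": ",".join(sorted(hits)),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "stage", "partners", "significant_in"])


def betweenness(graph: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Betweenness centrality: sum over unordered pairs {s,t}, s != v != t,
    of sigma_st(v)/sigma_st; pairs in different components contribute 0.

    With ``normalized`` the raw sum is scaled by 2/((n-1)(n-2)) for
    n >= 3 (0 for smaller graphs).
    """
    return nx.betweenness_centrality(graph, normalized=normalized)


def clustering_coefficient(graph: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient; 0 for degree < 2."""
    return nx.clustering(graph)


def _minmax(values: dict[str, float]) -> dict[str, float]:
    """Min-max scale to [0, 1]; a constant feature contributes 0 everywhere."""
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def score_network(
    net: StageNetwork,
    pathways: pd.DataFrame,
    ontology: OntologyBundle,
    namespace: str | None = DEFAULT_NAMESPACE,
    sim: SemanticSimilarity | None = None,
) -> StageNetwork:
    """Attach betweenness, clustering, PSS, node strength and edge strength.

    The three node features are min-max normalized within this stage
    network before averaging; a constant feature contributes 0 to
    every node.  Edge strength is the Wang gene similarity of the
    endpoints (0 when either endpoint has no term in the namespace).
    """
    g = net.graph
    bet = betweenness(g, normalized=True)
    clust = clustering_coefficient(g)
    scores: dict[str, PathwayScore] = pathway_scores(g.nodes, pathways)
    pss_raw = {n: scores[n].pss for n in g.nodes}
    bet_n, clust_n, pss_n = _minmax(bet), _minmax(clust), _minmax(pss_raw)
    for n in g.nodes:
        g.nodes[n]["betweenness"] = bet[n]
        g.nodes[n]["clustering"] = clust[n]
        g.nodes[n]["pss"] = pss_raw[n]
        g.nodes[n]["pss_norm"] = pss_n[n]
        g.nodes[n]["node_strength"] = (bet_n[n] + clust_n[n] + pss_n[n]) / 3.0
    if sim is None:
        sim = SemanticSimilarity(ontology, namespace=namespace)
    for a, b in g.edges:
        g.edges[a, b]["edge_strength"] = sim.gene_similarity(a, b)
    return net


def edge_strength(
    gene_a: str,
    gene_b: str,
    ontology: OntologyBundle,
    namespace: str | None = DEFAULT_NAMESPACE,
) -> float:
    """Wang semantic similarity of two genes (symmetric, in [0, 1])."""
    return SemanticSimilarity(ontology, namespace=namespace).gene_similarity(
        gene_a, gene_b
    )


def node_strengths(net: StageNetwork) -> dict[str, float]:
    return {n: d["node_strength"] for n, d in net.graph.nodes(data=True)}
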