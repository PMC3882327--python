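"""Seed-and-expand mining and scoring of epigenetic subnetworks.

A *subnetwork* is a connected gene set containing at least one
significant methylated gene in which every edge used has semantic
edge strength >= the similarity threshold (default 0.60).  Its score
is

    strength = ( sum node_strength + sum edge_strength ) / k

with the edge sum running over the k-1 retained spanning edges: the
growth edges for grown subnetworks, or the maximum-edge-strength
spanning tree of the induced qualifying subgraph for enumerated
ones.

Discovery is greedy: seeds are the significant methylated genes in
descending |delta-beta|; at each step the qualifying-edge neighbor
with the highest node strength joins, entering over its strongest
qualifying edge to the current set.  Ties are broken by higher
delta-beta for methylated candidates, then lexicographic gene ID,
so results are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .datatypes import ValidationError, normalize_pair
from .network import ROLE_METHYLATED, StageNetwork

log = logging.getLogger(__name__)

SIM_THRESHOLD = 0.60
MAX_SIZE = 5
CATEGORY_ORDER = ("lung_cancer", "other_cancer", "signaling", "metabolic_other")


@dataclass
class Subnetwork:
    """A scored connected gene set inside one stage network."""

    stage: str
    genes: tuple[str, ...]  # insertion order
    seed: str
    strength: float
    retained_edges: tuple[tuple[str, str], ...]
    pathway_profile: dict[str, int] = field(default_factory=dict)
    hub: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _qualifying_graph(net: StageNetwork, sim_threshold: float) -> nx.Graph:
    """Subgraph of edges whose edge strength reaches the threshold."""
    q = nx.Graph()
    q.add_nodes_from(net.graph.nodes(data=True))
    for a, b, d in net.graph.edges(data=True):
        if d.get("edge_strength", 0.0) >= sim_threshold:
            q.add_edge(a, b, **d)
    return q


def _max_spanning_edges(
    genes: frozenset[str], graph: nx.Graph
) -> tuple[tuple[str, str], ...] | None:
    """Maximum-edge-strength spanning tree of the induced subgraph.

    Deterministic Kruskal: edges sorted by (-strength, pair).
    Returns None when the induced subgraph is disconnected.
    """
    sub = graph.subgraph(genes)
    if len(genes) == 1:
        return ()
    if sub.number_of_edges() < len(genes) - 1 or not nx.is_connected(sub):
        return None
    edges = sorted(
        ((d["edge_strength"], normalize_pair(a, b)) for a, b, d in sub.edges(data=True)),
        key=lambda e: (-e[0], e[1]),
    )
    parent = {g: g for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str]] = []
    for _, (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b))
            if len(chosen) == len(genes) - 1:
                break
    return tuple(chosen)


def subnetwork_strength(
    genes: Iterable[str],
    retained_edges: Iterable[tuple[str, str]],
    net: StageNetwork,
) -> float:
    """(sum of node strengths + sum of retained edge strengths) / k."""
    genes = list(genes)
    if not genes:
        raise ValidationError("empty subnetwork")
    node_sum = sum(net.node_strength(g) for g in genes)
    edge_sum = sum(net.edge_strength(a, b) for a, b in retained_edges)
    return (node_sum + edge_sum) / len(genes)


def _validate(sub: Subnetwork, net: StageNetwork, sim_threshold: float) -> Subnetwork:
    """Check the structural invariants of a produced subnetwork."""
    meth = net.methylated
    if not set(sub.genes) & meth:
        raise ValidationError(f"subnetwork {sub.genes} lacks a methylated gene")
    span = nx.Graph(sub.retained_edges)
    span.add_nodes_from(sub.genes)
    if sub.size > 1 and not nx.is_connected(span):
        raise ValidationError(f"subnetwork {sub.genes} not connected by retained edges")
    for a, b in sub.retained_edges:
        if net.edge_strength(a, b) < sim_threshold:
            raise ValidationError(f"retained edge ({a},{b}) below similarity threshold")
    return sub


def _candidate_key(gene: str, net: StageNetwork) -> tuple:
    """Sort key: highest node strength, then higher delta-beta, then ID."""
    d = net.graph.nodes[gene]
    db = d.get("delta_beta") if d.get("role") == ROLE_METHYLATED else None
    return (-d["node_strength"], -(db if db is not None else float("-inf")), gene)


def seed_and_expand(
    net: StageNetwork,
    seed: str,
    target_size: int,
    sim_threshold: float = SIM_THRESHOLD,
    qualifying: nx.Graph | None = None,
) -> Subnetwork:
    """Greedy growth from a seed gene.

    At each step all qualifying-edge neighbors of the current set are
    candidates; the one with the highest node strength joins over its
    strongest qualifying edge to the set.  Growth stops at
    ``target_size`` or when no candidate qualifies.
    """
    if seed not in net.graph:
        raise ValidationError(f"seed {seed!r} not in stage network")
    q = qualifying if qualifying is not None else _qualifying_graph(net, sim_threshold)
    genes: list[str] = [seed]
    in_set = {seed}
    retained: list[tuple[str, str]] = []
    while len(genes) < target_size:
        candidates = {
            nbr for g in genes for nbr in q.neighbors(g) if nbr not in in_set
        }
        if not candidates:
            break
        nxt = min(candidates, key=lambda c: _candidate_key(c, net))
        # enter over the strongest qualifying edge to the current set
        entry = max(
            (e for e in ((g, nxt) for g in genes) if q.has_edge(*e)),
            key=lambda e: (q.edges[e]["edge_strength"], normalize_pair(*e)),
        )
        genes.append(nxt)
        in_set.add(nxt)
        retained.append(normalize_pair(*entry))
    sub = Subnetwork(
        stage=net.stage,
        genes=tuple(genes),
        seed=seed,
        strength=subnetwork_strength(genes, retained, net),
        retained_edges=tuple(retained),
    )
    return _validate(sub, net, sim_threshold)


def enumerate_subnetworks(
    net: StageNetwork,
    max_size: int = MAX_SIZE,
    sim_threshold: float = SIM_THRESHOLD,
) -> list[Subnetwork]:
    """All connected gene sets of size 2..max_size with >= 1 methylated gene.

    Connectivity is over qualifying edges only; each gene set is
    reported once (deduplicated), scored via its maximum-strength
    spanning tree, and returned ranked.
    """
    if max_size < 2:
        raise ValidationError("max_size must be >= 2")
    q = _qualifying_graph(net, sim_threshold)
    meth = net.methylated
    found: set[frozenset[str]] = set()
    order = {n: i for i, n in enumerate(sorted(q.nodes))}

    # ESU-style enumeration rooted at each node's minimum member: every
    # connected set is produced exactly once.
    def extend(sub: set[str], ext: list[str], closed: set[str], root: str) -> None:
        if len(sub) >= 2 and sub & meth:
            found.add(frozenset(sub))
        if len(sub) == max_size:
            return
        for i, w in enumerate(ext):
            fresh = [
                u
                for u in q.neighbors(w)
                if order[u] > order[root] and u not in closed
            ]
            extend(
                sub | {w},
                ext[i + 1 :] + sorted(fresh),
                closed | set(fresh) | {w},
                root,
            )

    for node in sorted(q.nodes):
        ext0 = sorted(u for u in q.neighbors(node) if order[u] > order[node])
        extend({node}, ext0, {node, *ext0}, node)

    subs: list[Subnetwork] = []
    for genes in found:
        span = _max_spanning_edges(genes, q)
        if span is None:
            continue
        ordered = tuple(sorted(genes))
        seed = _best_seed(genes, net)
        subs.append(
            Subnetwork(
                stage=net.stage,
                genes=ordered,
                seed=seed,
                strength=subnetwork_strength(genes, span, net),
                retained_edges=span,
            )
        )
    for s in subs:
        _validate(s, net, sim_threshold)
    return rank_subnetworks(subs)


def _best_seed(genes: frozenset[str], net: StageNetwork) -> str:
    """Representative seed: methylated member with highest |delta-beta|."""
    meth = [g for g in genes if net.graph.nodes[g].get("role") == ROLE_METHYLATED]
    pool = meth or sorted(genes)
    return min(
        pool,
        key=lambda g: (
            -abs(net.graph.nodes[g].get("delta_beta") or 0.0),
            g,
        ),
    )


def rank_subnetworks(subs: Iterable[Subnetwork]) -> list[Subnetwork]:
    """Descending strength; ties by larger size then sorted gene list."""
    return sorted(
        subs, key=lambda s: (-s.strength, -s.size, tuple(sorted(s.genes)))
    )


def discover_subnetworks(
    net: StageNetwork,
    target_size: int = 4,
    sim_threshold: float = SIM_THRESHOLD,
) -> list[Subnetwork]:
    """Seeded greedy discovery: one subnetwork per methylated seed.

    Seeds are all significant methylated genes in descending
    |delta-beta| (ties lexicographic); duplicated gene sets keep the
    first (highest-seed-rank) occurrence.
    """
    q = _qualifying_graph(net, sim_threshold)
    seeds = sorted(
        net.methylated,
        key=lambda g: (-abs(net.graph.nodes[g].get("delta_beta") or 0.0), g),
    )
    seen: set[frozenset[str]] = set()
    out: list[Subnetwork] = []
    for seed in seeds:
        sub = seed_and_expand(net, seed, target_size, sim_threshold, qualifying=q)
        if sub.gene_set not in seen:
            seen.add(sub.gene_set)
            out.append(sub)
    return rank_subnetworks(out)


def _extend_while_non_decreasing(
    sub: Subnetwork,
    net: StageNetwork,
    q: nx.Graph,
    max_size: int,
) -> Subnetwork:
    """Grow a subnetwork while its strength does not decrease."""
    genes = list(sub.genes)
    retained = list(sub.retained_edges)
    strength = sub.strength
    while len(genes) < max_size:
        candidates = {n for g in genes for n in q.neighbors(g) if n not in genes}
        if not candidates:
            break
        nxt = min(candidates, key=lambda c: _candidate_key(c, net))
        entry = max(
            (e for e in ((g, nxt) for g in genes) if q.has_edge(*e)),
            key=lambda e: (q.edges[e]["edge_strength"], normalize_pair(*e)),
        )
        new_strength = subnetwork_strength(
            genes + [nxt], retained + [normalize_pair(*entry)], net
        )
        if new_strength < strength:
            break
        genes.append(nxt)
        retained.append(normalize_pair(*entry))
        strength = new_strength
    return Subnetwork(
        stage=sub.stage,
        genes=tuple(genes),
        seed=sub.seed,
        strength=strength,
        retained_edges=tuple(retained),
    )


def propagate_conserved(
    stage_networks: Mapping[str, StageNetwork],
    top_k_size4: int = 10,
    max_size: int = 12,
    sim_threshold: float = SIM_THRESHOLD,
) -> tuple[set[str], dict[str, Subnetwork]]:
    """Cross-stage conserved gene set from propagated size-4 subnetworks.

    Per stage, the top-k enumerated size-4 subnetworks are each
    extended greedily while their strength does not decrease (up to
    ``max_size``); the best extended subnetwork per stage is kept
    and the conserved set is the intersection of those gene sets.
    A stage without any size-4 subnetwork empties the conserved set
    with a warning.
    """
    if len(stage_networks) < 2:
        raise ValidationError("need at least two stage networks")
    best_per_stage: dict[str, Subnetwork] = {}
    for stage, net in stage_networks.items():
        all_subs = enumerate_subnetworks(net, max_size=4, sim_threshold=sim_threshold)
        size4 = [s for s in all_subs if s.size == 4][:top_k_size4]
        if not size4:
            log.warning("stage %s has no size-4 subnetwork; conserved set empty", stage)
            return set(), {}
        q = _qualifying_graph(net, sim_threshold)
        extended = [
            _extend_while_non_decreasing(s, net, q, max_size) for s in size4
        ]
        best_per_stage[stage] = rank_subnetworks(extended)[0]
    conserved = set.intersection(
        *(set(s.genes) for s in best_per_stage.values())
    )
    supporting = {
        stage: sub
        for stage, sub in best_per_stage.items()
        if conserved <= set(sub.genes)
    }
    return conserved, supporting


# ---------------------------------------------------------------------------
# hub profile


def _pathway_category(gene: str, pathways: pd.DataFrame) -> str:
    """Single Step-D category for a gene (lung > cancer > signaling > rest).

    A gene of class ``other`` counts as ``signaling`` when any of
    its pathway ids contains the token "signaling".
    """
    rows = pathways[pathways["gene"] == gene]
    if (rows["class"] == "lung_cancer").any():
        return "lung_cancer"
    if (rows["class"] == "other_cancer").any():
        return "other_cancer"
    ids = rows.loc[rows["class"] == "other", "pathway_id"].str.lower()
    if ids.str.contains("signaling").any():
        return "signaling"
    return "metabolic_other"


def hub_profile(
    sub: Subnetwork, net: StageNetwork, pathways: pd.DataFrame
) -> tuple[str, dict[str, int]]:
    """Hub gene of a subnetwork and its full-network neighbor classes.

    The hub is the member with the highest degree in the full stage
    network (ties lexicographic); each of its neighbors is counted
    once, in its highest-priority pathway category, so the counts
    sum to the hub degree.
    """
    g = net.graph
    hub = min(sub.genes, key=lambda n: (-g.degree(n), n))
    counts = {c: 0 for c in CATEGORY_ORDER}
    for nbr in g.neighbors(hub):
        counts[_pathway_category(nbr, pathways)] += 1
    sub.hub = hub
    return hub, counts


def pathway_profile(sub: Subnetwork, pathways: pd.DataFrame) -> dict[str, int]:
    """Member counts per Step-D pathway category."""
    counts = {c: 0 for c in CATEGORY_ORDER}
    for gene in sub.genes:
        counts[_pathway_category(gene, pathways)] += 1
    sub.pathway_profile = counts
    return counts


def subnetworks_table(subs: list[Subnetwork], net: StageNetwork, pathways: pd.DataFrame) -> pd.DataFrame:
    """Flat `subnetworks_<stage>.tsv` layout."""
    rows = []
    for rank, sub in enumerate(subs, start=1):
        hub, _ = hub_profile(sub, net, pathways)
        profile = pathway_profile(sub, pathways)
        rows.append(
            {
                "rank": rank,
                "size": sub.size,
                "strength": sub.strength,
                "seed": sub.seed,
                "genes": ",".join(sub.genes),
                "hub": hub,
                "class_profile": "/".join(str(profile[c]) for c in CATEGORY_ORDER),
            }
        )
    return pd.DataFrame(
        rows, columns=["rank", "size", "strength", "seed", "genes", "hub", "class_profile"]
    )
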