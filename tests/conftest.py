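"""Shared fixtures: toy ontologies, hand-scored networks, small bundles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epistage.datatypes import MethylationDataset, OntologyBundle
from epistage.network import (
    ROLE_EXPRESSED,
    ROLE_METHYLATED,
    ROLE_NOVEL,
    StageNetwork,
)
from epistage.simulate import SimulationConfig, simulate_bundle, load_bundle


# ---------------------------------------------------------------------------
# oracles (independent brute-force implementations used only by tests)


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Raw betweenness by exhaustive BFS path enumeration (unordered pairs)."""
    out = {v: 0.0 for v in graph}
    nodes = sorted(graph)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / sigma
    return out


def clustering_oracle(graph: nx.Graph) -> dict:
    """Local clustering by explicit neighbour-pair edge counting."""
    out = {}
    for v in graph:
        nbrs = list(graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if graph.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(pooled)
    m = len(y)

    def u_stat(idx_y):
        yv = [pooled[i] for i in idx_y]
        xv = [pooled[i] for i in range(n) if i not in set(idx_y)]
        return sum(1.0 if b > a else 0.5 if b == a else 0.0 for b in yv for a in xv)

    obs = u_stat(tuple(range(n - m, n)))
    center = (n - m) * m / 2.0
    total = more = 0
    for idx in itertools.combinations(range(n), m):
        total += 1
        if abs(u_stat(idx) - center) >= abs(obs - center) - 1e-12:
            more += 1
    return more / total


def make_scored_network(
    edges,
    node_strength,
    edge_strength,
    methylated,
    stage="I",
    delta_beta=None,
    expressed=(),
) -> StageNetwork:
    """StageNetwork with hand-assigned scores (bypasses the scoring step)."""
    g = nx.Graph()
    for n, s in node_strength.items():
        if n in methylated:
            role = ROLE_METHYLATED
        elif n in set(expressed):
            role = ROLE_EXPRESSED
        else:
            role = ROLE_NOVEL
        g.add_node(
            n,
            role=role,
            node_strength=s,
            delta_beta=(delta_beta or {}).get(n),
        )
    for (a, b), es in edge_strength.items():
        g.add_edge(a, b, category="meth-meth", edge_strength=es)
    for a, b in edges:
        if not g.has_edge(a, b):
            g.add_edge(a, b, category="meth-meth", edge_strength=0.0)
    return StageNetwork(stage=stage, graph=g)


def random_scored_network(rng: np.random.Generator, n_nodes: int, p: float = 0.5):
    """Seeded random network with random scores; >=1 methylated node."""
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31 - 1)))
    nodes = [f"N{i}" for i in range(n_nodes)]
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    n_meth = max(1, int(rng.integers(1, n_nodes + 1)))
    meth = set(rng.choice(nodes, size=n_meth, replace=False))
    ns = {n: float(rng.random()) for n in nodes}
    es = {(a, b): float(rng.random()) for a, b in g.edges}
    db = {n: float(rng.uniform(-0.6, 0.6)) for n in meth}
    return make_scored_network(list(g.edges), ns, es, meth, delta_beta=db)


def make_meth_dataset(values: dict, groups: dict, stage: str = "I") -> MethylationDataset:
    """MethylationDataset from {row: [sample values]} and {sample: group}."""
    samples = list(groups)
    beta = pd.DataFrame(values, index=samples).T
    return MethylationDataset(stage=stage, beta=beta, group=pd.Series(groups))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def toy_ontology() -> OntologyBundle:
    """Two BP subtrees under one root plus an MF branch with a TF term.

    Layout (child -> parent):
        leaf_a1, leaf_a2 -> parent_a -> root
        leaf_b1          -> parent_b -> root
        tf_child -> EP:0003700 -> mf_root
    """
    dag = nx.DiGraph()
    edges = [
        ("parent_a", "root"),
        ("parent_b", "root"),
        ("leaf_a1", "parent_a"),
        ("leaf_a2", "parent_a"),
        ("leaf_b1", "parent_b"),
        ("EP:0003700", "mf_root"),
        ("tf_child", "EP:0003700"),
    ]
    dag.add_edges_from(edges)
    ns = {t: "biological_process" for t in dag.nodes}
    for t in ("mf_root", "EP:0003700", "tf_child"):
        ns[t] = "molecular_function"
    gene_terms = {
        "GA": {"leaf_a1"},
        "GB": {"leaf_a2"},
        "GC": {"leaf_b1"},
        "GD": {"leaf_a1"},
        "TF1": {"EP:0003700"},
        "TF2": {"tf_child"},
        "ROOTY1": {"root"},
        "ROOTY2": {"parent_b"},
    }
    return OntologyBundle(dag=dag, namespaces=ns, gene_terms=gene_terms)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Down-scaled study conditions for fast end-to-end tests."""
    return SimulationConfig(
        n_genes=120,
        n_hyper=8,
        n_hypo=4,
        n_switch=4,
        n_expressed=15,
        core_size=5,
        n_subtrees=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths, truth = simulate_bundle(small_config, out)
    return paths, truth


@pytest.fixture(scope="session")
def small_inputs(small_bundle):
    paths, truth = small_bundle
    return load_bundle(paths), truth
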