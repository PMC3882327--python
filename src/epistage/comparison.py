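"""Cross-stage set logic and cross-source network overlap.

Venn regions over per-stage significant gene sets, per-gene
hyper/hypo pattern strings across stages (e.g. ``hyper/hypo/hyper``
for a methylation switch in the middle stage), and the node-set
overlap between networks built from two interaction sources for the
same stage.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .datatypes import StageCalls, ValidationError
from .network import ROLE_EXPRESSED, ROLE_METHYLATED, StageNetwork, normalize_pair


def venn_regions(
    stage_sets: Mapping[str, set[str]],
) -> tuple[dict[tuple[str, ...], int], dict[tuple[str, ...], set[str]]]:
    """Disjoint Venn regions of 2-3 named gene sets.

    A region key is the sorted tuple of set names whose exclusive
    intersection it is; counts sum to the union size.
    """
    names = sorted(stage_sets)
    if not 2 <= len(names) <= 3:
        raise ValidationError("venn_regions expects 2 or 3 named sets")
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(stage_sets[n] for n in combo))
            outside = set.union(
                set(), *(stage_sets[n] for n in names if n not in combo)
            )
            regions[combo] = inside - outside
    counts = {k: len(v) for k, v in regions.items()}
    return counts, regions


def pattern_switches(
    all_stage_calls: Mapping[str, StageCalls],
    stages: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene methylation state strings across stages.

    State per stage is ``hyper``, ``hypo`` or ``absent``; the
    pattern is the '/'-joined string in stage order.  Returns the
    per-gene table and the per-pattern summary counts.
    """
    stages = list(stages) if stages is not None else sorted(all_stage_calls)
    if len(stages) < 2:
        raise ValidationError("pattern_switches needs >= 2 stages")
    state: dict[str, dict[str, str]] = {}
    for stage in stages:
        calls = all_stage_calls[stage]
        for rec in calls.hyper + calls.hypo:
            state.setdefault(rec.gene, {})[stage] = rec.kind
    rows = []
    for gene in sorted(state):
        states = [state[gene].get(s, "absent") for s in stages]
        rows.append({"gene": gene, **dict(zip(stages, states)), "pattern": "/".join(states)})
    df = pd.DataFrame(rows, columns=["gene", *stages, "pattern"])
    summary = (
        df["pattern"].value_counts().sort_index()
        if not df.empty
        else pd.Series(dtype=int)
    )
    return df, summary


def network_source_overlap(
    net_a: StageNetwork,
    net_b: StageNetwork,
    denominator: str = "union",
) -> pd.DataFrame:
    """Percent node-set overlap of two same-stage networks by node class.

    Classes: methylation nodes, expression nodes and the merged
    (all-node) sets.  The default convention is Jaccard
    (|A&B|/|A|B| x 100); ``denominator`` may instead be ``first`` or
    ``second``.  A shared-edge count is reported alongside.
    """
    if denominator not in {"union", "first", "second"}:
        raise ValidationError(f"unknown denominator convention {denominator!r}")

    def pct(a: set[str], b: set[str]) -> float:
        if denominator == "union":
            den = len(a | b)
        elif denominator == "first":
            den = len(a)
        else:
            den = len(b)
        return 100.0 * len(a & b) / den if den else 0.0

    edges_a = {normalize_pair(u, v) for u, v in net_a.graph.edges}
    edges_b = {normalize_pair(u, v) for u, v in net_b.graph.edges}
    classes = {
        "methylation": (net_a.methylated, net_b.methylated),
        "expression": (net_a.expressed, net_b.expressed),
        "merged": (set(net_a.graph.nodes), set(net_b.graph.nodes)),
    }
    rows = [
        {
            "node_class": name,
            "overlap_pct": pct(a, b),
            "n_first": len(a),
            "n_second": len(b),
            "shared_edges": len(edges_a & edges_b),
        }
        for name, (a, b) in classes.items()
    ]
    return pd.DataFrame(rows, columns=["node_class", "overlap_pct", "n_first", "n_second", "shared_edges"])


def venn_table(counts: Mapping[tuple[str, ...], int]) -> pd.DataFrame:
    rows = [
        {"region": "&".join(k), "count": v} for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["region", "count"])
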