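"""Shared data model for the stage-wise epigenetic analysis pipeline.

Each clinical stage (I--IV) of a tumour cohort is treated as an
independent normal-vs-disease dataset.  Methylation is carried as
beta-values (fraction methylated, in [0, 1]); expression as signed
log2 tumour/normal ratios.  Gene identifiers are case-preserved
symbols and matching across tables is exact-string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")
NORMAL = "normal"
DISEASE = "disease"

PATHWAY_CLASSES = ("lung_cancer", "other_cancer", "other")
#: Class rank used by the pathway significance score: lung cancer
#: pathways dominate other cancer pathways, which dominate the rest.
CLASS_RANK = {"lung_cancer": 3, "other_cancer": 2, "other": 1}


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class MethylationDataset:
    """Beta-value matrix for one stage with normal/disease labels.

    ``beta`` is a (row x sample) DataFrame; rows are probes until
    :func:`epistage.differential.collapse_probes_methylation` maps
    them to genes (``probe_to_gene`` is then consumed), after which
    rows are unique gene symbols.  Missing values stay missing; they
    are excluded per gene at test time, never imputed.
    """

    stage: str
    beta: pd.DataFrame
    group: pd.Series  # sample -> {normal, disease}
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage label {self.stage!r}")
        if not self.beta.columns.is_unique:
            dup = self.beta.columns[self.beta.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample column {dup!r}")
        if not self.beta.index.is_unique and self.probe_to_gene is None:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValidationError(f"duplicated gene row {dup!r}")
        bad = set(self.group.unique()) - {NORMAL, DISEASE}
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}")
        missing = [s for s in self.beta.columns if s not in self.group.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = (vals < 0.0) | (vals > 1.0)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise ValidationError(
                f"beta value {vals[r, c]!r} outside [0, 1] at row "
                f"{self.beta.index[r]!r}, column {self.beta.columns[c]!r}"
            )
        for grp in (NORMAL, DISEASE):
            if not (self.group.loc[list(self.beta.columns)] == grp).any():
                raise ValidationError(f"no {grp} samples in stage {self.stage}")

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.group[s] == NORMAL]

    @property
    def disease_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.group[s] == DISEASE]


@dataclass
class ExpressionDataset:
    """Probe x sample log2-ratio matrix for one stage.

    ``probe_to_gene`` is total over probes; values are finite or
    missing (NaN).
    """

    stage: str
    log2ratio: pd.DataFrame
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage label {self.stage!r}")
        if not self.log2ratio.columns.is_unique:
            dup = self.log2ratio.columns[self.log2ratio.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample column {dup!r}")
        unmapped = [p for p in self.log2ratio.index if p not in self.probe_to_gene]
        if unmapped:
            raise ValidationError(f"probes without gene mapping: {unmapped[:5]}")
        vals = self.log2ratio.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("non-finite log2 ratio in expression matrix")


@dataclass
class InteractionSet:
    """Undirected gene-gene interactions, deduplicated, no self-loops.

    Edges are stored as sorted tuples; ``sources`` maps each edge to
    its source tag(s) (``ppi`` and/or ``signaling``).
    """

    edges: list[tuple[str, str]]
    sources: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop {a!r} in interaction set")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValidationError(f"duplicate edge {key} in interaction set")
            seen.add(key)

    def subset(self, source: str) -> "InteractionSet":
        """Edges carrying the given source tag (``ppi`` or ``signaling``)."""
        edges = [e for e in self.edges if source in self.sources.get(e, {"ppi"})]
        return InteractionSet(edges, {e: {source} for e in edges})

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass
class GeneAnnotation:
    """Static annotation of one gene symbol.

    ``tss`` and ``probe_position`` are 1-based genomic coordinates;
    the promoter test uses inclusive window arithmetic on them.
    ``pathway_memberships`` is a list of (pathway id, class) pairs
    with class drawn from the fixed 3-class vocabulary.
    """

    gene: str
    chromosome: str | None = None
    strand: str | None = None
    tss: int | None = None
    cpg_island: bool = False
    probe_position: int | None = None
    go_terms: set[str] = field(default_factory=set)
    pathway_memberships: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValidationError(
                f"strand of {self.gene!r} must be '+' or '-', got {self.strand!r}"
            )
        for _, cls in self.pathway_memberships:
            if cls not in PATHWAY_CLASSES:
                raise ValidationError(f"unknown pathway class {cls!r}")


@dataclass
class OntologyBundle:
    """A miniature is_a ontology plus gene-to-term associations.

    ``dag`` is a DiGraph with child -> parent ``is_a`` edges (the
    obonet orientation); it must be acyclic.  Every associated term
    must exist in the DAG.
    """

    dag: nx.DiGraph
    namespaces: dict[str, str]
    gene_terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValidationError("ontology is_a graph contains a cycle")
        for gene, terms in self.gene_terms.items():
            for t in terms:
                if t not in self.dag:
                    raise ValidationError(
                        f"gene {gene!r} annotated to unknown term {t!r}"
                    )

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` including the term itself."""
        return {term} | nx.descendants(self.dag, term)

    def terms_in_namespace(self, gene: str, namespace: str) -> set[str]:
        return {
            t
            for t in self.gene_terms.get(gene, set())
            if self.namespaces.get(t) == namespace
        }


@dataclass
class SignificantGeneRecord:
    """One gene's stage-level significance call."""

    gene: str
    stage: str
    kind: str  # expressed | hyper | hypo
    delta_beta: float | None = None
    log2_summary: float | None = None
    p_value: float | None = None
    perm_p: float | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"expressed", "hyper", "hypo"}:
            raise ValidationError(f"unknown call kind {self.kind!r}")
        if self.kind == "hyper" and not self.delta_beta >= 0:
            raise ValidationError(f"hyper call {self.gene!r} with negative delta-beta")
        if self.kind == "hypo" and not self.delta_beta <= 0:
            raise ValidationError(f"hypo call {self.gene!r} with positive delta-beta")
        for p in (self.p_value, self.perm_p, self.q_value):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValidationError(f"p/q outside [0, 1] for gene {self.gene!r}")


@dataclass
class StageCalls:
    """All significance calls for one stage, grouped by kind."""

    stage: str
    hyper: list[SignificantGeneRecord] = field(default_factory=list)
    hypo: list[SignificantGeneRecord] = field(default_factory=list)
    expressed: list[SignificantGeneRecord] = field(default_factory=list)

    @property
    def methylated_genes(self) -> set[str]:
        return {r.gene for r in self.hyper} | {r.gene for r in self.hypo}

    @property
    def expressed_genes(self) -> set[str]:
        return {r.gene for r in self.expressed}

    @property
    def records(self) -> list[SignificantGeneRecord]:
        return list(self.hyper) + list(self.hypo) + list(self.expressed)

    def delta_beta_map(self) -> dict[str, float]:
        return {r.gene: r.delta_beta for r in self.hyper + self.hypo}


def annotation_for(
    annotations: Mapping[str, GeneAnnotation], gene: str
) -> GeneAnnotation:
    """Annotation lookup that degrades to an empty record for unknown genes."""
    try:
        return annotations[gene]
    except KeyError:
        return GeneAnnotation(gene=gene)


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key for an undirected edge."""
    return (a, b) if a <= b else (b, a)


def unique_genes(records: Iterable[SignificantGeneRecord]) -> set[str]:
    return {r.gene for r in records}
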