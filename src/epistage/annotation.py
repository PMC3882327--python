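"""Biological annotation of significant genes.

Covers the CpG-island flag, the promoter window around the TSS
(-1500/+500 bp, reflected on the minus strand), transcription-factor
status via ontology ancestor propagation, per-chromosome call
profiles, and the pathway significance score (PSS).

The PSS grades a gene by the pathway class it belongs to: lung
cancer pathways carry rank s=3, other cancer pathways s=2 and the
rest s=1.  With f = number of pathways of the chosen class that
contain the gene and F = total pathways in that class,

    pss = ( log10( (f/F) * 100 * F**s ) ) ** s

clamped to 0 when f = 0 or the log argument is <= 1.  The score is
min-max normalized across each stage network's nodes before it
enters the node strength.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .datatypes import (
    CLASS_RANK,
    GeneAnnotation,
    OntologyBundle,
    SignificantGeneRecord,
    ValidationError,
    annotation_for,
)

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
#: Term id of "DNA-binding transcription factor activity" in the packaged
#: mini-ontology; override for real GO (GO:0003700).
DEFAULT_TF_TERMS = frozenset({"EP:0003700"})


@dataclass
class PathwayScore:
    """Class-rank-weighted pathway membership score of one gene."""

    gene: str
    class_rank: int  # s in {1, 2, 3}
    f: int  # pathways of the chosen class containing the gene
    F: int  # total pathways in that class
    pss: float
    pss_norm: float | None = None


def cpg_status(gene: str, annotations: Mapping[str, GeneAnnotation]) -> bool:
    """TRUE iff the gene's probe lies inside a CpG island.

    Pass-through of the manifest flag; an unannotated gene is FALSE
    with a warning.
    """
    if gene not in annotations:
        log.warning("gene %s has no annotation; CpG status FALSE", gene)
        return False
    return annotations[gene].cpg_island


def promoter_overlap(position: int, tss: int, strand: str) -> bool:
    """Whether a (1-based) position falls in the promoter window.

    On the + strand the window is [tss-1500, tss+500]; on the -
    strand it is reflected to [tss-500, tss+1500].  Endpoints are
    inclusive.
    """
    if strand == "+":
        return tss - PROMOTER_UPSTREAM <= position <= tss + PROMOTER_DOWNSTREAM
    if strand == "-":
        return tss - PROMOTER_DOWNSTREAM <= position <= tss + PROMOTER_UPSTREAM
    raise ValidationError(f"unknown strand {strand!r}")


def gene_promoter_overlap(annotation: GeneAnnotation) -> bool | None:
    """Promoter status of a gene's probe; None when coordinates are absent."""
    if annotation.tss is None or annotation.probe_position is None:
        return None
    if annotation.strand is None:
        raise ValidationError(f"gene {annotation.gene!r} has no strand")
    return promoter_overlap(annotation.probe_position, annotation.tss, annotation.strand)


def is_transcription_factor(
    gene: str,
    ontology: OntologyBundle,
    tf_terms: frozenset[str] = DEFAULT_TF_TERMS,
) -> bool:
    """TRUE iff the gene is annotated to a TF term or one of its descendants.

    Propagation is along is_a ancestors only: a gene annotated to a
    descendant of a TF term inherits the TF function.
    """
    for term in ontology.gene_terms.get(gene, set()):
        if ontology.ancestors(term) & tf_terms:
            return True
    return False


def chromosome_profile(
    records: Iterable[SignificantGeneRecord],
    annotations: Mapping[str, GeneAnnotation],
) -> pd.DataFrame:
    """Hyper/hypo counts per (stage, chromosome).

    Genes without a chromosome are reported in an ``unplaced`` row so
    the totals reconcile with the significant-gene counts.
    """
    rows = []
    for r in records:
        if r.kind not in {"hyper", "hypo"}:
            continue
        chrom = annotation_for(annotations, r.gene).chromosome or "unplaced"
        rows.append({"stage": r.stage, "chromosome": chrom, "kind": r.kind})
    if not rows:
        return pd.DataFrame(columns=["stage", "chromosome", "hyper", "hypo"])
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["stage", "chromosome", "kind"])
        .size()
        .unstack("kind", fill_value=0)
        .reset_index()
    )
    for col in ("hyper", "hypo"):
        if col not in table.columns:
            table[col] = 0
    return table[["stage", "chromosome", "hyper", "hypo"]]


def pathway_significance_score(gene: str, pathways: pd.DataFrame) -> PathwayScore:
    """Raw pathway significance score of one gene.

    The highest-rank class containing the gene is chosen (lung
    cancer > other cancer > other); ``f`` and ``F`` are counted in
    that class only.  F = 0 yields 0 with a warning.
    """
    member = pathways[pathways["gene"] == gene]
    if member.empty:
        return PathwayScore(gene=gene, class_rank=1, f=0, F=0, pss=0.0)
    cls = max(member["class"].unique(), key=lambda c: CLASS_RANK[c])
    s = CLASS_RANK[cls]
    in_class = pathways[pathways["class"] == cls]
    F = in_class["pathway_id"].nunique()
    f = member.loc[member["class"] == cls, "pathway_id"].nunique()
    if F == 0:
        log.warning("pathway class %s empty; score 0 for %s", cls, gene)
        return PathwayScore(gene=gene, class_rank=s, f=f, F=F, pss=0.0)
    arg = (f / F) * 100.0 * F**s
    pss = math.log10(arg) ** s if (f > 0 and arg > 1.0) else 0.0
    return PathwayScore(gene=gene, class_rank=s, f=f, F=F, pss=pss)


def pathway_scores(genes: Iterable[str], pathways: pd.DataFrame) -> dict[str, PathwayScore]:
    return {g: pathway_significance_score(g, pathways) for g in genes}


def annotation_report(
    records: Iterable[SignificantGeneRecord],
    annotations: Mapping[str, GeneAnnotation],
    ontology: OntologyBundle,
    pathways: pd.DataFrame,
    tf_terms: frozenset[str] = DEFAULT_TF_TERMS,
) -> pd.DataFrame:
    """Flat `annotation_report.tsv` layout for significant genes."""
    rows = []
    for r in records:
        ann = annotation_for(annotations, r.gene)
        score = pathway_significance_score(r.gene, pathways)
        promoter = gene_promoter_overlap(ann) if ann.strand is not None else None
        rows.append(
            {
                "stage": r.stage,
                "gene": r.gene,
                "kind": r.kind,
                "cpg": cpg_status(r.gene, annotations),
                "promoter": promoter,
                "tf": is_transcription_factor(r.gene, ontology, tf_terms),
                "chromosome": ann.chromosome or "unplaced",
                "class_rank": score.class_rank,
                "pss": score.pss,
            }
        )
    cols = ["stage", "gene", "kind", "cpg", "promoter", "tf", "chromosome", "class_rank", "pss"]
    return pd.DataFrame(rows, columns=cols)
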