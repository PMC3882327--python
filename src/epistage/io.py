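"""Readers and writers for the plain-text table dialects.

All tables are tab-separated with a header row.  Dialects:

* beta matrix: ``gene_or_probe \\t <sample1> ...``; a sidecar
  ``samples.tsv`` (``sample \\t stage \\t group``) supplies labels.
* expression matrix: ``probe \\t gene \\t <sample1> ...``.
* interactions: ``geneA \\t geneB [\\t source]`` (extra columns ignored).
* annotation: ``gene \\t chromosome \\t strand \\t tss \\t
  cpg_island{TRUE,FALSE} \\t probe_position``.
* ontology: minimal OBO (id, name, namespace, is_a) read with obonet;
  associations: ``gene \\t term``.
* pathways: ``pathway_id \\t class \\t gene``; unknown class labels
  are coerced to ``other``.

Missing numeric values are written and read as ``NA`` and carried as
NaN.  Round-trip of any table reproduces its content exactly, modulo
row order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet
import pandas as pd

from .datatypes import (
    PATHWAY_CLASSES,
    ExpressionDataset,
    GeneAnnotation,
    InteractionSet,
    MethylationDataset,
    OntologyBundle,
    ValidationError,
    normalize_pair,
)

log = logging.getLogger(__name__)

_NA = "NA"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False, **kw)


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read ``sample \\t stage \\t group`` sidecar."""
    df = _read_tsv(path, dtype=str)
    for col in ("sample", "stage", "group"):
        if col not in df.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicated sample {dup!r} in sample sheet")
    return df.set_index("sample")


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(
    path: str | Path, group_map: Mapping[str, str], stage: str
) -> MethylationDataset:
    """Parse a beta-value matrix TSV into a :class:`MethylationDataset`.

    ``group_map`` maps every sample column to ``normal``/``disease``;
    an unlisted sample column is a hard error, as is any value
    outside [0, 1].  Probe rows mapping to the same gene are kept
    separate until probe collapse.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise ValidationError(f"duplicated sample column {sorted(dups)[0]!r}")
    df = _read_tsv(path, index_col=0)
    unknown = [s for s in df.columns if s not in group_map]
    if unknown:
        raise ValidationError(f"samples not in group map: {unknown}")
    group = pd.Series({s: group_map[s] for s in df.columns})
    gene_col = None
    if "gene" in df.columns:  # optional in-file probe->gene column
        gene_col = df.pop("gene")
        group = group.drop("gene")
    probe_to_gene = dict(gene_col) if gene_col is not None else None
    return MethylationDataset(
        stage=stage,
        beta=df.astype(float),
        group=group,
        probe_to_gene=probe_to_gene,
    )


def write_beta_matrix(ds: MethylationDataset, path: str | Path) -> None:
    out = ds.beta.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path, stage: str) -> ExpressionDataset:
    """Parse ``probe \\t gene \\t <samples...>`` into an :class:`ExpressionDataset`."""
    df = _read_tsv(path)
    if "probe" not in df.columns or "gene" not in df.columns:
        raise ValidationError("expression matrix needs 'probe' and 'gene' columns")
    df = df.set_index("probe")
    probe_to_gene = dict(df.pop("gene"))
    return ExpressionDataset(
        stage=stage, log2ratio=df.astype(float), probe_to_gene=probe_to_gene
    )


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> None:
    out = ds.log2ratio.copy()
    out.insert(0, "gene", [ds.probe_to_gene[p] for p in out.index])
    out.index.name = "probe"
    out.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# interactions


def read_interactions(path: str | Path) -> InteractionSet:
    """Parse a two-column (plus optional source tag) edge list.

    Pairs are normalized to unordered form and deduplicated;
    self-loops and rows with an empty symbol are dropped with a
    logged count.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("interaction table needs at least two columns")
    cols = list(df.columns)
    has_source = "source" in cols
    edges: dict[tuple[str, str], set[str]] = {}
    n_self = n_empty = 0
    for row in df.itertuples(index=False):
        a, b = getattr(row, cols[0]), getattr(row, cols[1])
        src = getattr(row, "source") if has_source else "ppi"
        if pd.isna(src) or not str(src).strip():
            src = "ppi"
        srcs = {s.strip() for s in str(src).split(",") if s.strip()}
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_empty += 1
            continue
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        edges.setdefault(normalize_pair(a, b), set()).update(srcs)
    if n_self:
        log.warning("dropped %d self-loop interaction(s)", n_self)
    if n_empty:
        log.warning("skipped %d interaction row(s) with empty symbol", n_empty)
    keys = sorted(edges)
    return InteractionSet(edges=keys, sources={k: edges[k] for k in keys})


def write_interactions(ia: InteractionSet, path: str | Path) -> None:
    rows = [
        {"geneA": a, "geneB": b, "source": ",".join(sorted(ia.sources.get((a, b), {"ppi"}))) }
        for a, b in ia.edges
    ]
    pd.DataFrame(rows, columns=["geneA", "geneB", "source"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    df = _read_tsv(path, dtype=str)
    required = ["gene", "chromosome", "strand", "tss", "cpg_island"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        gene = row.gene
        pos = getattr(row, "probe_position", None)
        out[gene] = GeneAnnotation(
            gene=gene,
            chromosome=None if pd.isna(row.chromosome) else row.chromosome,
            strand=None if pd.isna(row.strand) else row.strand,
            tss=None if pd.isna(row.tss) else int(row.tss),
            cpg_island=str(row.cpg_island).upper() == "TRUE",
            probe_position=None if pos is None or pd.isna(pos) else int(pos),
        )
    return out


def write_gene_annotation(
    annotations: Mapping[str, GeneAnnotation], path: str | Path
) -> None:
    rows = []
    for g in sorted(annotations):
        a = annotations[g]
        rows.append(
            {
                "gene": a.gene,
                "chromosome": a.chromosome,
                "strand": a.strand,
                "tss": a.tss,
                "cpg_island": "TRUE" if a.cpg_island else "FALSE",
                "probe_position": a.probe_position,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("tss", "probe_position"):
        df[col] = df[col].astype("Int64")  # avoid float-formatting coordinates
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# ontology + associations


def read_ontology(obo_path: str | Path, gaf_path: str | Path) -> OntologyBundle:
    """Read a minimal OBO file and a two-column gene->term table.

    The is_a graph must be acyclic and every associated term must
    exist in it (error naming the term otherwise).
    """
    graph = obonet.read_obo(str(obo_path))
    dag = nx.DiGraph()
    namespaces: dict[str, str] = {}
    dag.add_nodes_from(graph.nodes)
    for term, data in graph.nodes(data=True):
        namespaces[term] = data.get("namespace", "biological_process")
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValidationError("cyclic is_a relations in ontology")
    assoc = _read_tsv(gaf_path, dtype=str)
    if "gene" not in assoc.columns or "term" not in assoc.columns:
        raise ValidationError("association table needs 'gene' and 'term' columns")
    gene_terms: dict[str, set[str]] = {}
    for row in assoc.itertuples(index=False):
        if row.term not in dag:
            raise ValidationError(
                f"gene {row.gene!r} annotated to unknown term {row.term!r}"
            )
        gene_terms.setdefault(row.gene, set()).add(row.term)
    return OntologyBundle(dag=dag, namespaces=namespaces, gene_terms=gene_terms)


def write_ontology(bundle: OntologyBundle, obo_path: str | Path, gaf_path: str | Path) -> None:
    """Write the bundle back out as minimal OBO + association TSV."""
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: mini\n")
        for term in sorted(bundle.dag.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {bundle.namespaces.get(term, 'biological_process')}\n")
            for parent in sorted(bundle.dag.successors(term)):
                fh.write(f"is_a: {parent}\n")
    rows = [
        {"gene": g, "term": t}
        for g in sorted(bundle.gene_terms)
        for t in sorted(bundle.gene_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(gaf_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathways


def read_pathways(path: str | Path) -> pd.DataFrame:
    """Read ``pathway_id \\t class \\t gene`` membership rows.

    Class labels outside the fixed vocabulary (e.g. ``metabolic``)
    are coerced to ``other`` with a log entry.
    """
    df = _read_tsv(path, dtype=str)
    for col in ("pathway_id", "class", "gene"):
        if col not in df.columns:
            raise ValidationError(f"pathway table missing column {col!r}")
    bad = ~df["class"].isin(PATHWAY_CLASSES)
    if bad.any():
        log.info(
            "coerced %d pathway class label(s) %s to 'other'",
            int(bad.sum()),
            sorted(df.loc[bad, "class"].unique()),
        )
        df.loc[bad, "class"] = "other"
    return df.reset_index(drop=True)


def write_pathways(df: pd.DataFrame, path: str | Path) -> None:
    df[["pathway_id", "class", "gene"]].to_csv(path, sep="\t", index=False)
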