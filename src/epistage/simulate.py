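"""Synthetic multi-stage input bundles with known ground truth.

The generator emulates the study conditions end to end: per-stage
normal/disease beta-value matrices with a bimodal baseline (low ~0.1
and high ~0.8 modes, beta-distributed noise), planted hyper- and
hypomethylated genes shifted by +/-delta, stage-switching genes
(hyper / hypo / hyper across three stages), log2-ratio expression
matrices with planted differential expression at +/-2, a scale-free
protein-interaction graph with a planted conserved core wired as a
clique and present (significantly methylated) in every stage, a
miniature is_a ontology in which core genes share closely related
terms (pairwise Wang similarity ~0.8 by construction), and a
3-class pathway table in which core genes sit in several lung-cancer
pathways.

Everything is written in the exact file dialects of
:mod:`epistage.io` -- no in-memory shortcut -- so parsers are
exercised, and the same seed yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .datatypes import (
    DISEASE,
    NORMAL,
    ExpressionDataset,
    GeneAnnotation,
    InteractionSet,
    MethylationDataset,
    OntologyBundle,
    StageCalls,
    ValidationError,
    normalize_pair,
)

BP_ROOT = "EP:0000001"
MF_ROOT = "EP:0003674"
TF_TERM = "EP:0003700"  # "DNA-binding transcription factor activity"
TF_CHILD = "EP:0003701"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults are the benchmark conditions: 500 genes, three stages
    with 10 normal + 10 disease samples each, a beta-scale shift of
    delta = 0.4 (comfortably above the 0.25 calling threshold), and
    a planted 7-gene conserved core.
    """

    n_genes: int = 500
    stages: tuple[str, ...] = ("I", "II", "III")
    n_normal: int = 10
    n_disease: int = 10
    n_hyper: int = 30  # planted per stage (beyond core/switch)
    n_hypo: int = 15
    delta: float = 0.4
    beta_concentration: float = 50.0
    low_baseline: float = 0.1
    high_baseline: float = 0.8
    n_switch: int = 10
    n_expressed: int = 50
    expr_effect: float = 2.0
    expr_sigma: float = 0.5
    n_multiprobe: int = 10  # expression genes represented by 2 probes
    ppi_attachment: int = 2  # preferential-attachment edges per node
    core_size: int = 7
    core_lung_pathways: int = 3
    n_subtrees: int = 10
    leaves_per_subtree: int = 5
    terms_per_gene: int = 2
    tf_fraction: float = 0.15
    n_lung_pathways: int = 5
    n_other_cancer_pathways: int = 8
    n_other_pathways: int = 15
    emit_signaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size > self.n_genes:
            raise ValidationError("conserved core larger than gene universe")
        reserved = self.core_size + self.n_switch + len(self.stages) * (
            self.n_hyper + self.n_hypo
        )
        if reserved > self.n_genes:
            raise ValidationError("more planted genes than the gene universe holds")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of one simulated bundle."""

    meth_state: pd.DataFrame  # gene x stage in {hyper, hypo, none}
    expr_state: pd.DataFrame  # gene x stage in {up, down, none}
    core_genes: set[str]
    switch_genes: set[str]
    core_edges: set[tuple[str, str]]

    def planted_methylated(self, stage: str) -> dict[str, str]:
        col = self.meth_state[stage]
        return {g: s for g, s in col.items() if s != "none"}

    def frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.meth_state.index:
            for stage in self.meth_state.columns:
                rows.append(
                    {
                        "gene": gene,
                        "stage": stage,
                        "meth_state": self.meth_state.loc[gene, stage],
                        "expr_state": self.expr_state.loc[gene, stage],
                        "core": gene in self.core_genes,
                        "switch": gene in self.switch_genes,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class BundlePaths:
    """On-disk layout of a simulated bundle."""

    root: Path
    samples: Path
    beta: dict[str, Path]
    expression: dict[str, Path]
    interactions: Path
    annotation: Path
    obo: Path
    associations: Path
    pathways: Path
    truth: Path


def _beta_draw(
    rng: np.random.Generator, mu: np.ndarray, conc: float, size: tuple[int, ...]
) -> np.ndarray:
    mu = np.clip(mu, 0.02, 0.98)
    return rng.beta(mu * conc, (1 - mu) * conc, size=size)


def _build_ontology(
    cfg: SimulationConfig, rng: np.random.Generator, genes: list[str], core: list[str]
) -> OntologyBundle:
    dag = nx.DiGraph()
    namespaces = {BP_ROOT: "biological_process", MF_ROOT: "molecular_function"}
    dag.add_nodes_from([BP_ROOT, MF_ROOT])
    dag.add_edge(TF_TERM, MF_ROOT)
    dag.add_edge(TF_CHILD, TF_TERM)
    namespaces[TF_TERM] = namespaces[TF_CHILD] = "molecular_function"

    # dedicated shallow core subtree: one shared leaf + one sibling per
    # core gene forces pairwise core similarity ~0.8
    core_parent = "EP:0000100"
    dag.add_edge(core_parent, BP_ROOT)
    namespaces[core_parent] = "biological_process"
    shared = "EP:0000101"
    dag.add_edge(shared, core_parent)
    namespaces[shared] = "biological_process"
    core_leaves = {}
    for i, gene in enumerate(core):
        leaf = f"EP:{102 + i:07d}"
        dag.add_edge(leaf, core_parent)
        namespaces[leaf] = "biological_process"
        core_leaves[gene] = leaf

    background_leaves: list[str] = []
    for j in range(cfg.n_subtrees):
        parent = f"EP:{200 + j * 100:07d}"
        dag.add_edge(parent, BP_ROOT)
        namespaces[parent] = "biological_process"
        for l in range(cfg.leaves_per_subtree):
            leaf = f"EP:{201 + j * 100 + l:07d}"
            dag.add_edge(leaf, parent)
            namespaces[leaf] = "biological_process"
            background_leaves.append(leaf)

    gene_terms: dict[str, set[str]] = {}
    for gene in genes:
        if gene in core_leaves:
            gene_terms[gene] = {shared, core_leaves[gene]}
        else:
            k = int(rng.integers(1, cfg.terms_per_gene + 1))
            picks = rng.choice(len(background_leaves), size=k, replace=False)
            gene_terms[gene] = {background_leaves[i] for i in picks}
    n_tf = int(round(cfg.tf_fraction * len(genes)))
    tf_idx = rng.choice(len(genes), size=n_tf, replace=False)
    for i in tf_idx:
        term = TF_TERM if rng.random() < 0.5 else TF_CHILD
        gene_terms[genes[i]].add(term)
    return OntologyBundle(dag=dag, namespaces=namespaces, gene_terms=gene_terms)


def _build_pathways(
    cfg: SimulationConfig, rng: np.random.Generator, genes: list[str], core: list[str]
) -> pd.DataFrame:
    rows = []
    background = [g for g in genes if g not in set(core)]
    lung_ids = [f"lung_cancer_pw_{i + 1}" for i in range(cfg.n_lung_pathways)]
    for gene in core:
        picks = rng.choice(
            cfg.n_lung_pathways, size=min(cfg.core_lung_pathways, cfg.n_lung_pathways),
            replace=False,
        )
        for i in picks:
            rows.append({"pathway_id": lung_ids[i], "class": "lung_cancer", "gene": gene})
    for pid in lung_ids:  # a couple of background members per lung pathway
        for i in rng.choice(len(background), size=2, replace=False):
            rows.append({"pathway_id": pid, "class": "lung_cancer", "gene": background[i]})
    for j in range(cfg.n_other_cancer_pathways):
        pid = f"other_cancer_pw_{j + 1}"
        for i in rng.choice(len(background), size=10, replace=False):
            rows.append({"pathway_id": pid, "class": "other_cancer", "gene": background[i]})
    for j in range(cfg.n_other_pathways):
        name = "signaling_pw" if j % 3 == 0 else "metabolic_pw"
        pid = f"{name}_{j + 1}"
        for i in rng.choice(len(background), size=20, replace=False):
            rows.append({"pathway_id": pid, "class": "other", "gene": background[i]})
    df = pd.DataFrame(rows, columns=["pathway_id", "class", "gene"])
    return df.drop_duplicates().reset_index(drop=True)


def _build_annotation(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    planted_any: set[str],
) -> dict[str, GeneAnnotation]:
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    out = {}
    for gene in genes:
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(100_000, 100_000_000))
        cpg_p = 0.85 if gene in planted_any else 0.3
        in_window = rng.random() < 0.9
        if in_window:
            lo, hi = (-1500, 500) if strand == "+" else (-500, 1500)
            offset = int(rng.integers(lo, hi + 1))
        else:
            offset = int(rng.integers(5_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
        out[gene] = GeneAnnotation(
            gene=gene,
            chromosome=chroms[int(rng.integers(len(chroms)))],
            strand=strand,
            tss=tss,
            cpg_island=bool(rng.random() < cpg_p),
            probe_position=tss + offset,
        )
    return out


def simulate_bundle(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[BundlePaths, TruthTable]:
    """Generate and write a complete input bundle; return paths + truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- planted gene roles ------------------------------------------------
    perm = list(rng.permutation(cfg.n_genes))
    core = [genes[i] for i in perm[: cfg.core_size]]
    switch = [genes[i] for i in perm[cfg.core_size : cfg.core_size + cfg.n_switch]]
    background = [genes[i] for i in perm[cfg.core_size + cfg.n_switch :]]
    half = len(background) // 2
    hyper_pool, hypo_pool = background[:half], background[half:]

    meth_state = pd.DataFrame("none", index=genes, columns=list(cfg.stages))
    expr_state = pd.DataFrame("none", index=genes, columns=list(cfg.stages))
    baseline = pd.Series(index=genes, dtype=float)
    baseline[:] = np.where(
        rng.random(cfg.n_genes) < 0.5, cfg.low_baseline, cfg.high_baseline
    )
    baseline[hyper_pool] = cfg.low_baseline
    baseline[hypo_pool] = cfg.high_baseline
    baseline[core] = cfg.low_baseline
    baseline[switch] = 0.5

    planted = cfg.delta > 0
    for si, stage in enumerate(cfg.stages):
        if not planted:
            break
        hy = [hyper_pool[i] for i in rng.choice(len(hyper_pool), cfg.n_hyper, replace=False)]
        ho = [hypo_pool[i] for i in rng.choice(len(hypo_pool), cfg.n_hypo, replace=False)]
        meth_state.loc[hy, stage] = "hyper"
        meth_state.loc[ho, stage] = "hypo"
        meth_state.loc[core, stage] = "hyper"
        meth_state.loc[switch, stage] = "hyper" if si % 2 == 0 else "hypo"

    # --- beta matrices -----------------------------------------------------
    samples_rows = []
    beta_paths: dict[str, Path] = {}
    group_maps: dict[str, dict[str, str]] = {}
    for stage in cfg.stages:
        normal_ids = [f"{stage}_N{i + 1:02d}" for i in range(cfg.n_normal)]
        disease_ids = [f"{stage}_T{i + 1:02d}" for i in range(cfg.n_disease)]
        for s in normal_ids:
            samples_rows.append({"sample": s, "stage": stage, "group": NORMAL})
        for s in disease_ids:
            samples_rows.append({"sample": s, "stage": stage, "group": DISEASE})
        mu = baseline.to_numpy()
        normal = _beta_draw(rng, mu[:, None], cfg.beta_concentration, (cfg.n_genes, cfg.n_normal))
        shift = np.zeros(cfg.n_genes)
        state = meth_state[stage]
        shift[(state == "hyper").to_numpy()] = cfg.delta
        shift[(state == "hypo").to_numpy()] = -cfg.delta
        disease = _beta_draw(
            rng, (mu + shift)[:, None], cfg.beta_concentration, (cfg.n_genes, cfg.n_disease)
        )
        beta = pd.DataFrame(
            np.hstack([normal, disease]),
            index=pd.Index(genes, name="gene"),
            columns=normal_ids + disease_ids,
        ).round(4)
        path = out / f"beta_{stage}.tsv"
        group_maps[stage] = {s: NORMAL for s in normal_ids} | {s: DISEASE for s in disease_ids}
        ds = MethylationDataset(stage=stage, beta=beta, group=pd.Series(group_maps[stage]))
        io.write_beta_matrix(ds, path)
        beta_paths[stage] = path

    samples_path = out / "samples.tsv"
    pd.DataFrame(samples_rows).to_csv(samples_path, sep="\t", index=False)

    # --- expression matrices ----------------------------------------------
    expr_paths: dict[str, Path] = {}
    multi = [genes[i] for i in perm[-cfg.n_multiprobe:]] if cfg.n_multiprobe else []
    for stage in cfg.stages:
        n_samp = cfg.n_disease
        de_idx = rng.choice(cfg.n_genes, size=cfg.n_expressed, replace=False)
        effects = np.zeros(cfg.n_genes)
        signs = np.where(rng.random(cfg.n_expressed) < 0.5, 1.0, -1.0)
        effects[de_idx] = signs * cfg.expr_effect
        expr_state.loc[[genes[i] for i in de_idx], stage] = np.where(
            signs > 0, "up", "down"
        )
        probes, rows, probe_gene = [], [], []
        for gi, gene in enumerate(genes):
            n_probes = 2 if gene in multi else 1
            for pi in range(n_probes):
                probes.append(f"P_{gene}_{pi + 1}")
                probe_gene.append(gene)
                rows.append(rng.normal(effects[gi], cfg.expr_sigma, size=n_samp))
        mat = pd.DataFrame(
            np.vstack(rows),
            index=pd.Index(probes, name="probe"),
            columns=[f"{stage}_T{i + 1:02d}" for i in range(n_samp)],
        ).round(4)
        ds = ExpressionDataset(
            stage=stage, log2ratio=mat, probe_to_gene=dict(zip(probes, probe_gene))
        )
        path = out / f"expr_{stage}.tsv"
        io.write_expression_matrix(ds, path)
        expr_paths[stage] = path

    # --- interactions ------------------------------------------------------
    ba = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.ppi_attachment, seed=int(rng.integers(2**31 - 1))
    )
    relabel = {i: genes[i] for i in range(cfg.n_genes)}
    ppi = nx.relabel_nodes(ba, relabel)
    core_edges = {normalize_pair(a, b) for a, b in combinations(core, 2)}
    edge_sources: dict[tuple[str, str], set[str]] = {}
    for a, b in ppi.edges:
        edge_sources.setdefault(normalize_pair(a, b), set()).add("ppi")
    for e in core_edges:
        edge_sources.setdefault(e, set()).add("ppi")
    if cfg.emit_signaling:
        ppi_only = sorted(e for e in edge_sources if e not in core_edges)
        n_shared = int(0.4 * len(ppi_only))
        shared_idx = rng.choice(len(ppi_only), size=n_shared, replace=False)
        for i in shared_idx:
            edge_sources[ppi_only[i]].add("signaling")
        for e in core_edges:
            edge_sources[e].add("signaling")
        for _ in range(cfg.n_genes // 2):  # signaling-only extras
            a, b = rng.choice(cfg.n_genes, size=2, replace=False)
            e = normalize_pair(genes[a], genes[b])
            edge_sources.setdefault(e, set()).add("signaling")
    keys = sorted(edge_sources)
    ia = InteractionSet(edges=keys, sources={k: edge_sources[k] for k in keys})
    interactions_path = out / "interactions.tsv"
    io.write_interactions(ia, interactions_path)

    # --- ontology / pathways / annotation ----------------------------------
    bundle_ont = _build_ontology(cfg, rng, genes, core)
    obo_path, gaf_path = out / "ontology.obo", out / "associations.tsv"
    io.write_ontology(bundle_ont, obo_path, gaf_path)
    pathways = _build_pathways(cfg, rng, genes, core)
    pathways_path = out / "pathways.tsv"
    io.write_pathways(pathways, pathways_path)
    planted_any = set(meth_state.index[(meth_state != "none").any(axis=1)])
    annotation = _build_annotation(cfg, rng, genes, planted_any)
    annotation_path = out / "annotation.tsv"
    io.write_gene_annotation(annotation, annotation_path)

    truth = TruthTable(
        meth_state=meth_state,
        expr_state=expr_state,
        core_genes=set(core),
        switch_genes=set(switch),
        core_edges=core_edges,
    )
    truth_path = out / "truth.tsv"
    truth.frame().to_csv(truth_path, sep="\t", index=False)

    paths = BundlePaths(
        root=out,
        samples=samples_path,
        beta=beta_paths,
        expression=expr_paths,
        interactions=interactions_path,
        annotation=annotation_path,
        obo=obo_path,
        associations=gaf_path,
        pathways=pathways_path,
        truth=truth_path,
    )
    return paths, truth


def load_bundle(paths: BundlePaths):
    """Parse a written bundle back through the io layer."""
    samples = io.read_sample_sheet(paths.samples)
    meth, expr = {}, {}
    for stage, p in paths.beta.items():
        stage_samples = samples[samples["stage"] == stage]
        group_map = dict(stage_samples["group"])
        meth[stage] = io.read_beta_matrix(p, group_map, stage)
    for stage, p in paths.expression.items():
        expr[stage] = io.read_expression_matrix(p, stage)
    interactions = io.read_interactions(paths.interactions)
    annotation = io.read_gene_annotation(paths.annotation)
    ontology = io.read_ontology(paths.obo, paths.associations)
    pathways = io.read_pathways(paths.pathways)
    return meth, expr, interactions, annotation, ontology, pathways


def evaluate_recovery(
    calls: Mapping[str, StageCalls],
    truth: TruthTable,
    conserved: set[str] | None = None,
) -> dict[str, float]:
    """Confusion-matrix metrics of the methylation calls against truth.

    Sensitivity counts a planted gene as recovered only with the
    correct direction; FDR is the fraction of called genes that were
    not planted (any direction mismatch counts as false).  When a
    ``conserved`` gene set is supplied, core recall is reported too.
    """
    tp = fp = fn = 0
    stage_sens: dict[str, float] = {}
    for stage, sc in calls.items():
        planted = truth.planted_methylated(stage)
        called = {r.gene: r.kind for r in sc.hyper + sc.hypo}
        if set(called) - set(truth.meth_state.index):
            raise ValidationError("calls contain genes outside the truth universe")
        stp = sum(1 for g, k in called.items() if planted.get(g) == k)
        sfp = sum(1 for g, k in called.items() if planted.get(g) != k)
        sfn = sum(1 for g in planted if called.get(g) != planted[g])
        tp, fp, fn = tp + stp, fp + sfp, fn + sfn
        stage_sens[stage] = stp / len(planted) if planted else float("nan")
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fdr": fp / (tp + fp) if tp + fp else 0.0,
    }
    out.update({f"sensitivity_{s}": v for s, v in stage_sens.items()})
    if conserved is not None:
        out["core_recall"] = (
            len(conserved & truth.core_genes) / len(truth.core_genes)
            if truth.core_genes
            else float("nan")
        )
    return out


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    return SimulationConfig(**d)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["stages"] = list(d["stages"])
    return d
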