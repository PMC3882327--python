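"""End-to-end orchestration: differential calling through comparison.

`run_pipeline` executes the full analysis for every configured stage
and writes all module outputs plus a per-stage `summary.tsv` and a
machine-readable run manifest.  Reruns with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .annotation import DEFAULT_TF_TERMS, annotation_report, chromosome_profile
from .comparison import (
    network_source_overlap,
    pattern_switches,
    venn_regions,
    venn_table,
)
from .datatypes import StageCalls, ValidationError
from .differential import (
    DELTA_BETA_CUTOFF,
    FDR_LEVEL,
    LOG2_THRESHOLD,
    N_PERMUTATIONS,
    call_stage,
    calls_table,
)
from .network import build_stage_network, novel_gene_cross_stage, score_network
from .semsim import SemanticSimilarity
from .subnetworks import (
    SIM_THRESHOLD,
    discover_subnetworks,
    enumerate_subnetworks,
    propagate_conserved,
    subnetworks_table,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one full pipeline run.

    Every analysis constant is a default here, never hard-coded in a
    stage: log2 |1.4| for expression, |0.25| for delta-beta, 1% FDR,
    semantic-similarity threshold 0.60, 1000 permutations.
    """

    beta: dict[str, str]  # stage -> beta matrix path
    expression: dict[str, str]
    samples: str
    interactions: str
    annotation: str
    obo: str
    associations: str
    pathways: str
    out_dir: str
    log2_threshold: float = LOG2_THRESHOLD
    delta_beta_cutoff: float = DELTA_BETA_CUTOFF
    fdr: float = FDR_LEVEL
    sim_threshold: float = SIM_THRESHOLD
    n_perm: int = N_PERMUTATIONS
    max_subnetwork_size: int = 4
    top_k_size4: int = 10
    propagate_max_size: int = 12
    include_expr_edges: bool = True
    overlap_denominator: str = "union"
    q_method: str = "bh"
    expression_mode: str = "mean"
    seed: int = 0

    def validate(self) -> None:
        for name in ("samples", "interactions", "annotation", "obo", "associations", "pathways"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        for d in (self.beta, self.expression):
            for stage, p in d.items():
                if not Path(p).exists():
                    raise ValidationError(f"stage {stage} input missing: {p}")
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr must be in (0, 1)")
        if not 0 <= self.sim_threshold <= 1:
            raise ValidationError("sim_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @classmethod
    def for_bundle(cls, bundle, out_dir: str | Path, **overrides) -> "RunConfig":
        """Configuration pointing at a simulated bundle's files."""
        return cls(
            beta={s: str(p) for s, p in bundle.beta.items()},
            expression={s: str(p) for s, p in bundle.expression.items()},
            samples=str(bundle.samples),
            interactions=str(bundle.interactions),
            annotation=str(bundle.annotation),
            obo=str(bundle.obo),
            associations=str(bundle.associations),
            pathways=str(bundle.pathways),
            out_dir=str(out_dir),
            **overrides,
        )


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    calls: dict[str, StageCalls]
    networks: dict  # stage -> StageNetwork (ppi source)
    novel: dict  # stage -> list[NovelGeneRecord]
    subnetworks: dict  # stage -> list[Subnetwork]
    conserved: set[str]
    supporting: dict
    summary: pd.DataFrame
    out_dir: Path


def _write(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=float_format)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute differential calling -> annotation -> networks ->
    subnetworks -> cross-stage comparison, writing every output table."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = sorted(config.beta)

    failing = "input parsing"
    try:
        samples = io.read_sample_sheet(config.samples)
        interactions = io.read_interactions(config.interactions)
        annotations = io.read_gene_annotation(config.annotation)
        ontology = io.read_ontology(config.obo, config.associations)
        pathways = io.read_pathways(config.pathways)

        failing = "differential calling"
        calls: dict[str, StageCalls] = {}
        for stage in stages:
            group_map = dict(samples.loc[samples["stage"] == stage, "group"])
            meth = io.read_beta_matrix(config.beta[stage], group_map, stage)
            expr = (
                io.read_expression_matrix(config.expression[stage], stage)
                if stage in config.expression
                else None
            )
            calls[stage] = call_stage(
                meth,
                expr,
                log2_threshold=config.log2_threshold,
                delta_cutoff=config.delta_beta_cutoff,
                fdr=config.fdr,
                q_method=config.q_method,
                n_perm=config.n_perm,
                seed=config.seed,
                expression_mode=config.expression_mode,
            )
        _write(calls_table([calls[s] for s in stages]), out / "significant_genes.tsv")

        failing = "annotation"
        records = [r for s in stages for r in calls[s].records]
        _write(
            annotation_report(records, annotations, ontology, pathways, DEFAULT_TF_TERMS),
            out / "annotation_report.tsv",
        )
        _write(chromosome_profile(records, annotations), out / "chromosome_profile.tsv")

        failing = "network construction"
        sim = SemanticSimilarity(ontology)
        networks, novel = {}, {}
        signaling_networks = {}
        has_signaling = any("signaling" in s for s in interactions.sources.values())
        for stage in stages:
            net, nov = build_stage_network(
                calls[stage],
                interactions.subset("ppi"),
                include_expr_edges=config.include_expr_edges,
            )
            score_network(net, pathways, ontology, sim=sim)
            networks[stage], novel[stage] = net, nov
            _write(net.nodes_table(), out / f"nodes_{stage}.tsv")
            _write(net.edges_table(), out / f"network_{stage}.tsv")
            if has_signaling:
                snet, _ = build_stage_network(
                    calls[stage],
                    interactions.subset("signaling"),
                    include_expr_edges=config.include_expr_edges,
                )
                score_network(snet, pathways, ontology, sim=sim)
                signaling_networks[stage] = snet
        all_novel = [rec for s in stages for rec in novel[s]]
        _write(novel_gene_cross_stage(all_novel, calls), out / "novel_genes.tsv")

        failing = "subnetwork discovery"
        subs = {}
        for stage in stages:
            ranked = enumerate_subnetworks(
                networks[stage],
                max_size=config.max_subnetwork_size,
                sim_threshold=config.sim_threshold,
            )
            subs[stage] = ranked
            _write(
                subnetworks_table(ranked, networks[stage], pathways),
                out / f"subnetworks_{stage}.tsv",
            )
        conserved, supporting = (set(), {})
        if len(stages) >= 2:
            conserved, supporting = propagate_conserved(
                networks,
                top_k_size4=config.top_k_size4,
                max_size=config.propagate_max_size,
                sim_threshold=config.sim_threshold,
            )
        rows = [{"conserved_gene": g} for g in sorted(conserved)]
        for stage, sub in sorted(supporting.items()):
            rows.append(
                {"conserved_gene": f"[stage {stage}] " + ",".join(sub.genes)}
            )
        _write(pd.DataFrame(rows, columns=["conserved_gene"]), out / "conserved.tsv")

        failing = "cross-stage comparison"
        meth_sets = {s: calls[s].methylated_genes for s in stages}
        if 2 <= len(stages) <= 3:
            counts, _ = venn_regions(meth_sets)
            _write(venn_table(counts), out / "venn_methylated.tsv")
        patterns, pattern_counts = (
            pattern_switches(calls, stages) if len(stages) >= 2 else (pd.DataFrame(), pd.Series(dtype=int))
        )
        _write(patterns, out / "patterns.tsv")
        if has_signaling:
            overlap_rows = []
            for stage in stages:
                df = network_source_overlap(
                    signaling_networks[stage],
                    networks[stage],
                    denominator=config.overlap_denominator,
                )
                df.insert(0, "stage", stage)
                overlap_rows.append(df)
            _write(pd.concat(overlap_rows, ignore_index=True), out / "overlap.tsv")

        failing = "summary"
        summary_rows = []
        for stage in stages:
            sc = calls[stage]
            group = samples.loc[samples["stage"] == stage, "group"]
            summary_rows.append(
                {
                    "stage": stage,
                    "normal_samples": int((group == "normal").sum()),
                    "disease_samples": int((group == "disease").sum()),
                    "significant_genes": len(sc.expressed),
                    "methylated_genes": len(sc.methylated_genes),
                    "hyper": len(sc.hyper),
                    "hypo": len(sc.hypo),
                    "novel_genes": len(novel[stage]),
                }
            )
        summary = pd.DataFrame(summary_rows)
        _write(summary, out / "summary.tsv")

        manifest = {
            "config": asdict(config),
            "stages": stages,
            "conserved_genes": sorted(conserved),
            "pattern_counts": {k: int(v) for k, v in pattern_counts.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        log.error("pipeline failed during %s; partial outputs kept in %s", failing, out)
        raise

    return PipelineResult(
        calls=calls,
        networks=networks,
        novel=novel,
        subnetworks=subs,
        conserved=conserved,
        supporting=supporting,
        summary=summary,
        out_dir=out,
    )
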