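"""End-to-end orchestration: files in, interaction database out.

This is the programmatic counterpart of the ``run-all`` CLI subcommand;
each stage is an ordinary function from the stage modules, so partial
pipelines are just direct calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import clustering, domain_extraction, genome_context, interaction
from .config import PipelineConfig
from .domain_extraction import DomainInstance
from .genome_context import CognatePair, OperonAssignment
from .interaction import InteractionTable
from .sequence_io import (ClusterSet, DomainHit, GeneLocus, Model,
                          ProteinRecord, read_domtblout, read_fasta,
                          read_gene_table)
from .similarity import ScoringScheme, SimilarityEdge, all_vs_all


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    config: PipelineConfig
    proteins: list[ProteinRecord]
    loci: list[GeneLocus]
    dhp_instances: list[DomainInstance]
    rec_instances: list[DomainInstance]
    dhp_edges: list[SimilarityEdge]
    rec_edges: list[SimilarityEdge]
    dhp_clusters: ClusterSet
    rec_clusters: ClusterSet
    operons: OperonAssignment
    pairs: list[CognatePair]
    orphan_hpks: list[str]
    orphan_rrs: list[str]
    table: InteractionTable
    hybrids: list[str] = field(default_factory=list)

    @property
    def scheme(self) -> ScoringScheme:
        return scheme_from_config(self.config)


def scheme_from_config(config: PipelineConfig) -> ScoringScheme:
    return ScoringScheme(gap_open=config.gap_open,
                         gap_extend=config.gap_extend,
                         lam=config.lam, K=config.K)


def cluster_instances(
    instances: Sequence[DomainInstance],
    config: PipelineConfig,
    model: Model,
) -> tuple[list[SimilarityEdge], ClusterSet]:
    """All-vs-all similarity then Markov clustering for one model class."""
    if not instances:
        return [], ClusterSet(assignments={}, model=model)
    scheme = scheme_from_config(config)
    if len(instances) == 1:
        edges: list[SimilarityEdge] = []
    else:
        edges = all_vs_all(instances, scheme, config.evalue_cutoff)
    graph = clustering.build_graph(
        edges, nodes=[i.instance_id for i in instances],
        weight_cap=config.weight_cap)
    clusters = clustering.mcl(
        graph, inflation=config.inflation, expansion=config.expansion,
        prune_below=config.prune_below, max_iter=config.max_iter,
        tol=config.tol, model=model)
    return edges, clusters


def run_pipeline(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    loci: Sequence[GeneLocus],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run extraction, clustering, pairing and table building in memory."""
    config = config or PipelineConfig()
    instances = domain_extraction.extract_instances(
        proteins, hits, config.inclusion_threshold)
    dhp_instances = [i for i in instances if i.model == Model.DHP]
    rec_instances = [i for i in instances if i.model == Model.REC]
    hybrids = domain_extraction.find_hybrid_proteins(instances)

    dhp_edges, dhp_clusters = cluster_instances(dhp_instances, config, Model.DHP)
    rec_edges, rec_clusters = cluster_instances(rec_instances, config, Model.REC)

    operons = genome_context.assign_operons(loci, config.max_gap_bp)
    hpk_ids = sorted({i.protein_id for i in dhp_instances})
    rr_ids = sorted({i.protein_id for i in rec_instances})
    pairs = genome_context.cognate_pairs(
        operons, loci, hpk_ids, rr_ids, config.max_intervening)
    orphan_hpks, orphan_rrs = genome_context.find_orphans(
        operons, loci, hpk_ids, rr_ids, pairs)
    table = interaction.build_table(pairs, dhp_clusters, rec_clusters,
                                    count_mode=config.count_mode)
    return PipelineResult(
        config=config, proteins=list(proteins), loci=list(loci),
        dhp_instances=dhp_instances, rec_instances=rec_instances,
        dhp_edges=dhp_edges, rec_edges=rec_edges,
        dhp_clusters=dhp_clusters, rec_clusters=rec_clusters,
        operons=operons, pairs=pairs,
        orphan_hpks=orphan_hpks, orphan_rrs=orphan_rrs,
        table=table, hybrids=hybrids,
    )


def run_from_files(
    fasta: str | Path,
    domtblout: str | Path,
    genes: str | Path,
    model_map: Mapping[str, Model],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-based entry point used by the CLI's ``run-all``."""
    proteins = read_fasta(fasta)
    hits = read_domtblout(domtblout, model_map)
    loci = read_gene_table(genes)
    return run_pipeline(proteins, hits, loci, config)
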