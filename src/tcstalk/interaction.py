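"""Cluster-level interaction table and partner / cross-talk prediction.

Every genomic-context cognate pair votes for an interaction between the
kinase's DHp cluster and the regulator's REC cluster.  Row-normalising the
count matrix gives, for each DHp cluster, the observed likelihood of
pairing with each REC cluster — the lookup table behind both orphan
partner prediction and inter-species cross-talk prediction:

* an orphan kinase's cluster row ranks the candidate REC clusters;
* a kinase introduced into a foreign host may cross-talk with host
  kinases sharing its DHp cluster (competition for the same regulators)
  and with host regulators in its top partner REC cluster(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import NearestClusterResult, nearest_cluster
from .domain_extraction import DomainInstance, protein_of_instance
from .sequence_io import ClusterSet, Model
from .similarity import DEFAULT_EVALUE_CUTOFF, ScoringScheme
from .genome_context import CognatePair


@dataclass
class InteractionTable:
    """Counts and row-normalized probabilities over DHp x REC clusters."""

    counts: pd.DataFrame  # int counts; index DHp cluster ids, columns REC

    @property
    def probabilities(self) -> pd.DataFrame:
        """Row-stochastic probabilities; zero-count rows stay all-zero."""
        sums = self.counts.sum(axis=1)
        probs = self.counts.astype(float)
        supported = sums > 0
        probs.loc[supported] = probs.loc[supported].div(sums[supported], axis=0)
        return probs

    @property
    def no_prediction_rows(self) -> list[int]:
        """DHp clusters never observed in a cognate pair."""
        sums = self.counts.sum(axis=1)
        return [int(i) for i in self.counts.index[sums == 0]]

    @property
    def total_count(self) -> int:
        return int(self.counts.to_numpy().sum())


def _instances_by_protein(clusters: ClusterSet) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for instance_id in clusters.assignments:
        out.setdefault(protein_of_instance(instance_id), []).append(instance_id)
    return out


def build_table(
    pairs: Sequence[CognatePair],
    dhp_clusters: ClusterSet,
    rec_clusters: ClusterSet,
    count_mode: str = "per_instance_pair",
) -> InteractionTable:
    """Accumulate pair events into the cluster-level count matrix.

    With ``count_mode="per_instance_pair"`` (default) each cognate pair
    contributes one count per (DHp instance, REC instance) combination of
    its two proteins, so multi-domain proteins vote once per domain copy;
    ``"per_protein_pair"`` collapses that to a single count on the pair of
    clusters of the lowest-numbered instances.  A pair whose kinase has no
    clustered DHp instance (or regulator no REC instance) is a hard error.
    """
    if count_mode not in ("per_instance_pair", "per_protein_pair"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    dhp_by_protein = _instances_by_protein(dhp_clusters)
    rec_by_protein = _instances_by_protein(rec_clusters)
    n_dhp = dhp_clusters.n_clusters
    n_rec = rec_clusters.n_clusters
    counts = np.zeros((n_dhp, n_rec), dtype=int)
    for pair in pairs:
        dhp_insts = dhp_by_protein.get(pair.hpk_protein_id)
        rec_insts = rec_by_protein.get(pair.rr_protein_id)
        if not dhp_insts:
            raise KeyError(
                f"pair kinase {pair.hpk_protein_id!r} has no clustered DHp instance")
        if not rec_insts:
            raise KeyError(
                f"pair regulator {pair.rr_protein_id!r} has no clustered REC instance")
        if count_mode == "per_protein_pair":
            dhp_insts = [min(dhp_insts)]
            rec_insts = [min(rec_insts)]
        for di in dhp_insts:
            for ri in rec_insts:
                counts[dhp_clusters.assignments[di],
                       rec_clusters.assignments[ri]] += 1
    df = pd.DataFrame(counts, index=range(n_dhp), columns=range(n_rec))
    df.index.name = "dhp_cluster"
    return InteractionTable(counts=df)


@dataclass
class PartnerPrediction:
    """Ranked REC clusters for one DHp cluster, with optional candidates."""

    hpk_cluster: int
    ranking: list[tuple[int, float]]  # (rec_cluster, probability), best first
    no_prediction: bool = False
    #: per returned REC cluster, that species' candidate regulator proteins
    candidates: dict[int, list[str]] | None = None

    @property
    def best_cluster(self) -> int | None:
        return self.ranking[0][0] if self.ranking else None


def predict_partners(
    hpk_cluster: int,
    table: InteractionTable,
    rec_clusters: ClusterSet,
    species_filter: str | None = None,
    top_k: int = 1,
    rec_instances: Sequence[DomainInstance] | None = None,
) -> PartnerPrediction:
    """Rank candidate REC clusters for a DHp cluster from its table row.

    Ranking is by probability, ties broken by larger raw count then lower
    cluster id.  A zero row returns an explicit no-prediction result.
    With ``species_filter`` set, ``rec_instances`` supplies the species
    metadata needed to list that species' regulator proteins in each
    returned cluster.
    """
    if hpk_cluster not in table.counts.index:
        raise KeyError(f"unknown DHp cluster {hpk_cluster}")
    row_counts = table.counts.loc[hpk_cluster]
    if row_counts.sum() == 0:
        return PartnerPrediction(hpk_cluster=hpk_cluster, ranking=[],
                                 no_prediction=True)
    row_probs = table.probabilities.loc[hpk_cluster]
    order = sorted(
        (c for c in table.counts.columns if row_counts[c] > 0),
        key=lambda c: (-row_probs[c], -row_counts[c], c),
    )[:top_k]
    ranking = [(int(c), float(row_probs[c])) for c in order]
    candidates: dict[int, list[str]] | None = None
    if species_filter is not None:
        if rec_instances is None:
            raise ValueError("species_filter requires rec_instances")
        candidates = {}
        for cluster_id, _prob in ranking:
            members = {
                inst.protein_id for inst in rec_instances
                if inst.species == species_filter
                and rec_clusters.assignments.get(inst.instance_id) == cluster_id
            }
            candidates[cluster_id] = sorted(members)
    return PartnerPrediction(hpk_cluster=hpk_cluster, ranking=ranking,
                             candidates=candidates)


@dataclass
class CrosstalkReport:
    """Predicted host proteins at risk of cross-talk with an introduced TCS.

    ``kinase_candidates`` are host kinases whose DHp instance shares the
    query's cluster (they compete for the same regulators); the query's
    own protein is never listed.  ``substrate_candidates`` are host
    regulators whose REC instance lies in the query cluster's top partner
    cluster(s).  Empty lists are a valid "no cross-talk predicted" answer.
    """

    query: str
    host_species: str
    query_cluster: int | None = None
    best_hit_id: str | None = None
    partner_clusters: list[int] = field(default_factory=list)
    kinase_candidates: list[str] = field(default_factory=list)
    substrate_candidates: list[str] = field(default_factory=list)
    unassignable: bool = False
    no_prediction: bool = False


def _resolve_query(
    query: str,
    dhp_clusters: ClusterSet,
    dhp_instances: Sequence[DomainInstance],
    scheme: ScoringScheme | None,
    evalue_cutoff: float,
) -> tuple[int | None, str | None, str | None]:
    """Return (cluster, best_hit_id, query_protein_id or None)."""
    if query in dhp_clusters.assignments:
        return dhp_clusters.assignments[query], query, protein_of_instance(query)
    own = [i for i in dhp_instances
           if i.protein_id == query and i.instance_id in dhp_clusters.assignments]
    if own:
        best = min(own, key=lambda i: (i.evalue, i.instance_id))
        return dhp_clusters.assignments[best.instance_id], best.instance_id, query
    result: NearestClusterResult = nearest_cluster(
        query, dhp_instances, dhp_clusters, scheme, evalue_cutoff)
    return result.cluster_id, result.best_hit_id, None


def predict_crosstalk(
    query: str,
    host_species: str,
    dhp_clusters: ClusterSet,
    rec_clusters: ClusterSet,
    table: InteractionTable,
    dhp_instances: Sequence[DomainInstance],
    rec_instances: Sequence[DomainInstance],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    top_k: int = 1,
    probability_floor: float = 0.0,
) -> CrosstalkReport:
    """Predict host proteins that may cross-talk with an introduced kinase.

    ``query`` may be a clustered DHp instance id, a protein id carrying a
    clustered DHp instance, or a novel amino-acid sequence (routed to its
    nearest cluster by local alignment; an unassignable sequence yields an
    explicit unassignable report).  The host species must be present in
    the database.
    """
    known_species = ({i.species for i in dhp_instances}
                     | {i.species for i in rec_instances})
    if host_species not in known_species:
        raise KeyError(f"host species {host_species!r} absent from database")
    cluster, best_hit, query_protein = _resolve_query(
        query, dhp_clusters, dhp_instances, scheme, evalue_cutoff)
    if cluster is None:
        return CrosstalkReport(query=query, host_species=host_species,
                               unassignable=True)
    kinase_candidates = sorted({
        inst.protein_id for inst in dhp_instances
        if inst.species == host_species
        and dhp_clusters.assignments.get(inst.instance_id) == cluster
        and inst.protein_id != query_protein
    })
    prediction = predict_partners(cluster, table, rec_clusters, top_k=top_k)
    partner_clusters = [c for c, p in prediction.ranking
                        if p > probability_floor]
    substrate_candidates = sorted({
        inst.protein_id for inst in rec_instances
        if inst.species == host_species
        and rec_clusters.assignments.get(inst.instance_id) in partner_clusters
    }) if partner_clusters else []
    return CrosstalkReport(
        query=query,
        host_species=host_species,
        query_cluster=int(cluster),
        best_hit_id=best_hit,
        partner_clusters=partner_clusters,
        kinase_candidates=kinase_candidates,
        substrate_candidates=substrate_candidates,
        no_prediction=prediction.no_prediction,
    )
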