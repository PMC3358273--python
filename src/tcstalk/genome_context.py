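"""Operon assignment and genomic-context cognate pairing.

Genes are merged into operons when consecutive along a replicon, on the
same strand and separated by at most ``max_gap_bp`` intergenic bases.
A kinase (DHp-carrying) and regulator (REC-carrying) protein encoded in
one operon with at most two intervening genes are treated as a probable
cognate pair; kinases and regulators that never pair this way are the
orphans whose partners the interaction table is later asked to predict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import GeneLocus

#: default maximum intergenic distance (bp) joining two genes into an operon
DEFAULT_MAX_GAP_BP = 200
#: default maximum number of genes allowed between cognate partners
DEFAULT_MAX_INTERVENING = 2


@dataclass
class OperonAssignment:
    """Mapping of gene ids to globally dense operon ids, in genome order."""

    operon_of: dict[str, int]

    @property
    def n_operons(self) -> int:
        return len(set(self.operon_of.values())) if self.operon_of else 0

    def genes_in(self, operon_id: int) -> list[str]:
        return sorted(g for g, o in self.operon_of.items() if o == operon_id)


@dataclass(frozen=True)
class CognatePair:
    """A kinase and regulator predicted cognate from shared-operon context."""

    hpk_protein_id: str
    rr_protein_id: str
    species: str
    operon_id: int
    intervening_gene_count: int
    hybrid: bool = False  # both domains on one polypeptide

    def __post_init__(self) -> None:
        if self.intervening_gene_count < 0:
            raise ValueError("intervening_gene_count must be >= 0")


def assign_operons(
    loci: Sequence[GeneLocus], max_gap_bp: int = DEFAULT_MAX_GAP_BP
) -> OperonAssignment:
    """Merge consecutive co-oriented, closely spaced genes into operons.

    Two ordinally adjacent genes share an operon iff they lie on the same
    replicon and strand and the intergenic distance
    ``next.start - prev.end - 1`` is at most ``max_gap_bp``.  Operon ids
    are dense integers assigned in genome order (replicon, then position).
    """
    operon_of: dict[str, int] = {}
    next_id = 0
    by_replicon: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in loci:
        by_replicon.setdefault((locus.species, locus.replicon), []).append(locus)
    for key in sorted(by_replicon):
        group = sorted(by_replicon[key], key=lambda g: g.ordinal)
        prev: GeneLocus | None = None
        for gene in group:
            if prev is not None and (
                gene.strand == prev.strand
                and gene.start - prev.end - 1 <= max_gap_bp
            ):
                operon_of[gene.gene_id] = operon_of[prev.gene_id]
            else:
                operon_of[gene.gene_id] = next_id
                next_id += 1
            prev = gene
    return OperonAssignment(operon_of=operon_of)


def cognate_pairs(
    assignment: OperonAssignment,
    loci: Sequence[GeneLocus],
    hpk_ids: Iterable[str],
    rr_ids: Iterable[str],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[CognatePair]:
    """Kinase-regulator pairs sharing an operon within the gene-gap rule.

    A pair is emitted for every (kinase, regulator) protein combination in
    one operon with at most ``max_intervening`` genes strictly between
    their ordinals; a kinase flanked by two qualifying regulators yields
    two pairs.  A hybrid protein (both domain classes on one polypeptide)
    pairs with itself at intervening count 0 and remains eligible for
    cross-protein pairs.  Output is sorted by (species, kinase, regulator).
    """
    hpk_set, rr_set = set(hpk_ids), set(rr_ids)
    by_operon: dict[int, list[GeneLocus]] = {}
    for locus in loci:
        operon = assignment.operon_of.get(locus.gene_id)
        if operon is not None:
            by_operon.setdefault(operon, []).append(locus)
    pairs: list[CognatePair] = []
    for operon_id, genes in by_operon.items():
        hpks = [g for g in genes if g.protein_id in hpk_set]
        rrs = [g for g in genes if g.protein_id in rr_set]
        for h in hpks:
            for r in rrs:
                if h.protein_id == r.protein_id:
                    intervening, hybrid = 0, True
                else:
                    intervening = abs(h.ordinal - r.ordinal) - 1
                    hybrid = False
                if intervening <= max_intervening:
                    pairs.append(CognatePair(
                        hpk_protein_id=h.protein_id,
                        rr_protein_id=r.protein_id,
                        species=h.species,
                        operon_id=operon_id,
                        intervening_gene_count=intervening,
                        hybrid=hybrid,
                    ))
    pairs.sort(key=lambda p: (p.species, p.hpk_protein_id, p.rr_protein_id))
    return pairs


def find_orphans(
    assignment: OperonAssignment,
    loci: Sequence[GeneLocus],
    hpk_ids: Iterable[str],
    rr_ids: Iterable[str],
    pairs: Sequence[CognatePair],
) -> tuple[list[str], list[str]]:
    """Kinases and regulators that appear in no cognate pair.

    Orphans are the proteins whose partner is not apparent from genomic
    context; they are exactly the queries the interaction table exists to
    answer.  Each returned list is sorted by species then protein id.
    """
    paired_hpks = {p.hpk_protein_id for p in pairs}
    paired_rrs = {p.rr_protein_id for p in pairs}
    species_of = {g.protein_id: g.species for g in loci}
    hpk_set = set(hpk_ids) & set(species_of)
    rr_set = set(rr_ids) & set(species_of)
    orphan_hpks = sorted(hpk_set - paired_hpks,
                         key=lambda p: (species_of[p], p))
    orphan_rrs = sorted(rr_set - paired_rrs,
                        key=lambda p: (species_of[p], p))
    return orphan_hpks, orphan_rrs


_PAIR_COLUMNS = ["hpk_protein_id", "rr_protein_id", "species", "operon_id",
                 "intervening_gene_count", "hybrid"]


def write_pairs_table(
    pairs: Iterable[CognatePair], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write cognate pairs as TSV (round-trips through the reader)."""
    rows = [[p.hpk_protein_id, p.rr_protein_id, p.species, p.operon_id,
             p.intervening_gene_count, int(p.hybrid)] for p in pairs]
    df = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> list[CognatePair]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        CognatePair(
            hpk_protein_id=r.hpk_protein_id, rr_protein_id=r.rr_protein_id,
            species=r.species, operon_id=int(r.operon_id),
            intervening_gene_count=int(r.intervening_gene_count),
            hybrid=bool(int(r.hybrid)),
        )
        for r in df.itertuples(index=False)
    ]
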