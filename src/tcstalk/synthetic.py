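"""Synthetic multi-species TCS genomes with known ground truth.

The generator emulates the statistical structure the pipeline exploits in
real bacterial genomes: each species carries many kinase/regulator operon
pairs drawn from sequence families (one consensus per family, members are
point-mutated copies — a star phylogeny), families are paired by a fixed
bijection (family k kinases always partner family pi(k) regulators),
operons may contain up to two intervening decoy genes, and a few kinases
and regulators are planted as orphans in single-gene operons.  An
optional scenario removes one kinase family's operons from a designated
host species and plants a lone orphan kinase of that family plus a lone
orphan regulator of its partner family there — the layout in which a
foreign kinase introduced into the host has exactly one cluster-mate and
one predicted substrate.

Everything is drawn from one seeded generator, so a fixed seed gives
byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import (DomainHit, GeneLocus, Model, ProteinRecord,
                          assign_ordinals, write_domtblout, write_fasta,
                          write_gene_table)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: model names used in emitted domtblout files
MODEL_NAMES = {Model.DHP: "DHp_synth", Model.REC: "REC_synth"}
#: the matching map for :func:`tcstalk.sequence_io.read_domtblout`
MODEL_MAP = {name: model for model, name in MODEL_NAMES.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic multi-species dataset.

    Defaults describe the benchmark condition: 5 species, 8 kinase and 8
    regulator families under a seeded random bijective pairing, 10
    members per family per species, 60-residue domains mutated at 5% per
    residue, and 3 planted orphan kinases plus 3 planted orphan
    regulators spread round-robin over species.
    """

    n_species: int = 5
    n_hpk_families: int = 8
    n_rr_families: int = 8
    members_per_family_per_species: int = 10
    domain_length: int = 60
    within_family_mutation_rate: float = 0.05
    #: kinase family -> regulator family bijection; None draws a random
    #: permutation from the seed
    family_pairing: tuple[int, ...] | None = None
    #: intervening decoy genes per operon, sampled uniformly from this set
    decoy_choices: tuple[int, ...] = (0, 1, 2)
    n_orphan_hpks: int = 3
    n_orphan_rrs: int = 3
    #: operon-joining gap threshold the layout respects (bp)
    operon_gap_threshold: int = 200
    intra_operon_gap: tuple[int, int] = (5, 150)
    inter_operon_gap: tuple[int, int] = (400, 900)
    #: E-value written for every synthetic domain hit
    hit_evalue: float = 1e-40
    #: scenario knob: omit this kinase family's operons in crosstalk_host
    #: and plant a lone orphan kinase of the family plus a lone orphan
    #: regulator of its partner family there
    crosstalk_family: int | None = None
    crosstalk_host: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_family_mutation_rate < 0.5):
            raise ValueError("mutation rate must lie in [0, 0.5)")
        if self.n_hpk_families != self.n_rr_families:
            raise ValueError("bijective pairing needs equal family counts")
        if self.family_pairing is not None:
            if sorted(self.family_pairing) != list(range(self.n_rr_families)):
                raise ValueError("family_pairing must be a permutation")
        if max(self.intra_operon_gap) > self.operon_gap_threshold:
            raise ValueError("intra-operon gaps must respect the operon threshold")
        if min(self.inter_operon_gap) <= self.operon_gap_threshold:
            raise ValueError("inter-operon gaps must exceed the operon threshold")
        if (self.crosstalk_family is None) != (self.crosstalk_host is None):
            raise ValueError("set both crosstalk_family and crosstalk_host or neither")
        if self.crosstalk_family is not None:
            if not (0 <= self.crosstalk_family < self.n_hpk_families):
                raise ValueError("crosstalk_family out of range")
            if not (0 <= self.crosstalk_host < self.n_species):
                raise ValueError("crosstalk_host out of range")
        if not (0 < self.hit_evalue < 0.01):
            raise ValueError("hit_evalue must clear the inclusion threshold")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus ground truth; writable via :func:`write_dataset`."""

    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    loci: list[GeneLocus]
    ground_truth: dict
    config: SimulationConfig
    hpk_consensus: list[str] = field(default_factory=list)
    rec_consensus: list[str] = field(default_factory=list)

    def species_of(self, protein_id: str) -> str:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p.species
        raise KeyError(protein_id)


def species_name(index: int) -> str:
    return f"sp{index:02d}"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    for i, c in enumerate(out):
        if rng.random() < rate:
            # substitute with one of the 19 other residues
            choice = AA_ALPHABET[rng.integers(0, 19)]
            out[i] = choice if choice != c else AA_ALPHABET[19]
    return "".join(out)


class _Builder:
    """Accumulates proteins/genes while handing out sequential ids."""

    def __init__(self, config: SimulationConfig) -> None:
        self.config = config
        self.proteins: list[ProteinRecord] = []
        self.hits: list[DomainHit] = []
        self.loci: list[GeneLocus] = []
        self._protein_counter = 0
        self._gene_counter = 0

    def new_protein(self, species: str, sequence: str,
                    replicon: str) -> ProteinRecord:
        self._protein_counter += 1
        rec = ProteinRecord(
            protein_id=f"{90000000 + self._protein_counter}",
            species=species, sequence=sequence, replicon=replicon)
        self.proteins.append(rec)
        return rec

    def add_gene(self, protein: ProteinRecord, replicon: str,
                 start: int, strand: str) -> GeneLocus:
        self._gene_counter += 1
        end = start + 3 * len(protein.sequence) - 1
        locus = GeneLocus(
            gene_id=f"g{self._gene_counter:06d}",
            protein_id=protein.protein_id, species=protein.species,
            replicon=replicon, start=start, end=end, strand=strand)
        self.loci.append(locus)
        return locus

    def add_hit(self, protein: ProteinRecord, model: Model) -> None:
        self.hits.append(DomainHit(
            protein_id=protein.protein_id, model=model,
            env_start=1, env_end=len(protein.sequence),
            evalue=self.config.hit_evalue, hit_rank=1))


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one multi-species dataset with full ground truth.

    Per species a single replicon carries, in genome order: for every
    kinase family, ``members_per_family_per_species`` operons laid out as
    kinase, 0-2 decoys, partner-family regulator (one strand per operon,
    intra-operon gaps at or below the operon threshold, inter-operon gaps
    above it); then any planted orphans, each in a single-gene operon.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    n_fam = config.n_hpk_families
    if config.family_pairing is not None:
        pairing = list(config.family_pairing)
    else:
        pairing = [int(x) for x in rng.permutation(n_fam)]
    hpk_consensus = [_random_seq(rng, config.domain_length) for _ in range(n_fam)]
    rec_consensus = [_random_seq(rng, config.domain_length) for _ in range(n_fam)]

    builder = _Builder(config)
    hpk_family_of: dict[str, int] = {}
    rr_family_of: dict[str, int] = {}
    true_pairs: list[tuple[str, str]] = []
    orphan_hpks: list[str] = []
    orphan_rrs: list[str] = []
    crosstalk_truth: dict | None = None

    # round-robin placement of the planted orphans; in the cross-talk
    # scenario the host species must carry exactly one kinase of the
    # scenario family (and one partner-family regulator), so ordinary
    # orphans placed there step over that family
    def _orphan_family(i: int, sp: int) -> int:
        fam = i % n_fam
        if (config.crosstalk_family is not None and sp == config.crosstalk_host
                and fam == config.crosstalk_family):
            fam = (fam + 1) % n_fam
        return fam

    orphan_hpk_plan: dict[int, list[int]] = {}  # species -> families
    for i in range(config.n_orphan_hpks):
        sp = i % config.n_species
        orphan_hpk_plan.setdefault(sp, []).append(_orphan_family(i, sp))
    orphan_rr_plan: dict[int, list[int]] = {}  # species -> REC families
    for i in range(config.n_orphan_rrs):
        sp = i % config.n_species
        orphan_rr_plan.setdefault(sp, []).append(pairing[_orphan_family(i, sp)])

    rate = config.within_family_mutation_rate
    for sp_idx in range(config.n_species):
        species = species_name(sp_idx)
        replicon = f"{species}_chr"
        cursor = 1

        def place_operon(genes: list[tuple[ProteinRecord, Model | None]]) -> None:
            nonlocal cursor
            strand = "+" if rng.random() < 0.5 else "-"
            for j, (protein, model) in enumerate(genes):
                if j > 0:
                    lo, hi = config.intra_operon_gap
                    cursor += int(rng.integers(lo, hi + 1)) + 1
                locus = builder.add_gene(protein, replicon, cursor, strand)
                cursor = locus.end
                if model is not None:
                    builder.add_hit(protein, model)
            lo, hi = config.inter_operon_gap
            cursor += int(rng.integers(lo, hi + 1)) + 1

        for fam in range(n_fam):
            if (config.crosstalk_family == fam
                    and config.crosstalk_host == sp_idx):
                continue
            for _member in range(config.members_per_family_per_species):
                hpk_seq = _mutate(rng, hpk_consensus[fam], rate)
                rr_seq = _mutate(rng, rec_consensus[pairing[fam]], rate)
                hpk = builder.new_protein(species, hpk_seq, replicon)
                rr = builder.new_protein(species, rr_seq, replicon)
                n_decoys = int(rng.choice(config.decoy_choices))
                decoys = [
                    builder.new_protein(
                        species, _random_seq(rng, config.domain_length), replicon)
                    for _ in range(n_decoys)
                ]
                genes: list[tuple[ProteinRecord, Model | None]] = (
                    [(hpk, Model.DHP)]
                    + [(d, None) for d in decoys]
                    + [(rr, Model.REC)]
                )
                place_operon(genes)
                hpk_family_of[hpk.protein_id] = fam
                rr_family_of[rr.protein_id] = pairing[fam]
                true_pairs.append((hpk.protein_id, rr.protein_id))

        for fam in orphan_hpk_plan.get(sp_idx, []):
            orphan = builder.new_protein(
                species, _mutate(rng, hpk_consensus[fam], rate), replicon)
            place_operon([(orphan, Model.DHP)])
            hpk_family_of[orphan.protein_id] = fam
            orphan_hpks.append(orphan.protein_id)
        for rec_fam in orphan_rr_plan.get(sp_idx, []):
            orphan = builder.new_protein(
                species, _mutate(rng, rec_consensus[rec_fam], rate), replicon)
            place_operon([(orphan, Model.REC)])
            rr_family_of[orphan.protein_id] = rec_fam
            orphan_rrs.append(orphan.protein_id)

        if (config.crosstalk_family is not None
                and config.crosstalk_host == sp_idx):
            fam = config.crosstalk_family
            lone_hpk = builder.new_protein(
                species, _mutate(rng, hpk_consensus[fam], rate), replicon)
            place_operon([(lone_hpk, Model.DHP)])
            hpk_family_of[lone_hpk.protein_id] = fam
            orphan_hpks.append(lone_hpk.protein_id)
            lone_rr = builder.new_protein(
                species, _mutate(rng, rec_consensus[pairing[fam]], rate), replicon)
            place_operon([(lone_rr, Model.REC)])
            rr_family_of[lone_rr.protein_id] = pairing[fam]
            orphan_rrs.append(lone_rr.protein_id)
            crosstalk_truth = {
                "family": fam,
                "host_species": species,
                "host_hpks": [lone_hpk.protein_id],
                "host_rrs": [lone_rr.protein_id],
            }

    ground_truth = {
        "family_pairing": pairing,
        "hpk_family_of_protein": hpk_family_of,
        "rr_family_of_protein": rr_family_of,
        "true_pairs": sorted(true_pairs),
        "orphan_hpks": sorted(orphan_hpks),
        "orphan_rrs": sorted(orphan_rrs),
        "crosstalk": crosstalk_truth,
        "foreign": None,
    }
    return SyntheticDataset(
        proteins=builder.proteins,
        hits=builder.hits,
        loci=assign_ordinals(builder.loci),
        ground_truth=ground_truth,
        config=config,
        hpk_consensus=hpk_consensus,
        rec_consensus=rec_consensus,
    )


FOREIGN_SPECIES = "foreign"


def plant_foreign_tcs(
    dataset: SyntheticDataset,
    source_family: int,
    host_species: str,
    include_rr: bool = False,
    seed_offset: int = 10007,
) -> SyntheticDataset:
    """Add a foreign kinase (and optionally regulator) from a known family.

    The newcomer is a fresh point-mutated copy of ``source_family``'s
    consensus tagged with a dedicated foreign species name, mirroring the
    introduction of a well-characterised TCS into an alternate host.  The
    returned dataset's ground truth records the host proteins expected in
    a cross-talk report: host kinases of the same family and host
    regulators of the partner family.
    """
    config = dataset.config
    if not (0 <= source_family < config.n_hpk_families):
        raise ValueError(f"unknown source family {source_family}")
    if host_species not in {p.species for p in dataset.proteins}:
        raise ValueError(f"unknown host species {host_species!r}")
    rng = np.random.default_rng(config.rng_seed + seed_offset)
    builder = _Builder(config)
    builder._protein_counter = len(dataset.proteins) + 1000
    builder._gene_counter = len(dataset.loci) + 1000

    replicon = f"{FOREIGN_SPECIES}_chr"
    rate = config.within_family_mutation_rate
    cursor = 1
    foreign_hpk = builder.new_protein(
        FOREIGN_SPECIES,
        _mutate(rng, dataset.hpk_consensus[source_family], rate), replicon)
    locus = builder.add_gene(foreign_hpk, replicon, cursor, "+")
    builder.add_hit(foreign_hpk, Model.DHP)
    foreign_rr_id = None
    if include_rr:
        partner = dataset.ground_truth["family_pairing"][source_family]
        cursor = locus.end + min(config.inter_operon_gap) + 1
        foreign_rr = builder.new_protein(
            FOREIGN_SPECIES,
            _mutate(rng, dataset.rec_consensus[partner], rate), replicon)
        builder.add_gene(foreign_rr, replicon, cursor, "+")
        builder.add_hit(foreign_rr, Model.REC)
        foreign_rr_id = foreign_rr.protein_id

    partner_family = dataset.ground_truth["family_pairing"][source_family]
    species_by_protein = {p.protein_id: p.species for p in dataset.proteins}
    expected_hpks = sorted(
        pid for pid, fam in dataset.ground_truth["hpk_family_of_protein"].items()
        if fam == source_family and species_by_protein[pid] == host_species)
    expected_rrs = sorted(
        pid for pid, fam in dataset.ground_truth["rr_family_of_protein"].items()
        if fam == partner_family and species_by_protein[pid] == host_species)

    ground_truth = dict(dataset.ground_truth)
    hpk_fams = dict(ground_truth["hpk_family_of_protein"])
    hpk_fams[foreign_hpk.protein_id] = source_family
    ground_truth["hpk_family_of_protein"] = hpk_fams
    if foreign_rr_id is not None:
        rr_fams = dict(ground_truth["rr_family_of_protein"])
        rr_fams[foreign_rr_id] = partner_family
        ground_truth["rr_family_of_protein"] = rr_fams
    ground_truth["foreign"] = {
        "protein_id": foreign_hpk.protein_id,
        "rr_protein_id": foreign_rr_id,
        "family": source_family,
        "partner_family": partner_family,
        "host_species": host_species,
        "expected_kinase_candidates": expected_hpks,
        "expected_substrate_candidates": expected_rrs,
    }
    return SyntheticDataset(
        proteins=dataset.proteins + builder.proteins,
        hits=dataset.hits + builder.hits,
        loci=assign_ordinals(dataset.loci + builder.loci),
        ground_truth=ground_truth,
        config=config,
        hpk_consensus=dataset.hpk_consensus,
        rec_consensus=dataset.rec_consensus,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in exactly the formats the pipeline readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "domtblout": outdir / "domains.domtblout",
        "genes": outdir / "genes.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(dataset.proteins, paths["fasta"])
    lengths = {p.protein_id: len(p.sequence) for p in dataset.proteins}
    write_domtblout(dataset.hits, paths["domtblout"], MODEL_NAMES, lengths)
    write_gene_table(dataset.loci, paths["genes"])
    truth = dict(dataset.ground_truth)
    truth["config"] = dataclasses.asdict(dataset.config)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
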