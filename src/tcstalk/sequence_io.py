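"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`DomainHit` and :class:`GeneLocus`, plus the
:class:`ClusterSet` produced by the clustering stage.

Conventions
-----------
* Coordinates are 1-based and inclusive everywhere (GFF3 convention), both
  for nucleotides on a replicon and for residues within a protein.
* FASTA headers follow a pipe-delimited grammar::

      >protein_id|species[|replicon]

  ``protein_id`` is an opaque unique token that must not contain ``|`` or
  ``/``; ``species`` may contain spaces.
* Tabular outputs may start with ``#``-prefixed provenance comment lines;
  every reader here skips them.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: letters accepted in a sequence after ingest
VALID_AA = CANONICAL_AA | {"X"}


class Model(str, enum.Enum):
    """Domain model class: kinase-side DHp or regulator-side REC."""

    DHP = "DHP"
    REC = "REC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species/replicon metadata."""

    protein_id: str
    species: str
    sequence: str
    replicon: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain hit on a protein, as reported by a profile-HMM search."""

    protein_id: str
    model: Model
    env_start: int  # 1-based inclusive envelope coordinates
    env_end: int
    evalue: float  # per-domain independent E-value
    hit_rank: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"hit on {self.protein_id!r}: bad envelope "
                f"{self.env_start}..{self.env_end}"
            )
        if self.evalue < 0:
            raise ValueError(f"hit on {self.protein_id!r}: negative E-value")
        if self.hit_rank < 1:
            raise ValueError(f"hit on {self.protein_id!r}: hit_rank < 1")


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a replicon; the substrate of operon logic.

    ``ordinal`` is the 0-based index of the gene along its replicon after
    sorting by start coordinate; it is assigned by :func:`read_gene_table`
    (or :func:`assign_ordinals`), not by the caller.
    """

    gene_id: str
    protein_id: str
    species: str
    replicon: str
    start: int
    end: int
    strand: str  # "+" or "-"
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass
class ClusterSet:
    """A strict partition of domain instances into dense numbered clusters."""

    assignments: dict[str, int]
    model: Model | None = None
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values())) if self.assignments else 0

    def members(self, cluster_id: int) -> list[str]:
        return sorted(k for k, v in self.assignments.items() if v == cluster_id)

    def cluster_of(self, instance_id: str) -> int:
        return self.assignments[instance_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterSet):
            return NotImplemented
        return self.assignments == other.assignments and self.model == other.model


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(description: str) -> tuple[str, str, str | None]:
    parts = [p.strip() for p in description.split("|")]
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"FASTA header {description!r} does not match "
            "'protein_id|species[|replicon]'"
        )
    replicon = parts[2] if len(parts) > 2 and parts[2] else None
    return parts[0], parts[1], replicon


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a pipe-delimited-header FASTA file.

    Sequences are uppercased and ``*`` terminators stripped.  Residues
    outside the 20 canonical letters (other than ``X``) are replaced by
    ``X`` with a warning.  Duplicate protein ids or empty sequences are
    hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id, species, replicon = _parse_header(rec.description)
        if protein_id in seen:
            raise ValueError(f"duplicate protein_id {protein_id!r} in {path}")
        seen.add(protein_id)
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValueError(f"protein {protein_id!r} in {path}: empty sequence")
        bad = sorted(set(seq) - VALID_AA)
        if bad:
            warnings.warn(
                f"protein {protein_id!r}: unknown residue(s) "
                f"{''.join(bad)} replaced with X",
                stacklevel=2,
            )
            seq = "".join(c if c in VALID_AA else "X" for c in seq)
        records.append(ProteinRecord(protein_id, species, seq, replicon))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records in the pipe-delimited header grammar (round-trips)."""
    seqs = []
    for r in records:
        header = f"{r.protein_id}|{r.species}"
        if r.replicon is not None:
            header += f"|{r.replicon}"
        seqs.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

#: column indices of the HMMER3 per-domain table (whitespace separated)
_DOMTBL_TARGET = 0
_DOMTBL_QUERY = 3
_DOMTBL_DOM_NUM = 9
_DOMTBL_I_EVALUE = 12
_DOMTBL_ENV_FROM = 19
_DOMTBL_ENV_TO = 20
_DOMTBL_MIN_FIELDS = 22


def read_domtblout(
    path: str | Path, model_map: Mapping[str, Model]
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file into :class:`DomainHit` objects.

    ``model_map`` maps model (query) names to :class:`Model`; domain lines
    whose model name is not in the map are skipped with a log message.
    Envelope columns supply the coordinates and the per-domain independent
    E-value column supplies ``evalue``.  A malformed line raises with its
    line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout line "
                    f"({len(fields)} fields, expected >= {_DOMTBL_MIN_FIELDS})"
                )
            model_name = fields[_DOMTBL_QUERY]
            if model_name not in model_map:
                logger.info(
                    "%s:%d: skipping hit for unmapped model %r",
                    path, lineno, model_name,
                )
                continue
            try:
                hit = DomainHit(
                    protein_id=fields[_DOMTBL_TARGET],
                    model=model_map[model_name],
                    env_start=int(fields[_DOMTBL_ENV_FROM]),
                    env_end=int(fields[_DOMTBL_ENV_TO]),
                    evalue=float(fields[_DOMTBL_I_EVALUE]),
                    hit_rank=int(fields[_DOMTBL_DOM_NUM]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(
    hits: Iterable[DomainHit],
    path: str | Path,
    model_names: Mapping[Model, str],
    protein_lengths: Mapping[str, int] | None = None,
) -> None:
    """Emit hits in HMMER3 per-domain tabular format (round-trips).

    Columns this pipeline does not consume (full-sequence scores, hmm/ali
    coordinates) are filled with neutral placeholders.
    """
    protein_lengths = protein_lengths or {}
    with open(path, "w") as fh:
        fh.write(
            "# target name        accession   tlen query name           "
            "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
            "i-Evalue  score  bias  from    to  from    to  from    to  "
            "acc description of target\n"
        )
        for h in hits:
            tlen = protein_lengths.get(h.protein_id, h.env_end)
            qlen = h.env_end - h.env_start + 1
            fh.write(
                f"{h.protein_id} - {tlen} {model_names[h.model]} - {qlen} "
                f"{h.evalue:.2g} 0.0 0.0 {h.hit_rank} {h.hit_rank} "
                f"{h.evalue:.2g} {h.evalue:.2g} 0.0 0.0 "
                f"{h.env_start} {h.env_end} {h.env_start} {h.env_end} "
                f"{h.env_start} {h.env_end} 0.99 -\n"
            )


# ---------------------------------------------------------------------------
# gene coordinate tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "protein_id", "species", "replicon",
                 "start", "end", "strand"]


def assign_ordinals(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Sort loci per replicon by start and assign dense 0-based ordinals."""
    out: list[GeneLocus] = []
    by_replicon: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in loci:
        by_replicon.setdefault((locus.species, locus.replicon), []).append(locus)
    for key in sorted(by_replicon):
        group = sorted(by_replicon[key], key=lambda g: (g.start, g.end, g.gene_id))
        seen_coords: set[tuple[int, int]] = set()
        for ordinal, locus in enumerate(group):
            if (locus.start, locus.end) in seen_coords:
                warnings.warn(
                    f"genes with identical coordinates {locus.start}..{locus.end} "
                    f"on {locus.replicon} (kept, e.g. {locus.gene_id!r})",
                    stacklevel=2,
                )
            seen_coords.add((locus.start, locus.end))
            out.append(replace(locus, ordinal=ordinal))
    return out


def _read_gene_tsv(path: str | Path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene table columns {sorted(missing)}")
    loci = []
    for row in df.itertuples(index=False):
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ValueError(
                f"{path}: gene {row.gene_id!r} has missing/invalid strand "
                f"{strand!r}"
            )
        loci.append(GeneLocus(
            gene_id=str(row.gene_id), protein_id=str(row.protein_id),
            species=str(row.species), replicon=str(row.replicon),
            start=int(row.start), end=int(row.end), strand=strand,
        ))
    return loci


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _read_gene_gff3(path: str | Path, default_species: str | None) -> list[GeneLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = cols
            if ftype not in ("gene", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            attrs = _parse_gff_attributes(attr)
            protein_id = attrs.get("protein_id")
            if protein_id is None:
                raise ValueError(f"{path}:{lineno}: feature lacks protein_id attribute")
            species = attrs.get("species", default_species)
            if species is None:
                raise ValueError(
                    f"{path}:{lineno}: no species attribute and no default_species"
                )
            loci.append(GeneLocus(
                gene_id=attrs.get("ID", protein_id), protein_id=protein_id,
                species=species, replicon=seqid,
                start=int(start), end=int(end), strand=strand,
            ))
    return loci


def read_gene_table(
    path: str | Path, default_species: str | None = None
) -> list[GeneLocus]:
    """Read gene loci from a TSV table or a GFF3 subset; assign ordinals.

    A file whose name ends in ``.gff``/``.gff3`` (or whose first line is a
    ``##gff-version`` pragma) is parsed as GFF3 restricted to ``gene``/``CDS``
    features carrying a ``protein_id`` attribute; anything else is parsed as
    a TSV with columns gene_id, protein_id, species, replicon, start, end,
    strand.  Ordinals are assigned per replicon after sorting by start.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    if not is_gff:
        with open(path) as fh:
            first = fh.readline()
        is_gff = first.startswith("##gff-version")
    loci = (_read_gene_gff3(path, default_species) if is_gff
            else _read_gene_tsv(path))
    return assign_ordinals(loci)


def write_gene_table(
    loci: Iterable[GeneLocus], path: str | Path, header_comment: str | None = None
) -> None:
    """Write loci as the TSV dialect :func:`read_gene_table` accepts."""
    rows = [[g.gene_id, g.protein_id, g.species, g.replicon,
             g.start, g.end, g.strand] for g in loci]
    df = pd.DataFrame(rows, columns=_GENE_COLUMNS)
    _write_tsv(df, path, header_comment)


# ---------------------------------------------------------------------------
# cluster and probability tables (supplementary-table style outputs)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_cluster_table(
    clusters: ClusterSet,
    instances: Sequence,  # Sequence[DomainInstance]; avoids circular import
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write one row per clustered domain instance with its metadata."""
    meta = {i.instance_id: i for i in instances}
    rows = []
    for instance_id in sorted(clusters.assignments):
        inst = meta.get(instance_id)
        rows.append([
            instance_id,
            inst.protein_id if inst else instance_id.rsplit("/", 2)[0],
            inst.species if inst else "",
            (inst.model.value if inst else
             (clusters.model.value if clusters.model else "")),
            clusters.assignments[instance_id],
        ])
    df = pd.DataFrame(
        rows, columns=["domain_instance_id", "protein_id", "species",
                       "model", "cluster_id"],
    )
    _write_tsv(df, path, header_comment)


def read_cluster_table(path: str | Path) -> ClusterSet:
    """Read a cluster table written by :func:`write_cluster_table`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    assignments = dict(zip(df["domain_instance_id"], df["cluster_id"].astype(int)))
    models = set(df["model"].dropna()) - {""}
    model = Model(models.pop()) if len(models) == 1 else None
    return ClusterSet(assignments=assignments, model=model)


def write_probability_table(table, path: str | Path,
                            header_comment: str | None = None) -> None:
    """Write the row-stochastic DHp-cluster x REC-cluster probability matrix.

    Rows are DHp cluster ids, columns REC cluster ids; each supported row
    sums to 1.  ``table`` is an :class:`~tcstalk.interaction.InteractionTable`
    or a plain probability DataFrame.
    """
    probs = table if isinstance(table, pd.DataFrame) else table.probabilities
    probs = probs.copy()
    probs.index.name = "dhp_cluster"
    _write_tsv(probs, path, header_comment, index=True)


def read_probability_table(path: str | Path) -> pd.DataFrame:
    """Read a probability matrix back; index/columns are integer cluster ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(int)
    df.columns = df.columns.astype(int)
    df.index.name = "dhp_cluster"
    return df
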