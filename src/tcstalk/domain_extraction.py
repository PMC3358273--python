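"""Excise DHp/REC domain-instance subsequences from qualifying hits.

A profile-HMM search reports domain hits with per-domain independent
E-values; only hits strictly below the inclusion threshold (default 0.01)
yield a :class:`DomainInstance`.  A protein carrying several qualifying
hits of one model yields several instances, each identified as
``protein_id/model/rank``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import DomainHit, Model, ProteinRecord

#: default per-domain E-value inclusion threshold (strictly below)
DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class DomainInstance:
    """One extracted DHp or REC subsequence with its provenance."""

    instance_id: str
    protein_id: str
    species: str
    model: Model
    env_start: int
    env_end: int
    evalue: float
    subsequence: str

    def __len__(self) -> int:
        return len(self.subsequence)


def make_instance_id(protein_id: str, model: Model, rank: int) -> str:
    """Canonical instance identifier ``protein_id/model/rank``."""
    return f"{protein_id}/{model.value}/{rank}"


def protein_of_instance(instance_id: str) -> str:
    """Invert :func:`make_instance_id` (protein ids contain no ``/``)."""
    return instance_id.rsplit("/", 2)[0]


def extract_instances(
    proteins: Sequence[ProteinRecord],
    hits: Iterable[DomainHit],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[DomainInstance]:
    """Extract one domain instance per hit with ``evalue < threshold``.

    The threshold is applied strictly: a hit at exactly the threshold is
    excluded.  Envelope coordinates are 1-based inclusive, so a hit at
    3..7 on ``MKVLAQRST`` yields ``VLAQR``.  Hits whose coordinates exceed
    the parent sequence, or whose protein id is unknown, are hard errors.
    Output is sorted by (protein_id, model, rank) and therefore independent
    of input order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    by_id = {p.protein_id: p for p in proteins}
    instances: list[DomainInstance] = []
    seen_ids: set[str] = set()
    for hit in hits:
        if hit.evalue >= threshold:
            continue
        protein = by_id.get(hit.protein_id)
        if protein is None:
            raise KeyError(f"hit references unknown protein {hit.protein_id!r}")
        if hit.env_end > len(protein):
            raise ValueError(
                f"hit envelope {hit.env_start}..{hit.env_end} exceeds length "
                f"{len(protein)} of protein {hit.protein_id!r}"
            )
        instance_id = make_instance_id(hit.protein_id, hit.model, hit.hit_rank)
        if instance_id in seen_ids:
            raise ValueError(f"duplicate domain instance {instance_id!r}")
        seen_ids.add(instance_id)
        instances.append(DomainInstance(
            instance_id=instance_id,
            protein_id=hit.protein_id,
            species=protein.species,
            model=hit.model,
            env_start=hit.env_start,
            env_end=hit.env_end,
            evalue=hit.evalue,
            subsequence=protein.sequence[hit.env_start - 1:hit.env_end],
        ))
    instances.sort(key=lambda i: (i.protein_id, i.model.value, i.env_start,
                                  i.instance_id))
    return instances


def find_hybrid_proteins(instances: Iterable[DomainInstance]) -> list[str]:
    """Ids of proteins contributing both a DHp and a REC instance, sorted.

    Hybrid kinases carry a receiver domain on the same polypeptide as the
    kinase core; they participate in both sides of the pairing logic.
    """
    models_by_protein: dict[str, set[Model]] = {}
    for inst in instances:
        models_by_protein.setdefault(inst.protein_id, set()).add(inst.model)
    return sorted(
        pid for pid, models in models_by_protein.items()
        if Model.DHP in models and Model.REC in models
    )


_INSTANCE_COLUMNS = ["instance_id", "protein_id", "species", "model",
                     "env_start", "env_end", "evalue", "subsequence"]


def write_instance_table(
    instances: Iterable[DomainInstance], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write extracted instances as TSV (round-trips through the reader)."""
    rows = [[i.instance_id, i.protein_id, i.species, i.model.value,
             i.env_start, i.env_end, i.evalue, i.subsequence]
            for i in instances]
    df = pd.DataFrame(rows, columns=_INSTANCE_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_instance_table(path: str | Path) -> list[DomainInstance]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        DomainInstance(
            instance_id=r.instance_id, protein_id=r.protein_id,
            species=r.species, model=Model(r.model),
            env_start=int(r.env_start), env_end=int(r.env_end),
            evalue=float(r.evalue), subsequence=r.subsequence,
        )
        for r in df.itertuples(index=False)
    ]
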