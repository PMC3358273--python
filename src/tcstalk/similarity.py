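"""All-vs-all local-alignment similarity between domain instances.

Exact Smith–Waterman with affine gaps (BLOSUM62, gap = open + extend x len)
replaces heuristic database search: at the scale of extracted DHp/REC
domains exact dynamic programming is affordable and is the sensitivity
limit of a search with all heuristic filters disabled.  Raw scores are
converted to E-values with the Karlin–Altschul form

    E = K * m * n * exp(-lambda * S)

where ``m`` is the query length and ``n`` the total residue count of the
database searched, so the two directions of a pair generally differ in
E-value even though the raw score is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .domain_extraction import DomainInstance

#: default E-value cutoff for retaining a directed similarity edge
DEFAULT_EVALUE_CUTOFF = 10.0


def _blosum62_with_neutral_x():
    """BLOSUM62 with the unknown residue X scoring 0 against everything."""
    mat = substitution_matrices.load("BLOSUM62")
    for letter in mat.alphabet:
        mat["X", letter] = 0.0
        mat[letter, "X"] = 0.0
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value statistics.

    Defaults are the classic gapped protein-search parameters: BLOSUM62,
    gap open 11, gap extend 1, lambda 0.267, K 0.041.  A gap of length k
    costs ``gap_open + k * gap_extend``.
    """

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    matrix_name: str = "BLOSUM62"
    _aligner: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            aligner = Align.PairwiseAligner()
            aligner.mode = "local"
            if self.matrix_name == "BLOSUM62":
                aligner.substitution_matrix = _blosum62_with_neutral_x()
            else:
                aligner.substitution_matrix = substitution_matrices.load(
                    self.matrix_name)
            # first gap position costs open+extend, later ones extend each
            aligner.open_gap_score = -(self.gap_open + self.gap_extend)
            aligner.extend_gap_score = -self.gap_extend
            self._aligner = aligner
        return self._aligner


@dataclass(frozen=True)
class SimilarityEdge:
    """One directed similarity edge: query instance a against subject b."""

    a_id: str
    b_id: str
    raw_score: int
    evalue: float

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be non-negative")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


def local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Maximal local affine-gap alignment score (0 if nothing aligns)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return int(round(scheme.aligner.score(a, b)))


def local_align(
    a: str, b: str, scheme: ScoringScheme
) -> tuple[int, tuple[tuple[int, int], tuple[int, int]] | None]:
    """Score and 1-based inclusive aligned spans of the best local alignment.

    Returns ``(0, None)`` when the best local alignment is empty (all
    pairings score below zero).  The score is symmetric under swapping
    the arguments.
    """
    score = local_score(a, b, scheme)
    if score <= 0:
        return 0, None
    aln = scheme.aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    span_a = (int(a_blocks[0][0]) + 1, int(a_blocks[-1][1]))
    span_b = (int(b_blocks[0][0]) + 1, int(b_blocks[-1][1]))
    return score, (span_a, span_b)


def score_to_evalue(
    raw_score: float, m: int, n: int, scheme: ScoringScheme
) -> float:
    """Karlin–Altschul E-value ``K * m * n * exp(-lambda * S)``.

    Strictly decreasing in the score and linear in both the query length
    ``m`` and the database residue count ``n``.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


def all_vs_all(
    instances: Sequence[DomainInstance],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[SimilarityEdge]:
    """All-vs-all directed similarity edges among one model class.

    The raw score of each unordered pair is computed once (Smith–Waterman
    is symmetric); each direction gets its own E-value with the query's
    length as ``m`` and the total instance residue count as ``n``.  Edges
    with ``evalue <= evalue_cutoff`` are kept; self-pairs are excluded.
    Output is sorted by (a_id, b_id).
    """
    scheme = scheme or ScoringScheme()
    models = {inst.model for inst in instances}
    if len(models) > 1:
        raise ValueError(f"instances mix model classes: {sorted(m.value for m in models)}")
    ordered = sorted(instances, key=lambda i: i.instance_id)
    n_db = sum(len(i) for i in ordered)
    edges: list[SimilarityEdge] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            score = local_score(a.subsequence, b.subsequence, scheme)
            e_ab = score_to_evalue(score, len(a), n_db, scheme)
            e_ba = score_to_evalue(score, len(b), n_db, scheme)
            if e_ab <= evalue_cutoff:
                edges.append(SimilarityEdge(a.instance_id, b.instance_id,
                                            score, e_ab))
            if e_ba <= evalue_cutoff:
                edges.append(SimilarityEdge(b.instance_id, a.instance_id,
                                            score, e_ba))
    edges.sort(key=lambda e: (e.a_id, e.b_id))
    return edges


# ---------------------------------------------------------------------------
# tabular interchange (outfmt-6 style), so externally computed search
# results can be substituted for this module's output
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["qseqid", "sseqid", "raw_score", "evalue"]


def write_similarity_tsv(
    edges: Iterable[SimilarityEdge], path: str | Path,
    header_comment: str | None = None,
) -> None:
    rows = [[e.a_id, e.b_id, e.raw_score, e.evalue] for e in edges]
    df = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_similarity_tsv(path: str | Path) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    return [
        SimilarityEdge(str(r.qseqid), str(r.sseqid), int(r.raw_score),
                       float(r.evalue))
        for r in df.itertuples(index=False)
    ]
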