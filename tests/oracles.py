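"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately avoids the algorithmic shortcut the production
code relies on: the alignment oracle enumerates chains of matched residue
pairs instead of the affine DP recurrence; the Markov-clustering oracle
iterates the expansion-inflation map with plain Python lists; the operon
oracle tests every contiguous grouping of a replicon against the merge
rules; the pairing oracle enumerates every kinase-regulator combination.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def substitution_score(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_BLOSUM62[a, b])


def _gap_cost(length: int, gap_open: int, gap_extend: int) -> int:
    return gap_open + gap_extend * length if length > 0 else 0


def sw_brute_force(a: str, b: str, gap_open: int = 11,
                   gap_extend: int = 1) -> int:
    """Best local alignment score by enumerating matched-pair chains.

    A local alignment is an increasing chain of matched residue pairs;
    consecutive matches (pi, pj) -> (i, j) pay an affine penalty for each
    of the two intervening gaps.  O(n^2 m^2), intended for n, m <= 12.
    """
    n, m = len(a), len(b)
    best = 0
    chain = [[0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            sub = substitution_score(a[i], b[j])
            cand = sub
            for pi in range(i):
                for pj in range(j):
                    cost = (_gap_cost(i - pi - 1, gap_open, gap_extend)
                            + _gap_cost(j - pj - 1, gap_open, gap_extend))
                    cand = max(cand, chain[pi][pj] + sub - cost)
            chain[i][j] = cand
            best = max(best, cand)
    return best


def mcl_fixed_point(
    W: list[list[float]],
    inflation: float,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> set[frozenset[int]]:
    """Naive dense expansion-inflation iteration on plain Python lists.

    Returns the partition (connected components of the limit matrix's
    nonzero structure) as a set of frozensets of node indices.
    """
    n = len(W)

    def col_normalize(M):
        sums = [sum(M[i][j] for i in range(n)) for j in range(n)]
        return [[M[i][j] / sums[j] for j in range(n)] for i in range(n)]

    def matmul(A, B):
        return [[sum(A[i][k] * B[k][j] for k in range(n)) for j in range(n)]
                for i in range(n)]

    M = col_normalize([row[:] for row in W])
    for _ in range(max_iter):
        P = M
        for _ in range(expansion - 1):
            P = matmul(P, M)
        Q = [[P[i][j] ** inflation for j in range(n)] for i in range(n)]
        Q = col_normalize(Q)
        Q = [[x if x >= prune_below else 0.0 for x in row] for row in Q]
        Q = col_normalize(Q)
        delta = max(abs(Q[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = Q
        if delta < tol:
            break
    # undirected components of the nonzero structure
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if M[i][j] > 0 or M[j][i] > 0:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    parts: set[frozenset[int]] = set()
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        parts.add(frozenset(comp))
    return parts


def operon_brute_force(genes, max_gap_bp: int):
    """The unique contiguous grouping consistent with the merge rules.

    ``genes`` is one replicon's loci sorted by ordinal.  Every split into
    contiguous blocks is tested: inside a block every adjacency must
    satisfy (same strand, gap <= max_gap_bp), at every block boundary the
    adjacency must violate it.  Exactly one split qualifies; it is
    returned as a list of lists of gene ids.
    """
    n = len(genes)
    if n == 0:
        return []

    def joinable(prev, nxt) -> bool:
        return (prev.strand == nxt.strand
                and nxt.start - prev.end - 1 <= max_gap_bp)

    valid = []
    for boundaries in itertools.product([False, True], repeat=n - 1):
        ok = all(
            joinable(genes[i], genes[i + 1]) != boundary
            for i, boundary in enumerate(boundaries)
        )
        if ok:
            blocks, current = [], [genes[0].gene_id]
            for i, boundary in enumerate(boundaries):
                if boundary:
                    blocks.append(current)
                    current = []
                current.append(genes[i + 1].gene_id)
            blocks.append(current)
            valid.append(blocks)
    assert len(valid) == 1, "merge rules must determine a unique grouping"
    return valid[0]


def cognate_pairs_brute_force(loci, operon_of, hpk_ids, rr_ids,
                              max_intervening: int = 2):
    """Enumerate every kinase x regulator combination against the rules."""
    hpk_set, rr_set = set(hpk_ids), set(rr_ids)
    by_protein = {g.protein_id: g for g in loci}
    pairs = set()
    for hid in hpk_set:
        for rid in rr_set:
            h, r = by_protein.get(hid), by_protein.get(rid)
            if h is None or r is None:
                continue
            if operon_of[h.gene_id] != operon_of[r.gene_id]:
                continue
            if hid == rid:
                pairs.add((hid, rid, 0))
            elif abs(h.ordinal - r.ordinal) - 1 <= max_intervening:
                pairs.add((hid, rid, abs(h.ordinal - r.ordinal) - 1))
    return pairs
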