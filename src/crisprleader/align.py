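"""Alignment machinery: affine-gap global alignment, progressive MSA for
short DNA, and alignment-free k-mer distances for proteins.

Junction sequences here are at most ~60 nt, so a textbook Gotoh aligner and
a UPGMA-guided progressive profile aligner are sufficient.  Cas proteins
(up to ~1,400 aa) are compared alignment-free through shared-k-mer
distances, which is what the downstream clustering consumes.

Gap convention: a gap run of length g costs ``gap_open + (g - 1) * gap_extend``
(the opening position pays ``gap_open``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ScoringScheme",
    "MultipleAlignment",
    "DistanceMatrix",
    "global_align",
    "progressive_msa",
    "kmer_distance_matrix",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def score(self, x: str, y: str) -> int:
        # N is treated as unknown: mismatches everything except N itself
        if x == y:
            return self.match
        return self.mismatch


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows; ungapping row i returns input sequence i."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        self.values = v

    def to_phylip(self, path: str | Path) -> None:
        """Write PHYLIP square format (names truncated/padded to 10 chars)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def global_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment (Gotoh affine-gap DP).

    Returns (gapped_a, gapped_b, score).  Traceback ties are broken
    diagonal > up (gap in b) > left (gap in a), giving a deterministic
    alignment.
    """
    scheme = scheme or ScoringScheme()
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    # M: a[i-1]~b[j-1]; X: gap in b (consumes a, "up"); Y: gap in a ("left")
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scheme.score(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
    for j in range(1, m + 1):
        X[0, j] = NEG_INF
    # traceback from the best terminal state, ties diagonal > up > left
    i, j = n, m
    states = {"M": M, "X": X, "Y": Y}
    state = max(("M", "X", "Y"), key=lambda s: states[s][n, m])
    score = states[state][n, m]
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = scheme.score(a[i - 1], b[j - 1])
            target = M[i, j] - s
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i - 1, j - 1] - target) <= tol:
                    state = prev
                    break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == "X":
            val = X[i, j]
            if abs(M[i - 1, j] + go - val) <= tol:
                nxt = "M"
            elif abs(X[i - 1, j] + ge - val) <= tol:
                nxt = "X"
            else:
                nxt = "Y"
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = nxt
        else:  # Y
            val = Y[i, j]
            if abs(M[i, j - 1] + go - val) <= tol:
                nxt = "M"
            elif abs(X[i, j - 1] + go - val) <= tol:
                nxt = "X"
            else:
                nxt = "Y"
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = nxt
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# progressive MSA


def _profile_columns(rows: list[str]) -> list[dict[str, float]]:
    cols = []
    nr = len(rows)
    for j in range(len(rows[0])):
        counts: dict[str, float] = {}
        for r in rows:
            counts[r[j]] = counts.get(r[j], 0) + 1
        cols.append({sym: c / nr for sym, c in counts.items()})
    return cols


def _col_score(
    ca: dict[str, float], cb: dict[str, float], scheme: ScoringScheme
) -> float:
    s = 0.0
    for x, fx in ca.items():
        for y, fy in cb.items():
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                s += fx * fy * scheme.gap_extend
            else:
                s += fx * fy * scheme.score(x, y)
    return s


def _gap_col_score(col: dict[str, float], scheme: ScoringScheme,
                   opening: bool) -> float:
    pen = scheme.gap_open if opening else scheme.gap_extend
    return pen * sum(f for sym, f in col.items() if sym != "-")


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Affine profile-profile global alignment; returns gap-expanded rows."""
    ca, cb = _profile_columns(rows_a), _profile_columns(rows_b)
    n, m = len(ca), len(cb)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = X[i - 1, 0] + _gap_col_score(ca[i - 1], scheme, opening=(i == 1))
    for j in range(1, m + 1):
        Y[0, j] = Y[0, j - 1] + _gap_col_score(cb[j - 1], scheme, opening=(j == 1))
    X[0, 0] = Y[0, 0] = NEG_INF
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(ca[i - 1], cb[j - 1], scheme)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            op = _gap_col_score(ca[i - 1], scheme, opening=True)
            ex = _gap_col_score(ca[i - 1], scheme, opening=False)
            X[i, j] = max(M[i - 1, j] + op, X[i - 1, j] + ex, Y[i - 1, j] + op)
            op = _gap_col_score(cb[j - 1], scheme, opening=True)
            ex = _gap_col_score(cb[j - 1], scheme, opening=False)
            Y[i, j] = max(M[i, j - 1] + op, X[i, j - 1] + op, Y[i, j - 1] + ex)
    i, j = n, m
    states = {"M": M, "X": X, "Y": Y}
    state = max(("M", "X", "Y"), key=lambda s: states[s][n, m])
    ops: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            s = _col_score(ca[i - 1], cb[j - 1], scheme)
            target = M[i, j] - s
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i - 1, j - 1] - target) <= tol:
                    state = prev
                    break
            ops.append("M")
            i -= 1
            j -= 1
        elif state == "X":
            val = X[i, j]
            op = _gap_col_score(ca[i - 1], scheme, opening=True)
            ex = _gap_col_score(ca[i - 1], scheme, opening=False)
            if abs(M[i - 1, j] + op - val) <= tol:
                nxt = "M"
            elif abs(X[i - 1, j] + ex - val) <= tol:
                nxt = "X"
            else:
                nxt = "Y"
            ops.append("X")
            i -= 1
            state = nxt
        else:
            val = Y[i, j]
            op = _gap_col_score(cb[j - 1], scheme, opening=True)
            ex = _gap_col_score(cb[j - 1], scheme, opening=False)
            if abs(M[i, j - 1] + op - val) <= tol:
                nxt = "M"
            elif abs(X[i, j - 1] + op - val) <= tol:
                nxt = "X"
            else:
                nxt = "Y"
            ops.append("Y")
            j -= 1
            state = nxt
    ops.reverse()
    out_a = []
    out_b = []
    ia = ib = 0
    for op in ops:
        if op == "M":
            out_a.append(ia)
            out_b.append(ib)
            ia += 1
            ib += 1
        elif op == "X":
            out_a.append(ia)
            out_b.append(None)
            ia += 1
        else:
            out_a.append(None)
            out_b.append(ib)
            ib += 1
    new_a = ["".join(r[x] if x is not None else "-" for x in out_a) for r in rows_a]
    new_b = ["".join(r[x] if x is not None else "-" for x in out_b) for r in rows_b]
    return new_a, new_b


def _identity_distance(a: str, b: str, scheme: ScoringScheme) -> float:
    ga, gb, _ = global_align(a, b, scheme)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 1.0 - matches / len(ga) if ga else 0.0


def progressive_msa(
    seqs: Sequence[tuple[str, str]], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Pairwise identity distances feed average-linkage clustering; profiles
    are merged bottom-up with profile-profile affine alignment under the
    same scoring scheme.  Output row order matches input order.
    """
    scheme = scheme or ScoringScheme()
    if not seqs:
        raise ValueError("progressive_msa needs at least one sequence")
    labels = [lab for lab, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if len(seqs) == 1:
        return MultipleAlignment(labels=list(labels), rows=[seqs[0][1]])
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _identity_distance(seqs[i][1], seqs[j][1],
                                                         scheme)
    Z = linkage(squareform(dist, checks=False), method="average")
    # clusters[id] = (ordered member indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i][1]]) for i in range(n)
    }
    for step, (ia, ib, _d, _c) in enumerate(Z):
        a = clusters.pop(int(ia))
        b = clusters.pop(int(ib))
        rows_a, rows_b = _align_profiles(a[1], b[1], scheme)
        clusters[n + step] = (a[0] + b[0], rows_a + rows_b)
    (order, rows), = clusters.values()
    by_index = dict(zip(order, rows))
    return MultipleAlignment(
        labels=list(labels), rows=[by_index[i] for i in range(n)]
    )


def sum_of_pairs_score(msa: MultipleAlignment,
                       scheme: ScoringScheme | None = None) -> float:
    """Sum over row pairs of the alignment score implied by the gapped rows."""
    scheme = scheme or ScoringScheme()
    total = 0.0
    nr = len(msa.rows)
    for i in range(nr):
        for j in range(i + 1, nr):
            total += _pairwise_row_score(msa.rows[i], msa.rows[j], scheme)
    return total


def _pairwise_row_score(ra: str, rb: str, scheme: ScoringScheme) -> float:
    score = 0.0
    in_gap = False
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score += scheme.gap_extend if in_gap else scheme.gap_open
            in_gap = True
        else:
            score += scheme.score(x, y)
            in_gap = False
    return score


# ---------------------------------------------------------------------------
# k-mer distances


def kmer_distance_matrix(
    seqs: Sequence[tuple[str, str]], k: int = 4
) -> DistanceMatrix:
    """Alignment-free distances from shared distinct k-mers.

    d(i, j) = 1 - |Ki & Kj| / min(|Ki|, |Kj|), with Ks the set of distinct
    k-mers of sequence s.  Default k=4 suits proteins; use k=6 for DNA.
    """
    sets = []
    for label, seq in seqs:
        if len(seq) < k:
            raise ValueError(f"sequence {label!r} shorter than k={k}")
        sets.append({seq[i : i + k] for i in range(len(seq) - k + 1)})
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            d = 1.0 - shared / min(len(sets[i]), len(sets[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=[lab for lab, _ in seqs], values=values)
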