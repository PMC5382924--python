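"""Naive reference algorithms used to validate the fast implementations.

These are deliberately simple exhaustive computations (enumeration, not
heuristics) and share no code with the production paths in
:mod:`~crisprleader.arrays` and :mod:`~crisprleader.align`.  They are slow
and intended only for small inputs inside tests and validation scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import ScoringScheme
from .arrays import DetectorParams

__all__ = [
    "PeriodicArray",
    "enumerate_exact_arrays",
    "best_exact_array",
    "exhaustive_alignment_score",
    "random_additive_tree",
]


@dataclass(frozen=True)
class PeriodicArray:
    """An exact periodic repeat: copies at offset, offset+period, ..."""

    offset: int
    unit_length: int
    period: int
    n_copies: int

    @property
    def copy_starts(self) -> tuple[int, ...]:
        return tuple(self.offset + i * self.period for i in range(self.n_copies))


def enumerate_exact_arrays(
    seq: str, params: DetectorParams | None = None
) -> list[PeriodicArray]:
    """All maximal exact (length, period, offset) periodic substring triples.

    A triple qualifies when every copy is an exact character-for-character
    match, the unit length lies within the repeat bounds, the spacer
    (period - length) lies within the spacer bounds, and there are at least
    ``min_copies`` copies.  Maximality: the copy count cannot be extended in
    either direction, and the unit cannot be widened left or right at the
    same period without breaking exactness or the length bound.
    """
    params = params or DetectorParams()
    seq = seq.upper()
    n = len(seq)
    found = []
    for unit in range(params.min_repeat, params.max_repeat + 1):
        for spacer in range(params.min_spacer, params.max_spacer + 1):
            period = unit + spacer
            for offset in range(n - period - unit + 1):
                first = seq[offset : offset + unit]
                if "N" in first:
                    continue
                # count exact copies rightward
                m = 1
                while True:
                    s = offset + m * period
                    if s + unit > n or seq[s : s + unit] != first:
                        break
                    m += 1
                if m < params.min_copies:
                    continue
                # maximality in copies (leftward) and in unit width
                if offset - period >= 0 and seq[offset - period : offset - period + unit] == first:
                    continue
                starts = [offset + i * period for i in range(m)]
                if _extendable(seq, starts, unit, params):
                    continue
                found.append(PeriodicArray(offset, unit, period, m))
    return found


def _extendable(seq: str, starts: list[int], unit: int,
                params: DetectorParams) -> bool:
    """Can the unit be widened by one column at either edge?"""
    if unit + 1 > params.max_repeat:
        return False
    n = len(seq)
    left = all(s - 1 >= 0 for s in starts) and len(
        {seq[s - 1] for s in starts}
    ) == 1 and "N" not in {seq[s - 1] for s in starts}
    if left and all(starts[i] - 1 >= starts[i - 1] + unit
                    for i in range(1, len(starts))):
        return True
    right = all(s + unit < n for s in starts) and len(
        {seq[s + unit] for s in starts}
    ) == 1 and "N" not in {seq[s + unit] for s in starts}
    if right and all(starts[i] + unit < starts[i + 1]
                     for i in range(len(starts) - 1)):
        return True
    return False


def best_exact_array(
    seq: str, params: DetectorParams | None = None
) -> PeriodicArray | None:
    """The winning exact array under the detector's own tie-break:
    more copies, then longer unit, then smaller offset."""
    arrays = enumerate_exact_arrays(seq, params)
    if not arrays:
        return None
    return min(arrays, key=lambda a: (-a.n_copies, -a.unit_length, a.offset))


def random_additive_tree(
    rng, n_leaves: int, min_len: float = 0.1, max_len: float = 1.0
):
    """A random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix (by explicit path summation, independent of
    any tree library).

    Returns (newick, labels, distances) with labels ``L1..Ln``.
    """
    import numpy as np

    labels = [f"L{i + 1}" for i in range(n_leaves)]
    # adjacency with edge lengths; nodes 0..n-1 are leaves
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    children: dict[int, list[tuple[int, float]]] = {}
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 2:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        li = float(rng.uniform(min_len, max_len))
        lj = float(rng.uniform(min_len, max_len))
        adj[nxt] = []
        for child, ln in ((i, li), (j, lj)):
            adj[nxt].append((child, ln))
            adj[child].append((nxt, ln))
        children[nxt] = [(i, li), (j, lj)]
        active.append(nxt)
        nxt += 1
    a, b = active
    lab = float(rng.uniform(min_len, max_len))
    adj[a].append((b, lab))
    adj[b].append((a, lab))

    dists = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + ln
                    stack.append(v)
        for dst in range(n_leaves):
            dists[src, dst] = seen[dst]
    dists = (dists + dists.T) / 2  # remove float asymmetry from path order

    def newick(node: int) -> str:
        if node < n_leaves:
            return labels[node]
        parts = [f"{newick(c)}:{ln:.10f}" for c, ln in children[node]]
        return "(" + ",".join(parts) + ")"

    nwk = f"({newick(a)}:{lab:.10f},{newick(b)}:0.0);"
    return nwk, labels, dists


def exhaustive_alignment_score(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> float:
    """Maximum global alignment score by depth-first enumeration of every
    alignment (match/insert/delete op sequence), affine gap costs applied
    per gap run.  Exponential; use only for strings of length <= ~8."""
    scheme = scheme or ScoringScheme()

    def gap_cost(prev_op: str, op: str) -> float:
        return scheme.gap_extend if prev_op == op else scheme.gap_open

    best = [float("-inf")]

    def rec(i: int, j: int, score: float, prev_op: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + scheme.score(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score + gap_cost(prev_op, "X"), "X")
        if j < len(b):
            rec(i, j + 1, score + gap_cost(prev_op, "Y"), "Y")

    rec(0, 0, 0.0, "")
    return best[0]
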