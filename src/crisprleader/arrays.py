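"""CRISPR repeat-spacer array detection and leader-repeat junction extraction.

The detector is a seed-and-extend scanner for tandem repeats with CRISPR-like
geometry: a k-mer recurring at an array-like period nucleates a candidate,
whose repeat boundaries are then grown column-by-column while the copies
agree.  The first repeat is always reported verbatim as it occurs in the
genome (the genomic first repeat can differ from a database consensus), and
the leader is everything between the window start and that first repeat.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome import GenomeRecord, GenomicInterval, oriented_subsequence
from .operons import CasOperon, leader_search_window

__all__ = [
    "DetectorParams",
    "CrisprArray",
    "LeaderJunction",
    "EmptyLeaderError",
    "detect_crispr_array",
    "extract_leader_junction",
    "junctions_from_fasta",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the seed-and-extend tandem-repeat scanner.

    Repeat/spacer bounds follow the canonical CRISPR geometry (repeat and
    spacer units roughly 24-50 nt).  ``boundary_consensus`` is the minimum
    majority-base fraction required to extend a repeat boundary by one
    column.  ``copy_identity`` is the minimum per-copy agreement with the
    column consensus: copies below it (e.g. a chance seed hit in the
    A/T-rich leader free-riding on the majority vote of the true copies)
    are expelled and the boundaries re-extended.
    """

    k: int = 8
    min_repeat: int = 24
    max_repeat: int = 50
    min_spacer: int = 20
    max_spacer: int = 60
    min_copies: int = 2
    boundary_consensus: float = 0.75
    copy_identity: float = 0.75

    @property
    def min_period(self) -> int:
        return self.min_repeat + self.min_spacer

    @property
    def max_period(self) -> int:
        return self.max_repeat + self.max_spacer


@dataclass
class CrisprArray:
    """A detected repeat-spacer array, coordinates local to the search window."""

    repeat_unit_length: int
    repeat_copies: list[GenomicInterval]
    spacer_intervals: list[GenomicInterval]
    consensus_repeat: str
    first_repeat: str

    @property
    def n_copies(self) -> int:
        return len(self.repeat_copies)

    @property
    def start(self) -> int:
        return self.repeat_copies[0].start

    @property
    def end(self) -> int:
        return self.repeat_copies[-1].end


@dataclass(frozen=True)
class LeaderJunction:
    """Per-locus leader end and first repeat, transcription orientation."""

    locus_id: str
    leader20: str
    first_repeat: str
    truncated: bool = False

    @property
    def leader_end7(self) -> str:
        return self.leader20[-7:]

    @property
    def junction_leader3(self) -> str:
        return self.leader20[-3:]

    @property
    def junction_repeat4(self) -> str:
        return self.first_repeat[:4]


class EmptyLeaderError(ValueError):
    """The array abuts the window start; there is no leader to extract."""


def _extend_boundaries(
    seq: str, anchors: list[int], params: DetectorParams
) -> tuple[int, int] | None:
    """Grow the repeat left/right of the seed k-mer by majority vote.

    Returns (left_ext, right_ext) or None if an N interrupts a copy.
    """
    n = len(seq)
    m = len(anchors)
    need = params.boundary_consensus * m
    k = params.k

    def column_ok(positions: list[int]) -> bool:
        if any(p < 0 or p >= n for p in positions):
            return False
        chars = [seq[p] for p in positions]
        if "N" in chars:
            return False
        (sym, cnt), = Counter(chars).most_common(1)
        return cnt >= need

    left = 0
    while k + left < params.max_repeat:
        nxt = left + 1
        pos = [a - nxt for a in anchors]
        # never grow a copy back into the previous copy's seed
        if any(pos[i] < anchors[i - 1] + k for i in range(1, m)):
            break
        if not column_ok(pos):
            break
        left = nxt
    right = 0
    while k + left + right < params.max_repeat:
        pos = [a + k + right for a in anchors]
        if any(pos[i] >= anchors[i + 1] - left for i in range(m - 1)):
            break
        if not column_ok(pos):
            break
        right += 1
    return left, right


def _resolve_candidate(
    seq: str, chain: list[int], params: DetectorParams
) -> tuple[list[GenomicInterval], int] | None:
    """Extend a seed chain into repeat copies, expelling low-identity copies.

    A copy whose agreement with the column consensus falls below
    ``copy_identity`` (a chance seed hit outside the true array) is dropped
    and the boundaries re-extended over the remaining copies, until stable.
    """
    anchors = list(chain)
    k = params.k
    while True:
        ext = _extend_boundaries(seq, anchors, params)
        if ext is None:
            return None
        left, right = ext
        unit = k + left + right
        starts = [a - left for a in anchors]
        majority = []
        for j in range(unit):
            chars = [seq[s + j] for s in starts]
            (sym, _), = sorted(Counter(chars).most_common(),
                               key=lambda t: (-t[1], t[0]))[:1]
            majority.append(sym)
        bad = [
            i for i, s in enumerate(starts)
            if sum(seq[s + j] == majority[j] for j in range(unit)) / unit
            < params.copy_identity
        ]
        if not bad:
            break
        if len(anchors) - len(bad) < params.min_copies:
            return None
        anchors = [a for i, a in enumerate(anchors) if i not in set(bad)]
    if unit < params.min_repeat or unit > params.max_repeat:
        return None
    copies = [GenomicInterval(a - left, a + k + right) for a in anchors]
    return copies, unit


def _consensus(seq: str, copies: list[GenomicInterval]) -> str:
    cols = []
    length = copies[0].length
    for j in range(length):
        chars = [seq[c.start + j] for c in copies]
        (sym, _), = sorted(Counter(chars).most_common(),
                           key=lambda t: (-t[1], t[0]))[:1]
        cols.append(sym)
    return "".join(cols)


def detect_crispr_array(
    window_seq: str, params: DetectorParams | None = None
) -> list[CrisprArray]:
    """Locate CRISPR-like tandem arrays in a window sequence.

    Seed: every k-mer recurring with a gap inside the CRISPR period range
    nucleates a candidate chain of copies.  Extend: boundaries grow while the
    column's majority base fraction is at least ``boundary_consensus`` and
    the unit stays within the repeat-length bounds.  Overlapping candidates
    are merged keeping the one with more copies, then longer repeat, then
    smaller start.  Surviving arrays need >= ``min_copies`` copies and
    spacers within bounds.
    """
    params = params or DetectorParams()
    seq = window_seq.upper()
    n = len(seq)
    if n < 2 * params.min_repeat + params.min_spacer:
        return []
    k = params.k

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)

    candidates: list[tuple[list[GenomicInterval], int]] = []
    seen_chains: set[tuple[int, ...]] = set()
    for positions in index.values():
        if len(positions) < params.min_copies:
            continue
        used: set[int] = set()
        for start_idx, p0 in enumerate(positions):
            if p0 in used:
                continue
            chain = [p0]
            for q in positions[start_idx + 1 :]:
                gap = q - chain[-1]
                if params.min_period <= gap <= params.max_period:
                    chain.append(q)
                elif gap > params.max_period:
                    break
            if len(chain) < params.min_copies:
                continue
            used.update(chain)
            key = tuple(chain)
            if key in seen_chains:
                continue
            seen_chains.add(key)
            resolved = _resolve_candidate(seq, chain, params)
            if resolved is None:
                continue
            copies, unit = resolved
            # split wherever a spacer violates the bounds
            runs: list[list[GenomicInterval]] = [[copies[0]]]
            for c in copies[1:]:
                gap = c.start - runs[-1][-1].end
                if params.min_spacer <= gap <= params.max_spacer:
                    runs[-1].append(c)
                else:
                    runs.append([c])
            for run in runs:
                if len(run) >= params.min_copies:
                    candidates.append((run, unit))

    # merge overlapping candidates: more copies > longer repeat > smaller start
    candidates.sort(key=lambda t: (-len(t[0]), -t[1], t[0][0].start))
    kept: list[tuple[list[GenomicInterval], int]] = []
    for copies, unit in candidates:
        span = (copies[0].start, copies[-1].end)
        if any(span[0] < e and s < span[1]
               for s, e in ((c[0].start, c[-1].end) for c, _ in kept)):
            continue
        kept.append((copies, unit))

    arrays = []
    for copies, unit in sorted(kept, key=lambda t: t[0][0].start):
        spacers = [
            GenomicInterval(a.end, b.start)
            for a, b in zip(copies, copies[1:])
        ]
        arrays.append(
            CrisprArray(
                repeat_unit_length=unit,
                repeat_copies=copies,
                spacer_intervals=spacers,
                consensus_repeat=_consensus(seq, copies),
                first_repeat=seq[copies[0].start : copies[0].end],
            )
        )
    return arrays


def extract_leader_junction(
    record: GenomeRecord,
    operon: CasOperon,
    array: CrisprArray,
    window_nt: int = 400,
) -> LeaderJunction:
    """Extract the last 20 leader nucleotides and the verbatim first repeat.

    The leader runs from the window start (csn2-proximal edge) to the first
    repeat's start, in transcription orientation.  Leaders shorter than 20 nt
    are kept whole with the ``truncated`` flag set.
    """
    window = leader_search_window(operon, record, window_nt)
    wseq = oriented_subsequence(record, window)
    leader = wseq[: array.start]
    if not leader:
        raise EmptyLeaderError(
            f"locus {operon.locus_id}: array abuts window start, no leader"
        )
    return LeaderJunction(
        locus_id=operon.locus_id,
        leader20=leader[-20:],
        first_repeat=array.first_repeat,
        truncated=len(leader) < 20,
    )


def junctions_from_fasta(path, leader_len: int = 20) -> list[LeaderJunction]:
    """Read junction units (last ``leader_len`` leader nt + first repeat)
    from a FASTA file, one record per locus.

    Supports classifying an externally supplied junction dataset directly,
    bypassing genome mining.
    """
    from Bio import SeqIO

    junctions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) <= leader_len:
            raise ValueError(
                f"junction record {rec.id!r} too short "
                f"({len(seq)} nt <= leader length {leader_len})"
            )
        junctions.append(
            LeaderJunction(
                locus_id=rec.id,
                leader20=seq[:leader_len],
                first_repeat=seq[leader_len:],
                truncated=False,
            )
        )
    return junctions
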