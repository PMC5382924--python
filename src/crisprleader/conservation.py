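"""Positional conservation, IUPAC consensus, leader-end group calls, and
dataset statistics.

The conservation profile is the sequence-logo computation: per-column symbol
frequencies and information content R = log2(|alphabet|) - H, optionally
with the small-sample correction e(n) = (|alphabet| - 1) / (2 ln2 n).

Leader-end groups are the three conserved 3'-leader motifs of type II-A
loci: Group 1 ATTTGAG, Group 2 CTRCGAG (R = A or G), Group 3 a short CG.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import MultipleAlignment
from .arrays import LeaderJunction
from .phylo import CladePartition

__all__ = [
    "GROUP_MOTIFS",
    "ConservationProfile",
    "GroupAssignment",
    "DatasetStats",
    "build_profile",
    "information_content",
    "iupac_consensus",
    "classify_leader_end",
    "clade_mode_groups",
    "dataset_statistics",
]

DNA = ("A", "C", "G", "T")

GROUP_MOTIFS = {"Group1": "ATTTGAG", "Group2": "CTRCGAG", "Group3": "CG"}

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class ConservationProfile:
    """Per-column counts/frequencies over an alignment (logo matrix)."""

    alphabet: tuple[str, ...]
    counts: np.ndarray          # n_cols x |alphabet|, pseudocount included
    frequencies: np.ndarray     # rows sum to 1 except all-gap columns (NaN)
    gap_fraction: np.ndarray    # per column
    n_rows: int

    @property
    def n_cols(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(self.alphabet))
        df.insert(0, "position", np.arange(1, self.n_cols + 1))
        df["gap_fraction"] = self.gap_fraction
        return df


def build_profile(
    msa: MultipleAlignment,
    pseudocount: float = 0.0,
    alphabet: Sequence[str] = DNA,
) -> ConservationProfile:
    """Column-wise symbol counts and frequencies over non-gap symbols.

    All-gap columns get NaN frequencies (excluded from consensus calls).
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    alphabet = tuple(alphabet)
    idx = {sym: i for i, sym in enumerate(alphabet)}
    n_cols = msa.n_cols
    counts = np.full((n_cols, len(alphabet)), float(pseudocount))
    gaps = np.zeros(n_cols)
    for row in msa.rows:
        for j, sym in enumerate(row):
            if sym == "-":
                gaps[j] += 1
            elif sym in idx:
                counts[j, idx[sym]] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals[:, None] > 0, counts / totals[:, None], np.nan)
    return ConservationProfile(
        alphabet=alphabet,
        counts=counts,
        frequencies=freqs,
        gap_fraction=gaps / len(msa.rows),
        n_rows=len(msa.rows),
    )


def information_content(
    profile: ConservationProfile, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-column information in bits: log2|A| - H - e(n), clamped at 0."""
    a = len(profile.alphabet)
    bits = np.zeros(profile.n_cols)
    for j in range(profile.n_cols):
        f = profile.frequencies[j]
        if np.isnan(f).any():
            bits[j] = 0.0
            continue
        h = -sum(p * math.log2(p) for p in f if p > 0)
        e = 0.0
        if small_sample_correction:
            n_obs = profile.counts[j].sum()
            if n_obs > 0:
                e = (a - 1) / (2 * math.log(2) * n_obs)
        bits[j] = max(0.0, math.log2(a) - h - e)
    return bits


def iupac_consensus(profile: ConservationProfile, threshold: float = 0.9) -> str:
    """Smallest degenerate symbol covering >= threshold frequency per column.

    Bases are added in descending frequency (ties alphabetically); all-gap
    columns emit '-'.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = []
    for j in range(profile.n_cols):
        f = profile.frequencies[j]
        if np.isnan(f).any():
            out.append("-")
            continue
        order = sorted(zip(profile.alphabet, f), key=lambda t: (-t[1], t[0]))
        total = 0.0
        chosen: set[str] = set()
        for sym, freq in order:
            chosen.add(sym)
            total += freq
            if total >= threshold - 1e-12:
                break
        out.append(_IUPAC[frozenset(chosen)])
    return "".join(out)


# ---------------------------------------------------------------------------
# leader-end group classification


@dataclass(frozen=True)
class GroupAssignment:
    locus_id: str
    group: str                  # Group1 | Group2 | Group3 | unclassified
    matched_motif: str = ""
    mismatches: int = 0


def _motif_mismatches(seq: str, motif: str) -> int | None:
    """Hamming mismatches against a motif with IUPAC R; None if lengths differ."""
    if len(seq) != len(motif):
        return None
    mm = 0
    for s, m in zip(seq, motif):
        if m == "R":
            if s not in "AG":
                mm += 1
        elif s != m:
            mm += 1
    return mm


def classify_leader_end(
    junction: LeaderJunction, tolerance: int = 0
) -> GroupAssignment:
    """Assign a locus to a leader-end group from its last 7 leader nt.

    Precedence: ATTTGAG (Group 1) > CTRCGAG (Group 2, R not counted as a
    mismatch) > terminal CG (Group 3) > unclassified.
    """
    end7 = junction.leader_end7.upper()
    locus = junction.locus_id
    if not end7:
        return GroupAssignment(locus, "unclassified")
    for group in ("Group1", "Group2"):
        mm = _motif_mismatches(end7, GROUP_MOTIFS[group])
        if mm is not None and mm <= tolerance:
            return GroupAssignment(locus, group, GROUP_MOTIFS[group], mm)
    if end7[-2:] == "CG":
        return GroupAssignment(locus, "Group3", "CG", 0)
    return GroupAssignment(locus, "unclassified")


def clade_mode_groups(
    assignments: Sequence[GroupAssignment], clades: CladePartition
) -> list[GroupAssignment]:
    """Reassign each locus the majority motif-group of its tree clade.

    This mirrors deriving group membership from the Cas1 tree: clades are
    labelled by the most common motif-mode group among their members
    (unclassified loci do not vote; ties break by group name).
    """
    by_locus = {a.locus_id: a for a in assignments}
    out = []
    for clade in sorted(set(clades.assignment.values())):
        members = clades.members(clade)
        votes = Counter(
            by_locus[m].group for m in members
            if m in by_locus and by_locus[m].group != "unclassified"
        )
        if votes:
            majority = sorted(votes.items(), key=lambda t: (-t[1], t[0]))[0][0]
        else:
            majority = "unclassified"
        for m in members:
            base = by_locus.get(m)
            out.append(
                GroupAssignment(
                    locus_id=m,
                    group=majority,
                    matched_motif=base.matched_motif if base else "",
                    mismatches=base.mismatches if base else 0,
                )
            )
    out.sort(key=lambda a: a.locus_id)
    return out


# ---------------------------------------------------------------------------
# dataset statistics


@dataclass
class DatasetStats:
    """Every dataset-level count the junction analysis reports."""

    group_counts: dict[str, int]
    genera_per_group: dict[str, int]
    junction_gag_gttt_count: int
    n_group12: int
    repeat_length_mode: int
    repeat_length_exceptions: list[tuple[str, int]]
    count_missing_5prime_GTTT: int
    count_missing_3prime_C: int
    csn2_mean_length_per_clade: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_counts": dict(self.group_counts),
            "genera_per_group": dict(self.genera_per_group),
            "junction_gag_gttt_count": self.junction_gag_gttt_count,
            "n_group12": self.n_group12,
            "repeat_length_mode": self.repeat_length_mode,
            "repeat_length_exceptions": [list(t) for t in self.repeat_length_exceptions],
            "count_missing_5prime_GTTT": self.count_missing_5prime_GTTT,
            "count_missing_3prime_C": self.count_missing_3prime_C,
            "csn2_mean_length_per_clade": {
                str(k): v for k, v in self.csn2_mean_length_per_clade.items()
            },
        }


def dataset_statistics(
    junctions: Sequence[LeaderJunction],
    assignments: Sequence[GroupAssignment],
    genus_of: Mapping[str, str] | None = None,
    csn2_lengths: Mapping[str, int] | None = None,
    clades: CladePartition | None = None,
) -> DatasetStats:
    """Aggregate the headline counts of the junction analysis.

    Covers group sizes, genera per group, GAG/GTTT junction conservation in
    Groups 1 and 2, the modal first-repeat length with exceptions, repeat
    5' GTTT and 3' C conservation, and mean Csn2 length per tree clade.
    """
    j_ids = {j.locus_id for j in junctions}
    a_ids = {a.locus_id for a in assignments}
    if j_ids != a_ids:
        raise ValueError(
            f"junction/assignment locus sets differ: {sorted(j_ids ^ a_ids)}"
        )
    group_of = {a.locus_id: a.group for a in assignments}
    group_counts = Counter(a.group for a in assignments)

    genera_per_group: dict[str, int] = {}
    if genus_of:
        per_group: dict[str, set[str]] = {}
        for locus, group in group_of.items():
            if locus in genus_of:
                per_group.setdefault(group, set()).add(genus_of[locus])
        genera_per_group = {g: len(s) for g, s in sorted(per_group.items())}

    g12 = [j for j in junctions if group_of[j.locus_id] in ("Group1", "Group2")]
    gag_gttt = sum(
        1 for j in g12
        if j.junction_leader3 == "GAG" and j.junction_repeat4 == "GTTT"
    )

    lengths = {j.locus_id: len(j.first_repeat) for j in junctions}
    mode = Counter(lengths.values()).most_common(1)[0][0] if lengths else 0
    exceptions = sorted(
        (locus, ln) for locus, ln in lengths.items() if ln != mode
    )
    missing_gttt = sum(1 for j in junctions if not j.first_repeat.startswith("GTTT"))
    missing_c = sum(1 for j in junctions if not j.first_repeat.endswith("C"))

    csn2_means: dict[int, float] = {}
    if csn2_lengths and clades:
        per_clade: dict[int, list[int]] = {}
        for locus, clade in clades.assignment.items():
            if locus in csn2_lengths:
                per_clade.setdefault(clade, []).append(csn2_lengths[locus])
        csn2_means = {
            c: float(np.mean(v)) for c, v in sorted(per_clade.items())
        }

    return DatasetStats(
        group_counts=dict(sorted(group_counts.items())),
        genera_per_group=genera_per_group,
        junction_gag_gttt_count=gag_gttt,
        n_group12=len(g12),
        repeat_length_mode=mode,
        repeat_length_exceptions=exceptions,
        count_missing_5prime_GTTT=missing_gttt,
        count_missing_3prime_C=missing_c,
        csn2_mean_length_per_clade=csn2_means,
    )


def write_profile_tsv(profile: ConservationProfile, bits: np.ndarray,
                      path: str | Path) -> None:
    """Tab-separated logo matrix: position, per-symbol frequency, bits."""
    df = profile.to_frame()
    df["info_bits"] = bits
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
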