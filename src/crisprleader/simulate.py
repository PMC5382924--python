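"""Seeded synthetic genomes with planted type II-A CRISPR loci.

Each planted locus is a four-gene cas operon (cas9, cas1, cas2, csn2)
followed, in transcription direction, by an A/T-rich leader ending in a
group-specific 3' motif and a repeat-spacer array whose repeats start GTTT
and end AAAC.  Proteins are random sequences carrying fixed group- and
subgroup-"signature" segments so that k-mer distances cluster loci the way
real Cas proteins do; they are deliberately not homologs of real Cas
proteins.  Group 1 contains an "ancestral" subgroup (1a) with a long
(~320 aa) Csn2 and a derived subgroup (1b) with the short (218-230 aa)
form, mirroring the known Csn2 length dichotomy.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomeRecord, write_annotation_table, write_genbank, write_fasta

__all__ = [
    "SimConfig",
    "generate_synthetic_dataset",
    "plant_mutations",
    "write_dataset",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

GROUPS = ("Group1", "Group2", "Group3")

# Genus pools per group, mirroring the surveyed composition: Group 1 spans
# 42 genera, Group 2 only 5, Group 3 seven (several shared across groups,
# 50 distinct genera overall).
GENUS_POOLS = {
    "Group1": [f"genus{i:02d}" for i in range(1, 43)],
    "Group2": ["genus01", "genus02", "genus43", "genus44", "genus45"],
    "Group3": ["genus03", "genus43", "genus46", "genus47", "genus48",
               "genus49", "genus50"],
}

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic dataset.

    Group proportions default to the 87:55:25 composition of a 167-locus
    type II-A survey; repeats are 36 nt with ~30 nt spacers, leaders 150 nt
    at 70% A/T.  All mutation rates default to 0 (clean planted truth).
    """

    n_loci: int = 30
    group_proportions: tuple[float, float, float] = (87 / 167, 55 / 167, 25 / 167)
    motif_mutation_rate: float = 0.0
    repeat_length: int = 36
    repeat_mutation_rate: float = 0.0
    n_repeat_copies: int = 4
    spacer_length: int = 30
    leader_length: int = 150
    leader_at_fraction: float = 0.7
    reverse_strand_fraction: float = 0.5
    decoy_repeat_rate: float = 0.25
    csn2_long_fraction: float = 0.25
    protein_noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        for name in ("motif_mutation_rate", "repeat_mutation_rate",
                     "reverse_strand_fraction", "decoy_repeat_rate",
                     "csn2_long_fraction", "protein_noise_rate",
                     "leader_at_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.leader_length < 7:
            raise ValueError("leader_length must fit the 7-nt leader-end motif")
        if self.repeat_length < 9:
            raise ValueError("repeat_length must fit GTTT...AAAC plus one base")
        if self.n_repeat_copies < 2:
            raise ValueError("n_repeat_copies must be >= 2")


def plant_mutations(
    seq: str, rate: float, rng: np.random.Generator, alphabet: str = DNA_ALPHABET
) -> str:
    """Substitute each position, independently with probability ``rate``,
    by a uniformly chosen *different* symbol of the alphabet."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def largest_remainder_counts(proportions: tuple[float, ...], n: int) -> list[int]:
    """Deterministic integer allocation of n items to proportions."""
    raw = [p * n for p in proportions]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def _at_rich(rng: np.random.Generator, length: int, at_fraction: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < at_fraction:
            out.append("A" if rng.random() < 0.5 else "T")
        else:
            out.append("C" if rng.random() < 0.5 else "G")
    return "".join(out)


@dataclass
class _ProteinTemplates:
    """Fixed role cores plus group/subgroup signature segments."""

    cores: dict[str, str]
    group_segments: dict[tuple[str, str], str]
    sub_segments: dict[tuple[str, str], str]


_ROLE_LENGTHS = {"cas9": 1100, "cas1": 290, "cas2": 100}
_CSN2_LONG = 320
_CSN2_SHORT_MAX = 230
_CSN2_SHORT_MIN = 218
_SUBGROUPS = ("1a", "1b", "2", "3")


def _make_templates(rng: np.random.Generator) -> _ProteinTemplates:
    cores = {role: _random_seq(rng, L, AA_ALPHABET)
             for role, L in _ROLE_LENGTHS.items()}
    cores["csn2_long"] = _random_seq(rng, _CSN2_LONG, AA_ALPHABET)
    cores["csn2_short"] = _random_seq(rng, _CSN2_SHORT_MAX, AA_ALPHABET)
    group_segments = {}
    sub_segments = {}
    for role in ("cas9", "cas1", "cas2", "csn2"):
        base = _ROLE_LENGTHS.get(role, _CSN2_SHORT_MIN)
        for group in GROUPS:
            group_segments[(role, group)] = _random_seq(
                rng, max(8, round(0.30 * base)), AA_ALPHABET
            )
        for sub in _SUBGROUPS:
            sub_segments[(role, sub)] = _random_seq(
                rng, max(6, round(0.15 * base)), AA_ALPHABET
            )
    return _ProteinTemplates(cores, group_segments, sub_segments)


def _compose_protein(
    templates: _ProteinTemplates,
    role: str,
    group: str,
    subgroup: str,
    rng: np.random.Generator,
    noise_rate: float,
    csn2_len: int | None = None,
) -> str:
    if role == "csn2":
        core = (templates.cores["csn2_long"] if subgroup == "1a"
                else templates.cores["csn2_short"][:csn2_len])
    else:
        core = templates.cores[role]
    gseg = templates.group_segments[(role, group)]
    sseg = templates.sub_segments[(role, subgroup)]
    L = len(core)
    p1 = L // 4
    p2 = min(L - len(sseg), round(0.7 * L))
    seq = list(core)
    seq[p1 : p1 + len(gseg)] = gseg[: max(0, L - p1)]
    seq[p2 : p2 + len(sseg)] = sseg[: max(0, L - p2)]
    protein = "".join(seq)[:L]
    return plant_mutations(protein, noise_rate, rng, AA_ALPHABET)


def _enforce_boundary_identifiability(
    leader_last: str,
    spacers: list[str],
    pad3: str,
    n_copies: int,
    rng: np.random.Generator,
) -> tuple[list[str], str]:
    """Make the planted repeat boundaries the maximal periodic boundaries.

    If the characters flanking the repeat copies (leader end, spacer ends,
    downstream pad) agree by chance, the locus's true repeat — under any
    periodic-array definition — is wider than the planted unit and the
    truth table would contradict itself.  Flanking characters are resampled
    until no symbol holds a majority in either boundary-adjacent column
    (at most floor(n_copies / 2) occurrences).
    """
    limit = max(1, n_copies // 2)
    spacers = [list(s) for s in spacers]
    pad3 = list(pad3)

    def fix(column: list[str], mutable: list[int]) -> None:
        # column[i] for i in mutable may be redrawn; others are fixed
        while True:
            counts: dict[str, int] = {}
            for c in column:
                counts[c] = counts.get(c, 0) + 1
            top = max(counts, key=lambda c: (counts[c], c))
            if counts[top] <= limit:
                return
            i = next(i for i in mutable if column[i] == top)
            column[i] = DNA_ALPHABET[rng.integers(4)]

    left = [leader_last] + [s[-1] for s in spacers]
    fix(left, list(range(1, len(left))))
    for i, s in enumerate(spacers):
        s[-1] = left[i + 1]
    right = [s[0] for s in spacers] + [pad3[0]]
    fix(right, list(range(len(right))))
    for i, s in enumerate(spacers):
        s[0] = right[i]
    pad3[0] = right[-1]
    return ["".join(s) for s in spacers], "".join(pad3)


def _leader_end7(group: str, rng: np.random.Generator) -> str:
    if group == "Group1":
        return "ATTTGAG"
    if group == "Group2":
        return "CT" + ("A" if rng.random() < 0.5 else "G") + "CGAG"
    # Group 3: partially conserved A-rich run, strict terminal CG
    arich = "".join("A" if rng.random() < 0.8 else "T" for _ in range(5))
    return arich + "CG"


def generate_synthetic_dataset(
    config: SimConfig,
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Emit one contig per planted locus plus a per-locus truth table.

    Truth coordinates are forward-strand, half-open, with the locus strand
    attached, so ``oriented_subsequence`` on (leader_start, leader_end,
    strand) returns exactly the planted leader.
    """
    rng = np.random.default_rng(config.seed)
    templates = _make_templates(rng)

    counts = largest_remainder_counts(config.group_proportions, config.n_loci)
    groups = [g for g, c in zip(GROUPS, counts) for _ in range(c)]
    n_long = min(round(config.csn2_long_fraction * config.n_loci), counts[0])

    # group/subgroup repeat units: GTTT ... AAAC (first base G, last base C)
    repeat_units = {}
    for sub in _SUBGROUPS:
        middle = _random_seq(rng, config.repeat_length - 8, DNA_ALPHABET)
        repeat_units[sub] = "GTTT" + middle + "AAAC"

    records: list[GenomeRecord] = []
    truth_rows = []
    group1_seen = 0
    genus_counters = {g: 0 for g in GROUPS}
    for i, group in enumerate(groups):
        locus_id = f"synth{i + 1:03d}"
        if group == "Group1":
            subgroup = "1a" if group1_seen < n_long else "1b"
            group1_seen += 1
        else:
            subgroup = group[-1]
        csn2_len = (_CSN2_LONG if subgroup == "1a"
                    else int(rng.integers(_CSN2_SHORT_MIN, _CSN2_SHORT_MAX + 1)))
        proteins = {
            role: _compose_protein(templates, role, group, subgroup, rng,
                                   config.protein_noise_rate, csn2_len)
            for role in ("cas9", "cas1", "cas2", "csn2")
        }

        pad5 = _random_seq(rng, 100, DNA_ALPHABET)
        if rng.random() < config.decoy_repeat_rate:
            # tandem decoy with a period far below the CRISPR range
            unit = _random_seq(rng, 12, DNA_ALPHABET)
            pad5 = pad5[:10] + unit * 6 + pad5[10 + 72 :]

        parts = [pad5]
        annotations = []
        pos = len(pad5)
        names = {
            "cas9": "CRISPR-associated endonuclease Cas9/Csn1",
            "cas1": "CRISPR-associated protein Cas1",
            "cas2": "CRISPR-associated protein Cas2",
            "csn2": "CRISPR-associated protein Csn2",
        }
        for role in ("cas9", "cas1", "cas2", "csn2"):
            cds = "".join(_CODON[aa] for aa in proteins[role]) + "TAA"
            annotations.append(
                GeneAnnotation(names[role], pos, pos + len(cds), "+",
                               protein_sequence=proteins[role])
            )
            parts.append(cds)
            pos += len(cds)
            if role != "csn2":
                ig = _random_seq(rng, 20, DNA_ALPHABET)
                parts.append(ig)
                pos += len(ig)

        leader = _at_rich(rng, config.leader_length, config.leader_at_fraction)
        end7 = plant_mutations(_leader_end7(group, rng),
                               config.motif_mutation_rate, rng)
        leader = leader[:-7] + end7
        leader_start = pos
        parts.append(leader)
        pos += len(leader)

        unit = repeat_units[subgroup]
        spacers = [_random_seq(rng, config.spacer_length, DNA_ALPHABET)
                   for _ in range(config.n_repeat_copies - 1)]
        pad3 = _random_seq(rng, 60, DNA_ALPHABET)
        spacers, pad3 = _enforce_boundary_identifiability(
            leader[-1], spacers, pad3, config.n_repeat_copies, rng
        )
        copies = []
        for c in range(config.n_repeat_copies):
            rep = plant_mutations(unit, config.repeat_mutation_rate, rng)
            copies.append((pos, rep))
            parts.append(rep)
            pos += len(rep)
            if c < config.n_repeat_copies - 1:
                parts.append(spacers[c])
                pos += config.spacer_length
        parts.append(pad3)

        sequence = "".join(parts)
        record = GenomeRecord(locus_id, sequence, annotations,
                              source="synthetic")
        strand = "-" if rng.random() < config.reverse_strand_fraction else "+"
        leader_end = leader_start + len(leader)
        rep_start, first_rep = copies[0]
        rep_end = rep_start + len(first_rep)
        if strand == "-":
            record = record.reverse_complemented()
            n = len(sequence)
            leader_start, leader_end = n - leader_end, n - leader_start
            rep_start, rep_end = n - rep_end, n - rep_start
        records.append(record)

        g_idx = GROUPS.index(group)
        pool = GENUS_POOLS[group][: max(1, min(len(GENUS_POOLS[group]),
                                               counts[g_idx]))]
        genus = pool[genus_counters[group] % len(pool)]
        genus_counters[group] += 1
        truth_rows.append(
            {
                "locus_id": locus_id,
                "record_id": locus_id,
                "group": group,
                "subgroup": subgroup,
                "genus": genus,
                "strand": strand,
                "leader_end7": end7,
                "first_repeat": first_rep,
                "leader_start": leader_start,
                "leader_end": leader_end,
                "repeat_start": rep_start,
                "repeat_end": rep_end,
                "cas9_length": len(proteins["cas9"]),
                "cas1_length": len(proteins["cas1"]),
                "cas2_length": len(proteins["cas2"]),
                "csn2_length": len(proteins["csn2"]),
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_dataset(
    records: list[GenomeRecord],
    truth: pd.DataFrame,
    outdir: str | Path,
    format: str = "genbank",
) -> None:
    """Write records (GenBank, or FASTA + annotation table) and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "genbank":
        write_genbank(records, outdir / "genomes.gbk")
    elif format == "fasta":
        write_fasta([(r.record_id, r.sequence) for r in records],
                    outdir / "genomes.fasta")
        write_annotation_table(records, outdir / "annotations.tsv")
    else:
        raise ValueError(f"unknown output format {format!r}")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
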