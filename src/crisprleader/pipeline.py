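"""End-to-end orchestration: genomes in, junction groups and trees out.

Stages: parse -> find cas operons -> detect arrays in the downstream window
-> extract leader-repeat junctions -> classify leader ends -> per-group MSA,
conservation profile and IUPAC consensus -> protein k-mer distances -> NJ
trees (Cas1, Cas2, Cas9, Csn2, first repeat) -> clade cutting -> clade/group
concordance -> dataset statistics.  Every dropped locus is logged with a
reason code; dropped + reported always equals the number of assembled
operons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import MultipleAlignment, ScoringScheme, kmer_distance_matrix, progressive_msa
from .arrays import CrisprArray, DetectorParams, EmptyLeaderError, LeaderJunction, detect_crispr_array, extract_leader_junction
from .conservation import (
    DatasetStats,
    GroupAssignment,
    build_profile,
    clade_mode_groups,
    classify_leader_end,
    dataset_statistics,
    information_content,
    iupac_consensus,
    write_profile_tsv,
)
from .genome import GenomeRecord, oriented_subsequence, write_fasta
from .operons import (
    CasOperon,
    DegenerateWindowError,
    assemble_type_iia_operons,
    find_cas_genes,
    leader_search_window,
)
from .phylo import CladePartition, ConcordanceReport, clade_concordance, cut_tree_clades, neighbor_joining, tree_to_newick

logger = logging.getLogger("crisprleader")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]

TREE_COMPONENTS = ("cas1", "cas2", "cas9", "csn2", "repeat")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables with their defaults.

    Serializable to/from a flat JSON file; unknown keys are rejected.
    """

    window_nt: int = 400
    max_operon_span: int = 15_000
    detector_k: int = 8
    min_repeat: int = 24
    max_repeat: int = 50
    min_spacer: int = 20
    max_spacer: int = 60
    min_copies: int = 2
    boundary_consensus: float = 0.75
    match: int = 2
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1
    kmer_protein: int = 4
    kmer_dna: int = 6
    classify_mode: str = "motif"          # "motif" or "clade"
    tolerance: int = 0
    clade_k: int = 4
    consensus_threshold: float = 0.9
    small_sample_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classify_mode not in ("motif", "clade"):
            raise ValueError("classify_mode must be 'motif' or 'clade'")

    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            k=self.detector_k,
            min_repeat=self.min_repeat,
            max_repeat=self.max_repeat,
            min_spacer=self.min_spacer,
            max_spacer=self.max_spacer,
            min_copies=self.min_copies,
            boundary_consensus=self.boundary_consensus,
        )

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open,
                             self.gap_extend)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class LocusResult:
    operon: CasOperon
    array: CrisprArray
    junction: LeaderJunction
    window_truncated: bool


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the drop accounting."""

    loci: list[LocusResult]
    assignments: list[GroupAssignment]          # motif mode
    clade_assignments: list[GroupAssignment]    # clade mode (empty if < 2 loci)
    group_alignments: dict[str, MultipleAlignment]
    group_consensus: dict[str, str]
    trees: dict[str, str]                       # component -> newick
    partitions: dict[str, CladePartition]
    concordance: dict[str, ConcordanceReport]
    stats: DatasetStats | None
    dropped: list[tuple[str, str]]              # (locus/cluster id, reason)
    n_operons: int

    @property
    def junctions(self) -> list[LeaderJunction]:
        return [l.junction for l in self.loci]

    def effective_assignments(self, mode: str) -> list[GroupAssignment]:
        if mode == "clade" and self.clade_assignments:
            return self.clade_assignments
        return self.assignments

    def summary(self, config: PipelineConfig) -> dict:
        assigns = self.effective_assignments(config.classify_mode)
        counts: dict[str, int] = {}
        for a in assigns:
            counts[a.group] = counts.get(a.group, 0) + 1
        return {
            "n_loci": len(self.loci),
            "n_operons": self.n_operons,
            "classify_mode": config.classify_mode,
            "group_counts": dict(sorted(counts.items())),
            "dropped": [{"locus": l, "reason": r} for l, r in self.dropped],
            "concordance": {
                name: {"purity": rep.purity, "adjusted_rand": rep.adjusted_rand}
                for name, rep in sorted(self.concordance.items())
            },
            "stats": self.stats.to_dict() if self.stats else None,
            "consensus": dict(sorted(self.group_consensus.items())),
        }


def _junction_seq(j: LeaderJunction) -> str:
    """Last 20 leader nt + first repeat: the aligned junction unit."""
    return j.leader20 + j.first_repeat


def run_pipeline(
    records: Sequence[GenomeRecord],
    config: PipelineConfig | None = None,
    genus_of: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on parsed genome records; see module docstring."""
    config = config or PipelineConfig()
    params = config.detector_params()
    scheme = config.scoring_scheme()

    dropped: list[tuple[str, str]] = []
    loci: list[LocusResult] = []
    n_operons = 0
    for record in records:
        hits = find_cas_genes(record)
        rejects: list[tuple[str, str]] = []
        operons = assemble_type_iia_operons(
            hits, config.max_operon_span, record_id=record.record_id,
            strict=False, rejects=rejects,
        )
        for desc, reason in rejects:
            logger.warning("%s: cluster rejected (%s): %s",
                           record.record_id, reason, desc)
        n_operons += len(operons)
        for operon in operons:
            try:
                window = leader_search_window(operon, record, config.window_nt)
            except DegenerateWindowError:
                dropped.append((operon.locus_id, "degenerate_window"))
                continue
            wseq = oriented_subsequence(record, window)
            arrays = detect_crispr_array(wseq, params)
            if not arrays:
                dropped.append((operon.locus_id, "no_array"))
                continue
            array = arrays[0]  # csn2-proximal array wins
            missing = [r for r, h in operon.hits.items()
                       if not h.annotation.protein_sequence]
            if missing:
                dropped.append((operon.locus_id, "missing_protein"))
                continue
            try:
                junction = extract_leader_junction(record, operon, array,
                                                   config.window_nt)
            except EmptyLeaderError:
                dropped.append((operon.locus_id, "empty_leader"))
                continue
            loci.append(
                LocusResult(
                    operon=operon,
                    array=array,
                    junction=junction,
                    window_truncated=window.length < config.window_nt,
                )
            )
    for locus, reason in dropped:
        logger.warning("dropped locus %s: %s", locus, reason)

    assignments = [
        classify_leader_end(l.junction, config.tolerance) for l in loci
    ]

    # per-group junction alignment, profile, consensus
    group_alignments: dict[str, MultipleAlignment] = {}
    group_consensus: dict[str, str] = {}
    by_group: dict[str, list[LocusResult]] = {}
    for locus, assign in zip(loci, assignments):
        by_group.setdefault(assign.group, []).append(locus)
    for group, members in sorted(by_group.items()):
        seqs = [(l.junction.locus_id, _junction_seq(l.junction))
                for l in members]
        msa = progressive_msa(seqs, scheme)
        group_alignments[group] = msa
        profile = build_profile(msa)
        group_consensus[group] = iupac_consensus(profile,
                                                 config.consensus_threshold)

    trees: dict[str, str] = {}
    partitions: dict[str, CladePartition] = {}
    concordance: dict[str, ConcordanceReport] = {}
    clade_assignments: list[GroupAssignment] = []
    stats: DatasetStats | None = None
    if len(loci) >= 2:
        group_labels = {a.locus_id: a.group for a in assignments}
        for component in TREE_COMPONENTS:
            if component == "repeat":
                seqs = [(l.junction.locus_id, l.junction.first_repeat)
                        for l in loci]
                dm = kmer_distance_matrix(seqs, k=config.kmer_dna)
            else:
                seqs = [
                    (l.junction.locus_id,
                     l.operon.hits[component].annotation.protein_sequence or "")
                    for l in loci
                ]
                dm = kmer_distance_matrix(seqs, k=config.kmer_protein)
            tree = neighbor_joining(dm)
            trees[component] = tree_to_newick(tree)
            k = min(config.clade_k, len(loci))
            partition = cut_tree_clades(tree, k)
            partitions[component] = partition
            concordance[component] = clade_concordance(partition, group_labels)
        clade_assignments = clade_mode_groups(assignments, partitions["cas1"])

        effective = (clade_assignments if config.classify_mode == "clade"
                     else assignments)
        csn2_lengths = {
            l.junction.locus_id:
                len(l.operon.hits["csn2"].annotation.protein_sequence or "")
            for l in loci
        }
        stats = dataset_statistics(
            [l.junction for l in loci],
            effective,
            genus_of=genus_of,
            csn2_lengths=csn2_lengths,
            clades=partitions["csn2"],
        )
    elif loci:
        stats = dataset_statistics([l.junction for l in loci], assignments,
                                   genus_of=genus_of)

    return PipelineResult(
        loci=loci,
        assignments=assignments,
        clade_assignments=clade_assignments,
        group_alignments=group_alignments,
        group_consensus=group_consensus,
        trees=trees,
        partitions=partitions,
        concordance=concordance,
        stats=stats,
        dropped=dropped,
        n_operons=n_operons,
    )


def write_report(
    result: PipelineResult, config: PipelineConfig, outdir: str | Path
) -> None:
    """Write the full report bundle: tables, FASTA, Newick, profiles, JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    assigns = {a.locus_id: a for a in result.assignments}
    clade_assigns = {a.locus_id: a for a in result.clade_assignments}
    for l in result.loci:
        j = l.junction
        rows.append(
            {
                "locus_id": j.locus_id,
                "record_id": l.operon.record_id,
                "orientation": l.operon.orientation,
                "span_start": l.operon.span.start,
                "span_end": l.operon.span.end,
                "leader20": j.leader20,
                "leader_end7": j.leader_end7,
                "junction_leader3": j.junction_leader3,
                "first_repeat": j.first_repeat,
                "junction_repeat4": j.junction_repeat4,
                "repeat_length": len(j.first_repeat),
                "n_repeat_copies": l.array.n_copies,
                "truncated": j.truncated,
                "group_motif": assigns[j.locus_id].group,
                "group_clade": clade_assigns.get(
                    j.locus_id, assigns[j.locus_id]
                ).group,
            }
        )
    junctions = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "record_id", "orientation", "span_start", "span_end",
            "leader20", "leader_end7", "junction_leader3", "first_repeat",
            "junction_repeat4", "repeat_length", "n_repeat_copies",
            "truncated", "group_motif", "group_clade",
        ],
    )
    junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    pd.DataFrame(result.dropped, columns=["locus_id", "reason"]).to_csv(
        outdir / "dropped.tsv", sep="\t", index=False
    )
    if result.loci:
        write_fasta(
            [(l.junction.locus_id, l.junction.leader20) for l in result.loci],
            outdir / "leader20.fasta",
        )
        write_fasta(
            [(l.junction.locus_id, l.junction.first_repeat)
             for l in result.loci],
            outdir / "first_repeat.fasta",
        )
    for group, msa in result.group_alignments.items():
        write_fasta(list(zip(msa.labels, msa.rows)),
                    outdir / f"alignment_{group}.fasta")
        profile = build_profile(msa)
        bits = information_content(profile, config.small_sample_correction)
        write_profile_tsv(profile, bits, outdir / f"profile_{group}.tsv")
    for component, newick in result.trees.items():
        (outdir / f"tree_{component}.nwk").write_text(newick + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
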