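"""Genome records, annotations and coordinate conventions.

All coordinates inside the package are 0-based half-open on the forward
strand; conversion to and from 1-based inclusive conventions (GenBank,
GFF-like tables) happens only here, at the I/O boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "GenomeRecord",
    "reverse_complement",
    "parse_genome_record",
    "oriented_subsequence",
    "write_genbank",
    "write_fasta",
    "write_annotation_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """A named feature on a contig (CDS or gene), forward-strand coordinates."""

    name: str
    start: int
    end: int
    strand: str
    protein_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"annotation {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"annotation {self.name!r}: invalid strand {self.strand!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.start, self.end, self.strand)


@dataclass
class GenomeRecord:
    """One contig: its sequence plus ordered gene annotations."""

    record_id: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-DNA symbols {sorted(bad)!r}"
            )
        self.annotations = sorted(self.annotations, key=lambda a: (a.start, a.end))
        n = len(self.sequence)
        for ann in self.annotations:
            if ann.end > n:
                raise ValueError(
                    f"record {self.record_id!r}: annotation {ann.name!r} "
                    f"[{ann.start}, {ann.end}) exceeds contig length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self) -> "GenomeRecord":
        """The same contig read on the other strand (coordinates mirrored)."""
        n = len(self.sequence)
        anns = [
            replace(
                a,
                start=n - a.end,
                end=n - a.start,
                strand="-" if a.strand == "+" else "+",
            )
            for a in self.annotations
        ]
        return GenomeRecord(
            record_id=self.record_id,
            sequence=reverse_complement(self.sequence),
            annotations=anns,
            source=self.source,
        )


def oriented_subsequence(record: GenomeRecord, interval: GenomicInterval) -> str:
    """Sequence of ``interval`` read in its strand's 5'->3' direction."""
    if interval.end > len(record.sequence):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) out of bounds for "
            f"record {record.record_id!r} of length {len(record.sequence)}"
        )
    sub = record.sequence[interval.start : interval.end]
    return sub if interval.strand == "+" else reverse_complement(sub)


def _annotation_from_feature(feature: SeqFeature, record_id: str) -> GeneAnnotation:
    try:
        start = int(feature.location.start)
        end = int(feature.location.end)
    except (TypeError, AttributeError) as exc:  # fuzzy/malformed locations
        raise ValueError(
            f"record {record_id!r}: malformed location on feature "
            f"{feature.qualifiers.get('gene', feature.qualifiers.get('product', '?'))}"
        ) from exc
    strand = "-" if feature.location.strand == -1 else "+"
    quals = feature.qualifiers
    name = (quals.get("product") or quals.get("gene") or ["unnamed"])[0]
    translation = quals.get("translation")
    protein = translation[0] if translation else None
    return GeneAnnotation(name=name, start=start, end=end, strand=strand,
                          protein_sequence=protein)


def _read_annotation_table(path: Path) -> dict[str, list[GeneAnnotation]]:
    """5-column TSV (record_id, start, end, strand, name), 1-based inclusive."""
    table: dict[str, list[GeneAnnotation]] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise ValueError(f"{path}: line {i}: expected 5 columns, got {len(row)}")
            rec_id, start, end, strand, name = row[:5]
            table.setdefault(rec_id, []).append(
                GeneAnnotation(name=name, start=int(start) - 1, end=int(end),
                               strand=strand)
            )
    return table


def parse_genome_record(
    path: str | Path,
    format: str = "genbank",
    annotation_table: str | Path | None = None,
) -> list[GenomeRecord]:
    """Read one or more contigs from a GenBank flat file or FASTA.

    ``format`` is ``"genbank"`` or ``"fasta"``.  For FASTA, CDS annotations
    may come from a tab-separated 5-column table (1-based inclusive
    coordinates, GFF-style); with no table the records carry no annotations.
    Multi-contig files yield independent records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such genome file: {path}")
    if format == "genbank":
        records = []
        for rec in SeqIO.parse(str(path), "genbank"):
            anns = [
                _annotation_from_feature(f, rec.id)
                for f in rec.features
                if f.type == "CDS"
            ]
            records.append(
                GenomeRecord(rec.id, str(rec.seq), anns, source=str(path))
            )
        if not records:
            raise ValueError(f"{path}: no GenBank records parsed")
        return records
    if format == "fasta":
        table = _read_annotation_table(Path(annotation_table)) if annotation_table else {}
        records = [
            GenomeRecord(rec.id, str(rec.seq), table.get(rec.id, []), source=str(path))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise ValueError(f"{path}: no FASTA records parsed")
        return records
    raise ValueError(f"unknown genome format {format!r} (expected 'genbank' or 'fasta')")


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as GenBank flat files (CDS features, translations kept)."""
    seqrecs = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.record_id, name=rec.record_id[:16],
                       description="")
        sr.annotations["molecule_type"] = "DNA"
        for ann in rec.annotations:
            quals: dict[str, list[str]] = {"product": [ann.name]}
            if ann.protein_sequence:
                quals["translation"] = [ann.protein_sequence]
            sr.features.append(
                SeqFeature(
                    FeatureLocation(ann.start, ann.end,
                                    strand=1 if ann.strand == "+" else -1),
                    type="CDS",
                    qualifiers=quals,
                )
            )
        seqrecs.append(sr)
    SeqIO.write(seqrecs, str(path), "genbank")


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write (label, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for label, seq in entries:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_annotation_table(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write annotations as the 5-column 1-based inclusive TSV."""
    with open(path, "w") as fh:
        for rec in records:
            for ann in rec.annotations:
                fh.write(
                    f"{rec.record_id}\t{ann.start + 1}\t{ann.end}\t{ann.strand}\t{ann.name}\n"
                )
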