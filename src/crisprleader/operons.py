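"""Finding complete type II-A cas operons (cas9, cas1, cas2, csn2).

A locus qualifies as type II-A only when all four signature genes are
present; locus transcription direction is taken from the cas genes, and the
leader/array search window lies immediately downstream of csn2 in that
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome import GeneAnnotation, GenomeRecord, GenomicInterval

__all__ = [
    "ROLE_ORDER",
    "DEFAULT_SYNONYMS",
    "CasGeneHit",
    "CasOperon",
    "DuplicateRoleError",
    "DegenerateWindowError",
    "find_cas_genes",
    "assemble_type_iia_operons",
    "leader_search_window",
]

ROLE_ORDER: tuple[str, ...] = ("cas9", "cas1", "cas2", "csn2")

# Annotation-name matching: csn1 is the historical synonym of cas9.
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "cas9": ("cas9", "csn1"),
    "cas1": ("cas1",),
    "cas2": ("cas2",),
    "csn2": ("csn2",),
}


class DuplicateRoleError(ValueError):
    """A candidate operon cluster carries the same cas role more than once."""


class DegenerateWindowError(ValueError):
    """The downstream search window has zero length (csn2 at a contig edge)."""


@dataclass(frozen=True)
class CasGeneHit:
    role: str
    annotation: GeneAnnotation
    matched_synonym: str


@dataclass(frozen=True)
class CasOperon:
    """All four type II-A cas genes of one locus."""

    hits: Mapping[str, CasGeneHit]
    span: GenomicInterval
    orientation: str
    locus_id: str
    record_id: str = ""

    @property
    def csn2(self) -> GeneAnnotation:
        return self.hits["csn2"].annotation


def find_cas_genes(
    record: GenomeRecord,
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> list[CasGeneHit]:
    """Scan annotation names for cas gene synonyms (case-insensitive substring).

    Each annotation yields at most one hit: the first matching role in the
    fixed order cas9, cas1, cas2, csn2.
    """
    synonyms = synonyms or DEFAULT_SYNONYMS
    hits = []
    for ann in record.annotations:
        label = ann.name.lower()
        for role in ROLE_ORDER:
            matched = next((s for s in synonyms.get(role, ()) if s.lower() in label),
                           None)
            if matched is not None:
                hits.append(CasGeneHit(role=role, annotation=ann,
                                       matched_synonym=ann.name))
                break
    return hits


def assemble_type_iia_operons(
    hits: Iterable[CasGeneHit],
    max_operon_span: int = 15_000,
    record_id: str = "",
    strict: bool = True,
    rejects: list[tuple[str, str]] | None = None,
) -> list[CasOperon]:
    """Cluster cas gene hits into complete type II-A operons.

    Hits are clustered greedily by proximity (gap between consecutive cas
    genes <= max_operon_span / 4).  A cluster becomes an operon only when it
    contains each of the four roles exactly once and spans at most
    ``max_operon_span``; orientation is the majority strand of the four
    genes.  Incomplete clusters are dropped (reason recorded in ``rejects``
    as ``(description, reason_code)`` when a list is supplied).  Clusters
    with a duplicated role raise :class:`DuplicateRoleError` in strict mode
    and are dropped otherwise.  Orientation ties (2 vs 2) drop the cluster.
    """
    hits = sorted(hits, key=lambda h: (h.annotation.start, h.annotation.end))
    if not hits:
        return []
    max_gap = max_operon_span / 4
    clusters: list[list[CasGeneHit]] = [[hits[0]]]
    for h in hits[1:]:
        if h.annotation.start - clusters[-1][-1].annotation.end <= max_gap:
            clusters[-1].append(h)
        else:
            clusters.append([h])

    def note(desc: str, reason: str) -> None:
        if rejects is not None:
            rejects.append((desc, reason))

    operons: list[CasOperon] = []
    for cluster in clusters:
        roles: dict[str, list[CasGeneHit]] = {}
        for h in cluster:
            roles.setdefault(h.role, []).append(h)
        dupes = {r: hs for r, hs in roles.items() if len(hs) > 1}
        if dupes:
            coords = {
                r: [(h.annotation.start, h.annotation.end) for h in hs]
                for r, hs in dupes.items()
            }
            if strict:
                raise DuplicateRoleError(
                    f"duplicated cas role(s) in one cluster: {coords}"
                )
            note(str(coords), "duplicate_role")
            continue
        missing = [r for r in ROLE_ORDER if r not in roles]
        if missing:
            note(f"cluster at {cluster[0].annotation.start}", "missing_cas_gene")
            continue
        four = {r: roles[r][0] for r in ROLE_ORDER}
        start = min(h.annotation.start for h in four.values())
        end = max(h.annotation.end for h in four.values())
        if end - start > max_operon_span:
            note(f"cluster [{start}, {end})", "span_exceeded")
            continue
        plus = sum(1 for h in four.values() if h.annotation.strand == "+")
        if plus == 2:
            note(f"cluster [{start}, {end})", "orientation_tie")
            continue
        orientation = "+" if plus > 2 else "-"
        locus_id = f"{record_id or 'locus'}_op{len(operons) + 1}"
        operons.append(
            CasOperon(
                hits=four,
                span=GenomicInterval(start, end, orientation),
                orientation=orientation,
                locus_id=locus_id,
                record_id=record_id,
            )
        )
    return operons


def leader_search_window(
    operon: CasOperon, record: GenomeRecord, window_nt: int = 400
) -> GenomicInterval:
    """The ~400-nt stretch downstream of csn2, read in transcription direction.

    Returns forward-strand coordinates with the locus strand attached, so
    :func:`~crisprleader.genome.oriented_subsequence` yields the window as
    transcribed (leader before array).  Truncated at contig edges; a
    zero-length window raises :class:`DegenerateWindowError`.
    """
    csn2 = operon.csn2
    if operon.orientation == "+":
        start, end = csn2.end, min(csn2.end + window_nt, len(record.sequence))
    else:
        start, end = max(0, csn2.start - window_nt), csn2.start
    if end <= start:
        raise DegenerateWindowError(
            f"locus {operon.locus_id}: csn2 at contig edge, empty downstream window"
        )
    return GenomicInterval(start, end, operon.orientation)
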