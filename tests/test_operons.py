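"""Cas gene mining, operon assembly, and the downstream search window."""

import numpy as np
import pytest

from crisprleader.genome import GeneAnnotation, GenomeRecord, oriented_subsequence
from crisprleader.operons import (
    DegenerateWindowError,
    DuplicateRoleError,
    assemble_type_iia_operons,
    find_cas_genes,
    leader_search_window,
)


def _record(annotations, length=30_000):
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(4, size=length))
    return GenomeRecord("rec", seq, annotations)


def _four_gene_annotations(start=1000, gap=200, strand="+", size=900):
    anns = []
    pos = start
    for name in ("cas9", "cas1", "cas2", "csn2"):
        anns.append(GeneAnnotation(name, pos, pos + size, strand))
        pos += size + gap
    return anns


class TestFindCasGenes:
    @pytest.mark.parametrize(
        "label,role",
        [
            ("Csn1", "cas9"),
            ("CRISPR-associated endonuclease Cas9/Csn1", "cas9"),
            ("cas1", "cas1"),
            ("CRISPR-associated protein Csn2", "csn2"),
        ],
    )
    def test_synonym_matches(self, label, role):
        rec = _record([GeneAnnotation(label, 10, 40, "+")])
        (hit,) = find_cas_genes(rec)
        assert hit.role == role
        assert hit.matched_synonym == label

    def test_non_type_iia_names_ignored(self):
        rec = _record([GeneAnnotation("cas3", 10, 40, "+"),
                       GeneAnnotation("hypothetical protein", 50, 80, "+")])
        assert find_cas_genes(rec) == []

    def test_four_roles_found_once_each(self):
        rec = _record(_four_gene_annotations())
        hits = find_cas_genes(rec)
        assert sorted(h.role for h in hits) == ["cas1", "cas2", "cas9", "csn2"]


class TestAssembleOperons:
    def test_complete_cluster_same_strand(self):
        rec = _record(_four_gene_annotations())
        (operon,) = assemble_type_iia_operons(find_cas_genes(rec),
                                              record_id="rec")
        assert operon.orientation == "+"
        assert set(operon.hits) == {"cas9", "cas1", "cas2", "csn2"}

    def test_incomplete_cluster_dropped(self):
        anns = _four_gene_annotations()[:3]  # no csn2
        rejects = []
        operons = assemble_type_iia_operons(
            find_cas_genes(_record(anns)), rejects=rejects
        )
        assert operons == []
        assert rejects[0][1] == "missing_cas_gene"

    def test_two_distant_clusters_are_independent_loci(self):
        anns = _four_gene_annotations(start=1000) + _four_gene_annotations(
            start=21_000
        )
        operons = assemble_type_iia_operons(find_cas_genes(_record(anns)),
                                            record_id="rec")
        assert len(operons) == 2
        assert operons[0].locus_id != operons[1].locus_id

    def test_duplicate_role_raises_in_strict_mode(self):
        anns = _four_gene_annotations() + [
            GeneAnnotation("csn2", 6000, 6300, "+")
        ]
        with pytest.raises(DuplicateRoleError):
            assemble_type_iia_operons(find_cas_genes(_record(anns)))

    def test_duplicate_role_dropped_in_lenient_mode(self):
        anns = _four_gene_annotations() + [
            GeneAnnotation("csn2", 6000, 6300, "+")
        ]
        rejects = []
        operons = assemble_type_iia_operons(
            find_cas_genes(_record(anns)), strict=False, rejects=rejects
        )
        assert operons == []
        assert rejects[0][1] == "duplicate_role"

    def test_orientation_tie_rejected(self):
        anns = _four_gene_annotations()
        anns = [
            GeneAnnotation(a.name, a.start, a.end,
                           "+" if i < 2 else "-")
            for i, a in enumerate(anns)
        ]
        rejects = []
        operons = assemble_type_iia_operons(
            find_cas_genes(_record(anns)), rejects=rejects
        )
        assert operons == []
        assert rejects[0][1] == "orientation_tie"

    def test_majority_strand_sets_orientation(self):
        anns = _four_gene_annotations(strand="-")
        anns[0] = GeneAnnotation("cas9", anns[0].start, anns[0].end, "+")
        (operon,) = assemble_type_iia_operons(find_cas_genes(_record(anns)))
        assert operon.orientation == "-"

    def test_hit_order_does_not_change_result(self):
        rec = _record(_four_gene_annotations())
        hits = find_cas_genes(rec)
        a = assemble_type_iia_operons(hits, record_id="rec")
        b = assemble_type_iia_operons(list(reversed(hits)), record_id="rec")
        assert [(o.span.start, o.span.end, o.orientation) for o in a] == [
            (o.span.start, o.span.end, o.orientation) for o in b
        ]


class TestLeaderSearchWindow:
    def _operon(self, strand="+", csn2_start=4100, csn2_end=5000,
                record_len=10_000):
        anns = []
        pos = csn2_start - 3 * 750
        for name in ("cas9", "cas1", "cas2"):
            anns.append(GeneAnnotation(name, pos, pos + 700, strand))
            pos += 750
        anns.append(GeneAnnotation("csn2", csn2_start, csn2_end, strand))
        rec = _record(anns, length=record_len)
        (operon,) = assemble_type_iia_operons(find_cas_genes(rec))
        return operon, rec

    def test_forward_window_downstream_of_csn2(self):
        operon, rec = self._operon("+")
        window = leader_search_window(operon, rec, 400)
        assert (window.start, window.end, window.strand) == (5000, 5400, "+")

    def test_reverse_window_mirrors(self):
        anns = _four_gene_annotations(start=5000, gap=50, size=700,
                                      strand="-")
        # transcription right-to-left: csn2 is the leftmost gene
        anns = [GeneAnnotation("csn2", 2000 - 600, 2000, "-")] + anns[:3]
        rec = _record(anns)
        (operon,) = assemble_type_iia_operons(find_cas_genes(rec))
        window = leader_search_window(operon, rec, 400)
        assert (window.start, window.end, window.strand) == (1000, 1400, "-")

    def test_window_truncated_at_contig_end(self):
        operon, rec = self._operon("+", csn2_start=8500, csn2_end=9700,
                                   record_len=10_000)
        window = leader_search_window(operon, rec, 400)
        assert (window.start, window.end) == (9700, 10_000)
        assert window.length == 300

    def test_csn2_at_contig_edge_is_degenerate(self):
        operon, rec = self._operon("+", csn2_start=9000, csn2_end=10_000,
                                   record_len=10_000)
        with pytest.raises(DegenerateWindowError):
            leader_search_window(operon, rec, 400)


class TestStrandSymmetry:
    def test_reverse_complement_flips_operons_but_not_window_sequence(
        self, small_dataset
    ):
        _, records, _ = small_dataset
        for record in records[:6]:
            (operon,) = assemble_type_iia_operons(
                find_cas_genes(record), record_id=record.record_id
            )
            window = leader_search_window(operon, record)
            wseq = oriented_subsequence(record, window)

            flipped = record.reverse_complemented()
            (op2,) = assemble_type_iia_operons(
                find_cas_genes(flipped), record_id=flipped.record_id
            )
            assert op2.orientation != operon.orientation
            n = len(record.sequence)
            assert (op2.span.start, op2.span.end) == (
                n - operon.span.end, n - operon.span.start
            )
            w2 = leader_search_window(op2, flipped)
            assert oriented_subsequence(flipped, w2) == wseq
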