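"""Conservation profiles, information content, IUPAC consensus, leader-end
classification, and dataset statistics."""

import math

import numpy as np
import pytest

from crisprleader.align import MultipleAlignment
from crisprleader.arrays import LeaderJunction
from crisprleader.conservation import (
    GroupAssignment,
    build_profile,
    classify_leader_end,
    clade_mode_groups,
    dataset_statistics,
    information_content,
    iupac_consensus,
)
from crisprleader.phylo import CladePartition


def _msa(*rows):
    return MultipleAlignment([f"s{i}" for i in range(len(rows))], list(rows))


def _junction(locus, leader20, repeat):
    return LeaderJunction(locus_id=locus, leader20=leader20,
                         first_repeat=repeat)


class TestProfile:
    def test_uniform_column_frequency_one(self):
        profile = build_profile(_msa("A", "A", "A", "A"))
        assert profile.frequencies[0, 0] == 1.0

    def test_even_two_symbol_column(self):
        profile = build_profile(_msa("A", "A", "G", "G"))
        freqs = dict(zip(profile.alphabet, profile.frequencies[0]))
        assert freqs["A"] == 0.5 and freqs["G"] == 0.5

    def test_gaps_excluded_from_frequencies(self):
        profile = build_profile(_msa("A", "-", "A", "A"))
        assert profile.frequencies[0, 0] == 1.0
        assert profile.gap_fraction[0] == pytest.approx(0.25)

    def test_all_gap_column_flagged_nan(self):
        profile = build_profile(_msa("A-", "A-", "A-"))
        assert np.isnan(profile.frequencies[1]).all()

    def test_pseudocount_smooths_counts(self):
        profile = build_profile(_msa("A", "A"), pseudocount=1.0)
        freqs = dict(zip(profile.alphabet, profile.frequencies[0]))
        assert freqs["A"] == pytest.approx(3 / 6)
        assert freqs["C"] == pytest.approx(1 / 6)


class TestInformationContent:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            (("A", "C", "G", "T"), 0.0),   # uniform column
            (("A", "T", "A", "T"), 1.0),   # two-symbol even
            (("A", "A", "A", "A"), 2.0),   # single symbol
        ],
    )
    def test_analytic_values_without_correction(self, rows, expected):
        profile = build_profile(_msa(*rows))
        bits = information_content(profile, small_sample_correction=False)
        assert bits[0] == pytest.approx(expected)

    def test_small_sample_correction_subtracts_e_n(self):
        profile = build_profile(_msa("A", "A", "A", "A"))
        bits = information_content(profile, small_sample_correction=True)
        expected = 2.0 - 3 / (2 * math.log(2) * 4)
        assert bits[0] == pytest.approx(expected)

    def test_bits_bounded_between_zero_and_two(self):
        rng = np.random.default_rng(6)
        rows = ["".join("ACGT"[i] for i in rng.integers(4, size=15))
                for _ in range(8)]
        profile = build_profile(_msa(*rows))
        bits = information_content(profile, small_sample_correction=True)
        assert ((bits >= 0.0) & (bits <= 2.0)).all()


class TestIupacConsensus:
    def test_purine_column_yields_R(self):
        profile = build_profile(_msa("A", "A", "G", "G"))
        assert iupac_consensus(profile, 0.9) == "R"

    def test_single_base_column(self):
        profile = build_profile(_msa("A", "A"))
        assert iupac_consensus(profile, 0.9) == "A"

    def test_fully_degenerate_column_is_N(self):
        profile = build_profile(_msa("A", "C", "G", "T"))
        assert iupac_consensus(profile, 0.9) == "N"

    def test_threshold_one_on_single_sequence_returns_it(self):
        profile = build_profile(_msa("GATTACA"))
        assert iupac_consensus(profile, 1.0) == "GATTACA"


class TestClassification:
    @pytest.mark.parametrize(
        "leader20,expected",
        [
            ("AAAAAAAAAAAAAATTTGAG", "Group1"),
            ("AAAAAAAAAAAAACTACGAG", "Group2"),
            ("AAAAAAAAAAAAACTGCGAG", "Group2"),
            ("AAAAAAAAAAAATTAAAACG", "Group3"),
            ("AAAAAAAAAAAAAGGGGGGG", "unclassified"),
        ],
    )
    def test_motif_examples(self, leader20, expected):
        assignment = classify_leader_end(
            _junction("x", leader20, "GTTTAAAC")
        )
        assert assignment.group == expected

    def test_classification_depends_only_on_last_seven(self):
        a = classify_leader_end(_junction("x", "TTTTTTTTTTTTTATTTGAG", "GTTT"))
        b = classify_leader_end(_junction("y", "CCCCCCCCCCCCCATTTGAG", "GTTT"))
        assert a.group == b.group == "Group1"

    def test_tolerance_allows_one_mismatch(self):
        junction = _junction("x", "AAAAAAAAAAAAAATTTGAC", "GTTT")
        assert classify_leader_end(junction, tolerance=0).group != "Group1"
        assignment = classify_leader_end(junction, tolerance=1)
        assert assignment.group == "Group1"
        assert assignment.mismatches == 1

    def test_group1_takes_precedence_over_group2(self):
        assignment = classify_leader_end(
            _junction("x", "AAAAAAAAAAAAAATTTGAG", "GTTT"), tolerance=3
        )
        assert assignment.group == "Group1"

    def test_empty_leader_unclassified(self):
        assignment = classify_leader_end(_junction("x", "", "GTTT"))
        assert assignment.group == "unclassified"


class TestCladeMode:
    def test_clade_majority_overrides_member_motifs(self):
        assignments = [
            GroupAssignment("a", "Group1"),
            GroupAssignment("b", "Group1"),
            GroupAssignment("c", "unclassified"),
            GroupAssignment("d", "Group2"),
            GroupAssignment("e", "Group2"),
        ]
        clades = CladePartition({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2})
        out = {a.locus_id: a.group for a in
               clade_mode_groups(assignments, clades)}
        assert out == {"a": "Group1", "b": "Group1", "c": "Group1",
                       "d": "Group2", "e": "Group2"}


class TestDatasetStatistics:
    def _build(self):
        junctions, assignments = [], []
        groups = ["Group1"] * 5 + ["Group2"] * 3 + ["Group3"] * 2
        for i, group in enumerate(groups):
            locus = f"l{i}"
            leader = {"Group1": "AAAAAAAAAAAAAATTTGAG",
                      "Group2": "AAAAAAAAAAAAACTACGAG",
                      "Group3": "AAAAAAAAAAAATTAAAACG"}[group]
            repeat = "GTTT" + "A" * 28 + "AAAC"
            junctions.append(_junction(locus, leader, repeat))
            assignments.append(classify_leader_end(junctions[-1]))
        return junctions, assignments

    def test_planted_group_counts(self):
        junctions, assignments = self._build()
        stats = dataset_statistics(junctions, assignments)
        assert stats.group_counts == {"Group1": 5, "Group2": 3, "Group3": 2}

    def test_all_repeats_start_gttt_and_end_c(self):
        junctions, assignments = self._build()
        stats = dataset_statistics(junctions, assignments)
        assert stats.count_missing_5prime_GTTT == 0
        assert stats.count_missing_3prime_C == 0
        assert stats.junction_gag_gttt_count == 8  # all of Groups 1 and 2
        assert stats.n_group12 == 8

    def test_modal_length_and_exception_list(self):
        junctions, assignments = self._build()
        junctions[3] = _junction("l3", junctions[3].leader20,
                                 junctions[3].first_repeat[:-1])
        stats = dataset_statistics(junctions, assignments)
        assert stats.repeat_length_mode == 36
        assert stats.repeat_length_exceptions == [("l3", 35)]

    def test_locus_order_does_not_change_statistics(self):
        junctions, assignments = self._build()
        a = dataset_statistics(junctions, assignments)
        b = dataset_statistics(list(reversed(junctions)),
                               list(reversed(assignments)))
        assert a.to_dict() == b.to_dict()

    def test_genus_and_csn2_summaries(self):
        junctions, assignments = self._build()
        genus = {f"l{i}": f"g{i // 4}" for i in range(10)}
        csn2 = {f"l{i}": (320 if i < 2 else 224) for i in range(10)}
        clades = CladePartition(
            {f"l{i}": (1 if i < 2 else 2) for i in range(10)}
        )
        stats = dataset_statistics(junctions, assignments, genus_of=genus,
                                   csn2_lengths=csn2, clades=clades)
        assert stats.csn2_mean_length_per_clade == {1: 320.0, 2: 224.0}
        assert stats.genera_per_group["Group1"] == 2

    def test_mismatched_locus_sets_rejected(self):
        junctions, assignments = self._build()
        with pytest.raises(ValueError, match="l9"):
            dataset_statistics(junctions[:-1], assignments)
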