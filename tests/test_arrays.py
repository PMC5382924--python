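"""Seed-and-extend array detection against the brute-force periodic oracle,
and leader-repeat junction extraction."""

import numpy as np
import pytest

from crisprleader.arrays import (
    DetectorParams,
    detect_crispr_array,
    extract_leader_junction,
    junctions_from_fasta,
)
from crisprleader.genome import oriented_subsequence
from crisprleader.operons import assemble_type_iia_operons, find_cas_genes, leader_search_window
from crisprleader.reference import best_exact_array, enumerate_exact_arrays
from crisprleader.simulate import plant_mutations

from conftest import random_dna


def _best(arrays):
    if not arrays:
        return None
    return min(arrays, key=lambda a: (-a.n_copies, -a.repeat_unit_length,
                                      a.start))


class TestDetector:
    def test_three_exact_copies_found(self):
        rng = np.random.default_rng(1)
        repeat = random_dna(rng, 36)
        window = (
            random_dna(rng, 60)
            + repeat + random_dna(rng, 30)
            + repeat + random_dna(rng, 30)
            + repeat + random_dna(rng, 40)
        )
        oracle = best_exact_array(window)
        assert oracle is not None and oracle.n_copies == 3
        best = _best(detect_crispr_array(window))
        assert best is not None
        assert best.repeat_unit_length == oracle.unit_length
        assert best.n_copies == oracle.n_copies
        assert tuple(c.start for c in best.repeat_copies) == oracle.copy_starts
        assert best.first_repeat == window[oracle.offset:
                                           oracle.offset + oracle.unit_length]

    def test_random_window_has_no_array(self):
        rng = np.random.default_rng(2)
        window = random_dna(rng, 400)
        assert enumerate_exact_arrays(window) == []
        assert detect_crispr_array(window) == []

    def test_two_copies_is_minimal_configuration(self):
        rng = np.random.default_rng(3)
        repeat = random_dna(rng, 36)
        window = random_dna(rng, 50) + repeat + random_dna(rng, 30) + repeat \
            + random_dna(rng, 50)
        best = _best(detect_crispr_array(window))
        assert best is not None and best.n_copies == 2

    def test_too_short_window_yields_nothing(self):
        assert detect_crispr_array("ACGT" * 10) == []

    def test_candidate_repeat_containing_N_rejected(self):
        rng = np.random.default_rng(4)
        repeat = random_dna(rng, 17) + "N" + random_dna(rng, 18)
        window = random_dna(rng, 50) + repeat + random_dna(rng, 30) + repeat \
            + random_dna(rng, 50)
        assert detect_crispr_array(window) == []

    def test_repeats_and_spacers_alternate_within_bounds(self):
        rng = np.random.default_rng(5)
        repeat = random_dna(rng, 30)
        window = random_dna(rng, 40) + repeat + random_dna(rng, 25) + repeat \
            + random_dna(rng, 25) + repeat + random_dna(rng, 40)
        (array,) = detect_crispr_array(window)
        params = DetectorParams()
        for copy in array.repeat_copies:
            assert params.min_repeat <= copy.length <= params.max_repeat
        for spacer in array.spacer_intervals:
            assert params.min_spacer <= spacer.length <= params.max_spacer
        for copy, spacer in zip(array.repeat_copies, array.spacer_intervals):
            assert copy.end == spacer.start

    def test_oracle_equivalence_on_exact_windows(self):
        """Detector output matches brute-force periodic enumeration exactly
        on windows with unmutated planted repeats (30-window sample)."""
        rng = np.random.default_rng(11)
        for trial in range(30):
            if trial % 3 == 2:
                window = random_dna(rng, 300)
            else:
                unit = random_dna(rng, int(rng.integers(24, 41)))
                copies = int(rng.integers(2, 4))
                spacer = int(rng.integers(20, 61))
                arr = unit + "".join(
                    random_dna(rng, spacer) + unit for _ in range(copies - 1)
                )
                window = (random_dna(rng, int(rng.integers(20, 60))) + arr
                          + random_dna(rng, int(rng.integers(20, 60))))[:300]
            oracle = best_exact_array(window)
            best = _best(detect_crispr_array(window))
            if oracle is None:
                assert best is None
            else:
                assert best is not None
                assert (best.start, best.repeat_unit_length) == (
                    oracle.offset, oracle.unit_length
                )
                assert tuple(c.start for c in best.repeat_copies) == \
                    oracle.copy_starts

    def test_planted_boundary_recovery_under_mutation(self):
        """On 12-copy arrays with 2% per-copy substitution, the detected
        unit length equals the planted 36 nt in >= 95% of 200 trials."""
        rng = np.random.default_rng(5)
        ok = 0
        for _ in range(200):
            unit = "GTTT" + random_dna(rng, 28) + "AAAC"
            parts = [random_dna(rng, 30)]
            for c in range(12):
                parts.append(plant_mutations(unit, 0.02, rng))
                if c < 11:
                    parts.append(random_dna(rng, 30))
            parts.append(random_dna(rng, 30))
            best = _best(detect_crispr_array("".join(parts)))
            if best is not None and best.repeat_unit_length == 36:
                ok += 1
        assert ok >= 190


class TestJunctionExtraction:
    def _locus(self, dataset, idx=0):
        _, records, truth = dataset
        record = records[idx]
        (operon,) = assemble_type_iia_operons(
            find_cas_genes(record), record_id=record.record_id
        )
        (array,) = detect_crispr_array(
            oriented_subsequence(record, leader_search_window(operon, record))
        )
        return record, operon, array, truth.iloc[idx]

    def test_junction_fields_are_consistent_slices(self, small_dataset):
        record, operon, array, row = self._locus(small_dataset)
        junction = extract_leader_junction(record, operon, array)
        assert junction.leader_end7 == junction.leader20[-7:]
        assert junction.first_repeat.startswith(junction.junction_repeat4)
        assert junction.leader_end7 == row.leader_end7
        assert junction.first_repeat == row.first_repeat
        assert not junction.truncated

    def test_group1_junction_reads_atttgag_gttt(self, small_dataset):
        _, records, truth = small_dataset
        idx = int(truth.index[truth.group == "Group1"][0])
        record, operon, array, _ = self._locus(small_dataset, idx)
        junction = extract_leader_junction(record, operon, array)
        assert junction.leader_end7 == "ATTTGAG"
        assert junction.junction_leader3 == "GAG"
        assert junction.junction_repeat4 == "GTTT"

    def test_reverse_strand_locus_gives_identical_junction(self, small_dataset):
        record, operon, array, _ = self._locus(small_dataset)
        junction = extract_leader_junction(record, operon, array)

        flipped = record.reverse_complemented()
        (op2,) = assemble_type_iia_operons(
            find_cas_genes(flipped), record_id=flipped.record_id
        )
        (arr2,) = detect_crispr_array(
            oriented_subsequence(flipped, leader_search_window(op2, flipped))
        )
        j2 = extract_leader_junction(flipped, op2, arr2)
        assert (j2.leader20, j2.first_repeat) == (junction.leader20,
                                                  junction.first_repeat)

    def test_concatenation_reconstructs_window(self, small_dataset):
        record, operon, array, _ = self._locus(small_dataset)
        window = leader_search_window(operon, record)
        wseq = oriented_subsequence(record, window)
        leader = wseq[: array.start]
        assert leader + wseq[array.start:] == wseq
        assert wseq[array.start : array.start + array.repeat_unit_length] == \
            array.first_repeat


class TestJunctionFasta:
    def test_round_trip_classification_input(self, tmp_path):
        path = tmp_path / "junctions.fasta"
        path.write_text(">loc1\nAAAAAAAAAAAAAATTTGAGGTTTACGTACGT\n")
        (j,) = junctions_from_fasta(path)
        assert j.leader20.endswith("ATTTGAG")
        assert j.first_repeat.startswith("GTTT")

    def test_too_short_record_rejected(self, tmp_path):
        path = tmp_path / "junctions.fasta"
        path.write_text(">loc1\nACGTACGT\n")
        with pytest.raises(ValueError, match="loc1"):
            junctions_from_fasta(path)
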