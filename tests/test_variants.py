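"""Banded alignment, lesion-site classification, tallying and background filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcrquant.simulate import ReadSimConfig, simulate_amplicon_reads
from hcrquant.variants import (BAND, GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH,
                               ReferenceTranscript, align_and_classify,
                               banded_global_alignment, example_reference,
                               filter_by_background, tally_variants)


def biopython_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def classify_with_oracle(read, ref):
    """Full (unbanded) dynamic-programming classification via Biopython."""
    aln = biopython_aligner().align(ref.sequence, read)[0]
    ref_idx, read_idx = aln.indices
    pos0 = ref.lesion_opposite_pos - 1
    col = int(np.nonzero(ref_idx == pos0)[0][0])
    if read_idx[col] < 0:
        return "deletion", None
    base = read[read_idx[col]]
    if base != ref.lesion_base:
        return "misincorporation", base
    for k in (col - 1, col + 1):
        if 0 <= k < len(ref_idx) and ref_idx[k] < 0:
            return "insertion", read[read_idx[k]]
    return "match", None


class TestBandedAlignment:
    def test_identical_sequences_score_full_match(self):
        score, cols = banded_global_alignment("ACGU" * 6, "ACGU" * 6)
        assert score == 24 * MATCH
        assert all(r is not None and q is not None for r, q in cols)

    def test_score_matches_full_dp(self, reference):
        aligner = biopython_aligner()
        ref = reference.sequence
        rng = np.random.default_rng(9)
        bases = "ACGU"
        for _ in range(30):
            read = list(ref)
            kind = rng.choice(["sub", "del", "ins", "none"])
            i = int(rng.integers(0, len(ref)))
            if kind == "sub":
                read[i] = bases[(bases.index(read[i]) + 1) % 4]
            elif kind == "del":
                del read[i]
            elif kind == "ins":
                read.insert(i, bases[rng.integers(0, 4)])
            read = "".join(read)
            score, _ = banded_global_alignment(ref, read)
            assert score == pytest.approx(aligner.score(ref, read))

    def test_length_outside_band_rejected(self):
        with pytest.raises(ValueError):
            banded_global_alignment("A" * 30, "A" * 40)


class TestClassification:
    def test_perfect_read_is_match(self, reference):
        call = align_and_classify(reference.sequence, reference, "r")
        assert call.event == "match" and call.n_differences == 0

    def test_core_context_read_with_flanks(self):
        # the lesion-opposite U sits at core position 6 of GAGCGUACGAG
        ref = example_reference()
        assert ref.sequence[ref.lesion_opposite_pos - 1] == "U"
        assert "GAGCGUACGAG" in ref.sequence

    @pytest.mark.parametrize("base", ["A", "C", "G"])
    def test_substituted_lesion_base_is_misincorporation(self, reference, base):
        p = reference.lesion_opposite_pos - 1
        read = reference.sequence[:p] + base + reference.sequence[p + 1:]
        call = align_and_classify(read, reference, "r")
        assert call.event == "misincorporation" and call.base == base

    def test_deleted_lesion_base_matches_full_dp_oracle(self, reference):
        p = reference.lesion_opposite_pos - 1
        read = reference.sequence[:p] + reference.sequence[p + 1:]
        call = align_and_classify(read, reference, "r")
        assert call.event == "deletion"
        assert classify_with_oracle(read, reference)[0] == "deletion"

    def test_inserted_base_next_to_lesion_is_insertion(self, reference):
        p = reference.lesion_opposite_pos
        read = reference.sequence[:p] + "G" + reference.sequence[p:]
        call = align_and_classify(read, reference, "r")
        assert call.event == "insertion" and call.base == "G"

    def test_too_many_differences_unclassifiable(self, reference):
        seq = list(reference.sequence)
        for i in (2, 5, 8, 11):  # 4 substitutions in the left flank
            seq[i] = "A" if seq[i] != "A" else "C"
        call = align_and_classify("".join(seq), reference, "r")
        assert call.event == "unclassifiable"

    def test_offsite_substitution_still_match_at_lesion(self, reference):
        seq = list(reference.sequence)
        seq[2] = "G" if seq[2] != "G" else "A"
        call = align_and_classify("".join(seq), reference, "r")
        assert call.event == "match" and call.n_differences == 1

    def test_empty_read_rejected(self, reference):
        with pytest.raises(ValueError):
            align_and_classify("", reference, "r")

    def test_dna_alphabet_accepted(self, reference):
        dna = reference.sequence.replace("U", "T")
        call = align_and_classify(dna, reference, "r")
        assert call.event == "match"

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_single_edit_reads_agree_with_full_dp_oracle(self, seed):
        """Banded classification equals unbanded DP classification on reads
        carrying one random edit anywhere in the sequence."""
        ref = example_reference()
        rng = np.random.default_rng(seed)
        bases = "ACGU"
        read = list(ref.sequence)
        kind = ("sub", "del", "ins")[int(rng.integers(0, 3))]
        i = int(rng.integers(1, len(read) - 1))
        if kind == "sub":
            read[i] = bases[(bases.index(read[i]) + int(rng.integers(1, 4))) % 4]
        elif kind == "del":
            del read[i]
        else:
            read.insert(i, bases[int(rng.integers(0, 4))])
        read = "".join(read)
        mine = align_and_classify(read, ref, "r")
        oracle_event, oracle_base = classify_with_oracle(read, ref)
        assert mine.event == oracle_event
        assert mine.base == oracle_base


class TestTallyAndFilter:
    def _calls(self, counts_by_class):
        from hcrquant.variants import VariantCall

        calls = []
        i = 0
        for (event, base), count in counts_by_class.items():
            for _ in range(count):
                calls.append(VariantCall(f"r{i}", event, 21, base))
                i += 1
        return calls

    def test_all_match_tally(self):
        tally = tally_variants(self._calls({("match", None): 100}))
        assert tally.frequencies == {"match": 1.0}
        assert tally.n_unclassifiable == 0

    def test_mixed_tally_frequencies(self):
        tally = tally_variants(self._calls({("match", None): 95,
                                            ("misincorporation", "C"): 5}))
        assert tally.frequencies["misincorporation:C"] == pytest.approx(0.05)

    def test_unclassifiable_reported_separately(self):
        tally = tally_variants(self._calls({("match", None): 90,
                                            ("unclassifiable", None): 10}))
        assert tally.n_classified == 90 and tally.n_unclassifiable == 10
        assert tally.n_classified + tally.n_unclassifiable == 100

    def test_boundary_inclusive_at_ten_times_background(self):
        # frequency exactly 0.010 with background 0.001 and fold 10 -> retained
        tally = tally_variants(self._calls({("match", None): 990,
                                            ("deletion", None): 10}))
        assert tally.frequencies["deletion"] == pytest.approx(0.010)
        assert tally.retained["deletion"] is True

    def test_just_below_boundary_not_retained(self):
        tally = tally_variants(self._calls({("match", None): 9901,
                                            ("deletion", None): 99}))
        assert tally.frequencies["deletion"] < 0.010
        assert tally.retained["deletion"] is False

    def test_filter_monotone_in_fold_threshold(self):
        tally = tally_variants(self._calls({("match", None): 980,
                                            ("misincorporation", "A"): 20}))
        retained = [filter_by_background(tally, fold_threshold=f).retained[
            "misincorporation:A"] for f in (5, 10, 20, 21, 50)]
        assert retained == sorted(retained, reverse=True)

    def test_simulated_deletion_rate_recovered(self, reference):
        cfg = ReadSimConfig(reference=reference, background_error_rate=0.001,
                            lesion_event_profile={"deletion": 0.1},
                            n_reads=5000, seed=13)
        reads = simulate_amplicon_reads(cfg)
        calls = [align_and_classify(seq, reference, rid) for rid, seq in reads]
        assert len(calls) == 5000
        tally = tally_variants(calls)
        assert tally.frequencies["deletion"] == pytest.approx(0.1, abs=0.01)
        assert tally.retained["deletion"]

    def test_zero_classified_rejected(self):
        with pytest.raises(ValueError):
            tally_variants(self._calls({("unclassifiable", None): 5}))
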