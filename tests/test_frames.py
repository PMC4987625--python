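"""Insert extraction, mapping and natural-frame classification."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement
from hypothesis import given
from hypothesis import strategies as st

from phagemap import (InsertRead, classify_library, extract_insert,
                      fragment_length_stats, map_insert, merge_pairs)
from phagemap.frames import (EMPTY, NATURAL, NON_NATURAL, UNMAPPED,
                             EmptySetError, MappedFragment)
from phagemap.antigen import FUSION, ResidueSpan
from phagemap.simulate import DEFAULT_FLANK_LEFT as FL
from phagemap.simulate import DEFAULT_FLANK_RIGHT as FR

FLANKS = (FL, FR)


def _brute_force_hamming(seq, pattern, max_mismatch):
    """Independent sliding-window oracle for flank location."""
    best = None
    for i in range(len(seq) - len(pattern) + 1):
        mm = sum(a != b for a, b in zip(seq[i:i + len(pattern)], pattern))
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (i, mm)
    return best


class TestExtractInsert:
    def test_exact_flanks(self):
        read = FL + "ATGGCC" + FR
        assert extract_insert(read, FLANKS).insert_seq == "ATGGCC"

    def test_adjacent_flanks_give_empty_insert(self):
        assert extract_insert(FL + FR, FLANKS).insert_seq == ""

    def test_missing_flank_returns_none(self):
        assert extract_insert("ACGT" * 30, FLANKS, max_mismatch=2) is None

    @given(st.data())
    def test_mismatched_flank_matches_brute_force_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        insert = "".join(rng.choice(list("ACGT"), size=30))
        flank_l = list(FL)
        n_err = data.draw(st.integers(0, 2))
        for p in rng.choice(len(flank_l), size=n_err, replace=False):
            flank_l[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[flank_l[p]]
        read = "".join(flank_l) + insert + FR
        oracle = _brute_force_hamming(read, FL, 2)
        got = extract_insert(read, FLANKS, max_mismatch=2)
        assert (got is not None) == (oracle is not None)
        if got is not None:
            assert got.insert_seq == read[oracle[0] + len(FL):len(read) - len(FR)]


class TestMapInsert:
    def test_in_frame_substring_is_natural(self, ref):
        insert = ref.cds[99:249]  # start 100 -> frame5 0; length 150 -> mod3 0
        mf = map_insert(InsertRead("r", insert), ref)
        assert mf.frame_class == NATURAL
        assert mf.span_nt == (100, 249)
        assert mf.frame5 == 0 and mf.len_mod3 == 0
        # residues fully encoded: smallest r with 3r-2 >= 100 is 34; 249/3 = 83
        assert (mf.span_res.start_res, mf.span_res.end_res) == (34, 83)

    def test_reverse_complement_is_non_natural(self, ref):
        insert = reverse_complement(ref.cds[99:249])
        mf = map_insert(InsertRead("r", insert), ref)
        assert mf.frame_class == NON_NATURAL
        assert mf.orientation == "reverse"

    def test_eighteen_configurations_exactly_one_natural(self, ref):
        """Of the 18 orientation x frame5 x len_mod3 variants, one displays."""
        s, ln = 100, 150
        classes = []
        for d_start in range(3):
            for d_len in range(3):
                for rc in (False, True):
                    frag = ref.cds[s - 1 + d_start:s - 1 + d_start + ln - d_len]
                    insert = reverse_complement(frag) if rc else frag
                    classes.append(map_insert(InsertRead("r", insert), ref).frame_class)
        assert len(classes) == 18
        assert classes.count(NATURAL) == 1

    def test_internal_stop_in_displayed_frame_is_non_natural(self, ref):
        insert = list(ref.cds[99:249])
        # force a TAA codon at an in-frame position
        insert[30:33] = "TAA"
        mf = map_insert(InsertRead("r", "".join(insert)), ref,
                        max_mismatch_frac=0.05)
        assert mf.frame_class == NON_NATURAL

    def test_mismatches_within_tolerance_still_map(self, ref):
        insert = list(ref.cds[299:499])  # 200 nt, 2% tolerance -> 4 edits
        for p in (10, 90, 150):
            insert[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[insert[p]]
        mf = map_insert(InsertRead("r", "".join(insert)), ref)
        assert mf.frame_class != UNMAPPED
        assert mf.span_nt[0] == 300

    def test_foreign_sequence_is_unmapped(self, ref):
        mf = map_insert(InsertRead("r", "ACGT" * 40), ref)
        assert mf.frame_class == UNMAPPED

    def test_empty_insert_is_empty_class(self, ref):
        assert map_insert(InsertRead("r", ""), ref).frame_class == EMPTY


class TestClassifyLibrary:
    def test_empty_stream(self, ref):
        frags, summary = classify_library([], ref)
        assert frags == []
        assert summary.n_total == 0
        assert summary.fraction_natural is None

    def test_only_empty_clones_fraction_undefined(self, ref):
        reads = [(f"r{i}", FL + FR) for i in range(5)]
        _, summary = classify_library(reads, ref, vector_flanks=FLANKS)
        assert summary.n_empty == 5
        assert summary.fraction_natural is None

    def test_summary_is_permutation_invariant(self, ref):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(60):
            s = int(rng.integers(1, 1000))
            ln = int(rng.integers(30, 200))
            reads.append((f"r{i}", FL + ref.cds[s - 1:s - 1 + ln] + FR))
        _, fwd = classify_library(reads, ref, vector_flanks=FLANKS)
        rng.shuffle(reads)
        _, shuf = classify_library(reads, ref, vector_flanks=FLANKS)
        assert fwd.to_dict() == shuf.to_dict()


class TestFragmentLengthStats:
    @staticmethod
    def _frag(length_aa):
        return MappedFragment(read_id="x", frame_class=NATURAL,
                              span_res=ResidueSpan(1, length_aa, FUSION))

    def test_basic_stats_use_sample_sd(self):
        mean, median, sd = fragment_length_stats(
            [self._frag(n) for n in (10, 20, 30)])
        assert (mean, median, sd) == (20.0, 20.0, 10.0)

    def test_single_fragment(self):
        mean, median, sd = fragment_length_stats([self._frag(49)])
        assert (mean, median, sd) == (49.0, 49.0, 0.0)

    def test_empty_set_raises(self):
        with pytest.raises(EmptySetError):
            fragment_length_stats([])
        with pytest.raises(EmptySetError):
            fragment_length_stats(
                [MappedFragment(read_id="x", frame_class=NON_NATURAL)])


def test_merge_pairs_overlap(ref):
    frag = ref.cds[0:180]
    r1, r2 = frag[:120], reverse_complement(frag[60:])
    assert merge_pairs(r1, r2) == frag


def test_merge_pairs_fallback_to_read1():
    r1 = "ACGTACGTACGTACGTACGTACGTA"
    r2 = "GGGGGGGGGGGGGGGGGGGGGGGGG"
    assert merge_pairs(r1, r2) == r1
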