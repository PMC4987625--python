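"""Occurrence profiles, enrichment factors and the mean + 5 SD rule."""

import numpy as np
import pytest

from phagemap import (LibraryCounts, call_significant, enrichment_factor,
                      rank_fragments, residue_occurrence)
from phagemap.antigen import FUSION, ResidueSpan
from phagemap.enrichment import significance_threshold


def span(a, b):
    return ResidueSpan(a, b, FUSION)


def lib(counts, library_id="selected"):
    return LibraryCounts(library_id=library_id, fragment_counts=counts,
                         total_natural_reads=sum(counts.values()))


class TestResidueOccurrence:
    def test_single_fragment_full_occurrence(self, ref):
        occ = residue_occurrence(lib({span(1, 5): 4}), ref)
        assert np.all(occ[:5] == 1.0)
        assert np.all(occ[5:] == 0.0)

    def test_two_disjoint_fragments_split(self, ref):
        occ = residue_occurrence(lib({span(1, 5): 3, span(10, 12): 3}), ref)
        assert np.all(occ[:5] == 0.5)
        assert np.all(occ[9:12] == 0.5)
        assert occ[7] == 0.0

    def test_matches_brute_force_tally(self, ref):
        rng = np.random.default_rng(1)
        counts = {}
        for _ in range(20):
            a = int(rng.integers(1, ref.n_residues - 30))
            counts[span(a, a + int(rng.integers(5, 30)))] = int(rng.integers(1, 9))
        library = lib(counts)
        occ = residue_occurrence(library, ref)
        brute = np.zeros(ref.n_residues)
        for sp, c in counts.items():
            for r in range(sp.start_res, sp.end_res + 1):
                brute[r - 1] += c
        np.testing.assert_allclose(occ, brute / library.total_natural_reads)

    def test_zero_reads_rejected(self, ref):
        empty = LibraryCounts("u", {}, 0)
        with pytest.raises(ValueError, match="zero natural-frame reads"):
            residue_occurrence(empty, ref)


class TestCountConservation:
    def test_sum_of_counts_must_match_total(self):
        with pytest.raises(ValueError, match="conservation"):
            LibraryCounts("u", {span(1, 5): 3}, 5)

    def test_ranking_preserves_counts(self, ref):
        counts = {span(1, 10): 50, span(5, 20): 30, span(8, 9): 20}
        library = lib(counts)
        calls = rank_fragments(library, top_n=100)
        assert sum(c.frequency_selected for c in calls) * \
            library.total_natural_reads == pytest.approx(100)


class TestEnrichmentFactor:
    def test_pseudocount_arithmetic(self, ref):
        # residue tallies: sel 20 vs unsel 4 on residues 1-5, equal depth 30
        sel = lib({span(1, 5): 20, span(10, 12): 10})
        unsel = lib({span(1, 5): 4, span(10, 12): 26}, "unselected")
        prof = enrichment_factor(sel, unsel, ref, pseudocount=1.0)
        assert np.allclose(prof.enrichment_factor[:5], 21.0 / 5.0)

    def test_identical_libraries_flat_profile(self, ref):
        counts = {span(1, 5): 6, span(100, 150): 3}
        prof = enrichment_factor(lib(counts), lib(counts, "unselected"), ref)
        np.testing.assert_allclose(prof.enrichment_factor, 1.0)

    def test_matches_hand_computation(self, ref):
        sel = lib({span(1, 4): 2, span(3, 8): 5, span(7, 9): 1})
        unsel = lib({span(1, 4): 3, span(5, 10): 3}, "unselected")
        prof = enrichment_factor(sel, unsel, ref, pseudocount=1.0)
        # residue 3: sel covered by (1,4)+(3,8) = 7; unsel by (1,4) = 3
        assert prof.enrichment_factor[2] == pytest.approx(
            ((7 + 1) / 8) / ((3 + 1) / 6))
        # residue 20 covered by nothing: defined baseline Nunsel/Nsel
        assert prof.enrichment_factor[19] == pytest.approx(6 / 8)

    def test_scale_invariance_in_zero_pseudocount_limit(self, ref):
        sel = lib({span(1, 438): 4, span(10, 30): 2})
        unsel = lib({span(1, 438): 5}, "unselected")
        a = enrichment_factor(sel, unsel, ref, pseudocount=0.0)
        sel7 = lib({k: 7 * v for k, v in sel.fragment_counts.items()})
        unsel7 = lib({k: 7 * v for k, v in unsel.fragment_counts.items()},
                     "unselected")
        b = enrichment_factor(sel7, unsel7, ref, pseudocount=0.0)
        np.testing.assert_allclose(a.enrichment_factor, b.enrichment_factor)

    def test_raw_count_mode(self, ref):
        sel = lib({span(1, 5): 20, span(10, 12): 10})
        unsel = lib({span(1, 5): 4, span(10, 12): 6}, "unselected")
        prof = enrichment_factor(sel, unsel, ref, depth_normalize=False)
        assert prof.enrichment_factor[0] == pytest.approx(21.0 / 5.0)


class TestRankFragments:
    def test_frequency_ordering(self):
        calls = rank_fragments(lib({span(1, 5): 50, span(10, 20): 30,
                                    span(30, 31): 20}), top_n=3)
        assert [c.frequency_selected for c in calls] == [0.5, 0.3, 0.2]

    def test_tie_break_longer_then_leftmost(self):
        calls = rank_fragments(lib({span(5, 6): 1, span(1, 10): 1,
                                    span(2, 11): 1}), top_n=3)
        assert [(c.span.start_res, c.span.end_res) for c in calls] == \
            [(1, 10), (2, 11), (5, 6)]

    def test_top_n_larger_than_library_returns_all(self):
        calls = rank_fragments(lib({span(1, 5): 2}), top_n=30)
        assert len(calls) == 1


class TestCallSignificant:
    def test_zero_sd_threshold(self):
        unsel = lib({span(i, i + 5): 1 for i in range(1, 101)}, "unselected")
        sel = lib({span(1, 6): 2, span(10, 15): 98})
        calls = call_significant(sel, unsel)
        flagged = {(c.span.start_res, c.span.end_res)
                   for c in calls if c.significant}
        # every unselected frequency is 0.01 (sd 0): anything above is called
        assert flagged == {(1, 6), (10, 15)}

    def test_identical_library_not_significant(self):
        counts = {span(i, i + 10): c for i, c in
                  zip(range(1, 40, 4), (3, 5, 2, 4, 6, 3, 2, 5, 4, 3))}
        calls = call_significant(lib(counts), lib(counts, "unselected"))
        assert not any(c.significant for c in calls)

    def test_requires_two_unique_fragments(self):
        with pytest.raises(ValueError, match="unique fragments"):
            significance_threshold(lib({span(1, 5): 4}, "unselected"))

    def test_null_resample_median_zero_calls(self, ref):
        """A plain resample of the unselected pool triggers no calls (median)."""
        from phagemap.simulate import SimConfig, resample_library, simulate_library
        n_sig = []
        for seed in range(10):
            cfg = SimConfig(ref=ref, n_clones=300, empty_fraction=0.0,
                            reads_per_round=3000, seq_error_rate=0.0, seed=seed)
            _, truth = simulate_library(cfg)
            spans = [c.span_res for c in truth.clones]
            _, cu = resample_library(truth, cfg, 3000, stream=2)
            _, cs = resample_library(truth, cfg, 3000, stream=3)
            unsel = LibraryCounts.from_spans(spans, cu, "unselected")
            sel = LibraryCounts.from_spans(spans, cs, "selected")
            n_sig.append(sum(1 for c in call_significant(sel, unsel)
                             if c.significant))
        assert np.median(n_sig) == 0
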