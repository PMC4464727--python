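"""Profile construction, the split DP, and the one-/two-split pipelines."""

import numpy as np
import pytest

from splitalign.core import score_alignment
from splitalign.split_align import (
    ProfileError,
    build_profiles,
    one_split,
    split,
    two_split,
)
from splitalign.synthetic import enumerate_fragment_sets

from conftest import make_alignment, random_candidate


def min_internal_segment(values):
    """Most negative contiguous run (minimum-subarray scan)."""
    worst = run = 0.0
    for v in values:
        run = min(0.0, run + v)
        worst = min(worst, run)
    return worst


class TestBuildProfiles:
    def test_gapless_candidate_has_column_scores_and_zero_d(self, toy_scheme):
        prof = build_profiles([make_alignment("ACGT", "ACGA")], toy_scheme, 1.0)
        cand = prof.candidates[0]
        assert cand.A.tolist() == [2, 2, 2, -3]
        assert cand.D.tolist() == [0, 0, 0, 0]

    def test_fig10_style_deletion_cost(self, fig10_scheme):
        # gap cost 2 + 1 per letter: a length-1 deletion contributes -3 to D
        prof = build_profiles([make_alignment("ACG", "A-G")], fig10_scheme, 1.0)
        assert prof.candidates[0].D.tolist() == [0, -3]

    def test_insertion_run_charges_open_on_first_letter(self, fig10_scheme):
        prof = build_profiles([make_alignment("A--T", "ACGT")], fig10_scheme, 1.0)
        assert prof.candidates[0].A.tolist() == [1, -3, -1, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_profile_sums_reproduce_candidate_score(self, seed, toy_scheme):
        rng = np.random.default_rng(seed)
        aln = random_candidate(rng, toy_scheme, qstart=2, span=8)
        prof = build_profiles([aln], toy_scheme, 0.0)
        cand = prof.candidates[0]
        assert cand.A.sum() + cand.D.sum() == score_alignment(aln, toy_scheme)

    def test_mixed_query_names_rejected(self, toy_scheme):
        a = make_alignment("AC", "AC", qname="q1")
        b = make_alignment("AC", "AC", qname="q2")
        with pytest.raises(ProfileError):
            build_profiles([a, b], toy_scheme, 1.0)

    def test_unoriented_candidate_rejected(self, toy_scheme):
        aln = make_alignment("AC", "AC", qstrand="-")
        with pytest.raises(ProfileError):
            build_profiles([aln], toy_scheme, 1.0)


class TestSplit:
    def test_deep_dip_splits_into_two_fragments(self, toy_scheme):
        # column scores [2,2,-3...]: craft 5/-12 style via a wider matrix
        from splitalign.core import ScoreScheme

        scheme = ScoreScheme(
            np.where(np.eye(4, dtype=bool), 5, -12).astype(int), 2, 1
        )
        aln = make_alignment("AACAA", "AAGAA")  # scores [5,5,-12,5,5]
        frags, total = split(build_profiles([aln], scheme, 1.0))
        assert total == 18.0
        assert [(f.query_beg, f.query_end, f.score) for f in frags] == [
            (0, 2, 10),
            (3, 5, 10),
        ]

    def test_weak_candidate_below_f_gives_empty_set(self, fig10_scheme):
        aln = make_alignment("AAAAA", "AAAAA")  # total 5
        frags, total = split(build_profiles([aln], fig10_scheme, 10.0))
        assert frags == []
        assert total == 0.0

    def test_empty_candidate_list(self, toy_scheme):
        frags, total = split(build_profiles([], toy_scheme, 1.0))
        assert frags == [] and total == 0.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_optimum(self, seed, toy_scheme):
        rng = np.random.default_rng(seed)
        cands = [
            random_candidate(
                rng, toy_scheme, qstart=int(rng.integers(0, 10)),
                span=int(rng.integers(2, 10)),
            )
            for _ in range(int(rng.integers(1, 4)))
        ]
        f = float(rng.integers(0, 6))
        prof = build_profiles(cands, toy_scheme, f)
        frags, total = split(prof)
        best, _, _, _ = enumerate_fragment_sets(prof, t=1.0)
        assert total == pytest.approx(best)
        assert sum(fr.score for fr in frags) - f * len(frags) == pytest.approx(
            total
        )
        assert total >= 0.0
        assert (total == 0.0) == (frags == [])

    @pytest.mark.parametrize("seed", range(15))
    def test_no_fragment_contains_segment_below_minus_f(self, seed, toy_scheme):
        rng = np.random.default_rng(100 + seed)
        cands = [
            random_candidate(
                rng, toy_scheme, qstart=int(rng.integers(0, 6)),
                span=int(rng.integers(3, 12)),
            )
            for _ in range(2)
        ]
        f = float(rng.integers(0, 5))
        prof = build_profiles(cands, toy_scheme, f)
        frags, _ = split(prof)
        by_input = {c.input_index: c for c in prof.candidates}
        for fr in frags:
            cand = by_input[fr.source_index]
            lo = fr.query_beg - cand.beg
            hi = fr.query_end - cand.beg
            vals = []
            for jj in range(lo, hi):
                if jj > lo:
                    vals.append(float(cand.D[jj]))
                vals.append(float(cand.A[jj]))
            assert min_internal_segment(vals) >= -f - 1e-9

    def test_breakpoint_between_overlapping_candidates_is_optimal(
        self, toy_scheme
    ):
        # two candidates overlap on the query; the best solution switches
        a = make_alignment("AAAATT", "AAAATT", qstart=0)  # strong on the left
        b = make_alignment("TTCCCC", "AACCCC", qstart=2)  # strong on the right
        prof = build_profiles([a, b], toy_scheme, 1.0)
        frags, total = split(prof)
        best, _, _, _ = enumerate_fragment_sets(prof, t=1.0)
        assert total == pytest.approx(best)
        assert len(frags) == 2
        assert frags[0].query_end <= frags[1].query_beg


class TestOneSplit:
    def test_queries_are_split_independently(self, toy_scheme):
        a = make_alignment("ACGT", "ACGT", qname="q1")
        b = make_alignment("TTTT", "TTTT", qname="q2")
        frags = one_split([a, b], toy_scheme, f=1.0)
        assert sorted(fr.query.name for fr in frags) == ["q1", "q2"]
        solo = one_split([a], toy_scheme, f=1.0)
        assert [fr.score for fr in solo] == [
            fr.score for fr in frags if fr.query.name == "q1"
        ]

    def test_single_strong_candidate_returned_whole(self, toy_scheme):
        aln = make_alignment("ACGTACGT", "ACGTACGT")
        frags = one_split([aln], toy_scheme, f=2.0)
        assert len(frags) == 1
        assert (frags[0].query_beg, frags[0].query_end) == (0, 8)
        assert frags[0].score == 16

    def test_minus_strand_candidate_is_oriented(self, toy_scheme):
        aln = make_alignment("ACGTT", "ACGTT", qstrand="-", qstart=3)
        frags = one_split([aln], toy_scheme, f=1.0)
        assert len(frags) == 1
        assert frags[0].query.strand == "+"
        assert frags[0].ref.strand == "-"


class TestTwoSplit:
    def test_empty_input(self, toy_scheme):
        assert two_split([], toy_scheme, f=1.0) == []

    def test_one_to_one_high_scoring_input_is_fixed_point(self, toy_scheme):
        a = make_alignment("ACGTACGT", "ACGTACGT", qstart=0, rstart=0)
        b = make_alignment("GGGGCCCC", "GGGGCCCC", qstart=20, rstart=20)
        frags = two_split([a, b], toy_scheme, f=2.0)
        assert [(fr.query_beg, fr.query_end, fr.score) for fr in frags] == [
            (0, 8, 16),
            (20, 28, 16),
        ]

    def test_two_query_copies_of_one_reference_segment_leave_one(
        self, toy_scheme
    ):
        # both query segments align the same reference bases; after the
        # swapped pass at most one alignment may keep each reference base
        a = make_alignment("ACGTACGTAC", "ACGTACGTAC", qstart=0, rstart=0)
        b = make_alignment("ACGTACGTAC", "ACGTACGTAC", qstart=50, rstart=0)
        frags = two_split([a, b], toy_scheme, f=1.0)
        riv = sorted((fr.ref.fwd_start, fr.ref.fwd_end) for fr in frags)
        for x, y in zip(riv, riv[1:]):
            assert x[1] <= y[0]
        covered = sum(e - s for s, e in riv)
        assert covered <= 10

    def test_idempotent_on_own_output(self, toy_scheme):
        rng = np.random.default_rng(3)
        cands = [
            random_candidate(rng, toy_scheme, qstart=0, span=8),
            random_candidate(rng, toy_scheme, qstart=4, span=8),
        ]
        once = two_split(cands, toy_scheme, f=1.0)
        again = two_split(
            [fr.to_alignment() for fr in once], toy_scheme, f=1.0
        )
        assert [
            (fr.query.name, fr.query_beg, fr.query_end, fr.score) for fr in once
        ] == [
            (fr.query.name, fr.query_beg, fr.query_end, fr.score) for fr in again
        ]
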