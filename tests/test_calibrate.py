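"""Scale-factor calibration, score/probability conversion, event counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitalign import calibrate as cal
from splitalign.core import PairProbModel, ScoreScheme
from splitalign.synthetic import simulate_pair

from conftest import make_alignment


def uniform_scheme(match=1, mismatch=-1, open_=2, extend=1):
    m = np.where(np.eye(4, dtype=bool), match, mismatch).astype(int)
    return ScoreScheme(m, open_, extend)


class TestComputeScale:
    def test_uniform_matrix_has_closed_form_scale(self):
        # symmetry forces p = q = 1/4 and (e^lam + 3 e^-lam)/4 = 1 => lam = ln 3
        res = cal.compute_scale(uniform_scheme())
        assert res.lam == pytest.approx(math.log(3), rel=1e-12)
        assert res.t == pytest.approx(1 / math.log(3), rel=1e-12)
        assert np.allclose(res.p, 0.25, atol=1e-12)

    def test_residuals_are_tiny(self, hoxd70, human_chimp):
        for scheme in (hoxd70, human_chimp):
            res = cal.compute_scale(scheme)
            assert max(res.residuals()) < 1e-9

    def test_symmetric_matrix_gives_equal_backgrounds(self, hoxd55):
        res = cal.compute_scale(hoxd55)
        assert np.allclose(res.p, res.q, atol=1e-12)

    def test_log_odds_identity_holds_cellwise(self, hoxd70):
        res = cal.compute_scale(hoxd70)
        expect = res.p[:, None] * res.q[None, :] * np.exp(
            res.lam * hoxd70.matrix
        )
        assert np.allclose(res.pi, expect, rtol=1e-12)

    def test_invalid_matrix_rejected(self):
        # all-positive scores: expected score cannot be negative
        scheme = ScoreScheme(np.full((4, 4), 1, dtype=int), 2, 1)
        with pytest.raises(cal.CalibrationError):
            cal.compute_scale(scheme)


class TestScoresToProbs:
    def test_huge_gap_costs_give_zero_gap_probabilities(self):
        scheme = uniform_scheme(open_=10**6, extend=10**6)
        model = cal.scores_to_probs(scheme)
        assert model.alpha == 0.0
        assert model.beta == 0.0

    def test_round_trip_reproduces_integer_matrix(self, hoxd70):
        res = cal.compute_scale(hoxd70)
        model = cal.scores_to_probs(hoxd70, res)
        back = cal.probs_to_scores(model, res.t)
        assert np.array_equal(back.matrix, hoxd70.matrix)
        assert back.gap_open == hoxd70.gap_open
        assert back.gap_extend == hoxd70.gap_extend

    def test_zero_extension_cost_rejected(self):
        scheme = uniform_scheme(extend=0)
        with pytest.raises(cal.ModelError):
            cal.scores_to_probs(scheme)


class TestProbsToScores:
    def test_independent_pairs_give_zero_substitution_scores(self):
        phi = np.full(4, 0.25)
        model = PairProbModel(
            pi=np.outer(phi, phi), phi=phi, psi=phi, alpha=0.01, beta=0.5
        )
        scheme = cal.probs_to_scores(model, t=10.0)
        assert np.array_equal(scheme.matrix, np.zeros((4, 4), dtype=int))


class TestCountEvents:
    def test_hand_counted_substitutions(self):
        aln = make_alignment("ACGT", "ACGA")
        model, counts = cal.count_events([aln])
        assert counts["match_columns"] == 4
        assert counts["pi_counts"][3, 0] == 1  # t in ref aligned to a in query
        assert counts["pi_counts"].trace() == 3
        assert counts["gap_runs"] == 0

    def test_gap_run_counts_existence_once(self):
        aln = make_alignment("ACGGTA", "AC--TA")
        model, counts = cal.count_events([aln])
        assert counts["gap_runs"] == 1
        assert counts["gap_extensions"] == 1
        assert counts["gap_length_hist"] == {2: 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cal.count_events([])

    def test_parameter_recovery_from_simulation(self, hoxd70):
        # HoxD70's implied model has frequent gaps, so 30 kb pins down
        # pi, alpha, and beta well
        model = cal.scores_to_probs(hoxd70)
        _, _, truth = simulate_pair(model, 30_000, seed=5)
        est, counts = cal.count_events([truth])
        n = counts["pi_counts"].sum()
        se = math.sqrt(model.pi[0, 0] * (1 - model.pi[0, 0]) / n)
        assert abs(est.pi[0, 0] - model.pi[0, 0]) < 3 * se
        trials = counts["gap_runs"] + counts["gap_extensions"]
        se_beta = math.sqrt(model.beta * (1 - model.beta) / trials)
        assert abs(est.beta - model.beta) < 3 * se_beta + 0.05


class TestWindowIdentity:
    def test_perfect_alignment_gives_zero_rates(self):
        aln = make_alignment("A" * 400, "A" * 400)
        rates = cal.window_identity([aln], window=200)
        assert rates.tolist() == [0.0, 0.0]

    def test_alternating_mismatches_give_half(self):
        rtext = "AC" * 100
        qtext = "AA" * 100
        rates = cal.window_identity([make_alignment(rtext, qtext)], window=200)
        assert rates.tolist() == [0.5]

    def test_short_final_window_dropped_and_gaps_deleted(self):
        aln = make_alignment("AAAA-CCC", "AAAAGCCC")
        rates = cal.window_identity([aln], window=5)
        assert len(rates) == 1  # 7 substitution columns -> one window of 5

    def test_uniform_rate_matches_binomial(self):
        rng = np.random.default_rng(42)
        r = 0.1
        window = 50
        alns = []
        for _ in range(60):
            rt = "".join("ACGT"[k] for k in rng.integers(0, 4, 500))
            qt = "".join(
                "ACGT"[("ACGT".index(a) + 1) % 4] if rng.random() < r else a
                for a in rt
            )
            alns.append(make_alignment(rt, qt))
        rates = cal.window_identity(alns, window=window)
        counts = np.round(rates * window).astype(int)
        from scipy import stats

        edges = [-0.5, 1.5, 3.5, 5.5, 7.5, window + 0.5]
        obs, _ = np.histogram(counts, bins=edges)
        cdf = stats.binom.cdf(np.array(edges), window, r)
        expected = np.diff(cdf) * len(counts)
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=len(obs) - 1)


class TestSegmentSet:
    def test_all_negative_scores_give_empty_set(self):
        segs, total = cal.segment_set([-1, -2, -3], f=1.0)
        assert segs == [] and total == 0.0

    def test_dip_of_exactly_f_is_bridged(self):
        segs, total = cal.segment_set([3, 3, -1, 3], f=1.0)
        assert segs == [(0, 4)]
        assert total == 7.0

    def test_deep_dip_splits(self):
        segs, total = cal.segment_set([3, -5, 3], f=1.0)
        assert segs == [(0, 1), (2, 3)]
        assert total == 4.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        scores = rng.integers(-6, 7, size=n).astype(float)
        f = float(rng.integers(0, 4))
        segs, total = cal.segment_set(scores, f)

        best = 0.0

        def rec(j, acc):
            nonlocal best
            best = max(best, acc)
            for k in range(j, n):
                for e in range(k + 1, n + 1):
                    rec(e, acc + scores[k:e].sum() - f)

        rec(0, 0.0)
        assert total == pytest.approx(best)
        self._check_no_deep_internal_dip(scores, segs, f)

    @staticmethod
    def _check_no_deep_internal_dip(scores, segs, f):
        # no returned segment contains an internal run scoring < -f
        for beg, end in segs:
            run = best_drop = 0.0
            for v in scores[beg:end]:
                run = min(0.0, run + v)
                best_drop = min(best_drop, run)
            assert best_drop >= -f - 1e-9

    @settings(derandomize=True, max_examples=80)
    @given(
        st.lists(st.integers(min_value=-6, max_value=6), max_size=10),
        st.integers(min_value=0, max_value=4),
    )
    def test_total_dominates_best_single_segment(self, scores, f):
        vals = [float(s) for s in scores]
        segs, total = cal.segment_set(vals, float(f))
        n = len(vals)
        best_single = max(
            (sum(vals[i:j]) - f for i in range(n) for j in range(i + 1, n + 1)),
            default=0.0,
        )
        assert total >= max(best_single, 0.0) - 1e-9
        assert total >= 0.0
        self._check_no_deep_internal_dip(vals, segs, f)
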