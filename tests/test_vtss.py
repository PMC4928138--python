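"""Clustering-score profiles, peak finding and promoter selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_profile_score, make_collection
from promkit.vtss import (
    CLASS_BEST,
    CLASS_SECONDARY,
    CLASS_SINGLE,
    Candidate,
    call_vtss,
    clustering_profile,
    cosine_weight,
    find_peaks,
    select_promoters,
)


class TestCosineWeight:
    def test_center_weight_is_one(self):
        assert cosine_weight(0, 3000) == 1.0

    def test_edge_weight_is_zero(self):
        assert cosine_weight(1500, 3000) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_window(self):
        assert cosine_weight(750, 3000) == pytest.approx(math.cos(math.pi / 4))

    def test_outside_window_is_zero_by_contract(self):
        assert cosine_weight(1501, 3000) == 0.0

    @given(st.integers(-1500, 1500))
    @settings(deadline=None)
    def test_symmetric_and_bounded(self, d):
        w = cosine_weight(d, 3000)
        assert w == cosine_weight(-d, 3000)
        assert 0.0 <= w <= 1.0

    def test_strictly_decreasing_in_distance(self):
        weights = [cosine_weight(d, 3000) for d in range(0, 1501, 50)]
        assert all(a > b for a, b in zip(weights, weights[1:]))


class TestClusteringProfile:
    def test_single_tss_peaks_at_itself_with_its_score(self):
        profile = clustering_profile(make_collection([10_000]))
        assert profile.score_at(10_000) == pytest.approx(5.0)
        assert np.max(profile.scores) == pytest.approx(5.0)

    def test_two_stacked_tss_double_the_score(self):
        profile = clustering_profile(make_collection([10_000, 10_000]))
        assert profile.score_at(10_000) == pytest.approx(10.0)

    def test_two_tss_750_apart(self):
        profile = clustering_profile(make_collection([10_000, 10_750]))
        expected = 5 + 5 * math.cos(math.pi * 750 / 3000)
        assert profile.score_at(10_000) == pytest.approx(expected)
        assert expected == pytest.approx(8.5355, abs=1e-4)

    def test_score_zero_outside_reach(self):
        profile = clustering_profile(make_collection([10_000]))
        assert profile.score_at(10_000 + 1501) == 0.0
        assert profile.score_at(1) == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="no TSS evidence"):
            clustering_profile(make_collection([]))

    def test_matches_brute_force_oracle_everywhere(self, rng):
        """Vectorised profile equals the independent per-position sum."""
        for _ in range(20):
            n = int(rng.integers(1, 50))
            span = int(rng.integers(1, 30_000))
            positions = sorted(rng.integers(100_000, 100_000 + span + 1, size=n))
            scores = rng.choice([5.0, 5.0, 5.0, 2.5], size=n)
            profile = clustering_profile(make_collection(positions, scores=scores))
            centers = np.arange(profile.start, profile.end + 1)
            stride = max(1, len(centers) // 200)
            oracle = np.array(
                [
                    brute_force_profile_score(positions, scores, c)
                    for c in centers[::stride]
                ]
            )
            np.testing.assert_allclose(profile.scores[::stride], oracle, atol=1e-9)

    def test_translation_invariance(self, rng):
        positions = [10_000, 10_400, 12_000]
        k = 7919
        a = clustering_profile(make_collection(positions))
        b = clustering_profile(make_collection([p + k for p in positions]))
        assert b.start == a.start + k
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)


class TestFindPeaks:
    def test_single_tss_single_candidate(self):
        profile = clustering_profile(make_collection([10_000]))
        peaks = find_peaks(profile)
        assert len(peaks) == 1
        assert peaks[0].position == 10_000
        assert peaks[0].clustering_score == pytest.approx(5.0)

    def test_distant_tss_give_separate_candidates(self):
        profile = clustering_profile(make_collection([10_000, 20_000]))
        peaks = find_peaks(profile)
        assert sorted(p.position for p in peaks) == [10_000, 20_000]
        assert all(p.clustering_score == pytest.approx(5.0) for p in peaks)

    def test_close_tss_merge_into_one_candidate(self):
        profile = clustering_profile(make_collection([10_000, 10_200]))
        peaks = find_peaks(profile)
        assert len(peaks) == 1
        assert 10_000 <= peaks[0].position <= 10_200

    def test_plateau_reports_five_prime_most_position(self):
        # two equal-score TSSs produce a symmetric profile whose plateau
        # (if any) and equal peaks resolve 5'-most
        plus = find_peaks(clustering_profile(make_collection([10_000, 10_001])))
        assert len(plus) == 1 and plus[0].position == 10_000
        minus = find_peaks(
            clustering_profile(make_collection([10_000, 10_001], strand="-"))
        )
        assert len(minus) == 1 and minus[0].position == 10_001

    def test_candidates_sorted_by_descending_score(self):
        coll = make_collection([10_000, 10_000, 30_000])
        peaks = find_peaks(clustering_profile(coll))
        scores = [p.clustering_score for p in peaks]
        assert scores == sorted(scores, reverse=True)


class TestSelectPromoters:
    def test_shared_denominator_percent_rule(self):
        """Percent uses all candidate peaks, so 95/205.2 and 25/205.2."""
        weak = [Candidate(60_000 + i * 4000, 14.2) for i in range(6)]
        cands = [Candidate(38_468_271, 95.0), Candidate(38_457_480, 25.0)] + weak
        out = select_promoters(cands, "FGFR1", "8", "+")
        best = next(v for v in out if v.promoter_class == CLASS_BEST)
        secondary = [v for v in out if v.promoter_class == CLASS_SECONDARY]
        assert round(best.percent, 1) == 46.3
        assert best.position == 38_468_271
        assert len(secondary) == 1
        assert round(secondary[0].percent, 1) == 12.2

    def test_sub_threshold_candidates_dropped(self):
        cands = [Candidate(100, 100.0), Candidate(5000, 50.0), Candidate(9000, 7.0)]
        out = select_promoters(cands, "g", "chr1", "+")
        assert [round(v.percent, 1) for v in out] == [63.7, 31.8]
        assert [v.promoter_class for v in out] == [CLASS_BEST, CLASS_SECONDARY]

    def test_low_cumulative_score_keeps_only_five_prime_candidate(self):
        cands = [Candidate(5000, 5.0), Candidate(1000, 5.0)]
        out = select_promoters(cands, "g", "chr1", "+", min_cumulative_score=15.0)
        assert len(out) == 1
        assert out[0].position == 1000
        assert out[0].promoter_class == CLASS_SINGLE

    def test_equal_peaks_tie_break_five_prime(self):
        cands = [Candidate(5000, 50.0), Candidate(1000, 50.0)]
        out = select_promoters(cands, "g", "chr1", "+", min_cumulative_score=15.0)
        best = next(v for v in out if v.promoter_class == CLASS_BEST)
        assert best.position == 1000
        # mirrored on the minus strand
        out_m = select_promoters(cands, "g", "chr1", "-", min_cumulative_score=15.0)
        best_m = next(v for v in out_m if v.promoter_class == CLASS_BEST)
        assert best_m.position == 5000

    def test_single_survivor_classified_single(self):
        cands = [Candidate(1000, 100.0), Candidate(5000, 5.0)]
        out = select_promoters(cands, "g", "chr1", "+")
        assert len(out) == 1 and out[0].promoter_class == CLASS_SINGLE

    def test_percents_sum_to_100_before_thresholding(self, rng):
        for _ in range(50):
            n = rng.integers(1, 12)
            cands = [
                Candidate(int(p), float(s))
                for p, s in zip(
                    rng.integers(0, 10**6, size=n), rng.uniform(0.1, 100, size=n)
                )
            ]
            total = sum(
                100.0 * c.clustering_score / sum(x.clustering_score for x in cands)
                for c in cands
            )
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_promoters([Candidate(1, 10.0)], "g", "c", "+", percent_threshold=0)


class TestCallVtss:
    def test_translation_invariance_end_to_end(self):
        positions = [10_000] * 4 + [14_000] * 2
        k = 12_345
        a = call_vtss(make_collection(positions))
        b = call_vtss(make_collection([p + k for p in positions]))
        assert [(v.position + k, v.promoter_class, round(v.percent, 6)) for v in a] == [
            (v.position, v.promoter_class, round(v.percent, 6)) for v in b
        ]

    def test_monotonicity_adding_evidence_at_candidate(self):
        """Stacking another evidence point on a peak never lowers its score."""
        base = call_vtss(make_collection([10_000] * 4 + [20_000] * 4))
        more = call_vtss(make_collection([10_000] * 5 + [20_000] * 4))
        pos_score = {v.position: v.clustering_score for v in base}
        pos_score2 = {v.position: v.clustering_score for v in more}
        assert pos_score2[10_000] >= pos_score[10_000]
        assert pos_score2[20_000] == pytest.approx(pos_score[20_000])

    def test_strand_mirror_full_pipeline(self):
        pivot = 1_000_000
        positions = [10_000] * 3 + [10_150] * 2 + [40_000] * 5
        a = call_vtss(make_collection(positions, strand="+"))
        b = call_vtss(
            make_collection([pivot - p for p in positions], strand="-")
        )
        assert sorted(pivot - v.position for v in b) == sorted(v.position for v in a)
        assert {v.promoter_class for v in a} == {v.promoter_class for v in b}
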