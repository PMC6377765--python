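import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaidoh import scoring
from plaidoh.types import ScoreCutoffs


class TestTranscriptCisScore:
    def test_hand_evaluations(self):
        # 10 * |-log10(0.009+0.001)| * ((5+0.1)*(0.5+0.01)) = 10*2*2.601
        assert scoring.transcript_cis_score(0.009, 5, 0.5) == pytest.approx(52.02)
        # 10 * 1 * (0.1 * 0.01)
        assert scoring.transcript_cis_score(0.099, 0, 0) == pytest.approx(0.01)

    def test_zero_at_adj_p_0999(self):
        assert scoring.transcript_cis_score(0.999, 7.0, 0.9) == pytest.approx(0.0)

    def test_missing_inputs_floor_at_offsets(self):
        got = scoring.transcript_cis_score(0.009, None, None)
        assert got == pytest.approx(10 * 2 * 0.1 * 0.01)

    def test_undefined_adj_p_gives_none(self):
        assert scoring.transcript_cis_score(None, 1, 1) is None
        assert scoring.transcript_cis_score(float("nan"), 1, 1) is None

    def test_out_of_range_adj_p_raises(self):
        with pytest.raises(ValueError):
            scoring.transcript_cis_score(1.2, 0, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.0, 0.998), st.floats(0, 50), st.floats(0, 1),
        st.floats(0, 50), st.floats(0, 1),
    )
    def test_monotone_in_h3k4me3_and_fraction(self, adj_p, h, f, dh, df):
        base = scoring.transcript_cis_score(adj_p, h, f)
        assert scoring.transcript_cis_score(adj_p, h + dh, f) >= base - 1e-12
        assert scoring.transcript_cis_score(adj_p, h, min(f + df, 1.0)) >= base - 1e-12


class TestEnhancerScore:
    def test_hand_evaluations(self):
        assert scoring.enhancer_score(0, 0, 0) == pytest.approx(2.0)
        assert scoring.enhancer_score(2, 3, 50) == pytest.approx(10.5)
        assert scoring.enhancer_score(0, 0, 100) == pytest.approx(4.0)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            scoring.enhancer_score(-1, 0, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 100), st.floats(0, 100), st.floats(0, 1000),
        st.floats(0, 10), st.floats(0, 10), st.floats(0, 10),
    )
    def test_floor_and_monotonicity(self, a, b, c, da, db, dc):
        base = scoring.enhancer_score(a, b, c)
        assert base >= 2.0
        assert scoring.enhancer_score(a + da, b, c) >= base
        assert scoring.enhancer_score(a, b + db, c) >= base
        assert scoring.enhancer_score(a, b, c + dc) >= base


class TestRankScores:
    def test_missing_values_get_lowest_ranks(self):
        ranks = scoring.rank_scores([5.0, None, 3.0], seed=0)
        assert list(ranks) == [3, 1, 2]

    def test_distinct_values_rank_by_sort_order(self):
        vals = [10.0, 2.0, 7.0, 4.0]
        assert list(scoring.rank_scores(vals, seed=1)) == [4, 1, 3, 2]

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(2)
        vals = list(rng.integers(0, 5, 50).astype(float)) + [None] * 5
        ranks = scoring.rank_scores(vals, seed=3)
        assert sorted(ranks) == list(range(1, 56))

    def test_tie_break_deterministic_under_seed(self):
        vals = [1.0, 1.0, 1.0, 2.0]
        r1 = scoring.rank_scores(vals, seed=9)
        r2 = scoring.rank_scores(vals, seed=9)
        assert list(r1) == list(r2)


def cutoff_bruteforce(scores):
    """Independent oracle: full residual scan for the upper below-to-above
    crossing of the sorted curve vs its own least-squares line; the cutoff
    is the last below-line score there."""
    vals = sorted(s for s in scores if s is not None and math.isfinite(s))
    n = len(vals)
    if n < 3:
        return None
    xbar = (n + 1) / 2
    ybar = sum(vals) / n
    sxy = sum((i + 1 - xbar) * (v - ybar) for i, v in enumerate(vals))
    sxx = sum((i + 1 - xbar) ** 2 for i in range(n))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    tol = 1e-9 * max(1.0, max(abs(v) for v in vals))
    resid = [(v, v - (slope * (i + 1) + intercept)) for i, v in enumerate(vals)]
    resid = [(v, r) for v, r in resid if abs(r) > tol]
    best = None
    for (v0, r0), (v1, r1) in zip(resid, resid[1:]):
        if r0 < 0 and r1 > 0:
            best = v0
    return best if best is not None else vals[-1]


class TestInflectionCutoff:
    def test_quadratic_curve_matches_bruteforce(self):
        scores = [float(r * r) for r in range(1, 101)]
        assert scoring.inflection_cutoff(scores) == cutoff_bruteforce(scores)

    def test_linear_curve_degenerates_to_max(self):
        scores = [2.0 * r + 1 for r in range(1, 50)]
        assert scoring.inflection_cutoff(scores) == max(scores)

    def test_flat_tail_convex_fixture_isolates_high_scores(self):
        scores = [2.0] * 90 + [20.0, 25.0, 30.0, 40.0, 55.0]
        cut = scoring.inflection_cutoff(scores)
        assert cut == cutoff_bruteforce(scores)
        above = [s for s in scores if s > cut]
        assert above and max(above) == 55.0 and all(s >= 20 for s in above)

    def test_fewer_than_three_finite_undefined(self):
        assert scoring.inflection_cutoff([1.0, 2.0]) is None
        assert scoring.inflection_cutoff([1.0, None, float("nan")]) is None

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 200))
    def test_matches_bruteforce_on_random_curves(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = list(np.cumsum(rng.exponential(1.0, n)) ** rng.uniform(0.5, 3))
        got = scoring.inflection_cutoff(scores)
        assert got == pytest.approx(cutoff_bruteforce(scores))

    def test_cutoff_within_score_range(self):
        rng = np.random.default_rng(4)
        scores = list(rng.random(100) * 50)
        cut = scoring.inflection_cutoff(scores)
        assert min(scores) <= cut <= max(scores)


class TestScaleTo100:
    def test_arithmetic(self):
        assert scoring.scale_to_100([1, 2, 4]) == pytest.approx([25, 50, 100])

    def test_single_value(self):
        assert scoring.scale_to_100([7.0]) == pytest.approx([100.0])

    def test_all_zero_stays_zero(self):
        assert scoring.scale_to_100([0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_max_is_exactly_100(self):
        rng = np.random.default_rng(6)
        scaled = scoring.scale_to_100(list(rng.random(100) * 7))
        assert np.max(scaled) == 100.0


class TestQuadrants:
    CUTS = ScoreCutoffs(enhancer_cutoff=10.0, transcript_cutoff=5.0)

    @pytest.mark.parametrize(
        "enh,cis,expected",
        [
            (3.0, 2.0, "Q1"),
            (15.0, 2.0, "Q2"),
            (15.0, 8.0, "Q3"),
            (3.0, 8.0, "Q4"),
            (10.0, 5.0, "Q1"),  # exactly at cutoff counts as low
        ],
    )
    def test_assignment(self, enh, cis, expected):
        assert scoring.assign_quadrant(enh, cis, self.CUTS) == expected

    def test_missing_score_unassigned(self):
        assert scoring.assign_quadrant(None, 1.0, self.CUTS) is None
        assert scoring.assign_quadrant(1.0, 1.0, ScoreCutoffs(None, None)) is None

    def test_partition_completeness(self):
        rng = np.random.default_rng(7)
        quads = [
            scoring.assign_quadrant(e, c, self.CUTS)
            for e, c in zip(rng.random(500) * 20, rng.random(500) * 10)
        ]
        assert None not in quads
        assert sum(quads.count(q) for q in ("Q1", "Q2", "Q3", "Q4")) == 500
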