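from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sensorprune import (
    DegenerateSeriesError,
    SelectionResult,
    cluster_centroid,
    n_combinations,
    pcc,
    select_k,
)

from .conftest import make_frame


class TestPcc:
    def test_exact_positive_linear(self):
        assert pcc([1, 2, 3], [2, 4, 6]) == 1.0

    def test_exact_negative_linear(self):
        assert pcc([1, 2, 3], [3, 2, 1]) == -1.0

    def test_derived_four_point_case(self):
        # Hand evaluation: covariance sum 4, both sums of squares 5 -> 4/5.
        assert pcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-15)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateSeriesError):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateSeriesError):
            pcc([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pcc([1, 2], [1, 2, 3])

    @given(
        st.lists(
            # pressure-scale magnitudes; tiny values underflow the centered
            # sums of squares and only exercise float minutiae, not the metric
            st.floats(-100, 100).filter(lambda v: v == 0 or abs(v) > 1e-6),
            min_size=3,
            max_size=30,
        ),
        st.integers(0, 2**31),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_and_symmetry(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(xs)
        y = rng.uniform(-100, 100, size=len(x))
        # skip degenerate inputs: exactly constant arrays (scipy yields NaN
        # there) and underflow of the centered sum of squares
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        if ((x - x.mean()) ** 2).sum() == 0 or ((y - y.mean()) ** 2).sum() == 0:
            return
        expected = stats.pearsonr(x, y).statistic
        assert pcc(x, y) == pytest.approx(expected, abs=1e-10)
        assert pcc(x, y) == pytest.approx(pcc(y, x), abs=1e-12)
        assert -1.0 <= pcc(x, y) <= 1.0

    @given(
        st.floats(0.1, 50),
        st.floats(-20, 20),
        st.integers(0, 2**31),
    )
    @settings(max_examples=100, deadline=None)
    def test_positive_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 64, 20)
        y = rng.uniform(0, 64, 20)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert pcc(a * x + b, y) == pytest.approx(pcc(x, y), abs=1e-9)


class TestClusterCentroid:
    def test_single_member_identity(self):
        frame = make_frame(np.array([[1.0, 9.0], [2.0, 8.0], [3.0, 7.0]]))
        np.testing.assert_array_equal(
            cluster_centroid(frame, ["1"]), frame.column("1")
        )

    def test_mean_of_identical_is_identity(self):
        col = np.array([1.0, 5.0, 2.0])
        frame = make_frame(np.stack([col, col], axis=1))
        np.testing.assert_array_equal(cluster_centroid(frame, ["1", "2"]), col)

    def test_arithmetic_mean(self):
        frame = make_frame(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_array_equal(
            cluster_centroid(frame, ["1", "2"]), [1.0, 1.0]
        )

    def test_unknown_label(self):
        frame = make_frame(np.ones((3, 2)))
        with pytest.raises(KeyError):
            cluster_centroid(frame, ["zz"])

    def test_empty_members(self):
        frame = make_frame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            cluster_centroid(frame, [])


class TestNCombinations:
    @pytest.mark.parametrize(
        "m,k,expected",
        [(7, 2, 21), (3, 2, 3), (3, 1, 3), (7, 1, 7), (5, 5, 1), (10, 3, 120)],
    )
    def test_values(self, m, k, expected):
        assert n_combinations(m, k) == expected

    def test_matches_enumeration(self):
        for m in range(1, 8):
            for k in range(0, m + 1):
                brute = sum(1 for _ in combinations(range(m), k))
                assert n_combinations(m, k) == brute

    def test_k_greater_than_m(self):
        with pytest.raises(ValueError):
            n_combinations(3, 4)


class TestSelectK:
    def test_full_cluster_scores_exactly_one(self, fixture_frames):
        cluster = ("1", "2", "6")
        res = select_k(fixture_frames, cluster, 3)
        assert res.chosen == cluster
        assert res.chosen_score == 1.0

    @pytest.mark.parametrize("m,k,expected", [(3, 1, 3), (7, 1, 7), (3, 2, 3), (7, 2, 21)])
    def test_enumeration_counts(self, fixture_frames, m, k, expected):
        cluster = ("1", "2", "6") if m == 3 else ("3", "4", "5", "7", "8", "9", "10")
        res = select_k(fixture_frames, cluster, k)
        assert res.n_combinations == expected
        assert len({s for s, _ in res.scored}) == expected

    def test_scores_bounded_and_chosen_is_max(self, fixture_frames):
        res = select_k(fixture_frames, ("3", "4", "5", "7", "8", "9", "10"), 2)
        scores = [s for _, s in res.scored if s is not None]
        assert all(-1.0 <= s <= 1.0 for s in scores)
        assert res.chosen_score == max(scores)

    def test_matches_independent_exhaustive_search(self, fixture_frames):
        # Oracle: direct loop with scipy's correlation, coded separately.
        cluster = ("3", "4", "5", "7", "8", "9", "10")
        res = select_k(fixture_frames, cluster, 2)
        best_subset, best_score = None, -np.inf
        for subset in combinations(sorted(cluster, key=int), 2):
            vals = []
            for f in fixture_frames:
                full = np.mean([f.column(m) for m in cluster], axis=0)
                sub = np.mean([f.column(m) for m in subset], axis=0)
                vals.append(stats.pearsonr(sub, full).statistic)
            score = float(np.mean(vals))
            if score > best_score:
                best_subset, best_score = subset, score
        assert res.chosen == best_subset
        assert res.chosen_score == pytest.approx(best_score, abs=1e-10)

    def test_single_frame_reduces_to_per_frame_ranking(self, fixture_frames):
        cluster = ("1", "2", "6")
        res = select_k(fixture_frames[:1], cluster, 1)
        frame = fixture_frames[0]
        full = np.mean([frame.column(m) for m in cluster], axis=0)
        direct = {
            (m,): stats.pearsonr(frame.column(m), full).statistic for m in cluster
        }
        for subset, score in res.scored:
            assert score == pytest.approx(direct[subset], abs=1e-10)

    def test_planted_centroid_sensor_wins(self):
        # One sensor constructed equal to the cluster centroid + tiny noise.
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 64, 100)
        others = np.stack(
            [base + rng.normal(0, 5.0, 100) for _ in range(3)], axis=1
        )
        centroid = others.mean(axis=1)
        plant = centroid + rng.normal(0, 1e-6, 100)
        data = np.column_stack([others, plant])
        frame = make_frame(data, ("1", "2", "3", "4"))
        res = select_k([frame], ("1", "2", "3", "4"), 1)
        assert res.chosen == ("4",)

    def test_k_out_of_range(self, fixture_frames):
        with pytest.raises(ValueError):
            select_k(fixture_frames, ("1", "2"), 0)
        with pytest.raises(ValueError):
            select_k(fixture_frames, ("1", "2"), 3)

    def test_saturated_sensor_excluded_with_warning(self):
        # A constant (saturated) sensor makes its singleton subset degenerate.
        rng = np.random.default_rng(1)
        live = rng.uniform(0, 60, 50)
        flat = np.full(50, 64.0)
        frame = make_frame(np.column_stack([live, flat]), ("1", "2"))
        with pytest.warns(UserWarning, match="excluded"):
            res = select_k([frame], ("1", "2"), 1)
        scores = dict(res.scored)
        assert scores[("2",)] is None
        assert res.chosen == ("1",)

    def test_all_degenerate_raises(self):
        frame = make_frame(np.full((50, 2), 64.0), ("1", "2"))
        with pytest.raises(DegenerateSeriesError):
            select_k([frame], ("1", "2"), 1)

    def test_roundtrip(self, fixture_frames):
        res = select_k(fixture_frames, ("1", "2", "6"), 2)
        assert SelectionResult.from_dict(res.to_dict()) == res
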