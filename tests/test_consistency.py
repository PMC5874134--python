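"""Consistency phi, pooled correlation distributions, the permutation
t test, and size binning, each against an independent oracle."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from roiconsist import (
    consistency_vs_size,
    pearson,
    permutation_t_test,
    roi_consistencies,
    roi_consistency,
    within_between_distributions,
)
from roiconsist.consistency import ConsistencyRecord
from roiconsist.exceptions import (
    DegenerateInputError,
    ValidationError,
    ZeroVarianceError,
)
from roiconsist.synthetic import (
    SyntheticSpec,
    generate_parcellation,
    generate_voxel_timeseries,
)
from conftest import make_parcellation, make_vts


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-14)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        x=arrays(np.float64, 10, elements=st.floats(-100, 100)),
        y=arrays(np.float64, 10, elements=st.floats(-100, 100)),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson(x, y)
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(pearson(y, x), abs=1e-14)


def brute_force_phi(data):
    """Oracle: mean pairwise Pearson by explicit double loop."""
    n = data.shape[0]
    vals = [
        pearson(data[i], data[j]) for i, j in combinations(range(n), 2)
    ]
    return float(np.mean(vals))


class TestRoiConsistency:
    def test_identical_voxels_reach_exact_maximum(self):
        x = np.cos(np.arange(60.0))
        vts = make_vts(np.tile(x, (5, 1)))
        rec = roi_consistency(vts, make_parcellation([1] * 5), 1)
        assert rec.phi == 1.0

    def test_two_anticorrelated_voxels(self):
        vts = make_vts([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        rec = roi_consistency(vts, make_parcellation([1, 1]), 1)
        assert rec.phi == pytest.approx(-1.0)

    def test_three_voxel_hand_example(self):
        vts = make_vts([[1, 2, 3, 4], [1, 3, 2, 4], [4, 3, 2, 1]])
        rec = roi_consistency(vts, make_parcellation([1, 1, 1]), 1)
        assert rec.phi == pytest.approx(-1.0 / 3.0, abs=1e-14)

    def test_single_voxel_roi_undefined_with_warning(self):
        vts = make_vts([[1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="fewer than 2"):
            rec = roi_consistency(vts, make_parcellation([1]), 1)
        assert math.isnan(rec.phi) and not rec.defined

    def test_zero_variance_voxel_pair_skipped(self, rng):
        data = np.vstack([rng.standard_normal((2, 30)), np.ones(30)])
        vts = make_vts(data)
        with pytest.warns(UserWarning, match="zero-variance"):
            rec = roi_consistency(vts, make_parcellation([1, 1, 1]), 1)
        assert rec.phi == pytest.approx(pearson(data[0], data[1]))

    @given(
        n=st.integers(2, 12),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_enumeration(self, n, seed):
        data = np.random.default_rng(seed).standard_normal((n, 15))
        vts = make_vts(data)
        rec = roi_consistency(vts, make_parcellation([1] * n), 1)
        assert rec.phi == pytest.approx(brute_force_phi(data), abs=1e-12)

    def test_recovers_population_consistency(self):
        spec = SyntheticSpec(
            roi_sizes=(40,),
            n_timepoints=2000,
            shared_fraction=(0.5,),
            global_fraction=0.1,
            seed=13,
            grid_shape=(5, 5, 5),
        )
        parc = generate_parcellation(spec)
        vts = generate_voxel_timeseries(spec, parc)
        rec = roi_consistency(vts, parc, 1)
        assert rec.phi == pytest.approx(0.6, abs=3.0 / np.sqrt(2000 - 3))


class TestDistributions:
    def test_pair_counts(self):
        # ROI sizes {2, 3}: 1 + 3 within-pairs, 2*3 between-pairs
        data = np.random.default_rng(1).standard_normal((5, 40))
        vts = make_vts(data)
        parc = make_parcellation([1, 1, 2, 2, 2])
        s = within_between_distributions(vts, parc, n_permutations=50)
        assert len(s.within_values) == 4
        assert len(s.between_values) == 6
        assert s.within_mean == pytest.approx(np.mean(s.within_values))

    def test_single_roi_is_error(self):
        vts = make_vts(np.random.default_rng(2).standard_normal((3, 20)))
        with pytest.raises(DegenerateInputError):
            within_between_distributions(vts, make_parcellation([1, 1, 1]))

    def test_pair_cap_subsamples_reproducibly(self):
        data = np.random.default_rng(3).standard_normal((12, 30))
        vts = make_vts(data)
        parc = make_parcellation([1] * 6 + [2] * 6)
        s1 = within_between_distributions(vts, parc, pair_cap=10, seed=4, n_permutations=50)
        s2 = within_between_distributions(vts, parc, pair_cap=10, seed=4, n_permutations=50)
        assert len(s1.between_values) == 10
        assert np.array_equal(s1.between_values, s2.between_values)

    def test_separates_shared_from_independent(self):
        # a=0.3, R=0 across ROIs: within-mean ~0.3, between-mean ~0
        spec = SyntheticSpec(
            roi_sizes=(30, 30),
            n_timepoints=1500,
            shared_fraction=(0.3, 0.3),
            seed=21,
            grid_shape=(5, 5, 5),
        )
        parc = generate_parcellation(spec)
        vts = generate_voxel_timeseries(spec, parc)
        s = within_between_distributions(vts, parc, n_permutations=200, seed=0)
        tol = 3.0 / np.sqrt(1500 - 3)
        assert s.within_mean == pytest.approx(0.3, abs=tol)
        assert s.between_mean == pytest.approx(0.0, abs=tol)
        assert s.p_value < 0.05


def brute_force_permutation_p(a, b):
    """Oracle: enumerate every labeling of the pooled sample."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def tstat(idx_a):
        idx_a = list(idx_a)
        idx_b = [i for i in range(n) if i not in idx_a]
        xa, xb = pooled[idx_a], pooled[idx_b]
        sp2 = (
            (len(xa) - 1) * np.var(xa, ddof=1) + (len(xb) - 1) * np.var(xb, ddof=1)
        ) / (n - 2)
        return (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / len(xa) + 1 / len(xb)))

    t_obs = tstat(range(na))
    labelings = list(combinations(range(n), na))
    count = sum(abs(tstat(c)) >= abs(t_obs) - 1e-12 for c in labelings)
    return (1 + count) / (1 + len(labelings))


class TestPermutationTTest:
    def test_identical_multisets_give_t0_p1(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = permutation_t_test(a, a.copy(), n_permutations=100)
        assert t == 0.0 and p == 1.0

    def test_two_tailed_symmetry_under_swap(self):
        a = np.array([0.1, 0.5, 0.9, 1.3])
        b = np.array([2.0, 2.4, 2.8])
        _, p1 = permutation_t_test(a, b, n_permutations=500, seed=0)
        _, p2 = permutation_t_test(b, a, n_permutations=500, seed=0)
        assert p1 == p2

    def test_exhaustive_hand_example(self):
        t, p = permutation_t_test(
            np.array([1.0, 2.0]), np.array([8.0, 9.0]), n_permutations=999
        )
        assert p == pytest.approx(3.0 / 7.0)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(4)
        b = rng.standard_normal(3) + rng.uniform(-1, 1)
        _, p = permutation_t_test(a, b, n_permutations=10)
        assert p == pytest.approx(brute_force_permutation_p(a, b), abs=1e-12)

    def test_constant_pooled_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            permutation_t_test(np.ones(4), np.ones(5))

    def test_monte_carlo_path_close_to_exhaustive(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 1.0
        # C(24,12) >> exhaustive limit -> Monte-Carlo branch
        _, p1 = permutation_t_test(a, b, n_permutations=4000, seed=1)
        _, p2 = permutation_t_test(a, b, n_permutations=4000, seed=2)
        assert abs(p1 - p2) < 0.05


class TestConsistencyVsSize:
    def _records(self, sizes, phis):
        return [
            ConsistencyRecord(i + 1, p, s) for i, (s, p) in enumerate(zip(sizes, phis))
        ]

    def test_single_bin_is_overall_mean(self):
        recs = self._records([10, 50, 400], [0.1, 0.3, 0.5])
        table, _, _ = consistency_vs_size(recs, 1)
        assert len(table) == 1
        assert table["mean_phi"].iloc[0] == pytest.approx(0.3)

    def test_all_same_size_single_occupied_bin(self):
        recs = self._records([25, 25, 25], [0.2, 0.4, 0.6])
        table, r, p = consistency_vs_size(recs, 5)
        assert (table["n"] > 0).sum() == 1
        assert math.isnan(r)

    def test_undefined_phi_dropped(self):
        recs = self._records([10, 20], [0.5, math.nan])
        table, _, _ = consistency_vs_size(recs, 2)
        assert table["n"].sum() == 1

    def test_recovers_negative_size_consistency_relation(self):
        # shared fraction falls with ROI size -> negative size-phi correlation
        sizes = (8, 16, 27, 48, 80, 125)
        a = tuple(0.5 / (1.0 + math.log(s)) for s in sizes)
        spec = SyntheticSpec(
            roi_sizes=sizes,
            n_timepoints=800,
            shared_fraction=a,
            seed=17,
            grid_shape=(10, 10, 10),
        )
        parc = generate_parcellation(spec)
        vts = generate_voxel_timeseries(spec, parc)
        recs = roi_consistencies(vts, parc)
        _, r, p = consistency_vs_size(recs, 3)
        assert r < 0

    def test_bad_bin_count(self):
        with pytest.raises(ValidationError):
            consistency_vs_size(self._records([5], [0.1]), 0)
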