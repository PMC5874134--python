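"""Voxel-level vs ROI-level inter-ROI correlation, the pair table,
the identity-line bound, and the amplification/saturation properties."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roiconsist import (
    build_pair_table,
    identity_bound_check,
    pearson,
    relation_binned,
    roi_average,
    roi_consistencies,
    roi_level_correlation,
    voxel_level_correlation,
)
from roiconsist.exceptions import DegenerateInputError, ValidationError, ZeroVarianceError
from roiconsist.synthetic import (
    SyntheticSpec,
    expected_statistics,
    generate_parcellation,
    generate_voxel_timeseries,
)
from conftest import make_parcellation, make_vts


def brute_force_c_vox(data_i, data_j):
    """Oracle: mean cross-pair Pearson by explicit double loop."""
    vals = [
        pearson(x, y) for x, y in product(data_i, data_j)
    ]
    return float(np.mean(vals))


class TestVoxelLevel:
    def test_identical_series_give_exactly_one(self):
        x = np.sin(np.arange(50.0))
        vts = make_vts(np.tile(x, (6, 1)))
        parc = make_parcellation([1, 1, 1, 2, 2, 2])
        assert voxel_level_correlation(vts, parc, 1, 2) == 1.0

    def test_single_voxel_anticorrelated_rois(self):
        vts = make_vts([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        parc = make_parcellation([1, 2])
        assert voxel_level_correlation(vts, parc, 1, 2) == pytest.approx(-1.0)

    def test_four_pair_hand_example(self):
        vts = make_vts([[1, 2, 3], [2, 4, 6], [1, 2, 3], [3, 2, 1]])
        parc = make_parcellation([1, 1, 2, 2])
        # cross pairs correlate {1, -1, 1, -1}
        assert voxel_level_correlation(vts, parc, 1, 2) == pytest.approx(0.0, abs=1e-14)

    def test_same_roi_rejected(self):
        vts = make_vts(np.random.default_rng(0).standard_normal((4, 20)))
        with pytest.raises(ValidationError):
            voxel_level_correlation(vts, make_parcellation([1, 1, 2, 2]), 1, 1)

    @given(ni=st.integers(1, 12), nj=st.integers(1, 12), seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, ni, nj, seed):
        data = np.random.default_rng(seed).standard_normal((ni + nj, 12))
        vts = make_vts(data)
        parc = make_parcellation([1] * ni + [2] * nj)
        got = voxel_level_correlation(vts, parc, 1, 2)
        assert got == pytest.approx(brute_force_c_vox(data[:ni], data[ni:]), abs=1e-12)

    def test_pair_budget_subsampling_close_to_exact(self):
        data = np.random.default_rng(8).standard_normal((40, 100)) + np.random.default_rng(9).standard_normal(100) * 0.7
        vts = make_vts(data)
        parc = make_parcellation([1] * 20 + [2] * 20)
        exact = voxel_level_correlation(vts, parc, 1, 2)
        sub = voxel_level_correlation(vts, parc, 1, 2, pair_budget=150, seed=0)
        assert sub == pytest.approx(exact, abs=0.05)


class TestRoiLevel:
    def test_identical_and_negated_series(self):
        from roiconsist.signal import ROITimeSeriesSet

        x = np.array([1.0, 3.0, 2.0, 5.0])
        rts = ROITimeSeriesSet(
            data=np.vstack([x, x, -x]), roi_ids=[1, 2, 3], sizes=[1, 1, 1]
        )
        assert roi_level_correlation(rts, 1, 2) == 1.0
        assert roi_level_correlation(rts, 1, 3) == pytest.approx(-1.0)

    def test_constant_average_is_undefined(self):
        # averaging [1,2,3] and [3,2,1] gives the constant [2,2,2]
        vts = make_vts([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        parc = make_parcellation([1, 1, 2, 2])
        rts = roi_average(vts, parc)
        assert np.allclose(rts.row(2), 2.0)
        with pytest.raises(ZeroVarianceError):
            roi_level_correlation(rts, 1, 2)

    def test_recovers_closed_form_population_value(self):
        spec = SyntheticSpec(
            roi_sizes=(150, 150),
            n_timepoints=5000,
            shared_fraction=(0.3, 0.3),
            latent_correlation=np.array([[1.0, 2 / 3], [2 / 3, 1.0]]),
            seed=42,
            grid_shape=(10, 10, 10),
        )
        parc = generate_parcellation(spec)
        vts = generate_voxel_timeseries(spec, parc)
        rts = roi_average(vts, parc)
        _, pair_t = expected_statistics(spec)
        got = roi_level_correlation(rts, 1, 2)
        assert got == pytest.approx(
            pair_t["c_roi"].iloc[0], abs=3.0 / np.sqrt(5000 - 3)
        )


def _synthetic_pair_table(seed=0, n_rois=5, T=600):
    rng = np.random.default_rng(seed)
    a = tuple(rng.uniform(0.1, 0.9, n_rois))
    R = np.full((n_rois, n_rois), 0.4)
    np.fill_diagonal(R, 1.0)
    spec = SyntheticSpec(
        roi_sizes=tuple([12] * n_rois),
        n_timepoints=T,
        shared_fraction=a,
        latent_correlation=R,
        seed=seed,
        grid_shape=(6, 6, 6),
    )
    parc = generate_parcellation(spec)
    vts = generate_voxel_timeseries(spec, parc)
    rts = roi_average(vts, parc)
    recs = roi_consistencies(vts, parc)
    table, summary = build_pair_table(vts, rts, parc, recs)
    return spec, table, summary


class TestPairTable:
    def test_three_rois_three_rows(self):
        data = np.random.default_rng(3).standard_normal((6, 30))
        vts = make_vts(data)
        parc = make_parcellation([1, 1, 2, 2, 3, 3])
        rts = roi_average(vts, parc)
        table, _ = build_pair_table(vts, rts, parc, roi_consistencies(vts, parc))
        assert len(table) == 3
        assert set(map(tuple, table[["roi_i", "roi_j"]].values.tolist())) == {
            (1, 2), (1, 3), (2, 3),
        }

    def test_symmetric_under_relabeling(self):
        data = np.random.default_rng(4).standard_normal((6, 30))
        vts = make_vts(data)
        p1 = make_parcellation([1, 1, 2, 2, 3, 3])
        p2 = make_parcellation([3, 3, 2, 2, 1, 1])
        t1, _ = build_pair_table(vts, roi_average(vts, p1), p1, roi_consistencies(vts, p1))
        t2, _ = build_pair_table(vts, roi_average(vts, p2), p2, roi_consistencies(vts, p2))
        r1 = t1[(t1.roi_i == 1) & (t1.roi_j == 2)]["c_vox"].iloc[0]
        r2 = t2[(t2.roi_i == 2) & (t2.roi_j == 3)]["c_vox"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_undefined_pairs_flagged_not_dropped(self):
        vts = make_vts(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]
        )
        parc = make_parcellation([1, 1, 2, 2])
        rts = roi_average(vts, parc)
        table, summary = build_pair_table(vts, rts, parc, roi_consistencies(vts, parc))
        assert len(table) == 1
        assert "c_roi_undefined" in table["flag"].iloc[0]
        assert summary["n_flagged"] == 1

    def test_cvox_tracks_consistency_more_than_croi(self):
        # heterogeneous a, homogeneous R: C_vox rises with mean consistency
        # while C_roi is de-attenuated and much flatter
        _, table, summary = _synthetic_pair_table(seed=5, n_rois=6, T=800)
        assert summary["r_vox_vs_consistency"] > summary["r_roi_vs_consistency"]


class TestIdentityBound:
    def test_synthetic_run_has_no_violations(self):
        spec, table, _ = _synthetic_pair_table(seed=6, T=600)
        tol = 3.0 / np.sqrt(600 - 3)
        assert len(identity_bound_check(table, tol)) == 0

    def test_hand_built_violation_detected(self):
        table = pd.DataFrame(
            {
                "roi_i": [1], "roi_j": [2],
                "mean_consistency": [0.2], "c_vox": [0.5], "c_roi": [0.6],
                "flag": [""],
            }
        )
        assert len(identity_bound_check(table, 0.0)) == 1

    def test_tolerance_two_never_violated(self):
        _, table, _ = _synthetic_pair_table(seed=7)
        assert len(identity_bound_check(table, 2.0)) == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            identity_bound_check(pd.DataFrame(columns=["c_vox", "mean_consistency"]))


class TestRelationBinned:
    def test_single_bin_is_overall_mean(self):
        _, table, _ = _synthetic_pair_table(seed=8)
        binned = relation_binned(table, "c_vox", "c_roi", 1)
        assert binned["mean_y"].iloc[0] == pytest.approx(table["c_roi"].mean())

    def test_identity_fields_lie_on_diagonal(self):
        _, table, _ = _synthetic_pair_table(seed=9)
        binned = relation_binned(table, "c_vox", "c_vox", 4)
        occupied = binned[binned["n"] > 0]
        assert np.allclose(occupied["mean_x"], occupied["mean_y"])

    def test_roi_level_exceeds_voxel_level_in_every_bin(self):
        # fixed a = 0.33, N = 30: c_roi ~ c_vox / (a + (1-a)/N) > c_vox
        n_rois, a = 8, 0.33
        rng = np.random.default_rng(10)
        R = np.full((n_rois, n_rois), 0.0)
        iu = np.triu_indices(n_rois, 1)
        vals = rng.uniform(0.05 / a, 0.4 / a, len(iu[0]))
        R[iu] = vals
        R = R + R.T
        np.fill_diagonal(R, 1.0)
        # shrink toward identity until PSD
        while np.linalg.eigvalsh(R).min() < 1e-6:
            R = 0.9 * R
            np.fill_diagonal(R, 1.0)
        spec = SyntheticSpec(
            roi_sizes=tuple([30] * n_rois),
            n_timepoints=2500,
            shared_fraction=tuple([a] * n_rois),
            latent_correlation=R,
            seed=11,
            grid_shape=(8, 8, 8),
        )
        parc = generate_parcellation(spec)
        vts = generate_voxel_timeseries(spec, parc)
        rts = roi_average(vts, parc)
        table, _ = build_pair_table(vts, rts, parc, roi_consistencies(vts, parc))
        binned = relation_binned(table, "c_vox", "c_roi", 4)
        occupied = binned[binned["n"] > 0]
        assert (occupied["mean_y"] > occupied["mean_x"]).all()

    def test_saturation_of_the_closed_form(self):
        # sweep equal-a pairs at fixed latent correlation r: c_vox = a*r and
        # c_roi = c_vox / (a + (1-a)/N), so c_roi(c_vox) is concave and its
        # slope decreases as c_vox grows -- amplification saturates at low
        # voxel-level correlation already
        r, N = 0.8, 150
        a = np.linspace(0.05, 0.95, 200)
        c_vox = a * r
        c_roi = c_vox / (a + (1 - a) / N)
        slope = np.gradient(c_roi, c_vox)
        assert (np.diff(slope) < 0).all()
        assert (c_roi >= c_vox).all()

    def test_missing_field_rejected(self):
        _, table, _ = _synthetic_pair_table(seed=12)
        with pytest.raises(ValidationError):
            relation_binned(table, "nope", "c_roi", 3)
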