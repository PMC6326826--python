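"""Circular statistics, decussation, nearest neighbours, spacing, DWLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rodmap import (circular_mean, decussation_by_rows, decussation_from_means,
                    dwls_surface, inter_row_angle, nearest_neighbor_distances,
                    category_counts, spacing_summary)


class TestCircularMean:
    def test_worked_example_30_60_80(self):
        assert round(circular_mean([30, 60, 80]).mean_deg) == 57

    def test_single_angle(self):
        cs = circular_mean([123.0])
        assert cs.mean_deg == pytest.approx(123.0)
        assert cs.resultant_length == pytest.approx(1.0)
        assert cs.circular_sd_deg == pytest.approx(0.0, abs=1e-3)

    def test_wraparound(self):
        assert circular_mean([350, 10]).mean_deg == pytest.approx(0.0, abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            circular_mean([])

    def test_matches_scipy_oracle(self, rng):
        """Independent cross-check against scipy's circular statistics."""
        for _ in range(20):
            a = rng.uniform(0, 360, size=rng.integers(2, 200))
            cs = circular_mean(a)
            assert cs.mean_deg == pytest.approx(sps.circmean(a, high=360), abs=1e-8)
            assert cs.circular_sd_deg == pytest.approx(sps.circstd(a, high=360), abs=1e-8)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 359.99), min_size=1, max_size=30),
           st.floats(-720, 720))
    def test_rotation_equivariance(self, angles, delta):
        base = circular_mean(angles)
        if base.resultant_length < 1e-6:
            return  # mean direction undefined
        shifted = circular_mean([(a + delta) % 360 for a in angles])
        d = (shifted.mean_deg - base.mean_deg - delta) % 360
        assert min(d, 360 - d) < 1e-6 * max(1.0, abs(delta)) + 1e-5 / max(base.resultant_length, 1e-3)


class TestDecussation:
    @pytest.mark.parametrize("a,b,expected", [
        (104, 49, 55.0), (90, 90, 0.0), (10, 350, 20.0), (0, 180, 180.0),
    ])
    def test_from_means(self, a, b, expected):
        assert decussation_from_means(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("dec,expected", [(70.0, 110.0), (45.0, 135.0), (0.0, 180.0)])
    def test_inter_row_supplement(self, dec, expected):
        ra = {"tilt": "mesial", "mean_angle_deg": 100.0}
        rb = {"tilt": "lateral", "mean_angle_deg": 100.0 - dec}
        assert inter_row_angle(ra, rb) == pytest.approx(expected)

    def test_inter_row_same_tilt_errors(self):
        r = {"tilt": "mesial", "mean_angle_deg": 10.0}
        with pytest.raises(ValueError):
            inter_row_angle(r, dict(r))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0, 359.9), st.floats(0, 359.9))
    def test_supplement_identity(self, ma, mb):
        """inter-row angle + decussation angle of the same pair = 180."""
        ra = {"tilt": "mesial", "mean_angle_deg": ma}
        rb = {"tilt": "lateral", "mean_angle_deg": mb}
        assert inter_row_angle(ra, rb) + decussation_from_means(ma, mb) == pytest.approx(180.0)

    def test_by_rows_pairing_and_skip(self, caplog):
        rows = pd.DataFrame({
            "row_id": [1, 2, 3, 4],
            "tilt": ["mesial", "lateral", "lateral", "mesial"],
            "mean_angle_deg": [104.0, 49.0, 60.0, 110.0],
            "midpoint_x": [10.0, 20.0, 30.0, 40.0],
            "region": [1, 1, 2, 2],
        })
        pairs = decussation_by_rows(rows)
        # (1,2) alternates -> 55; (2,3) same tilt skipped; (3,4) -> 50
        assert len(pairs) == 2
        assert pairs["decussation_deg"].tolist() == pytest.approx([55.0, 50.0])
        assert np.allclose(pairs["decussation_deg"] + pairs["inter_row_angle_deg"], 180.0)

    def test_fewer_than_two_rows_empty(self):
        rows = pd.DataFrame({"row_id": [1], "tilt": ["mesial"],
                             "mean_angle_deg": [90.0], "midpoint_x": [0.0], "region": [1]})
        assert decussation_by_rows(rows).empty


class TestNearestNeighbors:
    def test_two_points_symmetric(self):
        d = nearest_neighbor_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert np.allclose(d, [5.0, 5.0])

    def test_unit_grid(self):
        g = np.stack(np.meshgrid(np.arange(5.0), np.arange(5.0)), -1).reshape(-1, 2)
        assert np.allclose(nearest_neighbor_distances(g), 1.0)

    def test_matches_brute_force_exactly(self, rng):
        pts = rng.uniform(0, 100, size=(500, 2))
        d = nearest_neighbor_distances(pts)
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt(diff[..., 0] ** 2 + diff[..., 1] ** 2)
        np.fill_diagonal(dist, np.inf)
        assert np.array_equal(d, dist.min(axis=1))

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances(np.array([[1.0, 2.0]]))


class TestSpacing:
    def test_single_uniform_row(self):
        n = 10
        df = pd.DataFrame({
            "category": ["inner_mesial"] * n,
            "row_id": [1] * n,
            "seq_index": range(n),
            "centroid_x": 4.0 * np.arange(n),
            "centroid_y": np.zeros(n),
            "norm_x": np.full(n, 0.1),
            "region": [1] * n,
        })
        out = spacing_summary(df, scale_pixels_per_um=1.0)
        assert len(out) == 1
        assert out["mean_spacing_um"].iloc[0] == pytest.approx(4.0)
        assert out["n"].iloc[0] == n - 1

    def test_empty_groups_absent(self):
        df = pd.DataFrame(columns=["category", "row_id", "seq_index",
                                   "centroid_x", "centroid_y", "norm_x", "region"])
        out = spacing_summary(df, 1.0)
        assert out.empty


class TestCategoryCounts:
    def test_reported_composition(self):
        """Counts of 5096/1922/216 give 70/27/3 percent."""
        cats = (["inner_mesial"] * 2687 + ["inner_lateral"] * 2409
                + ["outer"] * 1922 + ["cej"] * 216)
        out = category_counts(pd.DataFrame({"category": cats}))
        assert out["percent"] == {"inner": 70, "outer": 27, "cej": 3}
        assert out["counts"]["inner"] == 5096

    def test_single_category_is_100(self):
        out = category_counts(pd.DataFrame({"category": ["outer"] * 5}))
        assert out["percent"]["outer"] == 100

    def test_percentages_sum_to_100_within_rounding(self, rng):
        for _ in range(20):
            n = rng.integers(3, 2000, size=3)
            cats = (["inner_mesial"] * int(n[0]) + ["outer"] * int(n[1])
                    + ["cej"] * int(n[2]))
            out = category_counts(pd.DataFrame({"category": cats}))
            assert abs(sum(out["percent"].values()) - 100) <= 1


class TestDwls:
    def test_constant_field(self, rng):
        pts = rng.uniform(0, 1, size=(40, 2))
        z = np.full(40, 7.5)
        g = dwls_surface(pts, z, np.linspace(0, 1, 5), np.linspace(0, 1, 5))
        assert np.allclose(g, 7.5, atol=1e-9)

    @pytest.mark.parametrize("bandwidth", [0.05, 0.25, 2.0])
    def test_plane_recovered_exactly(self, rng, bandwidth):
        pts = rng.uniform(0, 1, size=(60, 2))
        z = 3.0 * pts[:, 0] - 2.0 * pts[:, 1] + 1.0
        gx, gy = np.linspace(0.1, 0.9, 4), np.linspace(0.1, 0.9, 4)
        g = dwls_surface(pts, z, gx, gy, bandwidth)
        expect = 3.0 * gx[None, :] - 2.0 * gy[:, None] + 1.0
        assert np.allclose(g, expect, atol=1e-6)

    def test_bad_bandwidth_and_small_n(self, rng):
        pts = rng.uniform(0, 1, size=(20, 2))
        with pytest.raises(ValueError):
            dwls_surface(pts, np.zeros(20), [0.5], [0.5], bandwidth=0.0)
        with pytest.raises(ValueError):
            dwls_surface(pts[:5], np.zeros(5), [0.5], [0.5])

    def test_correlates_with_true_angle_field(self, rng):
        """Smoothed surface tracks a lateral-to-mesial gradient, r >= 0.95."""
        n = 400
        pts = rng.uniform(0, 1, size=(n, 2))
        true = np.interp(pts[:, 0], [0.125, 0.375, 0.625, 0.875],
                         [58.4, 87.9, 117.5, 147.0])
        z = true + rng.normal(0, 12.5, size=n)
        gx = np.linspace(0.05, 0.95, 12)
        gy = np.linspace(0.05, 0.95, 6)
        g = dwls_surface(pts, z, gx, gy, bandwidth=0.25)
        truth_grid = np.interp(gx, [0.125, 0.375, 0.625, 0.875],
                               [58.4, 87.9, 117.5, 147.0])[None, :].repeat(6, 0)
        r = np.corrcoef(g.ravel(), truth_grid.ravel())[0, 1]
        assert r >= 0.95
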