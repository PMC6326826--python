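"""Synthetic map generator: geometry, layout, rendering, round trips."""

import numpy as np
import pytest

from rodmap import (ConfigurationError, GenerationError, GeneratorConfig,
                    apportion, build_band_geometry, extract_particles,
                    measure_particles, render_color_maps, sample_rod_layout,
                    simulate, threshold_layer)
from rodmap.config import AngleField
from rodmap.stats import circular_mean
from .conftest import match_to_truth, small_config


def constant_fields(angle, sd):
    return {k: AngleField((angle,) * 4, (sd,) * 4)
            for k in ("inner_mesial", "inner_lateral", "outer", "cej")}


class TestConfig:
    def test_fraction_sum_invariant(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(category_fractions=(0.5, 0.4, 0.2))

    def test_thickness_partition_invariant(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(inner_um=90.0, outer_um=21.0)

    def test_odd_row_count_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_rows=123)

    def test_radius_must_exceed_thickness(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(curvature=100.0)

    def test_mean_outside_axial_range_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(angle_fields=constant_fields(185.0, 10.0))

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = GeneratorConfig.from_yaml(p)
        assert back.to_dict() == cfg.to_dict()


class TestApportionment:
    def test_default_composition(self):
        """Largest remainder on 7233 x (0.70/0.27/0.03)."""
        counts = apportion(7233, (0.70, 0.27, 0.03))
        # independent largest-remainder computation
        quota = 7233 * np.array([0.70, 0.27, 0.03])
        floor = np.floor(quota).astype(int)
        order = np.argsort(-(quota - floor))
        expected = floor.copy()
        expected[order[: 7233 - floor.sum()]] += 1
        assert counts == expected.tolist() == [5063, 1953, 217]

    def test_sums_preserved(self, rng):
        for _ in range(50):
            total = int(rng.integers(1, 10000))
            f = rng.dirichlet(np.ones(rng.integers(2, 6)))
            assert sum(apportion(total, f)) == total


class TestGeometry:
    def test_flat_polylines_parallel_121px_apart(self):
        cfg = GeneratorConfig(seed=0, curvature="flat", pixels_per_um=1.0,
                              band_length_um=200.0)
        emap = build_band_geometry(cfg)
        dy = emap.surface_polyline[:, 1] - emap.dej_polyline[:, 1]
        assert np.allclose(dy, 121.0)
        assert np.allclose(np.diff(emap.dej_polyline[:, 1]), 0.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(pixels_per_um=0.0)

    def test_cej_endpoints_at_band_termini(self):
        emap = build_band_geometry(small_config())
        assert emap.cej_lateral[0] < emap.cej_mesial[0]


class TestLayout:
    def test_exact_counts_and_categories(self, small_run):
        cfg, _, truth, records, _ = small_run
        assert len(records) == cfg.total_profiles
        expect = dict(zip(("inner", "outer", "cej"),
                          apportion(cfg.total_profiles, cfg.category_fractions)))
        got = truth["category"].value_counts()
        assert got.get("inner_mesial", 0) + got.get("inner_lateral", 0) == expect["inner"]
        assert got.get("outer", 0) == expect["outer"]
        assert got.get("cej", 0) == expect["cej"]

    def test_every_inner_record_has_row(self, small_run):
        _, _, truth, _, _ = small_run
        inner = truth[truth["category"].str.startswith("inner")]
        assert (inner["row_id"] > 0).all()
        assert (truth.loc[~truth["category"].str.startswith("inner"), "row_id"] == 0).all()

    def test_two_rows_of_ten_alternating(self):
        cfg = small_config(
            seed=5, total_profiles=20, n_rows=2,
            category_fractions=(1.0, 0.0, 0.0),
            angle_fields={
                "inner_mesial": AngleField((75.0,) * 4, (2.0,) * 4),
                "inner_lateral": AngleField((105.0,) * 4, (2.0,) * 4),
                "outer": AngleField((90.0,) * 4, (2.0,) * 4),
                "cej": AngleField((90.0,) * 4, (2.0,) * 4),
            },
            spacing_fields={k: (3.0,) * 4 for k in
                            ("inner_mesial", "inner_lateral", "outer", "cej")},
        )
        emap = build_band_geometry(cfg)
        records = sample_rod_layout(cfg, emap)
        tilts = {}
        for r in records:
            tilts.setdefault(r.row_id, set()).add(r.tilt)
        assert sorted(len([r for r in records if r.row_id == k]) for k in tilts) == [10, 10]
        assert sorted(t for s in tilts.values() for t in s) == ["lateral", "mesial"]

    def test_degenerate_noise_gives_constant_angles(self):
        cfg = small_config(seed=2, angle_fields=constant_fields(90.0, 0.0))
        _, truth, _ = simulate(cfg)
        assert np.allclose(truth["angle_deg"], 90.0)

    def test_no_rendered_overlap(self, small_run):
        import shapely

        _, _, _, records, _ = small_run
        polys = np.array([r.polygon for r in records], dtype=object)
        centers = shapely.get_coordinates(shapely.centroid(polys))
        from scipy.spatial import cKDTree

        pairs = np.array(sorted(cKDTree(centers).query_pairs(
            5.0 * 16.0)))  # 5 um in px
        d = shapely.distance(polys[pairs[:, 0]], polys[pairs[:, 1]])
        assert d.min() >= 2.0  # at least 2 px clearance

    def test_infeasible_packing_names_limiting_region(self):
        cfg = small_config(seed=1, total_profiles=5000)
        with pytest.raises(GenerationError, match="region"):
            simulate(cfg)


class TestRendering:
    def test_component_count_per_layer_matches_records(self, small_run):
        _, emap, truth, _, _ = small_run
        for cat, n_expected in truth["category"].value_counts().items():
            labels, n = extract_particles(threshold_layer(emap.layers[cat]))
            assert n == n_expected

    def test_empty_record_list_blank_layers(self):
        emap = build_band_geometry(small_config())
        render_color_maps([], emap)
        assert set(emap.layers) == {"inner_mesial", "inner_lateral", "outer", "cej"}
        assert all(layer.sum() == 0 for layer in emap.layers.values())

    def test_record_outside_band_rejected(self):
        from rodmap.synthetic import GroundTruthRecord, RenderError, _ellipse_poly

        emap = build_band_geometry(small_config())
        bad = GroundTruthRecord(
            profile_id=1, category="outer", tilt="", x_px=5.0, y_px=5.0,
            angle_deg=0.0, row_id=0, seq_index=0, region=1, shape="ellipse",
            polygon=_ellipse_poly(np.array([-50.0, -50.0]), 0.0, 20.0, 10.0),
        )
        with pytest.raises(RenderError, match="1"):
            render_color_maps([bad], emap)


class TestRoundTrip:
    def test_centroids_recovered_within_one_pixel(self, small_run):
        _, _, truth, _, result = small_run
        for cat in ("inner_mesial", "inner_lateral", "outer", "cej"):
            m = match_to_truth(truth, result.profiles, cat)
            assert m["match_dist_px"].max() < 1.0

    def test_angle_recovery_for_elongated_profiles(self, small_run):
        """Per-rod Feret angles track truth; pooled means are unbiased."""
        _, _, truth, _, result = small_run
        m = match_to_truth(truth, result.profiles, "inner_mesial")
        err = (m["feret_angle_deg"] - m["true_angle_deg"] + 90) % 180 - 90
        assert np.mean(np.abs(err) <= 4.0) >= 0.95
        assert abs(err.mean()) < 1.0

    def test_zero_noise_pooled_mean_recovered(self):
        """SD -> 0 on a flat band: pooled recovered circular mean within 0.5 deg."""
        from rodmap import run_pipeline

        cfg = small_config(seed=4, angle_fields=constant_fields(60.0, 0.0))
        emap, truth, _ = simulate(cfg)
        result = run_pipeline(emap, config=cfg)
        inner = result.profiles[result.profiles["category"].str.startswith("inner")]
        got = circular_mean(inner["feret_angle_deg"]).mean_deg
        assert abs((got - 60.0 + 180) % 360 - 180) < 0.5

    def test_circular_sd_recovery_within_15_percent(self, default_run):
        """Recovered per-region circular SDs track the configured noise SDs
        (cells whose configured SD fits the axial half-range)."""
        cfg, truth, result = default_run
        prof = result.profiles
        checked = 0
        for cat in ("inner_mesial", "inner_lateral"):
            f = cfg.angle_fields[cat]
            sub = prof[prof["category"] == cat]
            for region in (1, 2, 3, 4):
                sd_cfg = f.sd[region - 1]
                if sd_cfg > 30.0:
                    continue
                g = sub[sub["region"] == region]
                sd_got = circular_mean(g["feret_angle_deg"]).circular_sd_deg
                assert abs(sd_got - sd_cfg) / sd_cfg < 0.15, (cat, region)
                checked += 1
        assert checked >= 5

    def test_reproducible_given_seed(self):
        cfg = small_config(seed=13)
        emap1, truth1, _ = simulate(cfg)
        emap2, truth2, _ = simulate(small_config(seed=13))
        assert truth1.equals(truth2)
        assert all(np.array_equal(emap1.layers[c], emap2.layers[c])
                   for c in emap1.layers)
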