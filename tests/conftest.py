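import logging

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from rodmap import AngleField, GeneratorConfig, run_pipeline, simulate

logging.getLogger("rodmap").setLevel(logging.ERROR)


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A fast flat band: ~700 profiles in 14 rows, same architecture.

    Tilt gradients are milder than the full-map defaults: the published
    section-frame anchors presume the curved band (rows at 147 degrees
    drift ~150 um sideways, more than this short flat band can hold).
    """
    kwargs = dict(
        seed=seed,
        curvature="flat",
        band_length_um=200.0,
        total_profiles=700,
        n_rows=14,
        angle_fields={
            "inner_mesial": AngleField((70.0, 85.0, 100.0, 115.0), (10.0,) * 4),
            "inner_lateral": AngleField((45.0, 55.0, 65.0, 75.0), (12.0,) * 4),
            "outer": AngleField((40.0, 60.0, 80.0, 100.0), (20.0,) * 4),
            "cej": AngleField((101.0,) * 4, (30.0,) * 4),
        },
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def grand_mean_config(seed: int) -> GeneratorConfig:
    """Flat band with constant tilt fields at the pooled grand means."""
    return GeneratorConfig(
        seed=seed,
        curvature="flat",
        band_length_um=400.0,
        total_profiles=3400,
        n_rows=60,
        angle_fields={
            "inner_mesial": AngleField((104.0,) * 4, (34.2,) * 4),
            "inner_lateral": AngleField((48.6,) * 4, (25.2,) * 4),
            "outer": AngleField((24.0, 46.0, 80.0, 122.0), (28.0,) * 4),
            "cej": AngleField((101.0,) * 4, (43.9,) * 4),
        },
    )


def match_to_truth(truth: pd.DataFrame, profiles: pd.DataFrame,
                   category: str) -> pd.DataFrame:
    """Join measured profiles to ground truth by nearest centroid."""
    t = truth[truth["category"] == category].reset_index(drop=True)
    p = profiles[profiles["category"] == category].reset_index(drop=True).copy()
    tree = cKDTree(t[["x_px", "y_px"]].to_numpy())
    d, idx = tree.query(p[["centroid_x", "centroid_y"]].to_numpy())
    p["match_dist_px"] = d
    for col in ("angle_deg", "row_id", "seq_index", "region"):
        p[f"true_{col}"] = t[col].to_numpy()[idx]
    return p


@pytest.fixture(scope="session")
def small_run():
    cfg = small_config()
    emap, truth, records = simulate(cfg)
    result = run_pipeline(emap, config=cfg)
    return cfg, emap, truth, records, result


@pytest.fixture(scope="session")
def default_runs():
    """Five full default maps (seeds 1-5), simulated and analysed."""
    out = []
    for seed in range(1, 6):
        cfg = GeneratorConfig(seed=seed)
        emap, truth, _ = simulate(cfg)
        result = run_pipeline(emap, config=cfg)
        out.append((cfg, truth, result))
    return out


@pytest.fixture(scope="session")
def default_run(default_runs):
    return default_runs[0]


@pytest.fixture(scope="session")
def grand_mean_runs():
    """Five constant-field maps pooling >=5000 profiles per tilt."""
    out = []
    for seed in range(101, 106):
        cfg = grand_mean_config(seed)
        emap, truth, _ = simulate(cfg)
        result = run_pipeline(emap, config=cfg)
        out.append((cfg, truth, result))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
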