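"""Optional plotting helpers mirroring the standard figures for this kind
of data: per-region circular (polar) plots of rod tilt angles and DWLS
surface plots of angle versus location."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import circular_mean, dwls_surface

_REGION_COLORS = {1: "tab:red", 2: "tab:blue", 3: "tab:green", 4: "tab:purple"}


def polar_plot(profiles: pd.DataFrame, category: str, path: str | Path) -> Path:
    """Circular plot of tilt angles per region for one category."""
    sub = profiles[profiles["category"] == category]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for region, g in sub.groupby("region", observed=True):
        th = np.radians(g["feret_angle_deg"].to_numpy())
        ax.scatter(th, np.ones_like(th) + 0.02 * region, s=2,
                   color=_REGION_COLORS.get(int(region), "gray"),
                   label=f"region {region} (n={len(g)})", alpha=0.4)
        cs = circular_mean(g["feret_angle_deg"])
        ax.plot([0, np.radians(cs.mean_deg)], [0, cs.resultant_length],
                color=_REGION_COLORS.get(int(region), "gray"), lw=2)
    ax.set_title(f"{category} tilt angles")
    ax.set_yticks([])
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def surface_plot(profiles: pd.DataFrame, category: str, path: str | Path,
                 grid: int = 40, bandwidth: float = 0.25) -> Path:
    """DWLS-smoothed angle surface over normalized location."""
    sub = profiles[profiles["category"] == category]
    pts = sub[["norm_x", "depth_fraction"]].to_numpy()
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid)
    z = dwls_surface(pts, sub["feret_angle_deg"].to_numpy(), gx, gy, bandwidth)
    fig, ax = plt.subplots(figsize=(7, 3))
    im = ax.pcolormesh(gx, gy, z, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="tilt angle (deg)")
    ax.set_xlabel("normalized x (lateral -> mesial)")
    ax.set_ylabel("depth fraction (DEJ -> surface)")
    ax.set_title(f"{category}: DWLS angle surface")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
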