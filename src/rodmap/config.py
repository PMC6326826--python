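"""Generator configuration and shared helpers.

The configuration mirrors the measured architecture of the mouse mandibular
incisor enamel band: a ~121 um thick curved band whose inner 100 um holds
oval rod profiles organised in alternating-tilt rows, a ~21 um outer layer of
diamond-shaped profiles, and small disorganised zones near the two
cementoenamel junctions (CEJ).  Angle and spacing fields are anchored per
region (four equal lateral-to-mesial quarters of the band) and per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

CATEGORIES = ("inner_mesial", "inner_lateral", "outer", "cej")
INNER_CATEGORIES = ("inner_mesial", "inner_lateral")

#: display colours of the four categories in the composite map
CATEGORY_COLORS = {
    "inner_mesial": (0, 0, 0),
    "inner_lateral": (220, 30, 30),
    "outer": (40, 60, 220),
    "cej": (200, 40, 200),
}


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a requested layout cannot be realised without overlap."""


@dataclass
class AngleField:
    """Region-anchored circular means and SDs (degrees) for one category.

    ``anchors[k]`` is the circular mean of region ``k+1`` (1 = lateral,
    4 = mesial); ``sd[k]`` the corresponding circular SD of the angular
    noise.  Means live on the axial half-turn [0, 180).
    """

    anchors: tuple[float, float, float, float]
    sd: tuple[float, float, float, float]

    def validate(self, name: str) -> None:
        if len(self.anchors) != 4 or len(self.sd) != 4:
            raise ConfigurationError(f"{name}: need 4 region anchors and 4 SDs")
        for a in self.anchors:
            if not (0.0 <= a < 180.0):
                raise ConfigurationError(f"{name}: mean {a} outside [0, 180)")
        for s in self.sd:
            if s < 0:
                raise ConfigurationError(f"{name}: negative SD {s}")


def _default_angle_fields() -> dict[str, AngleField]:
    # Printed region-1/region-4 anchors with linearly interpolated interiors
    # (the per-region step sizes match the reported ~30 deg/region mesial and
    # ~15 deg/region lateral progressions).
    return {
        "inner_mesial": AngleField((58.4, 87.9, 117.5, 147.0), (12.5, 13.0, 13.6, 14.1)),
        "inner_lateral": AngleField((29.9, 45.1, 60.4, 75.6), (52.8, 39.7, 26.6, 13.5)),
        "outer": AngleField((24.0, 46.0, 80.0, 122.0), (28.0, 28.0, 28.0, 28.0)),
        "cej": AngleField((101.0, 101.0, 101.0, 101.0), (43.9, 43.9, 43.9, 43.9)),
    }


def _default_spacing_fields() -> dict[str, tuple[float, float, float, float]]:
    # Mean inter-centroid spacing (um) per region.  Inner-mesial compresses
    # gradually lateral->mesial; inner-lateral compresses 1->2, is flat 2->3
    # and nearly doubles 3->4; the outer layer is packed tighter than the
    # inner layer with its minimum in the central labial region; CEJ spacing
    # is intermediate.  Absolute values are calibrated from packing so that
    # the default 5063 inner profiles fit the default 124 row paths.
    return {
        "inner_mesial": (2.86, 2.52, 2.27, 2.02),
        "inner_lateral": (3.02, 2.35, 2.35, 4.50),
        "outer": (2.60, 2.20, 2.00, 2.40),
        "cej": (2.50, 2.50, 2.50, 2.50),
    }


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic enamel-band cross-section."""

    seed: int = 0
    pixels_per_um: float = 16.0
    total_profiles: int = 7233
    category_fractions: tuple[float, float, float] = (0.70, 0.27, 0.03)
    n_rows: int = 124
    thickness_um: float = 121.0
    inner_um: float = 100.0
    outer_um: float = 21.0
    #: arc radius of the DEJ in um, or the string "flat"
    curvature: float | str = 540.0
    band_length_um: float = 700.0
    angle_fields: dict[str, AngleField] = field(default_factory=_default_angle_fields)
    spacing_fields: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_spacing_fields
    )
    #: "step" (anchors are exact region means) or "linear"
    field_interpolation: str = "step"
    #: "truncated" (location-calibrated truncated normal) or "wrapped"
    angle_noise: str = "truncated"
    #: inner rod ellipse long/short axes, um
    inner_axes_um: tuple[float, float] = (1.45, 0.65)
    #: outer rhombus long/short diagonals, um
    outer_diagonals_um: tuple[float, float] = (1.3, 0.7)
    #: CEJ blob base ellipse axes and radial irregularity fraction
    cej_axes_um: tuple[float, float] = (1.3, 0.8)
    cej_irregularity: float = 0.15
    #: fraction of CEJ profiles on the mesial side
    cej_mesial_fraction: float = 5.0 / 6.0
    #: minimum polygon clearance between rendered profiles, um (>= 2 px)
    clearance_um: float = 0.3
    #: identifiers carried into output tables
    mouse_id: int = 1
    incisor_id: str = "R"
    tooth_id: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.pixels_per_um <= 0:
            raise ConfigurationError("pixels_per_um must be positive")
        if self.total_profiles <= 0:
            raise ConfigurationError("total_profiles must be positive")
        if self.thickness_um <= 0:
            raise ConfigurationError("thickness_um must be positive")
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("category_fractions must sum to 1")
        if self.n_rows <= 0 or self.n_rows % 2:
            raise ConfigurationError("n_rows must be an even positive integer")
        if abs(self.inner_um + self.outer_um - self.thickness_um) > 1e-9:
            raise ConfigurationError("inner_um + outer_um must equal thickness_um")
        if not self.is_flat and float(self.curvature) <= self.thickness_um:
            raise ConfigurationError("curvature radius must exceed band thickness")
        if self.field_interpolation not in ("step", "linear"):
            raise ConfigurationError("field_interpolation must be 'step' or 'linear'")
        if self.angle_noise not in ("truncated", "wrapped"):
            raise ConfigurationError("angle_noise must be 'truncated' or 'wrapped'")
        for name, f in self.angle_fields.items():
            f.validate(name)
        for name, s in self.spacing_fields.items():
            if len(s) != 4 or min(s) <= 0:
                raise ConfigurationError(f"spacing field {name} needs 4 positive anchors")

    @property
    def is_flat(self) -> bool:
        return isinstance(self.curvature, str) and self.curvature == "flat"

    # -- derived counts -----------------------------------------------------
    def category_counts(self) -> dict[str, int]:
        """Integer apportionment (largest remainder) of the total count."""
        inner, outer, cej = apportion(self.total_profiles, self.category_fractions)
        return {"inner": inner, "outer": outer, "cej": cej}

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["angle_fields"] = {
            k: {"anchors": list(v.anchors), "sd": list(v.sd)}
            for k, v in self.angle_fields.items()
        }
        d["spacing_fields"] = {k: list(v) for k, v in self.spacing_fields.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "angle_fields" in d:
            d["angle_fields"] = {
                k: AngleField(tuple(v["anchors"]), tuple(v["sd"]))
                for k, v in d["angle_fields"].items()
            }
        if "spacing_fields" in d:
            d["spacing_fields"] = {k: tuple(v) for k, v in d["spacing_fields"].items()}
        for key in ("category_fractions", "inner_axes_um", "outer_diagonals_um", "cej_axes_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def apportion(total: int, fractions) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``fractions``.

    Returns non-negative integers summing exactly to ``total``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if total < 0 or np.any(fractions < 0):
        raise ValueError("total and fractions must be non-negative")
    quota = total * fractions / fractions.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts.tolist()
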