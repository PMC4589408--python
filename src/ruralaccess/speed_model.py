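"""Travel-speed rules: slope-dependent walking speed, friction coefficients,
road speeds, and cell/edge crossing times.

The pedestrian model is the Naismith-Langmuir rule expressed as minutes per
kilometre of horizontal distance: a basal pace of 15 min/km (4 km/h) modified
by the metres climbed or descended along the way.  Descents are rewarded only
inside a band of moderate slope angles; steeper descents are penalised.

Friction coefficients for slope class and land use multiply crossing times;
they are exposed as plain dataclasses so a run configuration can override any
individual value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SpeedRule",
    "FrictionTable",
    "RoadSpeedTable",
    "Impassable",
    "walking_speed",
    "walking_pace_min_per_km",
    "cell_crossing_time",
    "vehicle_speed",
    "MOTORIZED_CLASSES",
    "ROAD_CLASSES",
    "LANDUSE_CLASSES",
    "SEASONS",
]

ROAD_CLASSES = ("tarmac", "loose_surface", "dry_weather", "motorable", "footpath")
#: road classes on which vehicular travel is allowed
MOTORIZED_CLASSES = frozenset({"tarmac", "loose_surface", "dry_weather", "motorable"})
LANDUSE_CLASSES = ("open", "bushy", "forest", "barrier")
SEASONS = ("dry", "wet")


class Impassable(Exception):
    """Raised when a move crosses a barrier (lake/swamp) cell."""


@dataclass(frozen=True)
class SpeedRule:
    """Parameters of the slope-adjusted walking-pace rule.

    ``basal_speed_kmh``
        flat-ground walking speed.
    ``ascent_penalty_min_per_m``
        extra minutes per metre climbed.
    ``descent_bonus_min_per_m``
        minutes saved per metre descended, applied only for descent angles
        between ``bonus_min_deg`` (exclusive) and ``bonus_max_deg``
        (inclusive).
    ``steep_descent_penalty_min_per_m``
        extra minutes per metre descended on slopes steeper than
        ``bonus_max_deg``.
    """

    basal_speed_kmh: float = 4.0
    ascent_penalty_min_per_m: float = 0.1
    descent_bonus_min_per_m: float = 0.03
    steep_descent_penalty_min_per_m: float = 0.03
    bonus_min_deg: float = 5.0
    bonus_max_deg: float = 12.0

    def __post_init__(self) -> None:
        if self.basal_speed_kmh <= 0:
            raise ValueError("basal speed must be positive")
        for name in (
            "ascent_penalty_min_per_m",
            "descent_bonus_min_per_m",
            "steep_descent_penalty_min_per_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# slope-percent class bounds (upper edges, left-closed right-open) and their
# crossing-time coefficients; the final entry is open-ended
_SLOPE_CLASS_EDGES = (20.0, 40.0, 60.0, 80.0, 100.0)
_SLOPE_CLASS_COEFFS = (0.98, 1.00, 1.20, 1.04, 1.06, 1.08)

_LANDUSE_COEFFS = {
    "dry": {"open": 0.95, "bushy": 1.00, "forest": 1.05},
    "wet": {"open": 1.00, "bushy": 1.05, "forest": 1.10},
}


@dataclass(frozen=True)
class FrictionTable:
    """Crossing-time multipliers by slope-percent class and by land use/season."""

    slope_edges: tuple[float, ...] = _SLOPE_CLASS_EDGES
    slope_coeffs: tuple[float, ...] = _SLOPE_CLASS_COEFFS
    landuse_coeffs: dict = field(default_factory=lambda: {
        season: dict(classes) for season, classes in _LANDUSE_COEFFS.items()
    })

    def __post_init__(self) -> None:
        if len(self.slope_coeffs) != len(self.slope_edges) + 1:
            raise ValueError("need one slope coefficient per class plus the open tail")
        if any(c <= 0 for c in self.slope_coeffs):
            raise ValueError("slope coefficients must be positive")
        for season, classes in self.landuse_coeffs.items():
            if any(c <= 0 for c in classes.values()):
                raise ValueError(f"land-use coefficients for {season} must be positive")

    def slope_coeff(self, slope_percent: float) -> float:
        """Coefficient for an (unsigned) slope in percent; classes are
        left-closed, right-open."""
        s = abs(slope_percent)
        for edge, coeff in zip(self.slope_edges, self.slope_coeffs):
            if s < edge:
                return coeff
        return self.slope_coeffs[-1]

    def landuse_coeff(self, landuse: str, season: str) -> float:
        if landuse == "barrier":
            raise Impassable("barrier land use has no crossing time")
        try:
            return self.landuse_coeffs[season][landuse]
        except KeyError as exc:
            raise KeyError(f"no friction coefficient for {landuse!r}/{season!r}") from exc

    def with_overrides(self, *, slope: dict | None = None,
                       landuse: dict | None = None) -> "FrictionTable":
        """Return a copy with selected coefficients replaced.

        ``slope`` maps class index -> coefficient; ``landuse`` maps
        (season, class) -> coefficient.
        """
        coeffs = list(self.slope_coeffs)
        for idx, val in (slope or {}).items():
            coeffs[idx] = float(val)
        lu = {s: dict(c) for s, c in self.landuse_coeffs.items()}
        for (season, cls), val in (landuse or {}).items():
            lu[season][cls] = float(val)
        return replace(self, slope_coeffs=tuple(coeffs), landuse_coeffs=lu)


@dataclass(frozen=True)
class RoadSpeedTable:
    """Vehicular speeds (km/h) by road class; footpath speed is pedestrian."""

    speeds_kmh: dict = field(default_factory=lambda: {
        "tarmac": 75.0,
        "loose_surface": 45.0,
        "dry_weather": 40.0,
        "motorable": 20.0,
        "footpath": 4.0,
    })

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.speeds_kmh.values()):
            raise ValueError("road speeds must be strictly positive")

    def speed(self, road_class: str) -> float:
        try:
            return self.speeds_kmh[road_class]
        except KeyError as exc:
            raise KeyError(f"unknown road class {road_class!r}") from exc

    def with_overrides(self, overrides: dict) -> "RoadSpeedTable":
        speeds = dict(self.speeds_kmh)
        speeds.update({k: float(v) for k, v in overrides.items()})
        return RoadSpeedTable(speeds_kmh=speeds)


def walking_pace_min_per_km(signed_slope: float, rule: SpeedRule | None = None) -> float:
    """Minutes needed to cover 1 km horizontally at the given signed slope.

    ``signed_slope`` is rise over run (dimensionless); positive uphill.
    """
    rule = rule or SpeedRule()
    if not math.isfinite(signed_slope):
        raise ValueError("slope must be finite")
    base = 60.0 / rule.basal_speed_kmh
    vertical_m = abs(signed_slope) * 1000.0  # metres climbed/descended per km
    if signed_slope > 0:
        return base + rule.ascent_penalty_min_per_m * vertical_m
    if signed_slope < 0:
        angle = math.degrees(math.atan(abs(signed_slope)))
        if angle <= rule.bonus_min_deg:
            return base
        if angle <= rule.bonus_max_deg:
            return base - rule.descent_bonus_min_per_m * vertical_m
        return base + rule.steep_descent_penalty_min_per_m * vertical_m
    return base


def walking_speed(signed_slope: float, rule: SpeedRule | None = None) -> float:
    """Walking speed in km/h (horizontal) at a signed rise/run slope."""
    return 60.0 / walking_pace_min_per_km(signed_slope, rule)


def cell_crossing_time(speed_kmh: float, distance_m: float,
                       slope_class_coeff: float = 1.0,
                       landuse_coeff: float = 1.0) -> float:
    """Minutes to cross ``distance_m`` at ``speed_kmh`` with friction applied."""
    if speed_kmh <= 0:
        raise ValueError("speed must be positive")
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    if slope_class_coeff <= 0 or landuse_coeff <= 0:
        raise ValueError("friction coefficients must be positive")
    return (distance_m / 1000.0) / speed_kmh * 60.0 * slope_class_coeff * landuse_coeff


def vehicle_speed(road_class: str, table: RoadSpeedTable | None = None) -> float:
    """Vehicular speed (km/h) for a road class; exact table lookup."""
    return (table or RoadSpeedTable()).speed(road_class)
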