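"""Spatial grid of soil patches and the environmental forcing that drives it.

The arena is a rectangle of 0.01 m^2 (0.1 m x 0.1 m) patches, each carrying a
food stock and a pesticide concentration.  Environmental forcing is either
fixed (laboratory scenarios) or seasonal (field scenarios): per-season mean
soil temperature, moisture and manure input, with daily normally-distributed
variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PATCH_AREA_M2 = 0.01
PATCH_SIDE_M = 0.1

#: Season rotation and lengths (days); four seasons spanning one 365-day year.
SEASONS = ("autumn", "winter", "spring", "summer")
SEASON_LENGTHS = {"autumn": 91, "winter": 91, "spring": 92, "summer": 91}


def grid_shape(arena_m2: float) -> tuple[int, int]:
    """Rows x cols of 0.01 m^2 patches for a configured arena area.

    The rectangle closest to square with the required number of patches is
    chosen (e.g. 0.08 m^2 -> 8 patches -> 2 x 4).
    """
    n = round(arena_m2 / PATCH_AREA_M2)
    if n < 1 or abs(n * PATCH_AREA_M2 - arena_m2) > PATCH_AREA_M2 / 2:
        raise ValueError(f"arena area {arena_m2} m^2 is not a whole number of 0.01 m^2 patches")
    best = (1, n)
    for rows in range(1, int(math.isqrt(n)) + 1):
        if n % rows == 0:
            best = (rows, n // rows)
    return best


class Landscape:
    """Grid of patches with food stocks (g per patch) and a uniform pesticide
    concentration (mg/kg).  Positions map to patches by flooring over the
    0.1 m patch side; boundaries are handled reflectively by the movement
    routine in the engine."""

    def __init__(self, arena_m2: float, concentration: float = 0.0):
        self.rows, self.cols = grid_shape(arena_m2)
        self.arena_m2 = self.rows * self.cols * PATCH_AREA_M2
        self.width_m = self.cols * PATCH_SIDE_M
        self.height_m = self.rows * PATCH_SIDE_M
        self.food = np.zeros((self.rows, self.cols), dtype=float)
        self.concentration = float(concentration)

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def patch_index(self, x: float, y: float) -> tuple[int, int]:
        """Patch containing position (x, y) in metres."""
        col = min(int(x / PATCH_SIDE_M), self.cols - 1)
        row = min(int(y / PATCH_SIDE_M), self.rows - 1)
        return row, col

    def deplete(self, row: int, col: int, amount: float) -> float:
        """Remove up to ``amount`` g of food from a patch; returns the amount
        actually removed (the stock floors at zero)."""
        if amount < 0:
            raise ValueError(f"depletion amount must be non-negative, got {amount}")
        stock = self.food[row, col]
        removed = amount if amount <= stock else stock
        self.food[row, col] = stock - removed
        return removed

    def add_uniform(self, total_g: float) -> None:
        """Distribute ``total_g`` g of food uniformly over all patches."""
        if total_g < 0:
            raise ValueError(f"food quantity must be non-negative, got {total_g}")
        self.food += total_g / self.n_patches

    def total_food(self) -> float:
        return float(self.food.sum())


def scheduled_feed(landscape: Landscape, schedule: list[tuple[int, float]], day: int) -> float:
    """Apply any feeding events scheduled for ``day``; food is spread
    uniformly over the landscape.  Returns the total grams added."""
    added = 0.0
    for feed_day, total_g in schedule:
        if total_g < 0:
            raise ValueError(f"feeding schedule contains negative quantity {total_g}")
        if feed_day == day:
            landscape.add_uniform(total_g)
            added += total_g
    return added


def ambient_to_soil_temperature(ambient_c: float) -> int:
    """Soil temperature inside a manure heap from ambient air temperature.

    Decomposition warms the heap by 5 degC when ambient exceeds 10 degC; the
    result is reported to the nearest whole degree.
    """
    soil = ambient_c + 5.0 if ambient_c > 10.0 else ambient_c
    return round(soil)


@dataclass
class SeasonalField:
    """Per-season environmental means for the field (manure heap) scenario.

    ``soil_temp_c`` / ``soil_moisture_pct`` are the derived seasonal soil
    values; ``manure_kg_m2`` the seasonal manure stock.  Daily draws use
    SD 5 degC for temperature and 10 percentage points for moisture; patch
    food replenishment at season boundaries uses SD 10% of the mean.
    """

    soil_temp_c: dict[str, float] = field(
        default_factory=lambda: {"autumn": 9.0, "winter": 8.0, "spring": 17.0, "summer": 21.0}
    )
    soil_moisture_pct: dict[str, float] = field(
        default_factory=lambda: {"autumn": 60.0, "winter": 40.0, "spring": 70.0, "summer": 45.0}
    )
    manure_kg_m2: dict[str, float] = field(
        default_factory=lambda: {"autumn": 10.0, "winter": 15.0, "spring": 50.0, "summer": 5.0}
    )
    temp_sd_c: float = 5.0
    moisture_sd_pct: float = 10.0
    food_cv: float = 0.10

    def food_g_per_patch(self, season: str) -> float:
        # kg/m^2 -> g per 0.01 m^2 patch
        return self.manure_kg_m2[season] * 1000.0 * PATCH_AREA_M2

    def to_dict(self) -> dict:
        return {
            "soil_temp_c": dict(self.soil_temp_c),
            "soil_moisture_pct": dict(self.soil_moisture_pct),
            "manure_kg_m2": dict(self.manure_kg_m2),
            "temp_sd_c": self.temp_sd_c,
            "moisture_sd_pct": self.moisture_sd_pct,
            "food_cv": self.food_cv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeasonalField":
        return cls(**d)


def season_of_day(day: int) -> str:
    """Season of a simulation day, rotating autumn -> winter -> spring ->
    summer with lengths 91/91/92/91 days."""
    d = day % 365
    for s in SEASONS:
        if d < SEASON_LENGTHS[s]:
            return s
        d -= SEASON_LENGTHS[s]
    return SEASONS[-1]


def is_season_start(day: int) -> bool:
    d = day % 365
    edge = 0
    for s in SEASONS:
        if d == edge:
            return True
        edge += SEASON_LENGTHS[s]
    return False


def daily_field_draw(
    fieldenv: SeasonalField, season: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one day's (soil temperature degC, soil moisture %) around the
    seasonal means; moisture is truncated to [0, 100]."""
    t = rng.normal(fieldenv.soil_temp_c[season], fieldenv.temp_sd_c)
    sm = rng.normal(fieldenv.soil_moisture_pct[season], fieldenv.moisture_sd_pct)
    return t, float(np.clip(sm, 0.0, 100.0))


def season_start_replenish(
    landscape: Landscape, fieldenv: SeasonalField, season: str, rng: np.random.Generator
) -> None:
    """Reset every patch's food stock to an independent draw around the
    seasonal target (SD ``food_cv`` of the mean, floored at zero).

    The manure-heap food supply is a managed stock — dumped in bulk, largely
    removed in late spring — so the stock is reset, not topped up.
    """
    mean = fieldenv.food_g_per_patch(season)
    draws = rng.normal(mean, fieldenv.food_cv * mean, size=landscape.food.shape)
    landscape.food = np.maximum(draws, 0.0)
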