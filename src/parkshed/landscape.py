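"""Core raster-domain types: analysis grid, disturbance stack, unit records.

Coordinate conventions (used everywhere in the package):

* pixels are addressed ``(row, col)`` with the origin at the top-left and
  half-open ranges ``[0, n_rows) x [0, n_cols)``;
* the geotransform is the only bridge to projected/world coordinates:
  ``x = origin_x + (col + 0.5) * pixel_size`` and
  ``y = origin_y - (row + 0.5) * pixel_size`` for pixel centers;
* latitude is carried per row (degrees N, strictly decreasing with row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Tuple

import numpy as np

from .errors import ParameterError

PixelSet = FrozenSet[Tuple[int, int]]

AGENT_NONE = 0
AGENT_FIRE = 1
AGENT_HARVEST = 2
AGENT_CODES = {"none": AGENT_NONE, "fire": AGENT_FIRE, "harvest": AGENT_HARVEST}
AGENT_NAMES = {v: k for k, v in AGENT_CODES.items()}

IUCN_STRICT = ("Ia", "Ib", "II", "IV")
IUCN_ALL = ("Ia", "Ib", "II", "III", "IV", "V", "VI")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic landscape scenario.

    Rates are expected fractions of land pixels disturbed per year at the
    extreme rows; intensity is interpolated linearly in latitude between them.
    Fire intensity increases northward, harvest southward, reflecting the
    Canadian pattern of unsuppressed northern wildfire and southern managed
    forest.
    """

    n_rows: int = 100
    n_cols: int = 100
    pixel_size_m: float = 30.0
    lat_top: float = 62.0
    lat_bottom: float = 45.0
    n_ppas: int = 20
    ppa_area_range_px: Tuple[int, int] = (20, 80)
    water_fraction: float = 0.05
    agri_fraction: float = 0.05
    fire_rate_north: float = 0.02
    fire_rate_south: float = 0.0002
    harvest_rate_south: float = 0.008
    harvest_rate_north: float = 0.0
    mean_patch_size_px: float = 25.0
    year_range: Tuple[int, int] = (1985, 2015)
    establishment_year_range: Tuple[int, int] = (1950, 2006)
    master_seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("n_rows/n_cols must be >= 1")
        if self.pixel_size_m <= 0:
            raise ParameterError("pixel_size_m must be positive")
        if not self.lat_top > self.lat_bottom:
            raise ParameterError("lat_top must exceed lat_bottom")
        for name in ("water_fraction", "agri_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "fire_rate_north",
            "fire_rate_south",
            "harvest_rate_south",
            "harvest_rate_north",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_ppas < 0:
            raise ParameterError("n_ppas must be >= 0")
        lo, hi = self.ppa_area_range_px
        if lo < 1 or hi < lo:
            raise ParameterError("ppa_area_range_px must satisfy 1 <= min <= max")
        if self.mean_patch_size_px < 1:
            raise ParameterError("mean_patch_size_px must be >= 1")
        y0, y1 = self.year_range
        if not y0 < y1:
            raise ParameterError("year_range start must precede end")
        e0, e1 = self.establishment_year_range
        if e0 > e1:
            raise ParameterError("establishment_year_range min must be <= max")
        return self


@dataclass
class LandscapeGrid:
    """Analysis grid: geometry plus water/agriculture masks.

    A pixel is *land* iff it is in neither mask; only land pixels carry
    disturbance events or enter protected-area footprints and neighbourhood
    samples.
    """

    n_rows: int
    n_cols: int
    pixel_size_m: float
    lat_top: float
    lat_bottom: float
    water_mask: np.ndarray
    agri_mask: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self):
        shape = (self.n_rows, self.n_cols)
        if self.water_mask.shape != shape or self.agri_mask.shape != shape:
            raise ParameterError("masks must have shape (n_rows, n_cols)")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def land_mask(self) -> np.ndarray:
        return ~(self.water_mask | self.agri_mask)

    @property
    def latitude_of_row(self) -> np.ndarray:
        """Latitude (degrees N) at each row center; strictly decreasing."""
        step = (self.lat_top - self.lat_bottom) / self.n_rows
        return self.lat_top - (np.arange(self.n_rows) + 0.5) * step

    @property
    def geotransform(self) -> Tuple[float, float, float, float, float, float]:
        """GDAL-style affine (x0, dx, 0, y0, 0, -dy), origin at top-left corner."""
        return (
            self.origin_x,
            self.pixel_size_m,
            0.0,
            self.origin_y,
            0.0,
            -self.pixel_size_m,
        )

    def pixel_center(self, row, col) -> Tuple[np.ndarray, np.ndarray]:
        """World coordinates of pixel centers (vectorized)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.pixel_size_m
        y = self.origin_y - (row + 0.5) * self.pixel_size_m
        return x, y

    def latitude_at_row(self, row) -> np.ndarray:
        """Latitude at a (possibly fractional) row coordinate."""
        row = np.asarray(row, dtype=float)
        step = (self.lat_top - self.lat_bottom) / self.n_rows
        return self.lat_top - (row + 0.5) * step


@dataclass
class DisturbanceStack:
    """Per-pixel disturbance events: year (0 = none) and agent class.

    One event per pixel; ``event_agent == none`` iff ``event_year == 0``.
    """

    event_year: np.ndarray
    event_agent: np.ndarray

    def __post_init__(self):
        if self.event_year.shape != self.event_agent.shape:
            raise ParameterError("event_year and event_agent must share shape")

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "DisturbanceStack":
        return cls(
            event_year=np.zeros(shape, dtype=np.int16),
            event_agent=np.zeros(shape, dtype=np.uint8),
        )

    def validate(self) -> "DisturbanceStack":
        none_agent = self.event_agent == AGENT_NONE
        no_year = self.event_year == 0
        if not np.array_equal(none_agent, no_year):
            raise ParameterError("event_agent = none must coincide with event_year = 0")
        return self

    @property
    def shape(self) -> Tuple[int, int]:
        return self.event_year.shape


@dataclass
class PPARecord:
    """One park or protected area rasterized onto the analysis grid."""

    id: str
    footprint: PixelSet
    establishment_year: int
    iucn: str
    ecozone: Optional[str] = None

    def __post_init__(self):
        self.footprint = frozenset((int(r), int(c)) for r, c in self.footprint)

    @property
    def n_pixels(self) -> int:
        return len(self.footprint)

    def footprint_array(self) -> np.ndarray:
        """(k, 2) array of footprint pixels, lexicographically sorted."""
        return pixels_to_array(self.footprint)

    def centroid(self) -> Tuple[float, float]:
        """Area-weighted mean (row, col) of the land footprint's pixel centers."""
        arr = self.footprint_array()
        if arr.size == 0:
            raise ParameterError(f"PPA {self.id} has an empty footprint")
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def area_ha(self, pixel_size_m: float) -> float:
        return self.n_pixels * pixel_size_m**2 / 10_000.0


@dataclass
class EcozonePolygon:
    """A broad ecological stratification unit, as a polygon in world coordinates."""

    id: str
    geometry: object  # shapely geometry
    name: str = ""


def pixels_to_array(pixels) -> np.ndarray:
    """Sorted (k, 2) int array from any iterable of (row, col) pairs."""
    if len(pixels) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.array(sorted((int(r), int(c)) for r, c in pixels), dtype=np.int64)
    return arr


def pixel_bool_mask(pixels, shape) -> np.ndarray:
    """Boolean raster with True at each (row, col) in ``pixels``."""
    mask = np.zeros(shape, dtype=bool)
    if len(pixels):
        arr = pixels_to_array(pixels)
        mask[arr[:, 0], arr[:, 1]] = True
    return mask
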