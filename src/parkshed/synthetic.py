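"""Synthetic landscape scenarios.

Generates complete test scenarios — grid with water/agriculture masks,
protected-area footprints, and three decades of fire and harvest events —
with the spatial structure the downstream analysis assumes:

* fires are contiguous patches placed independently of protected-area
  boundaries, with expected intensity increasing with latitude (northern
  wildfire is rarely suppressed);
* harvest patches are strictly excluded from protected-area interiors, with
  intensity decreasing with latitude (commercial forestry concentrates in
  southern managed forests);
* neither agent ever disturbs water or agriculture pixels, and each pixel
  carries at most one event.

All randomness flows from one master seed through named substreams
(:mod:`parkshed.rng`), so scenarios are bit-reproducible.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np
from shapely.geometry import box

from .errors import ParameterError, PlacementError
from .landscape import (
    AGENT_FIRE,
    AGENT_HARVEST,
    IUCN_STRICT,
    DisturbanceStack,
    EcozonePolygon,
    LandscapeGrid,
    PPARecord,
    ScenarioConfig,
    pixel_bool_mask,
)
from .rng import substream

logger = logging.getLogger(__name__)

_NEIGHBOURS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def grow_patch(
    rng: np.random.Generator,
    allowed: np.ndarray,
    seed_pixel,
    target_size: int,
) -> List[tuple]:
    """Stochastic 4-neighbour region growth from ``seed_pixel``.

    Adds uniformly chosen frontier pixels until ``target_size`` is reached or
    no allowed neighbour remains; the result is always contiguous.  The
    caller's ``allowed`` mask is not modified.
    """
    r0, c0 = seed_pixel
    if not allowed[r0, c0]:
        return []
    n_rows, n_cols = allowed.shape
    region = {(r0, c0)}
    order = [(r0, c0)]
    frontier = []
    for dr, dc in _NEIGHBOURS:
        r, c = r0 + dr, c0 + dc
        if 0 <= r < n_rows and 0 <= c < n_cols and allowed[r, c]:
            frontier.append((r, c))
    while len(region) < target_size and frontier:
        idx = int(rng.integers(len(frontier)))
        frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
        pix = frontier.pop()
        if pix in region:
            continue
        region.add(pix)
        order.append(pix)
        for dr, dc in _NEIGHBOURS:
            r, c = pix[0] + dr, pix[1] + dc
            if (
                0 <= r < n_rows
                and 0 <= c < n_cols
                and allowed[r, c]
                and (r, c) not in region
            ):
                frontier.append((r, c))
    return order


def _grow_mask(rng, shape, fraction, mean_blob_px) -> np.ndarray:
    """Contiguous blobs covering approximately ``fraction`` of the grid."""
    mask = np.zeros(shape, dtype=bool)
    n_pixels = shape[0] * shape[1]
    target = int(round(fraction * n_pixels))
    if target <= 0:
        return mask
    count = 0
    guard = 0
    while count < target and guard < 100 * target:
        guard += 1
        seed = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        if mask[seed]:
            continue
        size = min(int(rng.geometric(1.0 / mean_blob_px)), target - count)
        patch = grow_patch(rng, ~mask, seed, max(size, 1))
        for r, c in patch:
            mask[r, c] = True
        count += len(patch)
    return mask


def generate_landscape(config: ScenarioConfig) -> LandscapeGrid:
    """Build the grid and realize water/agriculture masks as contiguous blobs.

    Blob totals land within ±20% (relative) of the requested fractions;
    deterministic given ``config.master_seed``.
    """
    config.validate()
    shape = (config.n_rows, config.n_cols)
    water = _grow_mask(
        substream(config.master_seed, "water"),
        shape,
        config.water_fraction,
        config.mean_patch_size_px,
    )
    agri = _grow_mask(
        substream(config.master_seed, "agri"),
        shape,
        config.agri_fraction,
        config.mean_patch_size_px,
    )
    return LandscapeGrid(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        pixel_size_m=config.pixel_size_m,
        lat_top=config.lat_top,
        lat_bottom=config.lat_bottom,
        water_mask=water,
        agri_mask=agri,
    )


def place_ppas(
    grid: LandscapeGrid,
    config: ScenarioConfig,
    retry_budget: int = 200,
) -> List[PPARecord]:
    """Place ``n_ppas`` pairwise-disjoint contiguous footprints on land pixels.

    Sizes are drawn uniformly within ``ppa_area_range_px``; establishment
    years uniformly within ``establishment_year_range``; IUCN classes
    uniformly from the strict categories Ia/Ib/II/IV.

    Raises :class:`PlacementError` (reporting how many were placed) if the
    requested count cannot be achieved within the retry budget.
    """
    config.validate()
    rng = substream(config.master_seed, "ppas")
    available = grid.land_mask.copy()
    land_total = int(available.sum())
    records: List[PPARecord] = []
    lo, hi = config.ppa_area_range_px
    e0, e1 = config.establishment_year_range
    for i in range(config.n_ppas):
        placed = False
        for _ in range(retry_budget):
            target = int(rng.integers(lo, hi + 1))
            flat = np.flatnonzero(available)
            if flat.size == 0:
                break
            pick = int(flat[int(rng.integers(flat.size))])
            seed = (pick // grid.n_cols, pick % grid.n_cols)
            patch = grow_patch(rng, available, seed, target)
            if len(patch) == target:
                for r, c in patch:
                    available[r, c] = False
                records.append(
                    PPARecord(
                        id=f"PPA{i:04d}",
                        footprint=frozenset(patch),
                        establishment_year=int(rng.integers(e0, e1 + 1)),
                        iucn=str(rng.choice(IUCN_STRICT)),
                    )
                )
                placed = True
                break
        if not placed:
            raise PlacementError(requested=config.n_ppas, placed=len(records))
    logger.info(
        "placed %d PPAs covering %d of %d land pixels",
        len(records),
        sum(p.n_pixels for p in records),
        land_total,
    )
    return records


def _rate_per_row(grid: LandscapeGrid, rate_south: float, rate_north: float) -> np.ndarray:
    """Expected annual disturbed fraction per row, linear in latitude."""
    lat = grid.latitude_of_row
    frac = (lat - grid.lat_bottom) / (grid.lat_top - grid.lat_bottom)
    return rate_south + (rate_north - rate_south) * frac


def _simulate_agent(
    grid: LandscapeGrid,
    config: ScenarioConfig,
    stack: DisturbanceStack,
    agent_code: int,
    rate_per_row: np.ndarray,
    eligible: np.ndarray,
    tag: str,
) -> DisturbanceStack:
    """Seed Poisson ignitions row-weighted by intensity; grow each into a patch.

    ``eligible`` limits both ignition and spread (land minus any exclusions);
    pixels already carrying an event are skipped, so each pixel keeps its
    first event.
    """
    land_per_row = eligible.sum(axis=1).astype(float)
    weights = rate_per_row * land_per_row
    expected_per_year = float(weights.sum())
    if expected_per_year <= 0:
        return stack
    row_probs = weights / weights.sum()
    y0, y1 = config.year_range
    for year in range(y0, y1 + 1):
        rng = substream(config.master_seed, tag, year)
        n_patches = int(rng.poisson(expected_per_year / config.mean_patch_size_px))
        allowed = eligible & (stack.event_year == 0)
        for _ in range(n_patches):
            row = int(rng.choice(grid.n_rows, p=row_probs))
            cols = np.flatnonzero(allowed[row])
            if cols.size == 0:
                continue
            col = int(cols[int(rng.integers(cols.size))])
            size = int(rng.geometric(1.0 / config.mean_patch_size_px))
            patch = grow_patch(rng, allowed, (row, col), size)
            for r, c in patch:
                stack.event_year[r, c] = year
                stack.event_agent[r, c] = agent_code
                allowed[r, c] = False
    return stack


def simulate_fire_events(
    grid: LandscapeGrid,
    ppas: Sequence[PPARecord],
    config: ScenarioConfig,
    stack: Optional[DisturbanceStack] = None,
) -> DisturbanceStack:
    """Add wildfire events: patches cross protected-area boundaries freely,
    stopping only at water/agriculture; intensity interpolates from
    ``fire_rate_south`` to ``fire_rate_north`` by row latitude."""
    if stack is None:
        stack = DisturbanceStack.empty(grid.shape)
    rates = _rate_per_row(grid, config.fire_rate_south, config.fire_rate_north)
    return _simulate_agent(
        grid, config, stack, AGENT_FIRE, rates, grid.land_mask, "fire"
    )


def simulate_harvest_events(
    grid: LandscapeGrid,
    ppas: Sequence[PPARecord],
    config: ScenarioConfig,
    stack: Optional[DisturbanceStack] = None,
) -> DisturbanceStack:
    """Add harvest events: same patch mechanism as fire, but candidate pixels
    strictly exclude every protected-area footprint; intensity interpolates
    from ``harvest_rate_south`` (high) to ``harvest_rate_north`` (low)."""
    if stack is None:
        stack = DisturbanceStack.empty(grid.shape)
    excluded = np.zeros(grid.shape, dtype=bool)
    for ppa in ppas:
        excluded |= pixel_bool_mask(ppa.footprint, grid.shape)
    eligible = grid.land_mask & ~excluded
    rates = _rate_per_row(grid, config.harvest_rate_south, config.harvest_rate_north)
    return _simulate_agent(
        grid, config, stack, AGENT_HARVEST, rates, eligible, "harvest"
    )


def generate_ecozones(grid: LandscapeGrid, n_zones: int = 3) -> List[EcozonePolygon]:
    """Horizontal latitude bands as ecozone polygons (world coordinates).

    A deliberately simple stratification: bands are the synthetic analogue of
    broad ecological zones ordered north to south.
    """
    if n_zones < 1:
        raise ParameterError("n_zones must be >= 1")
    edges = np.linspace(0, grid.n_rows, n_zones + 1)
    zones = []
    for i in range(n_zones):
        r0, r1 = edges[i], edges[i + 1]
        x0, _ = grid.origin_x, None
        x1 = grid.origin_x + grid.n_cols * grid.pixel_size_m
        y_top = grid.origin_y - r0 * grid.pixel_size_m
        y_bot = grid.origin_y - r1 * grid.pixel_size_m
        zones.append(
            EcozonePolygon(
                id=f"EZ{i}",
                geometry=box(x0, y_bot, x1, y_top),
                name=f"band {i} (north={i == 0})",
            )
        )
    return zones


def generate_scenario(config: ScenarioConfig, n_ecozones: int = 3):
    """Full scenario: grid, protected areas, ecozones, and event stack.

    Fire is simulated before harvest, so on the rare pixel both agents reach,
    fire wins (one event per pixel).
    """
    grid = generate_landscape(config)
    ppas = place_ppas(grid, config)
    zones = generate_ecozones(grid, n_zones=n_ecozones)
    stack = simulate_fire_events(grid, ppas, config)
    stack = simulate_harvest_events(grid, ppas, config, stack)
    stack.validate()
    return grid, ppas, zones, stack
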