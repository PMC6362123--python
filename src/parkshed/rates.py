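"""Eligibility filtering and percent-area-disturbed-per-year computation.

Rates are computed identically for protected areas, their GPE samples, and
whole ecozones: 100 x disturbed land pixels / land pixels / years analysed.
The year count is inclusive (1985-2015 spans 31 years).  Units protected
only for part of the window are truncated to their protection period, and
the same truncated period applies to the unit's GPE sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import shapely

from .errors import PreconditionError, UndefinedRateError
from .landscape import (
    AGENT_CODES,
    AGENT_FIRE,
    AGENT_HARVEST,
    DisturbanceStack,
    EcozonePolygon,
    LandscapeGrid,
    PPARecord,
    pixels_to_array,
)

logger = logging.getLogger(__name__)

ELIGIBLE_IUCN = frozenset({"Ia", "Ib", "II", "IV"})
MIN_AREA_M2 = 1_000_000.0  # 100 ha
MIN_TENURE_YEARS = 10


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive year window; 1985-2015 counts 31 years."""

    start_year: int = 1985
    end_year: int = 2015

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise PreconditionError(
                f"window start {self.start_year} after end {self.end_year}"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass(frozen=True)
class DisturbanceRate:
    unit_id: str
    unit_kind: str  # PPA | GPE | ECOZONE
    agent: str  # fire | harvest | total
    land_pixels: int
    disturbed_pixels: int
    start_year: int
    end_year: int

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def rate_pct_per_yr(self) -> float:
        return 100.0 * self.disturbed_pixels / self.land_pixels / self.n_years


class FilterResult(NamedTuple):
    eligible: List[PPARecord]
    excluded: List[Tuple[str, str]]  # (ppa_id, primary reason)


def filter_ppas(
    ppas: Sequence[PPARecord],
    window: AnalysisWindow,
    pixel_size_m: float = 30.0,
    min_area_m2: float = MIN_AREA_M2,
    min_tenure_years: int = MIN_TENURE_YEARS,
    eligible_iucn: frozenset = ELIGIBLE_IUCN,
) -> FilterResult:
    """Apply the study's eligibility rules.

    Keeps units with land area >= 100 ha (pixel count x pixel area, not a
    rounded pixel threshold), a strict IUCN class (Ia/Ib/II/IV), and at
    least 10 years of protection by the window's end.  The first failing
    rule — area, then category, then tenure — is the recorded reason.
    """
    eligible, excluded = [], []
    latest_est = window.end_year - (min_tenure_years - 1)
    for ppa in ppas:
        area_m2 = ppa.n_pixels * pixel_size_m**2
        if area_m2 < min_area_m2:
            excluded.append((ppa.id, "area"))
        elif ppa.iucn not in eligible_iucn:
            excluded.append((ppa.id, "category"))
        elif ppa.establishment_year > latest_est:
            excluded.append((ppa.id, "tenure"))
        else:
            eligible.append(ppa)
    for pid, reason in excluded:
        logger.info("PPA %s excluded (%s)", pid, reason)
    return FilterResult(eligible, excluded)


def effective_period(ppa: PPARecord, window: AnalysisWindow) -> AnalysisWindow:
    """Truncate the window to the unit's protection period.

    A unit established after the window start is assessed only from its
    establishment year; its GPE sample uses the same period.
    """
    start = max(window.start_year, ppa.establishment_year)
    if start > window.end_year:
        raise PreconditionError(
            f"PPA {ppa.id}: establishment {ppa.establishment_year} after window end"
        )
    return AnalysisWindow(start, window.end_year)


def compute_rate(
    pixels,
    stack: DisturbanceStack,
    period: AnalysisWindow,
    agent: str,
    unit_id: str = "",
    unit_kind: str = "PPA",
) -> DisturbanceRate:
    """Percent of the pixel set disturbed per year by ``agent`` in ``period``.

    ``agent`` is "fire", "harvest", or "total" (fire plus harvest; these
    never overlap since a pixel carries one event).
    """
    arr = pixels_to_array(pixels)
    if arr.shape[0] == 0:
        raise UndefinedRateError(f"unit {unit_id}: no land pixels, rate undefined")
    years = stack.event_year[arr[:, 0], arr[:, 1]]
    agents = stack.event_agent[arr[:, 0], arr[:, 1]]
    in_window = (years >= period.start_year) & (years <= period.end_year)
    if agent == "total":
        agent_match = agents != 0
    elif agent in ("fire", "harvest"):
        agent_match = agents == AGENT_CODES[agent]
    else:
        raise PreconditionError(f"unknown agent {agent!r}")
    disturbed = int((in_window & agent_match).sum())
    return DisturbanceRate(
        unit_id=unit_id,
        unit_kind=unit_kind,
        agent=agent,
        land_pixels=int(arr.shape[0]),
        disturbed_pixels=disturbed,
        start_year=period.start_year,
        end_year=period.end_year,
    )


def assign_ecozone(
    ppa: PPARecord,
    ecozones: Sequence[EcozonePolygon],
    grid: LandscapeGrid,
) -> Optional[str]:
    """Ecozone containing the area-weighted centroid of the land footprint.

    A centroid exactly on a shared boundary goes to the lexicographically
    smallest ecozone id; a centroid outside every zone returns None (the
    unit is excluded from ecozone-level analyses with a warning).
    """
    row, col = ppa.centroid()
    x, y = grid.pixel_center(row, col)
    point = shapely.Point(float(x), float(y))
    hits = sorted(z.id for z in ecozones if z.geometry.covers(point))
    if not hits:
        logger.warning("PPA %s: centroid outside all ecozones; unassigned", ppa.id)
        return None
    return hits[0]


def rasterize_ecozone(zone: EcozonePolygon, grid: LandscapeGrid) -> frozenset:
    """Land pixels whose centers fall in the ecozone polygon."""
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    x, y = grid.pixel_center(rows.ravel(), cols.ravel())
    inside = shapely.intersects_xy(zone.geometry, x, y)
    keep = inside & grid.land_mask.ravel()
    pix = np.flatnonzero(keep)
    return frozenset((int(p // grid.n_cols), int(p % grid.n_cols)) for p in pix)


def ecozone_rate(
    zone: EcozonePolygon,
    stack: DisturbanceStack,
    grid: LandscapeGrid,
    window: AnalysisWindow,
    agent: str,
) -> DisturbanceRate:
    """Zone-wide rate over all its land pixels, full window (no truncation)."""
    pixels = rasterize_ecozone(zone, grid)
    if not pixels:
        raise UndefinedRateError(f"ecozone {zone.id}: zero land pixels")
    return compute_rate(
        pixels, stack, window, agent, unit_id=zone.id, unit_kind="ECOZONE"
    )


def rate_rows(rates: Iterable[DisturbanceRate]) -> List[dict]:
    """Serialize rates to the CSV row schema of :mod:`parkshed.io`."""
    return [
        {
            "ppa_id": r.unit_id,
            "unit": r.unit_kind,
            "agent": r.agent,
            "start_year": r.start_year,
            "end_year": r.end_year,
            "land_pixels": r.land_pixels,
            "disturbed_pixels": r.disturbed_pixels,
            "rate_pct_per_yr": r.rate_pct_per_yr,
        }
        for r in rates
    ]
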