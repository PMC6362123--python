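"""Raster and vector I/O for the pipeline.

Rasters are single-band GeoTIFFs (int16 event year, uint8 agent codes,
uint8 masks) written through :mod:`tifffile`, carrying the georeferencing in
the standard GeoTIFF ModelPixelScale/ModelTiepoint tags.  Vectors are
GeoJSON in world coordinates.  Tables are CSV with a stable column order.

The single rasterization convention everywhere: a pixel belongs to a polygon
iff its *center* falls inside (boundary counts as inside).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .errors import AlignmentError, FormatError
from .landscape import (
    AGENT_CODES,
    DisturbanceStack,
    EcozonePolygon,
    LandscapeGrid,
    PPARecord,
)

logger = logging.getLogger(__name__)

# GeoTIFF georeferencing tags
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

RATE_COLUMNS = [
    "ppa_id",
    "unit",
    "agent",
    "start_year",
    "end_year",
    "land_pixels",
    "disturbed_pixels",
    "rate_pct_per_yr",
]
COMPARISON_COLUMNS = [
    "ecozone",
    "agent",
    "n_pairs",
    "mean_ppa",
    "mean_gpe",
    "t_stat",
    "p_value",
    "significant",
]


def write_raster(path, array: np.ndarray, grid: LandscapeGrid) -> None:
    """Write a single-band GeoTIFF with the grid's geotransform."""
    px = grid.pixel_size_m
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]
    tifffile.imwrite(str(path), np.ascontiguousarray(array), extratags=extratags)


def read_raster(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a single-band GeoTIFF; returns (array, (pixel_size, origin_x, origin_y))."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
    return array, (float(scale[0]), float(tie[3]), float(tie[4]))


def read_disturbance_rasters(year_path, agent_path) -> DisturbanceStack:
    """Load and validate an event-year / event-agent raster pair.

    Enforces the one-event consistency rule (agent = none iff year = 0),
    coercing violating pixels to no-event with a logged count.
    """
    year, geo_y = read_raster(year_path)
    agent, geo_a = read_raster(agent_path)
    if year.shape != agent.shape:
        raise AlignmentError(
            f"shape mismatch: {year.shape} (year) vs {agent.shape} (agent)"
        )
    if not np.allclose(geo_y, geo_a):
        raise AlignmentError(f"geotransform mismatch: {geo_y} vs {geo_a}")
    known = np.isin(agent, list(AGENT_CODES.values()))
    if not known.all():
        bad = sorted(int(v) for v in np.unique(agent[~known]))
        raise FormatError(f"unknown agent codes in {agent_path}: {bad}")
    year = year.astype(np.int16).copy()
    agent = agent.astype(np.uint8).copy()
    inconsistent = (agent == 0) != (year == 0)
    n_bad = int(inconsistent.sum())
    if n_bad:
        logger.warning("coerced %d inconsistent event pixels to no-event", n_bad)
        year[inconsistent] = 0
        agent[inconsistent] = 0
    return DisturbanceStack(event_year=year, event_agent=agent).validate()


def write_stack(out_dir, stack: DisturbanceStack, grid: LandscapeGrid) -> Tuple[Path, Path]:
    out_dir = Path(out_dir)
    year_path = out_dir / "event_year.tif"
    agent_path = out_dir / "event_agent.tif"
    write_raster(year_path, stack.event_year.astype(np.int16), grid)
    write_raster(agent_path, stack.event_agent.astype(np.uint8), grid)
    return year_path, agent_path


def write_masks(out_dir, grid: LandscapeGrid) -> Tuple[Path, Path]:
    out_dir = Path(out_dir)
    water_path = out_dir / "water_mask.tif"
    agri_path = out_dir / "agri_mask.tif"
    write_raster(water_path, grid.water_mask.astype(np.uint8), grid)
    write_raster(agri_path, grid.agri_mask.astype(np.uint8), grid)
    return water_path, agri_path


def _pixel_polygon(grid: LandscapeGrid, pixels) -> shapely.Geometry:
    """Union of pixel squares in world coordinates (for writing footprints)."""
    px = grid.pixel_size_m
    boxes = [
        shapely.box(
            grid.origin_x + c * px,
            grid.origin_y - (r + 1) * px,
            grid.origin_x + (c + 1) * px,
            grid.origin_y - r * px,
        )
        for r, c in sorted(pixels)
    ]
    return shapely.union_all(boxes)


def write_ppas_geojson(path, ppas: Sequence[PPARecord], grid: LandscapeGrid) -> None:
    features = []
    for ppa in ppas:
        geom = _pixel_polygon(grid, ppa.footprint)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "id": ppa.id,
                    "establishment_year": ppa.establishment_year,
                    "iucn": ppa.iucn,
                    "ecozone": ppa.ecozone,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ppa_polygons(path) -> List[Tuple[shapely.Geometry, dict]]:
    """Read PPA polygons; each feature must carry id, establishment_year, iucn."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = props.get("id", f"feature {i}")
        for key in ("id", "establishment_year", "iucn"):
            if props.get(key) is None:
                raise FormatError(f"feature {fid}: missing required property '{key}'")
        out.append((shape(feat["geometry"]), props))
    return out


def rasterize_ppas(
    polygons: Iterable[Tuple[shapely.Geometry, dict]],
    grid: LandscapeGrid,
) -> List[PPARecord]:
    """Map polygons to pixel footprints by the center-inclusion rule.

    The footprint keeps only land pixels (water/agriculture removed before
    any area is counted); polygons left with no land pixel are dropped with
    a warning.
    """
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    x, y = grid.pixel_center(rows.ravel(), cols.ravel())
    land = grid.land_mask.ravel()
    records = []
    for geom, props in polygons:
        minx, miny, maxx, maxy = geom.bounds
        bbox = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
        inside = np.zeros(x.shape, dtype=bool)
        idx = np.flatnonzero(bbox)
        if idx.size:
            inside[idx] = shapely.intersects_xy(geom, x[idx], y[idx])
        keep = inside & land
        if not keep.any():
            logger.warning("PPA %s: no land pixels on grid; dropped", props["id"])
            continue
        pix = np.flatnonzero(keep)
        footprint = frozenset(
            (int(p // grid.n_cols), int(p % grid.n_cols)) for p in pix
        )
        records.append(
            PPARecord(
                id=str(props["id"]),
                footprint=footprint,
                establishment_year=int(props["establishment_year"]),
                iucn=str(props["iucn"]),
                ecozone=props.get("ecozone"),
            )
        )
    return records


def write_ecozones_geojson(path, zones: Sequence[EcozonePolygon]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(z.geometry),
            "properties": {"id": z.id, "name": z.name},
        }
        for z in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ecozones_geojson(path) -> List[EcozonePolygon]:
    with open(path) as fh:
        doc = json.load(fh)
    zones = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if props.get("id") is None:
            raise FormatError(f"ecozone feature {i}: missing required property 'id'")
        zones.append(
            EcozonePolygon(
                id=str(props["id"]),
                geometry=shape(feat["geometry"]),
                name=str(props.get("name", "")),
            )
        )
    return zones


def write_gpe_points(path, samples, grid: LandscapeGrid) -> None:
    """GPE sample pixels as a GeoJSON point collection (pixel centers)."""
    features = []
    for s in samples:
        for r, c in sorted(s.sample):
            x, y = grid.pixel_center(r, c)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {"ppa_id": s.ppa_id},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_gpe_points(path, grid: LandscapeGrid) -> dict:
    """Inverse of :func:`write_gpe_points`: ppa_id -> frozenset of (row, col)."""
    with open(path) as fh:
        doc = json.load(fh)
    out: dict = {}
    px = grid.pixel_size_m
    for feat in doc.get("features", []):
        x, y = feat["geometry"]["coordinates"]
        col = int(np.floor((x - grid.origin_x) / px))
        row = int(np.floor((grid.origin_y - y) / px))
        out.setdefault(feat["properties"]["ppa_id"], set()).add((row, col))
    return {k: frozenset(v) for k, v in out.items()}


def write_rate_table(rows, path) -> None:
    """Rate table CSV; ``rows`` is an iterable of dicts or a DataFrame."""
    df = pd.DataFrame(list(rows), columns=RATE_COLUMNS)
    df.to_csv(path, index=False, columns=RATE_COLUMNS)


def read_rate_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_comparison_table(rows, path) -> None:
    df = pd.DataFrame(list(rows), columns=COMPARISON_COLUMNS)
    df.to_csv(path, index=False, columns=COMPARISON_COLUMNS)


def read_comparison_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config_yaml(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
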