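"""End-to-end orchestration: simulate -> delineate -> rates -> compare.

One YAML config and one master seed drive a full run; re-running with an
identical config produces byte-identical CSV outputs.  A run manifest
records the config hash, seed, per-stage counts and timings, and every
excluded unit with its primary reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .errors import ConfigError
from .gpe import DEFAULT_MAX_RADIUS_PX, GPESample, delineate_all
from .landscape import DisturbanceStack, EcozonePolygon, LandscapeGrid, PPARecord, ScenarioConfig
from .rates import (
    AnalysisWindow,
    assign_ecozone,
    compute_rate,
    ecozone_rate,
    effective_period,
    filter_ppas,
    rate_rows,
)
from .stats import (
    DEFAULT_ALPHA,
    LATITUDE_SPLIT_DEG,
    OCCURRENCE_THRESHOLD,
    bin_by_latitude,
    correlation_summary,
    paired_ttest,
    pct_units_disturbed,
    split_by_latitude,
)
from .synthetic import generate_scenario

logger = logging.getLogger(__name__)

ANALYSIS_DEFAULTS = {
    "window": [1985, 2015],
    "alpha": DEFAULT_ALPHA,
    "occurrence_threshold_pct_yr": OCCURRENCE_THRESHOLD,
    "latitude_split_deg": LATITUDE_SPLIT_DEG,
    "max_radius_px": DEFAULT_MAX_RADIUS_PX,
    "min_area_ha": 100.0,
    "min_tenure_years": 10,
    "n_ecozones": 3,
    "holm_correction": False,
}

_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}
AGENTS = ("fire", "harvest", "total")


def validate_config(doc: Optional[dict]) -> dict:
    """Normalize a config document: fill defaults, reject unknown keys,
    report every violation (not just the first)."""
    doc = doc or {}
    errors: List[str] = []
    if not isinstance(doc, dict):
        raise ConfigError(["config document must be a mapping"])
    unknown_top = set(doc) - {"scenario", "analysis"}
    for key in sorted(unknown_top):
        errors.append(f"unknown key '{key}'")
    scen_doc = doc.get("scenario") or {}
    for key in sorted(set(scen_doc) - _SCENARIO_FIELDS):
        errors.append(f"unknown key 'scenario.{key}'")
    ana_doc = doc.get("analysis") or {}
    for key in sorted(set(ana_doc) - set(ANALYSIS_DEFAULTS)):
        errors.append(f"unknown key 'analysis.{key}'")

    scen_kwargs = {k: v for k, v in scen_doc.items() if k in _SCENARIO_FIELDS}
    for key in ("ppa_area_range_px", "year_range", "establishment_year_range"):
        if key in scen_kwargs and isinstance(scen_kwargs[key], list):
            scen_kwargs[key] = tuple(scen_kwargs[key])
    try:
        scenario = ScenarioConfig(**scen_kwargs)
        scenario.validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"scenario: {exc}")
        scenario = None

    analysis = dict(ANALYSIS_DEFAULTS)
    analysis.update({k: v for k, v in ana_doc.items() if k in ANALYSIS_DEFAULTS})
    if not 0 < analysis["alpha"] < 1:
        errors.append(f"analysis.alpha must be in (0, 1), got {analysis['alpha']}")
    if analysis["occurrence_threshold_pct_yr"] < 0:
        errors.append("analysis.occurrence_threshold_pct_yr must be >= 0")
    if analysis["max_radius_px"] < 1:
        errors.append("analysis.max_radius_px must be >= 1")
    if analysis["min_tenure_years"] < 0:
        errors.append("analysis.min_tenure_years must be >= 0")
    if analysis["n_ecozones"] < 1:
        errors.append("analysis.n_ecozones must be >= 1")
    w = analysis["window"]
    if not (isinstance(w, (list, tuple)) and len(w) == 2 and w[0] <= w[1]):
        errors.append(f"analysis.window must be [start, end] with start <= end, got {w}")
    if errors:
        raise ConfigError(errors)
    return {
        "scenario": dataclasses.asdict(scenario),
        "analysis": analysis,
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def analyze(
    grid: LandscapeGrid,
    ppas: List[PPARecord],
    zones: List[EcozonePolygon],
    stack: DisturbanceStack,
    analysis: dict,
    master_seed: int,
) -> dict:
    """Run delineation, rate computation and the comparison layer in memory.

    Returns a dict of DataFrames (rates, comparisons, correlations,
    latitude_bins, latitude_split, occurrence, gpe_manifest) plus warnings.
    """
    window = AnalysisWindow(*analysis["window"])
    alpha = analysis["alpha"]
    warnings: List[dict] = []

    eligible, excluded = filter_ppas(
        ppas,
        window,
        pixel_size_m=grid.pixel_size_m,
        min_area_m2=analysis["min_area_ha"] * 10_000.0,
        min_tenure_years=analysis["min_tenure_years"],
    )
    for pid, reason in excluded:
        warnings.append({"unit": pid, "reason": f"filtered: {reason}"})

    for ppa in eligible:
        if ppa.ecozone is None:
            ppa.ecozone = assign_ecozone(ppa, zones, grid)
    assigned = [p for p in eligible if p.ecozone is not None]
    for p in eligible:
        if p.ecozone is None:
            warnings.append({"unit": p.id, "reason": "no ecozone"})

    gpes = delineate_all(
        assigned, grid, max_radius_px=analysis["max_radius_px"], master_seed=master_seed
    )
    # units whose candidate cannot even match the footprint leave the paired analysis
    usable: List[PPARecord] = []
    for ppa in assigned:
        g = gpes[ppa.id]
        if g.n_candidate < ppa.n_pixels:
            warnings.append({"unit": ppa.id, "reason": "gpe candidate smaller than footprint"})
        else:
            if not g.complete:
                warnings.append({"unit": ppa.id, "reason": "gpe candidate incomplete"})
            usable.append(ppa)

    manifest_rows = [
        {
            "ppa_id": p.id,
            "n_footprint": p.n_pixels,
            "n_candidate": gpes[p.id].n_candidate,
            "n_sample": gpes[p.id].n_sample,
            "max_ring_used": gpes[p.id].max_ring_used,
            "complete": gpes[p.id].complete,
            "seed": gpes[p.id].seed,
        }
        for p in assigned
    ]

    rates: List = []
    unit_rows: List[dict] = []
    for ppa in usable:
        period = effective_period(ppa, window)
        row, col = ppa.centroid()
        lat = float(grid.latitude_at_row(row))
        entry = {"ppa_id": ppa.id, "ecozone": ppa.ecozone, "latitude": lat}
        for agent in AGENTS:
            r_ppa = compute_rate(ppa.footprint, stack, period, agent, ppa.id, "PPA")
            r_gpe = compute_rate(
                gpes[ppa.id].sample, stack, period, agent, ppa.id, "GPE"
            )
            rates.extend([r_ppa, r_gpe])
            entry[f"ppa_{agent}"] = r_ppa.rate_pct_per_yr
            entry[f"gpe_{agent}"] = r_gpe.rate_pct_per_yr
        unit_rows.append(entry)
    for zone in zones:
        for agent in AGENTS:
            try:
                rates.append(ecozone_rate(zone, stack, grid, window, agent))
            except Exception:
                warnings.append({"unit": zone.id, "reason": "ecozone rate undefined"})

    units = pd.DataFrame(
        unit_rows,
        columns=["ppa_id", "ecozone", "latitude"]
        + [f"{k}_{a}" for a in AGENTS for k in ("ppa", "gpe")],
    )

    comparison_rows = []
    for zone in zones:
        sel = units[units["ecozone"] == zone.id]
        for agent in AGENTS:
            if len(sel) < 2:
                continue
            res = paired_ttest(
                sel[f"ppa_{agent}"], sel[f"gpe_{agent}"], alpha=alpha,
                ecozone=zone.id, agent=agent,
            )
            comparison_rows.append(
                {
                    "ecozone": res.ecozone,
                    "agent": res.agent,
                    "n_pairs": res.n_pairs,
                    "mean_ppa": res.mean_ppa,
                    "mean_gpe": res.mean_gpe,
                    "t_stat": res.t_stat,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )

    correlation_rows = []
    for agent in AGENTS:
        if len(units) >= 2:
            res = correlation_summary(
                units[f"ppa_{agent}"], units[f"gpe_{agent}"], agent=agent
            )
            correlation_rows.append(
                {"agent": agent, "r": res.r, "n": res.n, "defined": res.defined}
            )

    lat_rows = []
    split_rows = []
    occurrence_rows = []
    threshold = analysis["occurrence_threshold_pct_yr"]
    for agent in AGENTS:
        if len(units) == 0:
            continue
        for summary in bin_by_latitude(
            units["latitude"], units[f"ppa_{agent}"], units[f"gpe_{agent}"], agent=agent
        ):
            lat_rows.append(
                {
                    "bin_degree": summary.bin_degree,
                    "agent": summary.agent,
                    "mean_ppa_rate": summary.mean_ppa_rate,
                    "mean_gpe_rate": summary.mean_gpe_rate,
                    "n_units": summary.n_units,
                }
            )
        pooled_lat = np.concatenate([units["latitude"], units["latitude"]])
        pooled_rate = np.concatenate([units[f"ppa_{agent}"], units[f"gpe_{agent}"]])
        below, above = split_by_latitude(
            pooled_lat, pooled_rate, analysis["latitude_split_deg"]
        )
        split_rows.append(
            {
                "agent": agent,
                "threshold_deg": analysis["latitude_split_deg"],
                "mean_below": below if below is not None else np.nan,
                "mean_above": above if above is not None else np.nan,
            }
        )
        for kind in ("ppa", "gpe"):
            for zone in zones:
                sel = units[units["ecozone"] == zone.id]
                if len(sel) == 0:
                    continue
                occurrence_rows.append(
                    {
                        "ecozone": zone.id,
                        "unit": kind.upper(),
                        "agent": agent,
                        "pct_units_above_threshold": pct_units_disturbed(
                            sel[f"{kind}_{agent}"], threshold
                        ),
                        "n_units": len(sel),
                    }
                )

    return {
        "rates": pd.DataFrame(rate_rows(rates), columns=pio.RATE_COLUMNS),
        "units": units,
        "comparisons": pd.DataFrame(comparison_rows, columns=pio.COMPARISON_COLUMNS),
        "correlations": pd.DataFrame(
            correlation_rows, columns=["agent", "r", "n", "defined"]
        ),
        "latitude_bins": pd.DataFrame(
            lat_rows,
            columns=["bin_degree", "agent", "mean_ppa_rate", "mean_gpe_rate", "n_units"],
        ),
        "latitude_split": pd.DataFrame(
            split_rows, columns=["agent", "threshold_deg", "mean_below", "mean_above"]
        ),
        "occurrence": pd.DataFrame(
            occurrence_rows,
            columns=["ecozone", "unit", "agent", "pct_units_above_threshold", "n_units"],
        ),
        "gpe_manifest": pd.DataFrame(
            manifest_rows,
            columns=[
                "ppa_id", "n_footprint", "n_candidate", "n_sample",
                "max_ring_used", "complete", "seed",
            ],
        ),
        "gpes": gpes,
        "warnings": warnings,
    }


def run_pipeline(
    config: Optional[dict],
    out_dir,
    seed: Optional[int] = None,
) -> Path:
    """Full synthetic-mode run; writes rasters, vectors, CSVs and a manifest.

    ``seed`` overrides the scenario's master seed when given.
    """
    norm = validate_config(config)
    if seed is not None:
        norm["scenario"]["master_seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen = dict(norm["scenario"])
    for key in ("ppa_area_range_px", "year_range", "establishment_year_range"):
        scen[key] = tuple(scen[key])
    scenario = ScenarioConfig(**scen)
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    grid, ppas, zones, stack = generate_scenario(
        scenario, n_ecozones=norm["analysis"]["n_ecozones"]
    )
    timings["simulate"] = time.perf_counter() - t0

    pio.write_stack(out, stack, grid)
    pio.write_masks(out, grid)
    pio.write_ppas_geojson(out / "ppas.geojson", ppas, grid)
    pio.write_ecozones_geojson(out / "ecozones.geojson", zones)
    pio.write_config_yaml(out / "config.yaml", norm)

    t0 = time.perf_counter()
    result = analyze(grid, ppas, zones, stack, norm["analysis"], scenario.master_seed)
    timings["analyze"] = time.perf_counter() - t0

    result["rates"].to_csv(out / "rates.csv", index=False)
    result["units"].to_csv(out / "unit_rates.csv", index=False)
    result["comparisons"].to_csv(out / "comparisons.csv", index=False)
    result["correlations"].to_csv(out / "correlations.csv", index=False)
    result["latitude_bins"].to_csv(out / "latitude_bins.csv", index=False)
    result["latitude_split"].to_csv(out / "latitude_split.csv", index=False)
    result["occurrence"].to_csv(out / "occurrence.csv", index=False)
    result["gpe_manifest"].to_csv(out / "gpe_manifest.csv", index=False)
    pio.write_gpe_points(out / "gpe_samples.geojson", result["gpes"].values(), grid)

    manifest = {
        "config_hash": config_hash(norm),
        "master_seed": scenario.master_seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "counts": {
            "ppas_generated": len(ppas),
            "ppas_analyzed": int(result["units"].shape[0]),
            "ecozones": len(zones),
            "event_pixels": int((stack.event_year > 0).sum()),
        },
        "warnings": result["warnings"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return out
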