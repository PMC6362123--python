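"""Canonical synthetic study scenarios.

These fix the conditions under which the pipeline's structural claims are
checked: a boundary-ignoring wildfire regime with a strong south-to-north
intensity gradient, and a harvest regime confined to southern managed
forest and strictly excluded from protected areas.  They are used by the
test suite, the acceptance script and the examples alike.

Both scenarios use 100 m pixels so that unit footprints of a few hundred
pixels span realistic park areas (80-600 ha) around the 100 ha eligibility
threshold, and a mean event-patch size small relative to the units so that
each unit integrates many independent events and the latitude gradient —
not patch-sampling noise — dominates between-unit variation.
"""

from __future__ import annotations

from .landscape import ScenarioConfig


def fire_correlation_scenario(master_seed: int = 1) -> ScenarioConfig:
    """Boundary-ignoring fires only, 200 protected areas.

    The latitude gradient (0.02 %/yr of land burned annually in the far
    south up to 2 %/yr in the far north) dominates between-unit variation,
    and fires cross boundaries freely, so a unit and its neighbourhood
    sample burn at strongly correlated rates.
    """
    return ScenarioConfig(
        n_rows=500,
        n_cols=500,
        pixel_size_m=100.0,
        lat_top=62.0,
        lat_bottom=45.0,
        n_ppas=200,
        ppa_area_range_px=(80, 600),
        water_fraction=0.05,
        agri_fraction=0.05,
        fire_rate_north=0.02,
        fire_rate_south=0.0002,
        harvest_rate_south=0.0,
        harvest_rate_north=0.0,
        mean_patch_size_px=6.0,
        master_seed=master_seed,
    )


def harvest_contrast_scenario(master_seed: int = 1) -> ScenarioConfig:
    """Fire plus southern harvest, 50 protected areas.

    Harvest intensity falls linearly to zero northward and harvest patches
    never enter protected areas, so neighbourhood samples show
    significantly more harvest than their protected areas, while fire rates
    stay correlated between the two.
    """
    return ScenarioConfig(
        n_rows=250,
        n_cols=250,
        pixel_size_m=100.0,
        lat_top=60.0,
        lat_bottom=45.0,
        n_ppas=50,
        ppa_area_range_px=(80, 400),
        water_fraction=0.05,
        agri_fraction=0.05,
        fire_rate_north=0.01,
        fire_rate_south=0.001,
        harvest_rate_south=0.008,
        harvest_rate_north=0.0,
        mean_patch_size_px=6.0,
        master_seed=master_seed,
    )
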