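import numpy as np
import pytest

from parkshed.landscape import LandscapeGrid, PPARecord, ScenarioConfig


def make_grid(
    n_rows=10,
    n_cols=10,
    pixel_size_m=30.0,
    lat_top=60.0,
    lat_bottom=50.0,
    water=None,
    agri=None,
):
    """All-land grid unless explicit masks are given."""
    shape = (n_rows, n_cols)
    return LandscapeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_size_m=pixel_size_m,
        lat_top=lat_top,
        lat_bottom=lat_bottom,
        water_mask=np.zeros(shape, dtype=bool) if water is None else water,
        agri_mask=np.zeros(shape, dtype=bool) if agri is None else agri,
    )


def make_ppa(pixels, ppa_id="P1", establishment_year=1960, iucn="II", ecozone=None):
    return PPARecord(
        id=ppa_id,
        footprint=frozenset(pixels),
        establishment_year=establishment_year,
        iucn=iucn,
        ecozone=ecozone,
    )


def block(r0, c0, height, width):
    return {(r, c) for r in range(r0, r0 + height) for c in range(c0, c0 + width)}


@pytest.fixture
def grid10():
    return make_grid(10, 10)


@pytest.fixture
def small_config():
    """A small but complete scenario configuration for integration tests."""
    return ScenarioConfig(
        n_rows=80,
        n_cols=80,
        pixel_size_m=100.0,
        lat_top=60.0,
        lat_bottom=48.0,
        n_ppas=10,
        ppa_area_range_px=(30, 120),
        water_fraction=0.08,
        agri_fraction=0.05,
        fire_rate_north=0.01,
        fire_rate_south=0.001,
        harvest_rate_south=0.008,
        harvest_rate_north=0.0,
        mean_patch_size_px=6.0,
        master_seed=7,
    )
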