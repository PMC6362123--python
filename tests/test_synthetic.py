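"""Synthetic landscape generator: masks, footprints, and event structure."""

import dataclasses

import numpy as np
import pytest

from parkshed.errors import ParameterError, PlacementError
from parkshed.landscape import (
    AGENT_FIRE,
    AGENT_HARVEST,
    IUCN_STRICT,
    ScenarioConfig,
    pixel_bool_mask,
)
from parkshed.synthetic import (
    generate_ecozones,
    generate_landscape,
    generate_scenario,
    grow_patch,
    place_ppas,
    simulate_fire_events,
    simulate_harvest_events,
)

from conftest import make_grid, make_ppa, block


def with_overrides(config, **kw):
    return dataclasses.replace(config, **kw)


class TestGenerateLandscape:
    def test_zero_fractions_give_empty_masks(self):
        cfg = ScenarioConfig(water_fraction=0.0, agri_fraction=0.0, master_seed=1)
        grid = generate_landscape(cfg)
        assert not grid.water_mask.any()
        assert not grid.agri_mask.any()

    def test_water_pixel_count_within_20pct_of_request(self):
        cfg = ScenarioConfig(
            n_rows=100, n_cols=100, water_fraction=0.2, agri_fraction=0.0, master_seed=1
        )
        grid = generate_landscape(cfg)
        assert 1600 <= int(grid.water_mask.sum()) <= 2400

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(water_fraction=0.1, agri_fraction=0.1, master_seed=5)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        assert np.array_equal(a.water_mask, b.water_mask)
        assert np.array_equal(a.agri_mask, b.agri_mask)

    def test_latitude_strictly_decreasing_with_row(self):
        grid = generate_landscape(ScenarioConfig(master_seed=0))
        assert (np.diff(grid.latitude_of_row) < 0).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("water_fraction", 1.5),
            ("fire_rate_north", -0.1),
            ("ppa_area_range_px", (0, 5)),
            ("lat_top", 40.0),  # below lat_bottom
            ("year_range", (2015, 1985)),
        ],
    )
    def test_invalid_config_names_offending_field(self, field, value):
        cfg = with_overrides(ScenarioConfig(), **{field: value})
        with pytest.raises(ParameterError):
            cfg.validate()


class TestPlacePpas:
    def test_single_one_pixel_ppa_lands_on_land(self):
        cfg = ScenarioConfig(
            n_rows=10, n_cols=10, n_ppas=1, ppa_area_range_px=(1, 1),
            water_fraction=0.1, agri_fraction=0.0, master_seed=2,
        )
        grid = generate_landscape(cfg)
        (ppa,) = place_ppas(grid, cfg)
        assert ppa.n_pixels == 1
        (r, c) = next(iter(ppa.footprint))
        assert grid.land_mask[r, c]

    def test_twenty_footprints_pairwise_disjoint_and_contiguous(self):
        cfg = ScenarioConfig(
            n_rows=200, n_cols=200, n_ppas=20, ppa_area_range_px=(10, 50),
            water_fraction=0.05, agri_fraction=0.05, master_seed=2,
        )
        grid = generate_landscape(cfg)
        ppas = place_ppas(grid, cfg)
        assert len(ppas) == 20
        for i, a in enumerate(ppas):
            assert a.iucn in IUCN_STRICT
            assert 1950 <= a.establishment_year <= 2006
            for b in ppas[i + 1 :]:
                assert not (a.footprint & b.footprint)
            # contiguity: one 4-connected component
            from scipy import ndimage

            mask = pixel_bool_mask(a.footprint, grid.shape)
            _, n = ndimage.label(mask)
            assert n == 1

    def test_all_water_grid_raises_placement_error(self):
        cfg = ScenarioConfig(n_rows=10, n_cols=10, n_ppas=1, master_seed=0)
        grid = make_grid(10, 10, water=np.ones((10, 10), dtype=bool))
        with pytest.raises(PlacementError) as exc:
            place_ppas(grid, cfg)
        assert exc.value.placed == 0


class TestFireEvents:
    def test_zero_rates_no_fire(self):
        cfg = ScenarioConfig(
            n_rows=30, n_cols=30, fire_rate_north=0.0, fire_rate_south=0.0,
            water_fraction=0.0, agri_fraction=0.0, master_seed=1,
        )
        grid = generate_landscape(cfg)
        stack = simulate_fire_events(grid, [], cfg)
        assert not (stack.event_agent == AGENT_FIRE).any()

    def test_uniform_rate_matches_closed_form_burned_fraction(self):
        # expected fraction after 31 years of independent 0.004/yr burning
        cfg = ScenarioConfig(
            n_rows=100, n_cols=100, fire_rate_north=0.004, fire_rate_south=0.004,
            water_fraction=0.0, agri_fraction=0.0, mean_patch_size_px=25.0,
            master_seed=3,
        )
        grid = generate_landscape(cfg)
        stack = simulate_fire_events(grid, [], cfg)
        frac = (stack.event_agent == AGENT_FIRE).mean()
        expected = 1 - (1 - 0.004) ** 31
        assert 0.5 * expected <= frac <= 1.5 * expected

    def test_patch_crosses_ppa_boundary(self):
        # region growth seeded beside a footprint spreads onto both sides
        grid = make_grid(20, 20)
        ppa_pixels = block(5, 5, 5, 5)
        allowed = np.ones((20, 20), dtype=bool)
        rng = np.random.default_rng(0)
        patch = grow_patch(rng, allowed, (7, 4), 40)
        inside = set(patch) & ppa_pixels
        outside = set(patch) - ppa_pixels
        assert inside and outside

    def test_fire_ignores_boundaries_in_simulation(self):
        cfg = ScenarioConfig(
            n_rows=60, n_cols=60, n_ppas=4, ppa_area_range_px=(50, 100),
            fire_rate_north=0.02, fire_rate_south=0.02, water_fraction=0.0,
            agri_fraction=0.0, master_seed=4,
        )
        grid = generate_landscape(cfg)
        ppas = place_ppas(grid, cfg)
        stack = simulate_fire_events(grid, ppas, cfg)
        fire = stack.event_agent == AGENT_FIRE
        all_fp = set().union(*(p.footprint for p in ppas))
        inside = pixel_bool_mask(all_fp, grid.shape)
        assert (fire & inside).any() and (fire & ~inside).any()


class TestHarvestEvents:
    def test_zero_rates_no_harvest(self):
        cfg = ScenarioConfig(
            n_rows=30, n_cols=30, harvest_rate_south=0.0, harvest_rate_north=0.0,
            water_fraction=0.0, agri_fraction=0.0, master_seed=1,
        )
        grid = generate_landscape(cfg)
        stack = simulate_harvest_events(grid, [], cfg)
        assert not (stack.event_agent == AGENT_HARVEST).any()

    def test_harvest_never_intersects_ppa_footprints(self, small_config):
        grid = generate_landscape(small_config)
        ppas = place_ppas(grid, small_config)
        stack = simulate_harvest_events(grid, ppas, small_config)
        harvested = stack.event_agent == AGENT_HARVEST
        for ppa in ppas:
            fp = pixel_bool_mask(ppa.footprint, grid.shape)
            assert not (harvested & fp).any()

    def test_southern_gradient_concentrates_harvest_in_bottom_rows(self):
        cfg = ScenarioConfig(
            n_rows=90, n_cols=90, harvest_rate_south=0.004, harvest_rate_north=0.0,
            fire_rate_north=0.0, fire_rate_south=0.0,
            water_fraction=0.0, agri_fraction=0.0, master_seed=5,
        )
        grid = generate_landscape(cfg)
        stack = simulate_harvest_events(grid, [], cfg)
        harvested = stack.event_agent == AGENT_HARVEST
        top = harvested[:30].sum()
        bottom = harvested[60:].sum()
        assert bottom > top


class TestScenarioInvariants:
    def test_full_scenario_deterministic(self, small_config):
        g1, p1, _, s1 = generate_scenario(small_config)
        g2, p2, _, s2 = generate_scenario(small_config)
        assert np.array_equal(g1.water_mask, g2.water_mask)
        assert [p.footprint for p in p1] == [p.footprint for p in p2]
        assert np.array_equal(s1.event_year, s2.event_year)
        assert np.array_equal(s1.event_agent, s2.event_agent)

    def test_no_events_on_water_or_agriculture(self, small_config):
        grid, ppas, _, stack = generate_scenario(small_config)
        nonland = ~grid.land_mask
        assert not (stack.event_year[nonland] > 0).any()

    def test_one_event_per_pixel_and_consistency(self, small_config):
        grid, ppas, _, stack = generate_scenario(small_config)
        stack.validate()
        y0, y1 = small_config.year_range
        events = stack.event_year[stack.event_year > 0]
        assert ((events >= y0) & (events <= y1)).all()

    def test_ecozone_bands_cover_grid_rows(self, small_config):
        grid = generate_landscape(small_config)
        zones = generate_ecozones(grid, n_zones=3)
        assert len(zones) == 3
        assert sorted(z.id for z in zones) == ["EZ0", "EZ1", "EZ2"]
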