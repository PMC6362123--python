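"""Eligibility filters, period truncation, and rate arithmetic."""

import numpy as np
import pytest
from shapely.geometry import box

from parkshed.errors import PreconditionError, UndefinedRateError
from parkshed.landscape import AGENT_FIRE, AGENT_HARVEST, DisturbanceStack, EcozonePolygon
from parkshed.rates import (
    AnalysisWindow,
    assign_ecozone,
    compute_rate,
    ecozone_rate,
    effective_period,
    filter_ppas,
)

from conftest import make_grid, make_ppa, block

WINDOW = AnalysisWindow(1985, 2015)


def stack_with(shape, events):
    """events: {(r, c): (year, agent_code)}"""
    stack = DisturbanceStack.empty(shape)
    for (r, c), (year, agent) in events.items():
        stack.event_year[r, c] = year
        stack.event_agent[r, c] = agent
    return stack


class TestFilterPpas:
    def _ppa_of_area(self, ha, pixel_size_m=30.0, **kw):
        n = int(np.ceil(ha * 10_000 / pixel_size_m**2))
        side = int(np.ceil(np.sqrt(n)))
        pixels = list(block(0, 0, side, side))[:n]
        return make_ppa(pixels, **kw)

    def test_small_area_excluded(self):
        ppa = self._ppa_of_area(99, establishment_year=1990, iucn="II")
        result = filter_ppas([ppa], WINDOW)
        assert result.eligible == []
        assert result.excluded == [("P1", "area")]

    def test_category_iii_excluded(self):
        ppa = self._ppa_of_area(500, iucn="III", establishment_year=1990)
        result = filter_ppas([ppa], WINDOW)
        assert result.excluded == [("P1", "category")]

    def test_short_tenure_excluded(self):
        ppa = self._ppa_of_area(500, iucn="II", establishment_year=2007)
        result = filter_ppas([ppa], WINDOW)
        assert result.excluded == [("P1", "tenure")]

    def test_established_2006_is_eligible(self):
        ppa = self._ppa_of_area(500, iucn="II", establishment_year=2006)
        result = filter_ppas([ppa], WINDOW)
        assert result.eligible == [ppa]

    def test_threshold_is_exact_area_not_rounded_pixels(self):
        # 1112 pixels at 30 m = 100.08 ha (in), 1111 = 99.99 ha (out)
        keep = make_ppa(block(0, 0, 8, 139), ppa_id="IN", iucn="II",
                        establishment_year=1990)
        drop = make_ppa(block(0, 0, 11, 101), ppa_id="OUT", iucn="II",
                        establishment_year=1990)
        assert len(keep.footprint) == 1112 and len(drop.footprint) == 1111
        result = filter_ppas([keep, drop], WINDOW)
        assert [p.id for p in result.eligible] == ["IN"]
        assert result.excluded == [("OUT", "area")]


class TestEffectivePeriod:
    @pytest.mark.parametrize(
        "est,expected_start,expected_years",
        [(1960, 1985, 31), (1996, 1996, 20), (2006, 2006, 10)],
    )
    def test_truncation(self, est, expected_start, expected_years):
        ppa = make_ppa(block(0, 0, 2, 2), establishment_year=est)
        period = effective_period(ppa, WINDOW)
        assert period.start_year == expected_start
        assert period.end_year == 2015
        assert period.n_years == expected_years

    def test_establishment_after_window_end_raises(self):
        ppa = make_ppa(block(0, 0, 2, 2), establishment_year=2020)
        with pytest.raises(PreconditionError):
            effective_period(ppa, WINDOW)


class TestComputeRate:
    def test_no_events_rate_zero(self):
        pixels = block(0, 0, 10, 10)
        stack = DisturbanceStack.empty((10, 10))
        rate = compute_rate(pixels, stack, WINDOW, "fire")
        assert rate.rate_pct_per_yr == 0.0

    def test_31_of_100_burned_gives_one_percent_per_year(self):
        pixels = block(0, 0, 10, 10)
        events = {(i // 10, i % 10): (1985 + i % 31, AGENT_FIRE) for i in range(31)}
        stack = stack_with((10, 10), events)
        rate = compute_rate(pixels, stack, WINDOW, "fire")
        assert rate.rate_pct_per_yr == pytest.approx(1.0, abs=1e-12)

    def test_10_of_100_harvested_over_20_years_is_half_percent(self):
        pixels = block(0, 0, 10, 10)
        events = {(0, c): (2000, AGENT_HARVEST) for c in range(10)}
        stack = stack_with((10, 10), events)
        rate = compute_rate(pixels, stack, AnalysisWindow(1996, 2015), "harvest")
        assert rate.rate_pct_per_yr == pytest.approx(0.5, abs=1e-12)

    def test_events_outside_period_not_counted(self):
        pixels = block(0, 0, 2, 2)
        stack = stack_with((2, 2), {(0, 0): (1990, AGENT_FIRE)})
        rate = compute_rate(pixels, stack, AnalysisWindow(1996, 2015), "fire")
        assert rate.disturbed_pixels == 0

    def test_total_is_fire_plus_harvest(self):
        pixels = block(0, 0, 4, 4)
        stack = stack_with(
            (4, 4),
            {(0, 0): (1990, AGENT_FIRE), (1, 1): (1991, AGENT_HARVEST)},
        )
        fire = compute_rate(pixels, stack, WINDOW, "fire")
        harv = compute_rate(pixels, stack, WINDOW, "harvest")
        total = compute_rate(pixels, stack, WINDOW, "total")
        assert total.disturbed_pixels == fire.disturbed_pixels + harv.disturbed_pixels
        assert total.rate_pct_per_yr == pytest.approx(
            fire.rate_pct_per_yr + harv.rate_pct_per_yr, abs=1e-12
        )

    def test_rate_bounded_by_100_over_n_years(self):
        pixels = block(0, 0, 3, 3)
        events = {(r, c): (2000, AGENT_FIRE) for r, c in pixels}
        stack = stack_with((3, 3), events)
        rate = compute_rate(pixels, stack, WINDOW, "fire")
        assert rate.rate_pct_per_yr == pytest.approx(100.0 / 31)

    def test_empty_pixel_set_raises(self):
        with pytest.raises(UndefinedRateError):
            compute_rate(set(), DisturbanceStack.empty((2, 2)), WINDOW, "fire")


class TestAssignEcozone:
    def _zones(self, grid):
        # two vertical halves in world coordinates
        w = grid.n_cols * grid.pixel_size_m
        h = grid.n_rows * grid.pixel_size_m
        return [
            EcozonePolygon(id="A", geometry=box(0, -h, w / 2, 0)),
            EcozonePolygon(id="B", geometry=box(w / 2, -h, w, 0)),
        ]

    def test_wholly_inside_zone(self, grid10):
        ppa = make_ppa(block(2, 1, 2, 2))
        assert assign_ecozone(ppa, self._zones(grid10), grid10) == "A"

    def test_straddling_assigned_by_centroid(self, grid10):
        # 6 pixels in A (cols 2-4), 4 in B (cols 5-6): centroid col < 4.5
        pixels = {(0, c) for c in range(2, 7)} | {(1, c) for c in range(2, 5)}
        pixels |= {(1, 5)}
        ppa = make_ppa(pixels)
        row, col = ppa.centroid()
        assert col < 4.5
        assert assign_ecozone(ppa, self._zones(grid10), grid10) == "A"

    def test_centroid_on_shared_boundary_takes_smallest_id(self, grid10):
        # centroid exactly between cols 4 and 5 -> x = half width
        ppa = make_ppa({(0, 4), (0, 5)})
        assert assign_ecozone(ppa, self._zones(grid10), grid10) == "A"

    def test_centroid_outside_all_zones_unassigned(self, grid10):
        zones = [EcozonePolygon(id="A", geometry=box(1000, 1000, 2000, 2000))]
        ppa = make_ppa(block(0, 0, 2, 2))
        assert assign_ecozone(ppa, zones, grid10) is None


class TestEcozoneRate:
    def test_event_free_zone_rate_zero(self, grid10):
        w = grid10.n_cols * grid10.pixel_size_m
        h = grid10.n_rows * grid10.pixel_size_m
        zone = EcozonePolygon(id="Z", geometry=box(0, -h, w, 0))
        rate = ecozone_rate(zone, DisturbanceStack.empty((10, 10)), grid10, WINDOW, "fire")
        assert rate.rate_pct_per_yr == 0.0
        assert rate.land_pixels == 100

    def test_62_of_1000_fire_pixels_gives_0_2_pct_per_year(self):
        grid = make_grid(20, 50)
        w = grid.n_cols * grid.pixel_size_m
        h = grid.n_rows * grid.pixel_size_m
        zone = EcozonePolygon(id="Z", geometry=box(0, -h, w, 0))
        events = {(i // 50, i % 50): (1990, AGENT_FIRE) for i in range(62)}
        stack = stack_with((20, 50), events)
        rate = ecozone_rate(zone, stack, grid, WINDOW, "fire")
        assert rate.rate_pct_per_yr == pytest.approx(0.2, abs=1e-12)

    def test_zone_with_no_land_raises(self):
        grid = make_grid(5, 5, water=np.ones((5, 5), bool))
        zone = EcozonePolygon(id="Z", geometry=box(0, -150, 150, 0))
        with pytest.raises(UndefinedRateError):
            ecozone_rate(zone, DisturbanceStack.empty((5, 5)), grid, WINDOW, "fire")

    def test_zone_rate_ignores_establishment_years(self, grid10):
        # the zone rate uses the full window regardless of any PPA tenure
        w = grid10.n_cols * grid10.pixel_size_m
        h = grid10.n_rows * grid10.pixel_size_m
        zone = EcozonePolygon(id="Z", geometry=box(0, -h, w, 0))
        stack = stack_with((10, 10), {(0, 0): (1986, AGENT_FIRE)})
        rate = ecozone_rate(zone, stack, grid10, WINDOW, "fire")
        assert rate.start_year == 1985 and rate.disturbed_pixels == 1
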