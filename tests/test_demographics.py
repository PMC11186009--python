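"""Tiered population rules, areal apportionment and density arithmetic."""

import numpy as np
import pandas as pd
import pytest
import shapely

from pfaspest.demographics import (
    apportion,
    apportionment_weights,
    estimate_population,
    population_density,
)
from pfaspest.geotable import geometry_array


def grid_points(x0, y0, nx, ny, step, pop):
    xs, ys = np.meshgrid(x0 + (np.arange(nx) + 0.5) * step,
                         y0 + (np.arange(ny) + 0.5) * step)
    return pd.DataFrame({"cell_id": np.arange(nx * ny),
                         "x": xs.ravel(), "y": ys.ravel(),
                         "population": pop})


def bg_row(bg_id, geom, total_pop, latinx, nl_white, hh=100, rented=30, pov=25,
           **kw):
    others = total_pop - latinx - nl_white
    return {
        "bg_id": bg_id, "geometry": geom, "total_pop": total_pop,
        "latinx": latinx, "nl_white": nl_white,
        "nl_black": others // 2, "nl_asian": others - others // 2,
        "nl_native": 0, "nl_other": 0,
        "households_total": hh, "households_rented": rented,
        "households_poverty": pov, "persons_poverty": int(total_pop * pov / hh),
        **kw,
    }


class TestTieredPopulation:
    @pytest.fixture()
    def three_tier_fixture(self):
        # A: grid 20 < 25, SDWIS 150        -> 150
        # B: grid 20 < 25, SDWIS missing, 12 connections -> 36
        # C: grid 500 >= 25                  -> 500 (minus domestic wells)
        areas = pd.DataFrame({
            "system_id": ["A", "B", "C"],
            "geometry": [shapely.box(0, 0, 1000, 1000),
                         shapely.box(2000, 0, 3000, 1000),
                         shapely.box(4000, 0, 5000, 1000)],
        })
        grid = pd.concat([
            grid_points(0, 0, 2, 2, 500, 5),      # A: 4 cells x 5 = 20
            grid_points(2000, 0, 2, 2, 500, 5),   # B: 20
            grid_points(4000, 0, 2, 2, 500, 125), # C: 500
        ], ignore_index=True)
        admin = pd.DataFrame({
            "system_id": ["A", "B", "C"],
            "sdwis_population": [150.0, np.nan, 9999.0],
            "service_connections": [40, 12, 200],
        })
        return areas, grid, admin

    def test_substitution_rules_fire_per_tier(self, three_tier_fixture):
        areas, grid, admin = three_tier_fixture
        out = estimate_population(areas, grid, admin).set_index("system_id")
        assert out.loc["A", "population_served"] == 150
        assert out.loc["A", "tier"] == 2
        assert out.loc["B", "population_served"] == 36
        assert out.loc["B", "tier"] == 3
        # substitution never fires at >= 25: admin record (9999) ignored
        assert out.loc["C", "population_served"] == 500
        assert out.loc["C", "tier"] == 1

    def test_domestic_well_subtraction_floors_at_zero(self, three_tier_fixture):
        areas, grid, admin = three_tier_fixture
        dom = pd.DataFrame({"x": [4500.0] * 20 + [500.0] * 60,
                            "y": [500.0] * 80,
                            "persons": [3.0] * 80})
        out = estimate_population(areas, grid, admin, dom).set_index("system_id")
        assert out.loc["C", "population_served"] == 500 - 60
        assert out.loc["A", "population_served"] == 0  # 150 - 180 floored

    def test_no_coverage_no_admin_warns_zero(self):
        areas = pd.DataFrame({"system_id": ["X"],
                              "geometry": [shapely.box(0, 0, 10, 10)]})
        grid = grid_points(1000, 1000, 1, 1, 10, 50)
        admin = pd.DataFrame({"system_id": [], "sdwis_population": [],
                              "service_connections": []})
        with pytest.warns(UserWarning, match="no administrative"):
            out = estimate_population(areas, grid, admin)
        assert out["population_served"].iloc[0] == 0


class TestApportionment:
    def test_exact_coverage_inherits_percentages(self):
        bg = pd.DataFrame([bg_row("b1", shapely.box(0, 0, 100, 100),
                                  1000, 400, 500)])
        areas = pd.DataFrame({"system_id": ["S"],
                              "geometry": [shapely.box(0, 0, 100, 100)]})
        out = apportion(areas, bg)
        assert out["pct_latinx"].iloc[0] == pytest.approx(40.0)
        assert out["pct_nl_white"].iloc[0] == pytest.approx(50.0)
        assert out["pct_nl_poc"].iloc[0] == pytest.approx(10.0)

    def test_half_coverage_halves_counts_keeps_proportions(self):
        bg = pd.DataFrame([bg_row("b1", shapely.box(0, 0, 100, 100),
                                  1000, 400, 500)])
        areas = pd.DataFrame({"system_id": ["S"],
                              "geometry": [shapely.box(0, 0, 50, 100)]})
        out = apportion(areas, bg)
        assert out["total_pop"].iloc[0] == pytest.approx(500.0)
        assert out["latinx"].iloc[0] == pytest.approx(200.0)
        assert out["pct_latinx"].iloc[0] == pytest.approx(40.0)

    def test_tiling_systems_conserve_population(self):
        bg = pd.DataFrame([
            bg_row("b1", shapely.box(0, 0, 100, 100), 1000, 400, 500),
            bg_row("b2", shapely.box(100, 0, 250, 100), 600, 100, 400),
        ])
        areas = pd.DataFrame({
            "system_id": ["S1", "S2", "S3"],
            "geometry": [shapely.box(0, 0, 80, 100),
                         shapely.box(80, 0, 170, 100),
                         shapely.box(170, 0, 250, 100)],
        })
        out = apportion(areas, bg)
        assert out["total_pop"].sum() == pytest.approx(1600.0, rel=1e-12)

    def test_weights_sum_to_one_with_remainder(self, small_landscape):
        L = small_landscape
        w = apportionment_weights(L.service_areas, L.block_groups)
        per_bg = w.groupby("bg_id")["weight"].sum()
        # systems tile the region, so covered weight is 1 for every block group
        assert np.abs(per_bg.to_numpy() - 1.0).max() < 1e-9

    def test_race_composition_closes_to_100(self, small_table):
        t = small_table.dropna(subset=["pct_latinx"])
        closure = t["pct_latinx"] + t["pct_nl_white"] + t["pct_nl_poc"]
        assert np.abs(closure - 100.0).max() < 1e-6

    def test_poverty_denominator_switch(self):
        bg = pd.DataFrame([bg_row("b1", shapely.box(0, 0, 10, 10),
                                  1000, 400, 500, hh=200, pov=50)])
        areas = pd.DataFrame({"system_id": ["S"],
                              "geometry": [shapely.box(0, 0, 10, 10)]})
        hh = apportion(areas, bg, poverty_denominator="households")
        assert hh["pct_poverty"].iloc[0] == pytest.approx(25.0)
        per = apportion(areas, bg, poverty_denominator="persons")
        assert per["pct_poverty"].iloc[0] == pytest.approx(25.0)  # 250/1000

    def test_zero_area_block_group_rejected(self):
        bg = pd.DataFrame([bg_row("b1", shapely.box(0, 0, 0, 10), 10, 5, 5)])
        areas = pd.DataFrame({"system_id": ["S"],
                              "geometry": [shapely.box(0, 0, 10, 10)]})
        with pytest.raises(ValueError, match="zero-area"):
            apportion(areas, bg)


class TestPopulationDensity:
    def test_arithmetic(self):
        areas = pd.DataFrame({"system_id": ["S", "Z"],
                              "geometry": [shapely.box(0, 0, 1000, 1000),
                                           shapely.box(2000, 0, 3000, 1000)]})
        dens = population_density(areas, {"S": 1000.0, "Z": 0.0})
        assert dens.loc["S"] == pytest.approx(0.1)
        assert dens.loc["Z"] == 0.0

    def test_inverse_recovers_population(self, small_landscape, small_table):
        areas = small_landscape.service_areas
        dens = population_density(
            areas, small_table.set_index("system_id")["population_served"])
        area_m2 = shapely.area(geometry_array(areas))
        back = dens.to_numpy() * area_m2 / 100.0
        expect = small_table.set_index("system_id")["population_served"] \
            .reindex(areas["system_id"]).to_numpy()
        assert np.allclose(back, expect, rtol=1e-9)

    def test_zero_area_rejected(self):
        areas = pd.DataFrame({"system_id": ["S"],
                              "geometry": [shapely.box(0, 0, 0, 10)]})
        with pytest.raises(ValueError, match="zero-area"):
            population_density(areas, {"S": 10.0})
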