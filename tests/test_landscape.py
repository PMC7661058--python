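"""Woodland raster: growth curves, stock, regrowth, harvest, allocation."""

import numpy as np
import pytest

from elbawood.demand import LandRequirement
from elbawood.landscape import (BARE, SEA, Landscape, allocate_nonwood,
                                calibrate_growth, growth_curves, harvest_cells,
                                read_ascii_grid, regrow, standing_stock,
                                write_ascii_grid)


@pytest.fixture()
def curves(config):
    return growth_curves(config)


def uniform_island(n=6, veg=2, age=10.0, resolution=100.0) -> Landscape:
    shape = (n, n)
    return Landscape(
        resolution=resolution,
        veg=np.full(shape, veg, dtype=np.int8),
        age=np.full(shape, age),
        slope=np.zeros(shape),
    )


class TestGrowthCurve:
    @pytest.mark.parametrize("veg_class,increment",
                             [("oak", 2.2), ("macchia", 3.6), ("chestnut", 5.7)])
    def test_ten_year_mean_increment(self, config, veg_class, increment):
        curve = calibrate_growth(veg_class, config)
        assert curve.volume(10) / 10 == pytest.approx(increment, rel=0.01)

    def test_zero_age_zero_volume(self, config):
        for name in ("oak", "macchia", "chestnut"):
            assert calibrate_growth(name, config).volume(0) == pytest.approx(0.0)

    def test_maturity_reaches_99pct_of_asymptote(self, config):
        for name in ("oak", "macchia", "chestnut"):
            curve = calibrate_growth(name, config)
            assert curve.volume(42) >= 0.99 * curve.v_max

    def test_class_ordering_pointwise(self, config):
        oak = calibrate_growth("oak", config)
        macchia = calibrate_growth("macchia", config)
        chestnut = calibrate_growth("chestnut", config)
        ages = np.arange(1, 43)
        assert np.all(chestnut.volume(ages) >= macchia.volume(ages))
        assert np.all(macchia.volume(ages) >= oak.volume(ages))

    def test_monotone_increasing(self, config):
        curve = calibrate_growth("macchia", config)
        ages = np.linspace(0, 42, 200)
        assert np.all(np.diff(curve.volume(ages)) > 0)

    def test_impossible_fit_raises_with_diagnostics(self, config):
        import copy
        cfg = copy.deepcopy(config)
        cfg["sigmoid_midpoint"] = 400.0   # inflection beyond maturity: no solution
        with pytest.raises(RuntimeError, match="converge"):
            calibrate_growth("oak", cfg)


class TestStandingStock:
    def test_one_hectare_oak_at_age_ten(self, config, curves):
        ls = uniform_island(n=1, veg=1, age=10.0, resolution=100.0)
        stock = standing_stock(ls, curves, 0.69)
        assert stock[0, 0] == pytest.approx(2.2 * 10 * 0.69, rel=0.01)  # 15.18 t

    def test_age_zero_no_stock(self, config, curves):
        ls = uniform_island(age=0.0)
        assert standing_stock(ls, curves).sum() == pytest.approx(0.0)

    def test_cell_area_scaling(self, config, curves):
        big = uniform_island(n=1, veg=1, age=10.0, resolution=100.0)
        small = uniform_island(n=1, veg=1, age=10.0, resolution=10.0)
        ratio = standing_stock(big, curves)[0, 0] / standing_stock(small, curves)[0, 0]
        assert ratio == pytest.approx(100.0)

    def test_nonwoodland_cells_carry_nothing(self, curves):
        ls = uniform_island()
        ls.veg[0, 0] = SEA
        ls.veg[0, 1] = BARE
        stock = standing_stock(ls, curves)
        assert stock[0, 0] == 0 and stock[0, 1] == 0


class TestRegrow:
    def test_age_caps_at_maturity(self):
        ls = uniform_island(age=42.0)
        regrow(ls)
        assert np.all(ls.age == 42.0)

    def test_fresh_coppice_ages_by_one(self):
        ls = uniform_island(age=0.0)
        regrow(ls)
        assert np.all(ls.age == 1.0)

    def test_browsed_cells_accumulate_fractional_age(self):
        ls = uniform_island(age=0.0)
        ls.browse[0, 0] = True
        for _ in range(4):
            regrow(ls, browse_reduction=0.5)
        assert ls.age[0, 0] == pytest.approx(2.0)
        assert ls.age[1, 1] == pytest.approx(4.0)

    def test_no_harvest_no_browse_reaches_near_asymptote(self, config, curves):
        ls = uniform_island(age=0.0)
        for _ in range(42):
            regrow(ls)
        stock = standing_stock(ls, curves)
        v_max_mass = curves[2].v_max * ls.cell_area_ha * 0.69
        assert np.all(stock >= 0.99 * v_max_mass)


class TestHarvest:
    def test_two_oak_hectares_at_age_ten(self, config, curves):
        ls = uniform_island(n=2, veg=1, age=10.0)
        removed = harvest_cells(ls, np.array([0, 1]), curves, 0.69)
        assert removed == pytest.approx(2 * 15.18, rel=0.01)
        assert ls.age.ravel()[0] == 0 and ls.age.ravel()[1] == 0

    def test_empty_list_removes_nothing(self, curves):
        ls = uniform_island(age=10.0)
        before = ls.age.copy()
        assert harvest_cells(ls, np.array([], dtype=int), curves) == 0.0
        assert np.array_equal(ls.age, before)

    def test_harvest_everything_exhausts_stock(self, config, curves):
        ls = uniform_island(age=30.0)
        harvest_cells(ls, np.arange(ls.veg.size), curves)
        assert standing_stock(ls, curves).sum() == pytest.approx(0.0)

    def test_underage_cells_rejected(self, curves):
        ls = uniform_island(age=4.0)
        with pytest.raises(ValueError, match="age"):
            harvest_cells(ls, np.array([0]), curves, min_age=5.0)

    def test_stock_monotone_under_harvest_and_regrow(self, config, curves):
        ls = uniform_island(age=20.0)
        total = standing_stock(ls, curves).sum()
        harvest_cells(ls, np.array([0, 7, 12]), curves)
        after_harvest = standing_stock(ls, curves).sum()
        assert after_harvest < total
        regrow(ls)
        assert standing_stock(ls, curves).sum() >= after_harvest


class TestAllocateNonwood:
    def test_farmland_cell_count(self):
        ls = uniform_island(n=40, age=30.0)   # 1600 ha at 100 m cells
        priority = np.arange(ls.veg.size)
        requirement = LandRequirement(farmland_ha=100, pasture_ha=0,
                                      browse_ha=0, household_wood=0)
        unmet = allocate_nonwood(ls, requirement, priority)
        assert unmet == 0
        assert (ls.land_use == 1).sum() == 100
        assert np.all(ls.age.ravel()[:100] == 0)

    def test_zero_requirement_changes_nothing(self):
        ls = uniform_island(age=30.0)
        before_age = ls.age.copy()
        requirement = LandRequirement(0, 0, 0, 0)
        allocate_nonwood(ls, requirement, np.arange(ls.veg.size))
        assert np.array_equal(ls.age, before_age)
        assert (ls.land_use > 0).sum() == 0

    def test_farmland_excluded_from_woodland_mask(self):
        ls = uniform_island(age=30.0)
        requirement = LandRequirement(farmland_ha=5, pasture_ha=0,
                                      browse_ha=0, household_wood=0)
        allocate_nonwood(ls, requirement, np.arange(ls.veg.size))
        assert not ls.woodland.ravel()[:5].any()

    def test_shrinking_requirement_releases_cells(self):
        ls = uniform_island(age=30.0)
        priority = np.arange(ls.veg.size)
        allocate_nonwood(ls, LandRequirement(10, 0, 0, 0), priority)
        assert (ls.land_use == 1).sum() == 10
        allocate_nonwood(ls, LandRequirement(4, 0, 0, 0), priority)
        assert (ls.land_use == 1).sum() == 4

    def test_oversized_requirement_reports_unmet_area(self):
        ls = uniform_island(n=3, age=30.0)    # 9 ha only
        requirement = LandRequirement(farmland_ha=50, pasture_ha=0,
                                      browse_ha=0, household_wood=0)
        unmet = allocate_nonwood(ls, requirement, np.arange(ls.veg.size))
        assert unmet == pytest.approx(41.0)

    def test_browse_flags_woodland_and_zeroes_age_once(self):
        ls = uniform_island(age=30.0)
        priority = np.arange(ls.veg.size)
        requirement = LandRequirement(farmland_ha=0, pasture_ha=0,
                                      browse_ha=3, household_wood=0)
        allocate_nonwood(ls, requirement, priority)
        assert ls.browse.sum() == 3
        assert np.all(ls.age.ravel()[:3] == 0)
        ls.age.ravel()[:3] = 2.0   # regrown a little
        allocate_nonwood(ls, requirement, priority)   # same cells: not re-zeroed
        assert np.all(ls.age.ravel()[:3] == 2.0)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        array = np.arange(12, dtype=float).reshape(3, 4) / 7
        path = tmp_path / "grid.asc"
        write_ascii_grid(path, array, cellsize=50.0)
        loaded, meta = read_ascii_grid(path)
        np.testing.assert_allclose(loaded, array, rtol=1e-5)
        assert meta["cellsize"] == 50.0

    def test_landscape_save_load(self, tmp_path):
        ls = uniform_island(n=4)
        ls.region = np.zeros((4, 4), dtype=int)
        ls.save(tmp_path)
        reloaded = Landscape.load(tmp_path)
        assert reloaded.resolution == ls.resolution
        np.testing.assert_array_equal(reloaded.veg, ls.veg)
        np.testing.assert_allclose(reloaded.age, ls.age)
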