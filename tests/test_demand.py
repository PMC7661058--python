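"""Demand cascade: furnace-side arithmetic, labour, land, mining profile."""

import numpy as np
import pytest

from elbawood.demand import (LandRequirement, endosomatic_demand,
                             exosomatic_demand, island_series, labour_cascade,
                             mining_profile)
from elbawood.sampling import ParameterDraw
from elbawood.sites import DatingWindow, Site


def make_draw(**overrides) -> ParameterDraw:
    base = dict(
        furnace_inefficiency=5.25, kiln_type="mound", kiln_productivity=0.21,
        rotation_period=7, browse_reduction=0.5, household_fuel=1.0,
        ore_total=2.32, pasture_per_animal=0.95,
    )
    base.update(overrides)
    return ParameterDraw(**base)


def make_site(site_id=1, slag=(1000, 1000), window=(-110, -105, -104, -101)):
    return Site(id=site_id, name=f"s{site_id}", window=DatingWindow(*window),
                slag_min=slag[0], slag_max=slag[1])


class TestExosomatic:
    def test_cascade_arithmetic(self):
        draw = make_draw()
        draw.periods[1] = (-110, -101)      # 10 years inclusive
        draw.slag[1] = 1000.0
        site_demand = exosomatic_demand(make_site(), draw)
        assert site_demand.slag == pytest.approx(100.0)
        assert site_demand.charcoal == pytest.approx(525.0)
        assert site_demand.dry_wood == pytest.approx(2500.0)
        assert site_demand.wood_volume == pytest.approx(3623.19, abs=0.01)

    def test_identity_factors_pass_slag_through(self):
        draw = make_draw(furnace_inefficiency=1.0, kiln_productivity=1.0,
                         specific_gravity=1.0)
        draw.periods[1] = (-110, -101)
        draw.slag[1] = 1000.0
        site_demand = exosomatic_demand(make_site(), draw)
        assert site_demand.wood_volume == pytest.approx(site_demand.slag)

    def test_homogeneous_of_degree_one_in_slag(self):
        draw = make_draw()
        draw.periods[1] = (-110, -101)
        draw.slag[1] = 500.0
        half = exosomatic_demand(make_site(), draw)
        draw.slag[1] = 1000.0
        full = exosomatic_demand(make_site(), draw)
        assert full.dry_wood == pytest.approx(2 * half.dry_wood)

    def test_island_series_sums_sites_and_spans_years(self):
        draw = make_draw()
        sites = [make_site(1), make_site(2, window=(-108, -106, -104, -99))]
        draw.periods = {1: (-110, -101), 2: (-105, -100)}
        draw.slag = {1: 1000.0, 2: 600.0}
        series = island_series(sites, draw)
        assert series.index.min() == -110 and series.index.max() == -100
        assert series.loc[-103, "slag"] == pytest.approx(100.0 + 100.0)
        assert series.loc[-100, "slag"] == pytest.approx(100.0)
        # the cascade holds year by year
        np.testing.assert_allclose(series["dry_wood"],
                                   series["slag"] * 5.25 / 0.21)


class TestLabour:
    def test_smelter_count_from_slag(self, config):
        wf = labour_cascade({"slag": 2500.0}, make_draw(), config)
        assert wf.smelters == 1000

    def test_surcharges_compound(self, config):
        # core of exactly 1000: supervision 300, service 390, total 1690
        wf = labour_cascade({"slag": 2500.0}, make_draw(), config)
        assert wf.supervision == 300
        assert wf.service == 390
        assert wf.total == 1690

    def test_additive_service_alternative(self, config):
        import copy
        cfg = copy.deepcopy(config)
        cfg["labour"]["compound_service"] = False
        wf = labour_cascade({"slag": 2500.0}, make_draw(), cfg)
        assert wf.service == 300
        assert wf.total == 1600

    def test_zero_year_means_zero_workforce(self, config):
        wf = labour_cascade({}, make_draw(), config)
        assert wf.total == 0

    def test_negative_flow_rejected(self, config):
        with pytest.raises(ValueError, match="negative"):
            labour_cascade({"slag": -1.0}, make_draw(), config)

    def test_monotone_in_each_flow(self, config):
        base = {"slag": 1000.0, "wood": 20000.0, "felled_ha": 100.0,
                "overland_mass": 5000.0, "sea_mass": 1500.0,
                "regional_ore": 4000.0}
        reference = labour_cascade(base, make_draw(), config).total
        for key in base:
            bumped = dict(base, **{key: base[key] * 1.5})
            assert labour_cascade(bumped, make_draw(), config).total >= reference

    def test_kiln_type_sets_burner_productivity(self, config):
        draw_pit = make_draw(kiln_type="pit")
        draw_mound = make_draw(kiln_type="mound")
        flows = {"wood": 10000.0}
        pit = labour_cascade(flows, draw_pit, config).charcoal_burners
        mound = labour_cascade(flows, draw_mound, config).charcoal_burners
        # pit kilns take many small batches: far more person-days
        assert pit > 5 * mound


class TestEndosomatic:
    def test_household_wood_via_kiln_productivity(self, config):
        draw = make_draw(kiln_productivity=0.2, household_fuel=1.0)
        wf = labour_cascade({"slag": 2.5 * 600}, draw, config)
        capita = wf.total
        requirement = endosomatic_demand(wf, draw, config)
        # 1 t charcoal/capita at KP 0.2 -> 5 t dry wood per head
        assert requirement.household_wood == pytest.approx(5.0 * capita)
        assert requirement.farmland_ha == pytest.approx(2.0 * capita)
        assert requirement.browse_ha == pytest.approx(0.69 * capita)

    def test_zero_capita_zero_requirement(self, config):
        draw = make_draw()
        wf = labour_cascade({}, draw, config)
        requirement = endosomatic_demand(wf, draw, config)
        assert requirement.farmland_ha == 0
        assert requirement.household_wood == 0

    def test_endosomatic_positive_whenever_exosomatic_is(self, config):
        draw = make_draw()
        wf = labour_cascade({"slag": 1.0}, draw, config)  # tiniest furnace
        requirement = endosomatic_demand(wf, draw, config)
        assert requirement.household_wood > 0  # the goat never vanishes

    def test_negative_requirement_rejected(self):
        with pytest.raises(ValueError):
            LandRequirement(farmland_ha=-1, pasture_ha=0, browse_ha=0,
                            household_wood=0)


class TestMiningProfile:
    def test_uniform_profile_rate(self, config):
        series = mining_profile(make_draw(ore_total=2.32), config, "uniform")
        assert series.size == 800
        assert series.iloc[0] == pytest.approx(2900.0)

    def test_conserves_total_ore(self, config):
        draw = make_draw(ore_total=1.7)
        for profile in ("uniform", None):
            series = mining_profile(draw, config, profile)
            assert series.sum() == pytest.approx(1.7e6)

    def test_default_profile_peaks_above_mean(self, config):
        series = mining_profile(make_draw(), config)
        assert series.max() > series.mean()

    def test_unnormalised_explicit_weights_warn(self, config):
        import pandas as pd
        years = np.arange(config["mine_start"], config["mine_end"])
        weights = pd.Series(2.0, index=years)
        with pytest.warns(UserWarning, match="normalis"):
            series = mining_profile(make_draw(ore_total=1.0), config, weights)
        assert series.sum() == pytest.approx(1e6)


class TestLedgerExport:
    def test_tidy_ledger_covers_all_site_years(self):
        draw = make_draw()
        sites = [make_site(1), make_site(2)]
        draw.periods = {1: (-110, -101), 2: (-105, -100)}
        draw.slag = {1: 1000.0, 2: 600.0}
        from elbawood.demand import demand_ledger
        ledger = demand_ledger(sites, draw)
        assert set(ledger.columns) == {"year", "site_id", "quantity", "value",
                                       "unit", "category"}
        assert len(ledger) == (10 + 6) * 4
        slag_total = ledger.query("quantity == 'slag'")["value"].sum()
        assert slag_total == pytest.approx(1600.0)
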