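"""The annual simulation loop: demand, felling, land allocation, regrowth.

One simulation couples the demand cascade of all sites against the raster
woodland.  Each year, every active site walks its transport-cost ordering
and fells the cheapest cells older than the run's rotation period until its
annual dry-wood requirement is met; in full-metabolism mode the workforce's
household fuel is apportioned to sites in proportion to their slag output
and its farmland/pasture/browse claims are allocated afterwards.  Ages then
advance by one year (capped at maturity).  The run stops at complete
deforestation — the first year a requirement stays unmet although no cell
anywhere is older than the rotation period — or when all sites fall silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import demand as demand_mod
from .demand import LandRequirement, Workforce
from .landscape import (MAX_AGE, Landscape, growth_curves, standing_stock,
                        regrow, harvest_cells, allocate_nonwood)
from .sampling import ParameterDraw
from .sites import Site
from .transport import TransportParams, site_cost_surface

__all__ = ["YearRecord", "SimulationResult", "run_simulation", "run_year"]


@dataclass
class YearRecord:
    """State and flows of one simulated year."""

    year: int
    active_sites: list
    wood_demand: float       # t dry wood required (exo + apportioned endo)
    wood_felled: float       # t dry wood actually removed
    area_felled: float       # ha
    area_browsed: float      # ha flagged for browse
    farmland: float          # ha under farmland + pasture
    workforce_total: int
    shortage: bool
    woodland_pct: float      # % of initial woodland with trees > 5 yr
    mature_pct: float        # % of initial woodland with trees at maturity
    region_felled: np.ndarray | None = None   # ha per region


@dataclass
class SimulationResult:
    """Outcome of one simulation run."""

    manifest: dict
    records: list = field(default_factory=list)
    shortage_year: int | None = None
    min_woodland_pct: float = 100.0
    min_mature_pct: float = 100.0
    max_annual_cleared_pct: float = 0.0
    total_slag: float = 0.0
    total_charcoal: float = 0.0
    total_wood: float = 0.0
    peak_workforce: int = 0

    @property
    def felling_series(self) -> pd.Series:
        """Annual felled dry mass (t) indexed by year."""
        if not self.records:
            return pd.Series(dtype=float, name="wood_felled")
        return pd.Series({r.year: r.wood_felled for r in self.records},
                         name="wood_felled").sort_index()

    def write_jsonl(self, path) -> None:
        """Write one JSON line per simulated year."""
        import json
        with open(path, "w") as handle:
            for r in self.records:
                payload = {k: v for k, v in r.__dict__.items()
                           if k != "region_felled"}
                if r.region_felled is not None:
                    payload["region_felled"] = [float(v) for v in r.region_felled]
                handle.write(json.dumps(payload) + "\n")

    @property
    def demand_series(self) -> pd.Series:
        if not self.records:
            return pd.Series(dtype=float, name="wood_demand")
        return pd.Series({r.year: r.wood_demand for r in self.records},
                         name="wood_demand").sort_index()


class _EngineState:
    """Mutable per-run state shared by the yearly steps."""

    def __init__(self, sites: list[Site], landscape: Landscape,
                 draw: ParameterDraw, config: Mapping, mode: str):
        if mode not in ("exo", "exo+endo"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.config = config
        self.draw = draw
        self.landscape = landscape.copy()
        self.curves = growth_curves(config)
        self.sg = draw.specific_gravity
        self.sites = sorted(sites, key=lambda s: (str(type(s.id).__name__), s.id))
        self.demands = {s.id: demand_mod.exosomatic_demand(s, draw) for s in sites}
        tp = config.get("transport", {})
        self.tparams = TransportParams(
            body_mass_kg=tp.get("body_mass_kg", 70.0),
            load_kg=tp.get("load_kg", 20.0),
            terrain_factor=tp.get("terrain_factor", 1.2),
            ranking=tp.get("ranking", "cost"),
        )
        self.orders = {}
        for s in self.sites:
            if s.location is None:
                raise ValueError(f"site {s.id!r} has no grid location")
            self.orders[s.id], _ = site_cost_surface(
                self.landscape, s.location, self.tparams)
        # static conversion priority for non-wood land: open (unwooded) land
        # first, then gentle slopes, then proximity to the nearest site
        # (farmers take the plains before clearing forest; workers live near
        # their worksites)
        flat_slope = self.landscape.slope.ravel()
        dist = np.full(self.landscape.shape, np.inf)
        rows, cols = np.meshgrid(np.arange(self.landscape.shape[0]),
                                 np.arange(self.landscape.shape[1]), indexing="ij")
        for s in self.sites:
            r0, c0 = s.location
            dist = np.minimum(dist, np.hypot(rows - r0, cols - c0))
        land = self.landscape.land.ravel()
        wooded = (self.landscape.veg > 0).ravel().astype(int)
        keys = np.lexsort((np.arange(flat_slope.size), dist.ravel(),
                           np.round(flat_slope, 4), wooded))
        self.nonwood_priority = keys[land[keys]]
        self.initial_woodland = int(self.landscape.woodland.sum())
        self.mining = demand_mod.mining_profile(draw, config) \
            if mode == "exo+endo" else None
        self.prev_felled_ha = 0.0

    def stock(self) -> np.ndarray:
        return standing_stock(self.landscape, self.curves, self.sg)

    def woodland_pct(self, min_age: float) -> float:
        if self.initial_woodland == 0:
            return 100.0
        ls = self.landscape
        count = int(((ls.age >= min_age) & ls.woodland).sum())
        return 100.0 * count / self.initial_woodland


def _year_workforce(state: _EngineState, year: int,
                    active: list[Site]) -> tuple[Workforce, LandRequirement]:
    """Workforce and land requirement implied by the year's scheduled flows."""
    draw, config = state.draw, state.config
    slag = sum(state.demands[s.id].slag for s in active)
    wood = sum(state.demands[s.id].dry_wood for s in active)
    charcoal = sum(state.demands[s.id].charcoal for s in active)
    regional_ore = float(state.mining.get(year, 0.0)) if state.mining is not None else 0.0
    workforce = demand_mod.labour_cascade(
        {"slag": slag, "wood": wood, "felled_ha": state.prev_felled_ha,
         "overland_mass": charcoal, "sea_mass": slag * draw.slag_to_ore,
         "regional_ore": regional_ore},
        draw, config)
    extra = workforce.miners if (config.get("include_mining_endosomatic", True)
                                 and not config["labour"]["include_miners_in_total"]) \
        else 0
    requirement = demand_mod.endosomatic_demand(
        workforce, draw, config, extra_capita=extra)
    return workforce, requirement


def run_year(state: _EngineState, year: int) -> YearRecord:
    """Execute one annual step; returns its record (state is mutated)."""
    ls = state.landscape
    draw = state.draw
    active = [s for s in state.sites
              if state.demands[s.id].t_s <= year <= state.demands[s.id].t_e]
    if state.config.get("randomize_site_order") and len(active) > 1:
        # seeded per year, so a run stays reproducible from its config
        shuffler = np.random.default_rng(
            (int(state.config.get("site_order_seed", 0)), abs(year), year >= 0))
        active = [active[i] for i in shuffler.permutation(len(active))]

    workforce: Workforce | None = None
    requirement: LandRequirement | None = None
    endo_wood = 0.0
    if state.mode == "exo+endo" and active:
        workforce, requirement = _year_workforce(state, year, active)
        endo_wood = requirement.household_wood

    total_slag = sum(state.demands[s.id].slag for s in active) or 1.0
    stock = state.stock().ravel()
    eligible = (ls.woodland & (ls.age > draw.rotation_period)).ravel()

    wood_demand = 0.0
    wood_felled = 0.0
    cells_felled = 0
    shortage = False
    region_felled = None
    if ls.region is not None:
        region_felled = np.zeros(int(ls.region.max()) + 1)

    for site in active:
        site_demand = state.demands[site.id].dry_wood \
            + endo_wood * state.demands[site.id].slag / total_slag
        wood_demand += site_demand
        order = state.orders[site.id]
        candidates = order[eligible[order]]
        if candidates.size:
            gains = stock[candidates]
            cum = np.cumsum(gains)
            take = int(np.searchsorted(cum, site_demand) + 1)
            take = min(take, candidates.size)
            chosen = candidates[:take]
            removed = harvest_cells(ls, chosen, state.curves, state.sg)
            wood_felled += removed
            cells_felled += chosen.size
            eligible[chosen] = False
            stock[chosen] = 0.0
            if region_felled is not None:
                regions = ls.region.ravel()[chosen]
                np.add.at(region_felled, regions[regions >= 0],
                          ls.cell_area_ha)
            if cum[take - 1] < site_demand:
                shortage = True   # ordering exhausted: island has no eligible cell
        else:
            shortage = True

    land_unmet = 0.0
    browsed_ha = 0.0
    farm_ha = 0.0
    if requirement is not None:
        land_unmet = allocate_nonwood(
            ls, requirement, state.nonwood_priority,
            zero_browse_age=state.config.get("browse_zeroes_age", True))
        browsed_ha = float(ls.browse.sum()) * ls.cell_area_ha
        farm_ha = float((ls.land_use > 0).sum()) * ls.cell_area_ha
        if land_unmet > 0:
            shortage = True

    record = YearRecord(
        year=year,
        active_sites=[s.id for s in active],
        wood_demand=wood_demand,
        wood_felled=wood_felled,
        area_felled=cells_felled * ls.cell_area_ha,
        area_browsed=browsed_ha,
        farmland=farm_ha,
        workforce_total=workforce.total if workforce else 0,
        shortage=shortage,
        woodland_pct=0.0,   # filled after regrowth below
        mature_pct=0.0,
        region_felled=region_felled,
    )

    regrow(ls, draw.browse_reduction,
           state.config.get("browse_slows_growth", True))
    record.woodland_pct = state.woodland_pct(5.0 + 1e-9)
    record.mature_pct = state.woodland_pct(MAX_AGE)
    state.prev_felled_ha = record.area_felled
    return record


def run_simulation(sites: list[Site], landscape: Landscape, draw: ParameterDraw,
                   config: Mapping, mode: str = "exo") -> SimulationResult:
    """Run one full simulation; deterministic given its inputs."""
    manifest = {
        "mode": mode,
        "furnace_inefficiency": draw.furnace_inefficiency,
        "kiln_type": draw.kiln_type,
        "kiln_productivity": draw.kiln_productivity,
        "rotation_period": draw.rotation_period,
        "browse_reduction": draw.browse_reduction,
        "household_fuel": draw.household_fuel,
        "ore_total": draw.ore_total,
    }
    result = SimulationResult(manifest=manifest)
    if not sites:
        return result

    state = _EngineState(sites, landscape, draw, config, mode)
    result.total_slag = float(sum(draw.slag.values()))
    result.total_charcoal = result.total_slag * draw.furnace_inefficiency
    result.total_wood = result.total_charcoal / draw.kiln_productivity

    start = min(d.t_s for d in state.demands.values())
    end = max(d.t_e for d in state.demands.values())
    for year in range(start, end + 1):
        record = run_year(state, year)
        result.records.append(record)
        if record.shortage and result.shortage_year is None:
            result.shortage_year = year
        if record.shortage:
            break   # complete deforestation: the run stops

    pct_wood = [r.woodland_pct for r in result.records] or [100.0]
    pct_mature = [r.mature_pct for r in result.records] or [100.0]
    result.min_woodland_pct = float(min(pct_wood))
    result.min_mature_pct = float(min(pct_mature))
    if state.initial_woodland:
        cleared = [r.area_felled / (state.initial_woodland
                                    * landscape.cell_area_ha) * 100.0
                   for r in result.records]
        result.max_annual_cleared_pct = float(max(cleared, default=0.0))
    result.peak_workforce = max((r.workforce_total for r in result.records),
                                default=0)
    return result
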