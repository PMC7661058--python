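"""Demand cascade: slag -> charcoal -> wood -> land and labour.

The exosomatic side converts a site's sampled slag mass into constant annual
charcoal, dry-wood and wood-volume requirements over its activity period.
The endosomatic side sizes the workforce behind a year's material flows from
per-capita annual productivities and converts the resulting population into
farmland, pasture, browse and household-fuel requirements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sampling import ParameterDraw
from .sites import Site

__all__ = [
    "SiteDemand",
    "Workforce",
    "LandRequirement",
    "exosomatic_demand",
    "island_series",
    "labour_cascade",
    "endosomatic_demand",
    "mining_profile",
]


@dataclass(frozen=True)
class SiteDemand:
    """Constant annual exosomatic requirement of one site in one run."""

    site_id: int | str
    t_s: int
    t_e: int
    slag: float          # t/yr
    charcoal: float      # t/yr
    dry_wood: float      # t/yr
    wood_volume: float   # m3/yr

    @property
    def duration(self) -> int:
        return self.t_e - self.t_s + 1


def exosomatic_demand(site: Site, draw: ParameterDraw) -> SiteDemand:
    """Annual furnace-side requirement of ``site`` under ``draw``.

    The sampled slag mass is spread evenly over the sampled activity period
    (inclusive of both end years); charcoal, dry wood and wood volume follow
    from the run's furnace inefficiency, kiln productivity and specific
    gravity.
    """
    t_s, t_e = draw.periods[site.id]
    mass = draw.slag[site.id]
    annual_slag = mass / (t_e - t_s + 1)
    charcoal = annual_slag * draw.furnace_inefficiency
    dry_wood = charcoal / draw.kiln_productivity
    return SiteDemand(
        site_id=site.id, t_s=t_s, t_e=t_e,
        slag=annual_slag, charcoal=charcoal, dry_wood=dry_wood,
        wood_volume=dry_wood / draw.specific_gravity,
    )


def island_series(sites: list[Site], draw: ParameterDraw) -> pd.DataFrame:
    """Aggregate annual exosomatic demand series over all sites.

    Returns a DataFrame indexed by calendar year (signed integers) with
    columns ``slag``, ``charcoal`` and ``dry_wood`` (t/yr).
    """
    demands = [exosomatic_demand(site, draw) for site in sites]
    t0 = min(d.t_s for d in demands)
    t1 = max(d.t_e for d in demands)
    years = np.arange(t0, t1 + 1)
    slag = np.zeros(years.size)
    for d in demands:
        slag[d.t_s - t0: d.t_e - t0 + 1] += d.slag
    charcoal = slag * draw.furnace_inefficiency
    wood = charcoal / draw.kiln_productivity
    return pd.DataFrame({"slag": slag, "charcoal": charcoal, "dry_wood": wood},
                        index=pd.Index(years, name="year"))


def demand_ledger(sites: list[Site], draw: ParameterDraw) -> pd.DataFrame:
    """Tidy per-year ledger of the exosomatic cascade, one row per quantity.

    Columns: ``year, site_id, quantity, value, unit, category`` — suitable
    for direct CSV export.
    """
    rows = []
    for site in sites:
        sd = exosomatic_demand(site, draw)
        for year in range(sd.t_s, sd.t_e + 1):
            rows.extend([
                (year, site.id, "slag", sd.slag, "t", "exosomatic"),
                (year, site.id, "charcoal", sd.charcoal, "t", "exosomatic"),
                (year, site.id, "dry_wood", sd.dry_wood, "t", "exosomatic"),
                (year, site.id, "wood_volume", sd.wood_volume, "m3", "exosomatic"),
            ])
    return pd.DataFrame(rows, columns=["year", "site_id", "quantity",
                                       "value", "unit", "category"])


@dataclass(frozen=True)
class Workforce:
    """Per-year workforce counts by occupational group.

    ``transport_animals`` are beasts of burden, not people; they are kept
    out of the human ``total`` but drive pasture area and driver counts.
    ``miners`` are sized from the regional ore demand and are excluded from
    the headline ``total`` unless configured otherwise.
    """

    smelters: int
    charcoal_burners: int
    woodcutters: int
    transport_animals: int
    drivers: int
    seafarers: int
    miners: int
    supervision: int
    service: int
    total: int


def labour_cascade(island_year_totals: Mapping[str, float], draw: ParameterDraw,
                   config: Mapping) -> Workforce:
    """Size the workforce behind one year's island-wide material flows.

    ``island_year_totals`` carries the year's flows in tonnes (and hectares):
    ``slag`` (t), ``wood`` (t dry wood carbonised), ``felled_ha`` (ha),
    ``overland_mass`` (t moved by animal), ``sea_mass`` (t sea freight) and
    ``regional_ore`` (t, full regional extraction attributed to mining).
    Fractional counts are rounded up per group; supervision and service
    surcharges apply to the human core subtotal (compounded by default).
    """
    lab = config["labour"]
    flows = {k: float(island_year_totals.get(k, 0.0)) for k in
             ("slag", "wood", "felled_ha", "overland_mass", "sea_mass", "regional_ore")}
    for name, value in flows.items():
        if value < 0:
            raise ValueError(f"negative {name} in labour cascade: {value}")

    smelters = math.ceil(flows["slag"] / lab["smelter_t_per_capita"])
    if draw.kiln_type == "pit":
        batches = flows["wood"] / lab["pit_batch_t"]
        person_days = batches * lab["pit_person_days"]
    else:
        batches = flows["wood"] / lab["mound_batch_t"]
        person_days = batches * lab["mound_person_days"]
    charcoal_burners = math.ceil(person_days / lab["working_days"])
    woodcutters = math.ceil(flows["felled_ha"] / lab["woodcutter_ha_per_capita"])
    animals = math.ceil(flows["overland_mass"] / lab["animal_t_per_capita"])
    drivers = math.ceil(animals / lab["animals_per_driver"])
    seafarers = math.ceil(flows["sea_mass"] / lab["seafarer_t_per_capita"])
    miners = math.ceil(flows["regional_ore"] / lab["miner_t_per_capita"])

    core = smelters + charcoal_burners + woodcutters + drivers + seafarers
    if lab["include_miners_in_total"]:
        core += miners
    supervision = math.ceil(lab["supervision_rate"] * core)
    service_base = core + supervision if lab["compound_service"] else core
    service = math.ceil(lab["service_rate"] * service_base)

    return Workforce(
        smelters=smelters, charcoal_burners=charcoal_burners,
        woodcutters=woodcutters, transport_animals=animals, drivers=drivers,
        seafarers=seafarers, miners=miners, supervision=supervision,
        service=service, total=core + supervision + service,
    )


@dataclass(frozen=True)
class LandRequirement:
    """Per-year non-furnace land and fuel requirement of the population."""

    farmland_ha: float
    pasture_ha: float
    browse_ha: float
    household_wood: float   # t dry wood /yr

    def __post_init__(self) -> None:
        for name in ("farmland_ha", "pasture_ha", "browse_ha", "household_wood"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative land requirement {name}")


def endosomatic_demand(workforce: Workforce, draw: ParameterDraw,
                       config: Mapping, *, extra_capita: int = 0) -> LandRequirement:
    """Convert a year's population into land and household-fuel requirements.

    ``extra_capita`` adds people outside ``workforce.total`` (e.g. miners
    when they are excluded from the headline total but live on the island).
    Household charcoal is by default produced like industrial charcoal, so
    the wood requirement is charcoal divided by the run's kiln productivity.
    """
    capita = workforce.total + extra_capita
    food = config["food"]
    household_charcoal = capita * draw.household_fuel
    if config.get("household_charcoal", True):
        household_wood = household_charcoal / draw.kiln_productivity
    else:
        household_wood = household_charcoal
    return LandRequirement(
        farmland_ha=food["farmland_ha_per_capita"] * capita,
        pasture_ha=(food["pasture_ha_per_capita"] * capita
                    + draw.pasture_per_animal * workforce.transport_animals),
        browse_ha=food["browse_ha_per_capita"] * capita,
        household_wood=household_wood,
    )


def mining_profile(draw: ParameterDraw, config: Mapping,
                   profile=None) -> pd.Series:
    """Distribute the run's total ore extraction over the mining chronology.

    Returns a Series of ore mass (t/yr) indexed by year over
    ``[mine_start, mine_end)``.  ``profile`` may be ``'uniform'``, a list of
    ``(year, weight)`` nodes (piecewise-linear, the default from the config),
    or an explicit per-year weight Series (normalised with a warning if the
    weights do not sum to one).  The series always integrates exactly to the
    drawn ore total.
    """
    years = np.arange(config["mine_start"], config["mine_end"])
    if profile is None:
        profile = config["mine_profile"]
    if isinstance(profile, str) and profile == "uniform":
        weights = np.ones(years.size)
    elif isinstance(profile, pd.Series):
        weights = profile.reindex(years).fillna(0.0).to_numpy(float)
        if not np.isclose(weights.sum(), 1.0):
            warnings.warn("mining profile weights do not sum to 1; normalising",
                          stacklevel=2)
    else:
        nodes = sorted((int(y), float(w)) for y, w in profile)
        node_years = [y for y, _ in nodes]
        node_weights = [w for _, w in nodes]
        weights = np.interp(years, node_years, node_weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError("mining profile has no positive weight")
    ore = weights / total * draw.ore_total * 1e6
    return pd.Series(ore, index=pd.Index(years, name="year"), name="ore_t")
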