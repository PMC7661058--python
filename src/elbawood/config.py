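"""Model configuration: defaults and YAML/JSON overrides.

Every tunable of the simulator lives in one flat-ish dictionary so a run
manifest (seed + resolved configuration) can be serialised next to its
outputs.  Values are the model's defaults for the Elba case; any key can be
overridden from a YAML or JSON file or a plain ``dict``.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Default model parameters (units in comments).
DEFAULTS: dict[str, Any] = {
    # --- smelting technology -------------------------------------------------
    # charcoal : slag ratio, right-skewed (lognormal), truncated to its range
    "furnace_inefficiency": {"low": 2.0, "high": 8.5, "mean": 5.25, "sd": 1.75},
    # charcoal : dry wood ratio per kiln type; normal(mid-range, range/6)
    "kiln_productivity": {
        "pit": {"low": 0.07, "high": 0.17},
        "mound": {"low": 0.135, "high": 0.28},
    },
    # 'pit' | 'mound' | 'mixed'; 'mixed' draws the type per run
    "kiln_mode": "mixed",
    "p_mound": 0.5,                      # P(mound) under kiln_mode='mixed'
    # --- mining --------------------------------------------------------------
    "ore_total_mt": {"low": 0.97, "high": 3.67},   # Mt, uniform
    "slag_to_ore": 1.35,                 # kg ore charged per kg slag produced
    "mine_start": -600,                  # mining chronology span (years)
    "mine_end": 200,
    # piecewise-linear extraction-intensity nodes (year -> relative weight);
    # a documented stand-in for the speculative published intensity curve
    "mine_profile": [(-600, 0.2), (-200, 1.0), (-30, 1.0), (200, 0.1)],
    # --- labour (per-capita annual productivities) ---------------------------
    "labour": {
        "miner_t_per_capita": 23.0,          # t ore /capita/yr
        "pit_batch_t": 3.5,                  # t wood carbonised per pit batch
        "pit_person_days": 12.5,
        "mound_batch_t": 45.0,               # t wood per mound batch
        "mound_person_days": 25.0,
        "woodcutter_ha_per_capita": 13.0,    # ha felled /capita/yr
        "smelter_t_per_capita": 2.5,         # t slag /capita/yr
        "animal_t_per_capita": 187.5,        # t overland freight /animal/yr
        "animals_per_driver": 5.0,
        "seafarer_t_per_capita": 300.0,      # t sea freight /capita/yr
        "supervision_rate": 0.30,
        "service_rate": 0.30,
        # service applies after supervision (compounded); False = additive
        "compound_service": True,
        "working_days": 250.0,               # person-days -> capita conversion
        "include_miners_in_total": False,    # headline workforce excludes mining
    },
    # --- food and household supply -------------------------------------------
    "food": {
        "farmland_ha_per_capita": 2.0,
        "pasture_ha_per_capita": 0.72,
        "pasture_ha_per_animal": {"low": 0.8, "high": 1.1},
        "browse_ha_per_capita": 0.69,
    },
    "household_fuel": {"low": 0.5, "high": 2.0},   # t charcoal /capita/yr
    # domestic charcoal produced like industrial charcoal (wood = charcoal/KP);
    # False = households burn raw wood 1:1
    "household_charcoal": True,
    # --- wood supply ----------------------------------------------------------
    "increments": {"oak": 2.2, "macchia": 3.6, "chestnut": 5.7},  # m3/ha/yr, 10-yr mean
    "specific_gravity": 0.69,            # t dry wood per m3
    "rotation": {"low": 5, "high": 10},  # yrs, discrete uniform (inclusive)
    "browse_reduction": {"low": 0.40, "high": 0.60},  # fraction of increment lost
    "max_age": 42,                       # yrs, maturity cap of the growth curve
    "sigmoid_midpoint": 21.0,            # yrs, S-curve inflection age
    # browse handling: zero the cell age on first assignment and/or slow regrowth
    "browse_zeroes_age": True,
    "browse_slows_growth": True,
    # --- transport / felling order -------------------------------------------
    "transport": {
        "body_mass_kg": 70.0,
        "load_kg": 20.0,
        "terrain_factor": 1.2,
        "ranking": "cost",               # 'cost' | 'time'
    },
    # --- engine ----------------------------------------------------------------
    "resolution_m": 100.0,
    "include_mining_endosomatic": True,  # miners' households burden the island
    "randomize_site_order": False,
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the default configuration."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if key in base and isinstance(base[key], dict) and isinstance(value, Mapping):
            _merge(base[key], value)
        else:
            base[key] = value
    return base


def load_config(source: str | Path | Mapping | None = None) -> dict[str, Any]:
    """Build a configuration: defaults overlaid with ``source``.

    ``source`` may be a mapping, a path to a YAML/JSON file, or None.
    """
    config = default_config()
    if source is None:
        return config
    if isinstance(source, Mapping):
        return _merge(config, source)
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return config
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {source!r} does not contain a mapping")
    return _merge(config, data)


def write_manifest(path: str | Path, seed: int, config: Mapping) -> None:
    """Serialise a run manifest (seed + resolved parameters) as JSON."""
    payload = {"seed": int(seed), "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
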