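"""Monte Carlo parameter sampling.

One simulation run is driven by a single :class:`ParameterDraw` holding the
sampled technology globals plus, per site, an activity period and a slag
mass.  All bounded draws follow the principle of insufficient reason: a
normal centred between the admissible extremes, with a standard deviation of
one sixth of the interval length, truncated to the interval by rejection
(redraw until inside).  Furnace inefficiency is right-skewed and is drawn
from a lognormal whose underlying parameters are moment-matched to the
stated arithmetic mean and standard deviation, again truncated by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .sites import DatingWindow, Site, round_half_away

__all__ = [
    "HeapGeometry",
    "ParameterDraw",
    "truncated_normal",
    "draw_activity_period",
    "draw_slag_mass",
    "heap_mass",
    "draw_furnace_inefficiency",
    "draw_kiln_productivity",
    "draw_globals",
    "draw_parameters",
]

# default admissible constants for slag-heap volumetry
_HEAP_DELTAS = (0.41, 0.75)
_HEAP_RATIOS = (0.24, 0.4, 0.5)
_HEAP_DENSITIES = (2.0, 2.2)


@dataclass(frozen=True)
class HeapGeometry:
    """Slag-heap volumetry: ``W = ((h*delta) * a * b) * Q * rho``.

    ``a``, ``b`` (m) span the footprint, ``h`` (m) is the height/depth,
    ``delta`` corrects for the irregular underground/surface topography,
    ``Q`` is the slag-to-debris ratio of the accumulation and ``rho``
    (t/m^3) the slag density.
    """

    a: float
    b: float
    h: float
    delta: float = 0.41
    Q: float = 0.24
    rho: float = 2.0
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("a", "b", "h", "delta", "Q", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"heap geometry {name} must be positive")
        if self.strict:
            for name, allowed in (
                ("delta", _HEAP_DELTAS), ("Q", _HEAP_RATIOS), ("rho", _HEAP_DENSITIES),
            ):
                value = getattr(self, name)
                if not any(np.isclose(value, v) for v in allowed):
                    raise ValueError(
                        f"heap geometry {name}={value} not in the default set {allowed}; "
                        "pass strict=False to override"
                    )


def heap_mass(geom: HeapGeometry) -> float:
    """Slag mass (t) of an accumulation from its documented geometry."""
    return ((geom.h * geom.delta) * geom.a * geom.b) * geom.Q * geom.rho


@dataclass
class ParameterDraw:
    """All sampled quantities of one Monte Carlo run."""

    furnace_inefficiency: float          # kg charcoal per kg slag
    kiln_type: str                       # 'pit' | 'mound'
    kiln_productivity: float             # kg charcoal per kg dry wood
    rotation_period: int                 # yrs
    browse_reduction: float              # fraction of increment lost to browse
    household_fuel: float                # t charcoal /capita/yr
    ore_total: float                     # Mt over the whole mining chronology
    pasture_per_animal: float            # ha /animal
    slag_to_ore: float = 1.35            # kg ore per kg slag
    specific_gravity: float = 0.69       # t dry wood per m3
    periods: dict = field(default_factory=dict)   # site id -> (t_s, t_e)
    slag: dict = field(default_factory=dict)      # site id -> W (t)

    @property
    def wood_per_slag(self) -> float:
        """t dry wood carbonised per t slag produced."""
        return self.furnace_inefficiency / self.kiln_productivity


def truncated_normal(mean: float, sd: float, low: float, high: float,
                     rng: np.random.Generator) -> float:
    """One N(mean, sd) draw truncated to [low, high] by rejection."""
    if low > high:
        raise ValueError(f"empty truncation interval [{low}, {high}]")
    if sd <= 0 or low == high:
        return float(min(max(mean, low), high))
    while True:
        value = rng.normal(mean, sd)
        if low <= value <= high:
            return float(value)


def draw_activity_period(window: DatingWindow, rng: np.random.Generator
                         ) -> tuple[int, int]:
    """Sample a site's activity period ``(t_s, t_e)`` from its window.

    The start is normal on ``[t_alpha, t_beta]`` and the end normal on
    ``[t_gamma, t_delta]``, each centred on the interval midpoint with a
    standard deviation of one sixth of the interval length and redrawn until
    inside; both are rounded to the nearest year.  A zero-width interval
    returns its single admissible year without sampling.
    """
    t_s = truncated_normal(
        (window.t_alpha + window.t_beta) / 2,
        (window.t_beta - window.t_alpha) / 6,
        window.t_alpha, window.t_beta, rng,
    )
    t_e = truncated_normal(
        (window.t_gamma + window.t_delta) / 2,
        (window.t_delta - window.t_gamma) / 6,
        window.t_gamma, window.t_delta, rng,
    )
    t_s, t_e = round_half_away(t_s), round_half_away(t_e)
    # rounding cannot cross the inner bounds, and t_beta <= t_gamma
    assert t_s <= t_e
    return t_s, t_e


def draw_slag_mass(slag_min: float, slag_max: float,
                   rng: np.random.Generator) -> float:
    """Sample a site's true slag mass (t) between its documented extremes."""
    if not 0 < slag_min <= slag_max:
        raise ValueError(f"need 0 < slag_min <= slag_max, got ({slag_min}, {slag_max})")
    return truncated_normal(
        (slag_min + slag_max) / 2, (slag_max - slag_min) / 6,
        slag_min, slag_max, rng,
    )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a lognormal with arithmetic mean/sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(mu), float(np.sqrt(sigma2))


def draw_furnace_inefficiency(rng: np.random.Generator, *,
                              low: float = 2.0, high: float = 8.5,
                              mean: float = 5.25, sd: float = 1.75) -> float:
    """Sample the charcoal:slag ratio (kg/kg) of the smelting process.

    Right-skewed: lognormal moment-matched to the stated arithmetic mean and
    standard deviation, redrawn until inside ``[low, high]``.
    """
    mu, sigma = lognormal_params(mean, sd)
    while True:
        value = rng.lognormal(mu, sigma)
        if low <= value <= high:
            return float(value)


def draw_kiln_productivity(kiln_type: str, rng: np.random.Generator,
                           ranges: Mapping | None = None) -> float:
    """Sample the charcoal:dry-wood yield (kg/kg) of a kiln type."""
    ranges = ranges or {"pit": {"low": 0.07, "high": 0.17},
                        "mound": {"low": 0.135, "high": 0.28}}
    if kiln_type not in ranges:
        raise ValueError(f"unknown kiln type {kiln_type!r}; expected one of {sorted(ranges)}")
    low, high = ranges[kiln_type]["low"], ranges[kiln_type]["high"]
    return truncated_normal((low + high) / 2, (high - low) / 6, low, high, rng)


def _uniform(bounds: Mapping, rng: np.random.Generator) -> float:
    return float(rng.uniform(bounds["low"], bounds["high"]))


def draw_globals(config: Mapping, rng: np.random.Generator) -> dict:
    """Sample the island-wide globals of one run (no per-site quantities)."""
    mode = config["kiln_mode"]
    if mode == "mixed":
        kiln_type = "mound" if rng.uniform() < config["p_mound"] else "pit"
    elif mode in ("pit", "mound"):
        kiln_type = mode
    else:
        raise ValueError(f"unknown kiln_mode {mode!r}")
    fi = config["furnace_inefficiency"]
    return {
        "furnace_inefficiency": draw_furnace_inefficiency(
            rng, low=fi["low"], high=fi["high"], mean=fi["mean"], sd=fi["sd"]),
        "kiln_type": kiln_type,
        "kiln_productivity": draw_kiln_productivity(
            kiln_type, rng, config["kiln_productivity"]),
        "rotation_period": int(rng.integers(config["rotation"]["low"],
                                            config["rotation"]["high"] + 1)),
        "browse_reduction": _uniform(config["browse_reduction"], rng),
        "household_fuel": _uniform(config["household_fuel"], rng),
        "ore_total": _uniform(config["ore_total_mt"], rng),
        "pasture_per_animal": _uniform(config["food"]["pasture_ha_per_animal"], rng),
        "slag_to_ore": float(config["slag_to_ore"]),
        "specific_gravity": float(config["specific_gravity"]),
    }


def draw_parameters(sites: list[Site], config: Mapping,
                    rng: np.random.Generator) -> ParameterDraw:
    """Sample the complete parameter set of one Monte Carlo run."""
    draw = ParameterDraw(**draw_globals(config, rng))
    for site in sites:
        draw.periods[site.id] = draw_activity_period(site.window, rng)
        draw.slag[site.id] = draw_slag_mass(site.slag_min, site.slag_max, rng)
    return draw
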