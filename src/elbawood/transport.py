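"""Transport cost: walking speed, load-carriage energetics, felling order.

Felling preference is a function of transport cost from the smelting site:
walking speed on a grade follows Tobler's hiking function, and the metabolic
cost of carrying a load follows the Pandolf equation uphill with the Santee
downhill correction.  Per the model's fidelity level, the cost to a cell
uses the straight segment from site to cell — its Euclidean length and the
mean slope sampled along it — rather than a full least-cost path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape

__all__ = ["TransportParams", "tobler_speed", "pandolf_cost", "site_cost_surface"]


@dataclass(frozen=True)
class TransportParams:
    """Load-carriage parameters: body mass, load, terrain factor."""

    body_mass_kg: float = 70.0
    load_kg: float = 20.0
    terrain_factor: float = 1.2
    ranking: str = "cost"   # 'cost' (kJ) or 'time' (h) as the felling-order key

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        if self.load_kg < 0 or self.terrain_factor <= 0:
            raise ValueError("load and terrain factor must be non-negative/positive")
        if self.ranking not in ("cost", "time"):
            raise ValueError(f"unknown ranking key {self.ranking!r}")


def tobler_speed(slope):
    """Walking speed (km/h) on a grade (rise/run): ``6 exp(-3.5|s+0.05|)``."""
    slope = np.asarray(slope, dtype=float)
    return 6.0 * np.exp(-3.5 * np.abs(slope + 0.05))


def pandolf_cost(slope, distance_m, params: TransportParams = TransportParams()):
    """Metabolic cost (kJ) of carrying the load over ``distance_m`` at ``slope``.

    The metabolic rate (W) is ``1.5 Wb + 2 (Wb+L)(L/Wb)^2 +
    eta (Wb+L)(1.5 v^2 + 0.35 v g)`` with the grade ``g`` in percent and the
    Tobler speed ``v`` in m/s; for negative grades the Santee correction is
    subtracted.  The rate is floored at the standing term so steep descents
    cannot go negative.  Cost is rate times travel time.
    """
    slope = np.asarray(slope, dtype=float)
    distance = np.asarray(distance_m, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    w, load, eta = params.body_mass_kg, params.load_kg, params.terrain_factor
    v = tobler_speed(slope) / 3.6          # m/s
    g = slope * 100.0                      # percent grade
    total = w + load
    rate = 1.5 * w + 2.0 * total * (load / w) ** 2 \
        + eta * total * (1.5 * v ** 2 + 0.35 * v * g)
    downhill = eta * (g * total * v / 3.5
                      - total * (g + 6.0) ** 2 * v / w
                      + 25.0 - v ** 2)
    rate = np.where(g < 0, rate - downhill, rate)
    rate = np.maximum(rate, 1.5 * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        seconds = np.where(distance > 0, distance / v, 0.0)
    return rate * seconds / 1000.0         # W * s -> kJ


def _mean_slope_along_paths(landscape: Landscape, site_rc: tuple[int, int],
                            n_samples: int = 33) -> np.ndarray:
    """Mean raster slope sampled on the straight segment site -> each cell."""
    nrows, ncols = landscape.shape
    r0, c0 = site_rc
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    t = np.linspace(0.0, 1.0, n_samples)
    # (ncells, n_samples) sample coordinates, nearest-neighbour lookup
    rr = np.rint(r0 + (rows.ravel()[:, None] - r0) * t).astype(int)
    cc = np.rint(c0 + (cols.ravel()[:, None] - c0) * t).astype(int)
    return landscape.slope[rr, cc].mean(axis=1)


def site_cost_surface(landscape: Landscape, site_rc: tuple[int, int],
                      params: TransportParams = TransportParams()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Rank every cell by transport cost from a site.

    Returns ``(order, cost)``: ``order`` is all flat cell indices sorted by
    the ranking key (ties broken by distance, then row-major index, so the
    ordering is deterministic); ``cost`` is the per-cell key value.  The
    site's own cell has zero cost and rank one.
    """
    nrows, ncols = landscape.shape
    r0, c0 = site_rc
    if not (0 <= r0 < nrows and 0 <= c0 < ncols):
        raise ValueError(f"site location {site_rc} is off the {landscape.shape} grid")
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    distance = np.hypot(rows - r0, cols - c0).ravel() * landscape.resolution
    mean_slope = _mean_slope_along_paths(landscape, site_rc)
    if params.ranking == "time":
        with np.errstate(divide="ignore"):
            key = distance / (tobler_speed(mean_slope) / 3.6) / 3600.0
    else:
        key = pandolf_cost(mean_slope, distance, params)
    order = np.lexsort((np.arange(key.size), distance, key))
    return order, key
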