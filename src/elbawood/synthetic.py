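"""Synthetic inputs: island rasters, slope fields, site catalogues.

The generator emulates the statistical structure the simulator assumes —
an island of spatially coherent vegetation patches (oak, macchia, chestnut)
with a slope field, coastal smelting sites, and a site catalogue whose
dating windows span a production arc (few small early sites, many larger
ones in the intensive phase).  The ``elba_like`` preset reproduces the real
case's magnitudes (circa 224 km2 of land, macchia-dominant cover, the
packaged 29-site catalogue); ``abundant`` and ``scarce`` presets pin the
ratio of initial woodland stock to expected demand at generous and hopeless
levels for calibration tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .config import default_config
from .landscape import CLASS_CODES, SEA, BARE, Landscape, growth_curves, standing_stock
from .sites import DatingFind, Site, derive_window, load_sites, packaged_catalogue_path

__all__ = ["IslandSpec", "make_island", "place_sites", "elba_catalogue",
           "elba_like_spec", "abundant_spec", "scarce_spec", "measured_ratio"]


@dataclass
class IslandSpec:
    """Recipe for one synthetic island scenario."""

    shape: tuple[int, int] = (120, 120)
    resolution: float = 100.0            # m per cell
    landmass_fraction: float = 0.5       # of the grid
    mix: Mapping[str, float] = dataclass_field(
        default_factory=lambda: {"oak": 0.25, "macchia": 0.55, "chestnut": 0.08})
    relief: float = 0.3                  # typical slope magnitude (rise/run)
    smooth: float = 6.0                  # coherence length of the noise, cells
    n_sites: int = 10
    stock_to_demand_ratio: float | None = None   # None: keep catalogue slag as-is
    use_packaged_catalogue: bool = False
    n_regions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.landmass_fraction <= 0.95):
            raise ValueError("landmass fraction must be in (0, 0.95]")
        total = sum(self.mix.values())
        if total > 1.0 + 1e-9:
            raise ValueError("vegetation mix fractions must sum to <= 1")
        if self.stock_to_demand_ratio is not None and self.stock_to_demand_ratio <= 0:
            raise ValueError("stock_to_demand_ratio must be positive")


def _coherent_noise(shape, smooth, rng) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal(shape), smooth, mode="nearest")
    return (noise - noise.mean()) / (noise.std() + 1e-12)


def make_island(spec: IslandSpec) -> Landscape:
    """Generate the raster landscape of a spec; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    r0, c0 = (nrows - 1) / 2, (ncols - 1) / 2
    radial = 1.0 - np.hypot((rows - r0) / (nrows / 2), (cols - c0) / (ncols / 2))

    base = _coherent_noise(spec.shape, spec.smooth, rng) + 2.0 * radial
    threshold = np.quantile(base, 1.0 - spec.landmass_fraction)
    land = base > threshold
    land[0, :] = land[-1, :] = land[:, 0] = land[:, -1] = False  # guarantee coast

    # synthetic elevation above sea level -> slope magnitude
    elevation = np.where(land, base - threshold, 0.0)
    if elevation.max() > 0:
        elevation = elevation / elevation.max()
    scale = spec.relief * spec.resolution * 12.0   # peak height, m
    gy, gx = np.gradient(elevation * scale, spec.resolution)
    slope = np.hypot(gy, gx)
    slope[~land] = 0.0

    # vegetation classes in coherent patches, honouring the mix among land cells
    veg = np.full(spec.shape, SEA, dtype=np.int8)
    veg[land] = BARE
    patchiness = _coherent_noise(spec.shape, spec.smooth, rng)
    values = patchiness[land]
    quantile_edge = 0.0
    for name in ("chestnut", "oak", "macchia"):   # rarest first for clean patches
        frac = spec.mix.get(name, 0.0)
        if frac <= 0:
            continue
        low = np.quantile(values, quantile_edge)
        high = np.quantile(values, min(1.0, quantile_edge + frac))
        select = land & (patchiness >= low) & (patchiness < high) \
            if quantile_edge + frac < 1.0 else land & (patchiness >= low)
        veg[select & (veg == BARE)] = CLASS_CODES[name]
        quantile_edge += frac

    age = np.where(veg > 0, 42.0, 0.0)   # undisturbed mature woodland

    region = None
    if spec.n_regions > 0:
        angle = np.arctan2(rows - r0, cols - c0)
        region = ((angle + np.pi) / (2 * np.pi) * spec.n_regions).astype(int)
        region = np.clip(region, 0, spec.n_regions - 1)
        region[~land] = -1

    return Landscape(resolution=spec.resolution, veg=veg, age=age,
                     slope=slope, region=region)


def _coastal_cells(landscape: Landscape) -> np.ndarray:
    """Flat indices of land cells bordering the sea."""
    land = landscape.land
    interior = binary_erosion(land)
    coast = land & ~interior
    return np.flatnonzero(coast.ravel())


def _production_arc_catalogue(n_sites: int, rng: np.random.Generator
                              ) -> tuple[list[dict], dict]:
    """Windows and relative slag sizes along an early->intensive arc."""
    entries, finds = [], {}
    for i in range(n_sites):
        frac = i / max(n_sites - 1, 1)
        centre = int(round(-260 + 190 * frac + rng.normal(0, 15)))
        n_finds = int(rng.integers(1, 4))
        site_finds = []
        for _ in range(n_finds):
            width = int(rng.integers(40, 120))
            mid = centre + int(rng.normal(0, 25))
            site_finds.append(DatingFind(site_id=i + 1, a=mid - width // 2,
                                         b=mid + width // 2))
        with warnings.catch_warnings():
            # nested find intervals are expected here; the midpoint repair
            # inside derive_window is the intended behaviour
            warnings.simplefilter("ignore", UserWarning)
            window = derive_window(site_finds)
        # early sites small, intensive-phase sites larger
        size = (0.4 + 1.6 * frac) * rng.lognormal(0.0, 0.4)
        entries.append({"id": i + 1, "name": f"synthetic-{i + 1}",
                        "window": window, "size": size})
        finds[i + 1] = site_finds
    return entries, finds


def place_sites(landscape: Landscape, spec: IslandSpec,
                config: Mapping | None = None
                ) -> tuple[list[Site], dict]:
    """Place the site catalogue on the coast and scale its slag masses.

    Returns ``(sites, finds)``.  Locations are coastal cells spread evenly
    around the shoreline (deterministic from the spec seed).  With
    ``use_packaged_catalogue`` the packaged 29-site windows and slag bounds
    are used verbatim; otherwise windows are derived from generated dating
    finds along the production arc.  When ``stock_to_demand_ratio`` is set,
    slag bounds are rescaled so that the initial island dry mass divided by
    the expected total wood demand (mid-range parameters) hits the ratio.
    """
    config = config or default_config()
    coast = _coastal_cells(landscape)
    if coast.size == 0:
        raise ValueError("landscape has no coastal cells")
    rng = np.random.default_rng((spec.seed, 1))

    if spec.use_packaged_catalogue:
        catalogue = elba_catalogue()
        finds: dict = {}
    else:
        entries, finds = _production_arc_catalogue(spec.n_sites, rng)
        base = 2000.0
        catalogue = [
            Site(id=e["id"], name=e["name"], window=e["window"],
                 slag_min=0.5 * base * e["size"], slag_max=1.5 * base * e["size"])
            for e in entries
        ]

    # spread sites around the coastline by angle, with a random phase
    nrows, ncols = landscape.shape
    rr, cc = np.unravel_index(coast, landscape.shape)
    angles = np.arctan2(rr - (nrows - 1) / 2, cc - (ncols - 1) / 2)
    order = np.argsort(angles, kind="stable")
    offset = int(rng.integers(coast.size))
    step = coast.size / len(catalogue)
    for i, site in enumerate(catalogue):
        pick = coast[order[(offset + int(i * step)) % coast.size]]
        site.location = tuple(int(v) for v in np.unravel_index(pick, landscape.shape))

    if spec.stock_to_demand_ratio is not None:
        current = _expected_wood_demand(catalogue, config)
        stock = _initial_stock(landscape, config)
        target_demand = stock / spec.stock_to_demand_ratio
        factor = target_demand / current
        for site in catalogue:
            site.slag_min *= factor
            site.slag_max *= factor
    return catalogue, finds


def _initial_stock(landscape: Landscape, config: Mapping) -> float:
    curves = growth_curves(config)
    return float(standing_stock(landscape, curves,
                                config["specific_gravity"]).sum())


def _mid_kiln_productivity(config: Mapping) -> float:
    ranges = config["kiln_productivity"]
    mids = {k: (v["low"] + v["high"]) / 2 for k, v in ranges.items()}
    mode = config["kiln_mode"]
    if mode in mids:
        return mids[mode]
    p = config["p_mound"]
    return p * mids["mound"] + (1 - p) * mids["pit"]


def _expected_wood_demand(catalogue: list[Site], config: Mapping) -> float:
    """Expected total dry-wood demand (t) at mid-range parameters."""
    fi = config["furnace_inefficiency"]["mean"]
    kp = _mid_kiln_productivity(config)
    mid_slag = sum((s.slag_min + s.slag_max) / 2 for s in catalogue)
    return mid_slag * fi / kp


def measured_ratio(landscape: Landscape, catalogue: list[Site],
                   config: Mapping | None = None) -> float:
    """Realised stock-to-demand ratio of a generated scenario."""
    config = config or default_config()
    return _initial_stock(landscape, config) / _expected_wood_demand(catalogue, config)


def elba_catalogue() -> list[Site]:
    """The packaged 29-site Elba catalogue (windows and slag bounds)."""
    return load_sites(packaged_catalogue_path())


# --- presets ------------------------------------------------------------------

def elba_like_spec(resolution: float = 100.0, seed: int = 0) -> IslandSpec:
    """An island of the real case's magnitudes at the given working resolution."""
    land_cells = 224e6 / resolution ** 2          # ~224 km2 of land
    fraction = 0.6
    side = math.ceil(math.sqrt(land_cells / fraction))
    return IslandSpec(
        shape=(side, side), resolution=resolution, landmass_fraction=fraction,
        mix={"oak": 0.25, "macchia": 0.55, "chestnut": 0.08},
        relief=0.3, smooth=max(3.0, 600.0 / resolution),
        n_sites=29, use_packaged_catalogue=True,
        stock_to_demand_ratio=None, n_regions=12, seed=seed,
    )


def abundant_spec(seed: int = 0) -> IslandSpec:
    """Small island with ten times more standing stock than expected demand."""
    return IslandSpec(shape=(60, 60), resolution=100.0, landmass_fraction=0.5,
                      n_sites=5, stock_to_demand_ratio=10.0, seed=seed)


def scarce_spec(seed: int = 0) -> IslandSpec:
    """Small island with a tenth of the stock the expected demand requires."""
    return IslandSpec(shape=(60, 60), resolution=100.0, landmass_fraction=0.5,
                      n_sites=5, stock_to_demand_ratio=0.1, seed=seed)
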