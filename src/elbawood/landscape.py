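"""Raster woodland state: growth, harvest, browse and land allocation.

The island is a regular grid.  Every woodland cell carries a vegetation
class (oak forest, Mediterranean macchia shrubland, sweet chestnut forest),
a tree age (0..42 yr, fractional while browsed) and a slope value.  Standing
volume follows a logistic S-curve per class, anchored so that the mean
annual increment over the first ten years matches the class's tabulated
value and the stand is within 1% of its asymptotic volume at the 42-yr
maturity horizon.  Dry mass is volume times a constant specific gravity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .demand import LandRequirement

__all__ = [
    "SEA", "BARE", "CLASS_CODES",
    "GrowthCurve", "calibrate_growth", "Landscape",
    "standing_stock", "regrow", "harvest_cells", "allocate_nonwood",
    "read_ascii_grid", "write_ascii_grid",
]

SEA = -1          # vegetation code: open water
BARE = 0          # land without woodland vegetation
CLASS_CODES = {"oak": 1, "macchia": 2, "chestnut": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

# land-use flags on top of the vegetation layer
USE_WOODLAND = 0
USE_FARMLAND = 1
USE_PASTURE = 2

MAX_AGE = 42      # yrs; tree age caps here ("mature" woodland)


@dataclass(frozen=True)
class GrowthCurve:
    """Logistic standing-volume curve of one vegetation class.

    ``V(age) = scale * (sigmoid(k*(age - a0)) - sigmoid(-k*a0))`` so that
    ``V(0) = 0``; ``v_max`` is the asymptotic volume above the offset.
    """

    veg_class: str
    v_max: float      # m3/ha, asymptote
    k: float          # 1/yr, steepness
    a0: float         # yr, inflection age
    scale: float      # m3/ha, logistic amplitude

    def volume(self, age):
        """Standing volume (m3/ha) at ``age`` (scalar or array)."""
        age = np.asarray(age, dtype=float)
        f = 1.0 / (1.0 + np.exp(-self.k * (age - self.a0)))
        f0 = 1.0 / (1.0 + np.exp(self.k * self.a0))
        return self.scale * (f - f0)


def calibrate_growth(veg_class: str, config: Mapping) -> GrowthCurve:
    """Fit the class's S-curve from its 10-yr mean annual increment.

    Constraints: V(0) = 0; V(10)/10 equals the configured increment; the
    42-yr volume reaches 99% of the asymptote.  The inflection age ``a0``
    (default: mid-span, 21 yr) fixes the remaining degree of freedom.
    """
    increment = config["increments"][veg_class]
    a0 = float(config.get("sigmoid_midpoint", 21.0))
    max_age = float(config.get("max_age", MAX_AGE))

    def saturation_gap(k: float) -> float:
        with np.errstate(over="ignore"):
            f = lambda a: 1.0 / (1.0 + np.exp(-k * (a - a0)))
            return (f(max_age) - f(0.0)) - 0.99 * (1.0 - f(0.0))

    try:
        k = brentq(saturation_gap, 1e-4, 5.0, xtol=1e-12)
    except ValueError as exc:  # bracket failure
        raise RuntimeError(
            f"growth-curve fit for {veg_class!r} did not converge "
            f"(a0={a0}, max_age={max_age}): {exc}"
        ) from exc
    f = lambda a: 1.0 / (1.0 + np.exp(-k * (a - a0)))
    scale = 10.0 * increment / (f(10.0) - f(0.0))
    v_max = scale * (1.0 - f(0.0))
    return GrowthCurve(veg_class=veg_class, v_max=v_max, k=k, a0=a0, scale=scale)


def growth_curves(config: Mapping) -> dict[int, GrowthCurve]:
    """Calibrated curves keyed by vegetation-class code."""
    return {code: calibrate_growth(name, config)
            for name, code in CLASS_CODES.items()}


@dataclass
class Landscape:
    """Raster state of the island.

    Arrays share one 2-D shape: ``veg`` (class codes, ``SEA``/``BARE``
    outside woodland), ``age`` (yr, meaningful only on woodland cells),
    ``slope`` (rise/run), ``land_use`` (woodland/farmland/pasture) and the
    ``browse`` flag (cell remains woodland but regrows slowly).  ``region``
    optionally labels cells for regional aggregation.
    """

    resolution: float                   # m per cell edge
    veg: np.ndarray                     # int8
    age: np.ndarray                     # float
    slope: np.ndarray                   # float
    land_use: np.ndarray = None         # int8
    browse: np.ndarray = None           # bool
    region: np.ndarray | None = None    # int, -1 = unassigned

    def __post_init__(self) -> None:
        if self.land_use is None:
            self.land_use = np.zeros(self.veg.shape, dtype=np.int8)
        if self.browse is None:
            self.browse = np.zeros(self.veg.shape, dtype=bool)
        shapes = {a.shape for a in (self.veg, self.age, self.slope,
                                    self.land_use, self.browse)}
        if len(shapes) != 1:
            raise ValueError(f"landscape layers disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.veg.shape

    @property
    def cell_area_ha(self) -> float:
        return self.resolution ** 2 / 1e4

    @property
    def woodland(self) -> np.ndarray:
        """Cells currently available as woodland (not farm/pasture)."""
        return (self.veg > 0) & (self.land_use == USE_WOODLAND)

    @property
    def land(self) -> np.ndarray:
        return self.veg != SEA

    def copy(self) -> "Landscape":
        return copy.deepcopy(self)

    def save(self, directory: str | Path) -> None:
        """Write the state as ESRI ASCII grids (veg/age/slope/region)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(directory / "veg.asc", self.veg, self.resolution)
        write_ascii_grid(directory / "age.asc", self.age, self.resolution)
        write_ascii_grid(directory / "slope.asc", self.slope, self.resolution)
        if self.region is not None:
            write_ascii_grid(directory / "region.asc", self.region, self.resolution)

    @classmethod
    def load(cls, directory: str | Path) -> "Landscape":
        directory = Path(directory)
        veg, meta = read_ascii_grid(directory / "veg.asc")
        age, _ = read_ascii_grid(directory / "age.asc")
        slope, _ = read_ascii_grid(directory / "slope.asc")
        region = None
        if (directory / "region.asc").exists():
            region, _ = read_ascii_grid(directory / "region.asc")
            region = region.astype(int)
        return cls(resolution=meta["cellsize"], veg=veg.astype(np.int8),
                   age=age.astype(float), slope=slope.astype(float),
                   region=region)


def standing_stock(landscape: Landscape, curves: Mapping[int, GrowthCurve],
                   specific_gravity: float = 0.69) -> np.ndarray:
    """Dry mass (t) standing on each cell; zero outside woodland."""
    stock = np.zeros(landscape.shape, dtype=float)
    area = landscape.cell_area_ha
    for code, curve in curves.items():
        mask = (landscape.veg == code) & (landscape.land_use == USE_WOODLAND)
        if mask.any():
            stock[mask] = curve.volume(landscape.age[mask]) * area * specific_gravity
    return stock


def regrow(landscape: Landscape, browse_reduction: float = 0.0,
           browse_slows_growth: bool = True) -> Landscape:
    """Advance tree ages by one year (in place), capped at maturity.

    Browsed cells accumulate age at the reduced rate ``1 - browse_reduction``
    (a fractional-age accumulator standing in for the lost increment).
    """
    wood = landscape.woodland
    gain = np.ones(landscape.shape)
    if browse_slows_growth:
        gain[landscape.browse] = 1.0 - browse_reduction
    landscape.age[wood] = np.minimum(landscape.age[wood] + gain[wood], MAX_AGE)
    return landscape


def harvest_cells(landscape: Landscape, cells: np.ndarray,
                  curves: Mapping[int, GrowthCurve],
                  specific_gravity: float = 0.69,
                  min_age: float | None = None) -> float:
    """Fell the given cells (flat indices): return dry mass (t), zero ages.

    Callers pre-filter for eligibility; if ``min_age`` is given, any listed
    cell at or below it raises.
    """
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        return 0.0
    flat_veg = landscape.veg.ravel()
    flat_use = landscape.land_use.ravel()
    if np.any(flat_veg[cells] <= 0) or np.any(flat_use[cells] != USE_WOODLAND):
        raise ValueError("harvest list contains non-woodland cells")
    flat_age = landscape.age.ravel()
    if min_age is not None and np.any(flat_age[cells] <= min_age):
        raise ValueError(f"harvest list contains cells at age <= {min_age}")
    area = landscape.cell_area_ha
    removed = 0.0
    for code, curve in curves.items():
        sel = cells[flat_veg[cells] == code]
        if sel.size:
            removed += float(np.sum(curve.volume(flat_age[sel]))) * area * specific_gravity
    flat_age[cells] = 0.0
    return removed


def allocate_nonwood(landscape: Landscape, requirement: LandRequirement,
                     priority: np.ndarray, zero_browse_age: bool = True) -> float:
    """Assign farmland, pasture and browse for the year (in place).

    ``priority`` is an array of flat cell indices in conversion order
    (cheapest first, land cells only).  Farmland and pasture claim the
    cheapest cells (ages zeroed, excluded from felling while flagged);
    browse flags the next-cheapest woodland cells, which stay woodland but
    regrow slowly (age zeroed on first assignment).  Assignments are redone
    from the same order every year, so a shrinking requirement releases the
    most expensive cells first.  Returns the unmet area (ha), which is
    positive when the island is smaller than the requirement.
    """
    area = landscape.cell_area_ha
    n_farm = int(np.ceil(requirement.farmland_ha / area))
    n_pasture = int(np.ceil(requirement.pasture_ha / area)) if requirement.pasture_ha else 0
    n_browse = int(np.ceil(requirement.browse_ha / area)) if requirement.browse_ha else 0

    flat_use = landscape.land_use.ravel()
    flat_age = landscape.age.ravel()
    flat_veg = landscape.veg.ravel()

    converted = priority[:n_farm + n_pasture]
    newly_converted = converted[flat_use[converted] == USE_WOODLAND]
    flat_age[newly_converted] = 0.0
    released = priority[n_farm + n_pasture:][
        flat_use[priority[n_farm + n_pasture:]] != USE_WOODLAND]
    flat_use[released] = USE_WOODLAND
    flat_use[converted[:n_farm]] = USE_FARMLAND
    flat_use[converted[n_farm:]] = USE_PASTURE

    # browse claims the next-cheapest still-woodland cells
    flat_browse = landscape.browse.ravel()
    remaining = priority[n_farm + n_pasture:]
    candidates = remaining[(flat_veg[remaining] > 0)
                           & (flat_use[remaining] == USE_WOODLAND)]
    browse_cells = candidates[:n_browse]
    new_flags = browse_cells[~flat_browse[browse_cells]]
    if zero_browse_age:
        flat_age[new_flags] = 0.0
    flat_browse[:] = False
    flat_browse[browse_cells] = True

    unmet_cells = max(0, n_farm + n_pasture - converted.size) \
        + max(0, n_browse - browse_cells.size)
    return unmet_cells * area


# --- ESRI ASCII grid I/O ------------------------------------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray, cellsize: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999) -> None:
    """Write a 2-D array as an ESRI ASCII grid (plain text)."""
    array = np.asarray(array)
    header = (
        f"ncols {array.shape[1]}\n"
        f"nrows {array.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as handle:
        handle.write(header)
        np.savetxt(handle, array, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header metadata)."""
    meta: dict = {}
    with open(path) as handle:
        for _ in range(6):
            key, value = handle.readline().split()
            meta[key.lower()] = float(value)
        array = np.loadtxt(handle)
    array = np.atleast_2d(array)
    expected = (int(meta["nrows"]), int(meta["ncols"]))
    if array.shape != expected:
        raise ValueError(f"grid {path!r}: data shape {array.shape} != header {expected}")
    return array, meta


def read_raster(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a raster (.asc, or .tif via tifffile); returns (array, cellsize).

    TIFF rasters carry no georeferencing here; the cell size must then be
    supplied separately (returned as NaN).
    """
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt"):
        array, meta = read_ascii_grid(path)
        return array, meta["cellsize"]
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path)), float("nan")
    raise ValueError(f"unsupported raster format: {path.suffix!r}")
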