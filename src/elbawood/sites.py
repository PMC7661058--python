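"""Smelting-site catalogue: dating windows and slag-mass bounds.

A site's chronology is carried as four signed years (negative = BCE,
astronomical-style continuous integer axis):

* ``t_alpha`` / ``t_delta`` — outer bounds: activity cannot start before
  ``t_alpha`` nor end after ``t_delta``;
* ``t_beta`` / ``t_gamma`` — inner bounds: activity certainly started by
  ``t_beta`` and lasted at least until ``t_gamma``.

Windows are derived from dated finds (ceramics, coins, radiocarbon ages),
each of which only brackets its true deposition moment by an interval
``[a, b]``.  The packaged 29-site Elba catalogue ships with the package and
seeds every island-scale simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DatingFind",
    "DatingWindow",
    "Site",
    "derive_window",
    "load_sites",
    "load_finds",
    "write_sites",
    "packaged_catalogue_path",
]

_SITE_COLUMNS = [
    "id", "name", "t_alpha", "t_beta", "t_gamma", "t_delta",
    "slag_min", "slag_max", "x", "y",
]

# sanity range for any year handled here
_YEAR_MIN, _YEAR_MAX = -1000, 500


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class DatingFind:
    """One dated find: the deposition moment lies within ``[a, b]``."""

    site_id: int | str
    a: int
    b: int
    material: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise ValueError(f"find interval reversed: [{self.a}, {self.b}]")
        if not (_YEAR_MIN <= self.a and self.b <= _YEAR_MAX):
            raise ValueError(f"find interval [{self.a}, {self.b}] outside sanity range")


@dataclass(frozen=True)
class DatingWindow:
    """Activity-window bounds ``t_alpha <= t_beta <= t_gamma <= t_delta``."""

    t_alpha: int
    t_beta: int
    t_gamma: int
    t_delta: int

    def __post_init__(self) -> None:
        if not (self.t_alpha <= self.t_beta <= self.t_gamma <= self.t_delta):
            raise ValueError(
                "dating window must satisfy t_alpha <= t_beta <= t_gamma <= t_delta, "
                f"got {self.as_tuple()}"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.t_alpha, self.t_beta, self.t_gamma, self.t_delta)

    @property
    def max_duration(self) -> int:
        """Longest admissible activity duration in years (inclusive)."""
        return self.t_delta - self.t_alpha + 1

    @property
    def min_duration(self) -> int:
        """Shortest admissible activity duration in years (inclusive)."""
        return self.t_gamma - self.t_beta + 1


@dataclass
class Site:
    """One smelting site: chronology, slag-mass bounds, optional location."""

    id: int | str
    name: str
    window: DatingWindow
    slag_min: float
    slag_max: float
    location: tuple[int, int] | None = None  # (row, col) on the working grid
    heap: "object | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.slag_min <= self.slag_max):
            raise ValueError(
                f"site {self.id!r}: need 0 < slag_min <= slag_max, "
                f"got ({self.slag_min}, {self.slag_max})"
            )


def derive_window(finds: Sequence[DatingFind]) -> DatingWindow:
    """Derive a site's activity window from its dated finds.

    Multiple finds: the outer bounds are the envelope of the find intervals
    (``t_alpha = min a_i``, ``t_delta = max b_i``) and the inner 'certain'
    interval is the smallest interval meeting every find
    (``t_beta = min b_i``, ``t_gamma = max a_i``).

    A single find: the certain interval is the central half of the find's
    interval, ``t_beta = a + (b-a)/4`` and ``t_gamma = b - (b-a)/4``
    (rounded, ties away from zero).

    Strongly overlapping finds can yield ``t_gamma < t_beta``; the window is
    then repaired by collapsing the certain interval to its midpoint (a
    warning is emitted).
    """
    if not finds:
        raise ValueError("cannot derive a dating window from an empty find list")
    if len(finds) == 1:
        a, b = finds[0].a, finds[0].b
        quarter = (b - a) / 4
        t_beta = round_half_away(a + quarter)
        t_gamma = round_half_away(b - quarter)
        return DatingWindow(a, t_beta, t_gamma, b)

    t_alpha = min(f.a for f in finds)
    t_delta = max(f.b for f in finds)
    t_beta = min(f.b for f in finds)
    t_gamma = max(f.a for f in finds)
    if t_gamma < t_beta:
        midpoint = round_half_away((t_beta + t_gamma) / 2)
        warnings.warn(
            f"overlapping finds collapse the certain interval to {midpoint}",
            stacklevel=2,
        )
        t_beta = t_gamma = midpoint
    return DatingWindow(t_alpha, t_beta, t_gamma, t_delta)


def _site_from_row(row: pd.Series, index: int) -> Site:
    try:
        window = DatingWindow(
            int(row["t_alpha"]), int(row["t_beta"]),
            int(row["t_gamma"]), int(row["t_delta"]),
        )
    except ValueError as exc:
        raise ValueError(f"sites CSV row {index}: {exc}") from exc
    location = None
    if pd.notna(row.get("x")) and pd.notna(row.get("y")):
        location = (int(row["y"]), int(row["x"]))  # (row, col)
    try:
        return Site(
            id=int(row["id"]) if str(row["id"]).lstrip("-").isdigit() else row["id"],
            name=str(row["name"]),
            window=window,
            slag_min=float(row["slag_min"]),
            slag_max=float(row["slag_max"]),
            location=location,
        )
    except ValueError as exc:
        raise ValueError(f"sites CSV row {index}: {exc}") from exc


def load_sites(path: str | Path) -> list[Site]:
    """Load and validate a site-catalogue CSV (schema: ``id,name,t_alpha,
    t_beta,t_gamma,t_delta,slag_min,slag_max,x,y``)."""
    frame = pd.read_csv(path)
    missing = [c for c in _SITE_COLUMNS if c not in frame.columns and c not in ("x", "y")]
    if missing:
        raise ValueError(f"sites CSV {path!r} is missing columns: {missing}")
    return [_site_from_row(row, i) for i, row in frame.iterrows()]


def write_sites(sites: Iterable[Site], path: str | Path) -> None:
    """Write a site catalogue back to CSV (lossless round-trip)."""
    rows = []
    for s in sites:
        rows.append({
            "id": s.id,
            "name": s.name,
            "t_alpha": s.window.t_alpha,
            "t_beta": s.window.t_beta,
            "t_gamma": s.window.t_gamma,
            "t_delta": s.window.t_delta,
            "slag_min": s.slag_min,
            "slag_max": s.slag_max,
            "x": s.location[1] if s.location else None,
            "y": s.location[0] if s.location else None,
        })
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, index=False)


def load_finds(path: str | Path) -> dict:
    """Load a finds CSV (``site_id,a,b,material,reference``) grouped by site."""
    frame = pd.read_csv(path)
    for column in ("site_id", "a", "b"):
        if column not in frame.columns:
            raise ValueError(f"finds CSV {path!r} is missing column {column!r}")
    grouped: dict = {}
    for _, row in frame.iterrows():
        find = DatingFind(
            site_id=row["site_id"], a=int(row["a"]), b=int(row["b"]),
            material=str(row.get("material", "") or ""),
            reference=str(row.get("reference", "") or ""),
        )
        grouped.setdefault(find.site_id, []).append(find)
    return grouped


def packaged_catalogue_path() -> Path:
    """Path to the packaged 29-site Elba catalogue CSV."""
    return Path(resources.files("elbawood") / "data" / "elba_sites.csv")
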