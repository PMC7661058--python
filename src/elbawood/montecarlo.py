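"""Ensemble driving and outcome statistics.

Repeated simulations under independently drawn parameter sets give the
likelihood of fuel shortage — reported both as the raw fraction of runs (the
model's definition of likelihood) and as the calibrated verbal category of
the IPCC scheme — together with robust Mdn±MAD summaries, felling-series
timing statistics and regional aggregation.

Two ensemble entry points exist: :func:`run_ensemble` executes the full
spatial engine, while :func:`demand_ensemble` propagates the demand cascade
alone (no landscape), which is all the chronology/slag/workforce statistics
need and is orders of magnitude faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from . import demand as demand_mod
from .engine import SimulationResult, run_simulation
from .landscape import Landscape, calibrate_growth
from .sampling import draw_parameters
from .sites import Site

__all__ = ["run_ensemble", "demand_ensemble", "ipcc_term", "timing_stats",
           "summarize", "regional_summary", "EnsembleSummary"]

# calibrated likelihood language: (term, lower-exclusive, upper bound)
_IPCC_LADDER = [
    ("virtually certain", 0.99),
    ("extremely likely", 0.95),
    ("very likely", 0.90),
    ("likely", 0.66),
]
_IPCC_LOW = [
    ("exceptionally unlikely", 0.01),
    ("extremely unlikely", 0.05),
    ("very unlikely", 0.10),
    ("unlikely", 0.33),
]


def ipcc_term(p: float) -> str:
    """Calibrated verbal category for a probability (most specific band wins)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    for term, bound in _IPCC_LADDER:
        if p > bound:
            return term
    for term, bound in _IPCC_LOW:
        if p < bound:
            return term
    return "about as likely as not"


def _mad(values) -> float:
    """Unscaled median absolute deviation."""
    return float(median_abs_deviation(values, scale=1.0))


def _series_timing(years: np.ndarray, values: np.ndarray) -> dict:
    """Argmax / strongest-increase / strongest-decrease years of one series.

    A leading and trailing zero are implied so the onset and the shutdown of
    activity count as changes.  Ties resolve to the earliest year and are
    flagged.
    """
    if years.size == 0:
        raise ValueError("empty felling series")
    padded = np.concatenate(([0.0], values, [0.0]))
    diff = np.diff(padded)                       # diff[i] belongs to year years[i]
    diff_years = np.concatenate((years, [years[-1] + 1]))
    peak_year = int(years[np.argmax(values)])
    up_year = int(diff_years[np.argmax(diff)])
    down_year = int(diff_years[np.argmin(diff)])
    tie = (np.sum(values == values.max()) > 1
           or np.sum(diff == diff.max()) > 1
           or np.sum(diff == diff.min()) > 1)
    return {
        "peak_year": peak_year,
        "increase_year": up_year,
        "decrease_year": down_year,
        "lag_increase_to_peak": peak_year - up_year,
        "lag_peak_to_decrease": down_year - peak_year,
        "tied": bool(tie),
    }


def timing_stats(series: Iterable[pd.Series]) -> dict:
    """Ensemble timing summary over annual felling series (t dry wood).

    Per run: the argmax year, the year of the strongest year-over-year
    increase and decrease, and the lags between them; over runs: medians,
    unscaled MADs and central 67%/95% intervals.
    """
    rows = []
    for s in series:
        s = s.dropna()
        if s.empty:
            continue
        rows.append(_series_timing(s.index.to_numpy(int), s.to_numpy(float)))
    if not rows:
        raise ValueError("no non-empty felling series")
    frame = pd.DataFrame(rows)
    out: dict = {"n_runs": len(frame), "ties": int(frame["tied"].sum())}
    for column in ("peak_year", "increase_year", "decrease_year",
                   "lag_increase_to_peak", "lag_peak_to_decrease"):
        values = frame[column].to_numpy(float)
        out[column] = {
            "median": float(np.median(values)),
            "mad": _mad(values),
            "interval67": [float(np.quantile(values, q)) for q in (0.165, 0.835)],
            "interval95": [float(np.quantile(values, q)) for q in (0.025, 0.975)],
        }
    return out


def run_ensemble(sites: list[Site], landscape: Landscape, config: Mapping,
                 n_runs: int, seed: int, mode: str = "exo",
                 progress: bool = False) -> list[SimulationResult]:
    """Run ``n_runs`` independent simulations (seed-sequence spawned RNGs).

    ``mode='exo'`` disables the endosomatic side entirely; ``'exo+endo'``
    includes household fuel, food land and browse.  With identical seeds the
    two modes share their parameter draws run by run (common random
    numbers).
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    results = []
    children = np.random.SeedSequence(seed).spawn(n_runs)
    iterator = enumerate(children)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(list(iterator), desc=f"ensemble[{mode}]")
        except ImportError:
            pass
    for _, child in iterator:
        rng = np.random.default_rng(child)
        draw = draw_parameters(sites, config, rng)
        results.append(run_simulation(sites, landscape, draw, config, mode=mode))
    return results


def demand_ensemble(sites: list[Site], config: Mapping, n_draws: int,
                    seed: int, stock_per_ha: float | None = None) -> pd.DataFrame:
    """Engine-free Monte Carlo over the demand cascade alone.

    Per draw: sample the full parameter set, build the aggregate annual
    demand series over the catalogue, and record totals, timing and the
    peak-year workforce.  ``stock_per_ha`` (t dry mass per felled hectare,
    default: mature macchia) converts wood demand into felled area for the
    woodcutter group.  Returns one row per draw.
    """
    if stock_per_ha is None:
        curve = calibrate_growth("macchia", config)
        stock_per_ha = curve.volume(config.get("max_age", 42)) \
            * config["specific_gravity"]
    t0 = min(s.window.t_alpha for s in sites)
    t1 = max(s.window.t_delta for s in sites)
    years = np.arange(t0, t1 + 1)

    children = np.random.SeedSequence(seed).spawn(n_draws)
    rows = []
    for child in children:
        rng = np.random.default_rng(child)
        draw = draw_parameters(sites, config, rng)
        slag_series = np.zeros(years.size)
        for site in sites:
            t_s, t_e = draw.periods[site.id]
            slag_series[t_s - t0: t_e - t0 + 1] += \
                draw.slag[site.id] / (t_e - t_s + 1)
        wood_series = slag_series * draw.wood_per_slag
        timing = _series_timing(years, wood_series)
        peak_index = np.argmax(slag_series)
        peak_slag = float(slag_series[peak_index])
        peak_wood = float(wood_series[peak_index])
        mining = demand_mod.mining_profile(draw, config)
        workforce = demand_mod.labour_cascade(
            {"slag": peak_slag,
             "wood": peak_wood,
             "felled_ha": peak_wood / stock_per_ha,
             "overland_mass": peak_slag * draw.furnace_inefficiency,
             "sea_mass": peak_slag * draw.slag_to_ore,
             "regional_ore": float(mining.get(int(years[peak_index]), 0.0))},
            draw, config)
        total_slag = float(sum(draw.slag.values()))
        rows.append({
            "total_slag": total_slag,
            "total_charcoal": total_slag * draw.furnace_inefficiency,
            "total_wood": total_slag * draw.wood_per_slag,
            "peak_slag": peak_slag,
            "peak_wood": peak_wood,
            "peak_workforce": workforce.total,
            "peak_year": timing["peak_year"],
            "increase_year": timing["increase_year"],
            "decrease_year": timing["decrease_year"],
            "lag_peak_to_decrease": timing["lag_peak_to_decrease"],
            "furnace_inefficiency": draw.furnace_inefficiency,
            "kiln_productivity": draw.kiln_productivity,
            "kiln_type": draw.kiln_type,
        })
    return pd.DataFrame(rows)


@dataclass
class EnsembleSummary:
    """Robust summary of a simulation ensemble."""

    n_runs: int
    shortage_likelihood: float
    shortage_wilson95: tuple[float, float]
    ipcc: str
    medians: dict = field(default_factory=dict)     # quantity -> (median, MAD)
    timing: dict = field(default_factory=dict)
    shortage_years: dict = field(default_factory=dict)   # year -> count
    period_likelihoods: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "shortage_likelihood": self.shortage_likelihood,
            "shortage_wilson95": list(self.shortage_wilson95),
            "ipcc": self.ipcc,
            "medians": {k: {"median": m, "mad": d}
                        for k, (m, d) in self.medians.items()},
            "timing": self.timing,
            "shortage_years": self.shortage_years,
            "period_likelihoods": self.period_likelihoods,
        }


def _wilson(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = successes / n
    denom = 1 + z ** 2 / n
    centre = (p + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def summarize(results: Sequence[SimulationResult]) -> EnsembleSummary:
    """Mdn±MAD summaries, shortage likelihood and timing of an ensemble."""
    if not results:
        raise ValueError("no results to summarise")
    n = len(results)
    shortages = [r.shortage_year for r in results if r.shortage_year is not None]
    likelihood = len(shortages) / n

    def mdnmad(values):
        values = np.asarray(list(values), dtype=float)
        return (float(np.median(values)), _mad(values))

    medians = {
        "total_slag": mdnmad(r.total_slag for r in results),
        "total_charcoal": mdnmad(r.total_charcoal for r in results),
        "total_wood": mdnmad(r.total_wood for r in results),
        "peak_workforce": mdnmad(r.peak_workforce for r in results),
        "min_woodland_pct": mdnmad(r.min_woodland_pct for r in results),
        "max_annual_cleared_pct": mdnmad(r.max_annual_cleared_pct for r in results),
    }
    series = [r.felling_series for r in results if not r.felling_series.empty]
    timing = timing_stats(series) if series else {}
    histogram: dict[int, int] = {}
    for year in shortages:
        histogram[year] = histogram.get(year, 0) + 1
    periods = {
        "3rd_c_bce": (-300, -201), "2nd_c_bce": (-200, -101),
        "1st_c_bce": (-100, -1), "1st_c_ce": (1, 100),
    }
    period_likelihoods = {
        name: sum(1 for y in shortages if low <= y <= high) / n
        for name, (low, high) in periods.items()
    }
    return EnsembleSummary(
        n_runs=n,
        shortage_likelihood=likelihood,
        shortage_wilson95=_wilson(len(shortages), n),
        ipcc=ipcc_term(likelihood),
        medians=medians,
        timing=timing,
        shortage_years=dict(sorted(histogram.items())),
        period_likelihoods=period_likelihoods,
    )


def regional_summary(results: Sequence[SimulationResult],
                     n_regions: int) -> pd.DataFrame:
    """Per-region annual felled area: ensemble mean and quantiles.

    Returns a tidy frame with columns ``region, year, mean_ha, q25, q75``.
    Runs whose records carry no regional data are ignored.
    """
    rows = []
    for run_id, result in enumerate(results):
        for record in result.records:
            if record.region_felled is None:
                continue
            for region in range(min(n_regions, record.region_felled.size)):
                rows.append((run_id, region, record.year,
                             record.region_felled[region]))
    if not rows:
        raise ValueError("no regional data in the ensemble")
    frame = pd.DataFrame(rows, columns=["run", "region", "year", "felled_ha"])
    grouped = frame.groupby(["region", "year"])["felled_ha"]
    out = grouped.agg(mean_ha="mean",
                      q25=lambda v: v.quantile(0.25),
                      q75=lambda v: v.quantile(0.75)).reset_index()
    return out
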