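#!/usr/bin/env python
"""Plot the headline series: demand uncertainty and woodland depletion.

Reads the outputs of 02 and 04 (run those first) plus a fresh small
ensemble for the felling band, and writes PNG figures to results/figures/.
Requires matplotlib (the 'plots' extra).
"""

import json
import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from elbawood.config import default_config
from elbawood.landscape import Landscape
from elbawood.montecarlo import run_ensemble
from elbawood.sites import load_sites

OUT = Path(__file__).resolve().parents[1] / "results"
FIGS = OUT / "figures"


def felling_band() -> None:
    landscape = Landscape.load(OUT / "island")
    sites = load_sites(OUT / "island" / "sites.csv")
    config = default_config()
    config["kiln_mode"] = "mound"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        results = run_ensemble(sites, landscape, config, 40, seed=7,
                               mode="exo+endo")
    frames = [pd.Series({r.year: r.area_felled for r in res.records})
              for res in results]
    table = pd.concat(frames, axis=1)
    years = table.index.to_numpy()

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.fill_between(years, table.quantile(0.165, axis=1),
                    table.quantile(0.835, axis=1), alpha=0.3,
                    label="67% of runs")
    ax.plot(years, table.median(axis=1), lw=1.5, label="median")
    ax.set_xlabel("year (negative = BCE)")
    ax.set_ylabel("area felled (ha/yr)")
    ax.set_title("Annual felling on the synthetic Elba (full metabolism)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIGS / "felling_band.png", dpi=150)


def demand_histograms() -> None:
    draws = pd.read_csv(OUT / "demand_draws.csv")
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    axes[0].hist(draws.total_slag / 1e3, bins=60, color="#705040")
    axes[0].set_xlabel("total slag (kt)")
    axes[1].hist(draws.total_wood / 1e6, bins=60, color="#3a7d44")
    axes[1].set_xlabel("fuelwood carbonised (Mt)")
    axes[2].hist(draws.peak_workforce, bins=60, color="#365f8a")
    axes[2].set_xlabel("peak workforce (capita)")
    for ax in axes:
        ax.set_ylabel("draws")
    fig.suptitle("Monte Carlo demand uncertainty (29-site catalogue)")
    fig.tight_layout()
    fig.savefig(FIGS / "demand_uncertainty.png", dpi=150)


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    if not (OUT / "demand_draws.csv").exists():
        raise SystemExit("run analysis/02_demand_uncertainty.py first")
    if not (OUT / "island" / "veg.asc").exists():
        raise SystemExit("run analysis/03_synthetic_island.py first")
    demand_histograms()
    felling_band()
    print(f"wrote figures to {FIGS}")


if __name__ == "__main__":
    main()
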