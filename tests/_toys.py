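"""Shared toy-scenario builders for engine-level tests."""

import numpy as np

from elbawood.landscape import Landscape
from elbawood.sampling import ParameterDraw
from elbawood.sites import DatingWindow, Site


def toy_island(n=5, age=42.0, veg=2, resolution=100.0):
    return Landscape(resolution=resolution,
                     veg=np.full((n, n), veg, dtype=np.int8),
                     age=np.full((n, n), age),
                     slope=np.zeros((n, n)))


def toy_draw(site_specs, **overrides):
    """site_specs: {site_id: (t_s, t_e, slag_mass)}"""
    base = dict(furnace_inefficiency=5.0, kiln_type="mound",
                kiln_productivity=0.2, rotation_period=5, browse_reduction=0.5,
                household_fuel=1.0, ore_total=2.32, pasture_per_animal=0.95)
    base.update(overrides)
    draw = ParameterDraw(**base)
    for sid, (t_s, t_e, mass) in site_specs.items():
        draw.periods[sid] = (t_s, t_e)
        draw.slag[sid] = mass
    return draw


def toy_site(site_id=1, location=(0, 0)):
    return Site(id=site_id, name=f"toy{site_id}",
                window=DatingWindow(-120, -110, -40, -30),
                slag_min=1.0, slag_max=10000.0, location=location)
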