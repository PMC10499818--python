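"""Reusable benchmark protocols: planar-wave CV and time-step convergence.

These wrap the standard verification experiment — a planar wave paced from
one edge of a homogeneous, fibre-aligned 2D sheet, with conduction
velocity measured along an interior axial transect — so that convergence
studies and solver comparisons run the exact same configuration.
"""

from __future__ import annotations

import numpy as np

from .analysis import axial_transect, conduction_velocity
from .cells import CellModel
from .grid import StructuredGrid, generate_idealised_field
from .network import CouplingParameters
from .simulate import run_simulation
from .stimulus import edge_stimulus

__all__ = ["planar_wave_cv", "cv_relative_difference"]


def planar_wave_cv(dt: float, nx: int = 100, ny: int = 100,
                   dx: float = 0.25, g_a: float = 1.6, g_t: float = 0.4,
                   model: CellModel | None = None,
                   margin: int = 10,
                   max_duration: float = 200.0) -> float:
    """CV (mm/ms) of a planar wave on a homogeneous x-fibre sheet.

    Edge stimulus at the low-x face; CV measured between the endpoints of
    an interior transect along x (``margin`` nodes clear of the stimulus
    and boundary).  The run stops as soon as the transect is fully
    activated.
    """
    grid = StructuredGrid((nx, ny), (dx, dx))
    fld = generate_idealised_field(grid, (1.0, 0.0))
    params = CouplingParameters(g_a=g_a, g_t1=g_t)
    protocol = edge_stimulus(grid, axis=0, width=3)
    transect = axial_transect(grid, axis=0, margin=margin)
    res = run_simulation(grid=grid, fld=fld, params=params, model=model,
                         protocol=protocol, dt=dt, duration=max_duration,
                         stop_when_activated=transect)
    return conduction_velocity(res.activation, transect)


def cv_relative_difference(dt_a: float, dt_b: float, **kwargs) -> float:
    """Relative CV difference (percent) between two integration steps.

    ``100 * |CV(dt_a) - CV(dt_b)| / CV(dt_b)`` with ``dt_b`` the finer
    (reference) step.
    """
    cv_a = planar_wave_cv(dt_a, **kwargs)
    cv_b = planar_wave_cv(dt_b, **kwargs)
    return 100.0 * abs(cv_a - cv_b) / cv_b
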