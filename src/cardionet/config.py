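"""YAML run-configuration parsing for the command-line interface.

A config file has sections ``grid``, ``field``, ``coupling``,
``heterogeneity`` (optional), ``cell``, ``protocol`` and ``numerics``;
every builder below maps one section onto the corresponding library
object.  The CLI is a thin shell over these builders — scripts using the
library directly do not need them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .cells import MitchellSchaeffer, PassiveMembrane
from .grid import (StructuredGrid, generate_idealised_field,
                   generate_varying_field, read_geometry)
from .heterogeneity import HeterogeneitySpec
from .network import (CouplingParameters, conductance_from_anisotropy,
                      diffusion_to_conductance)
from .stimulus import edge_stimulus, focal_stimulus, StimulusProtocol

__all__ = [
    "load_config",
    "build_grid_and_field",
    "build_coupling",
    "build_heterogeneity",
    "build_cell_model",
    "build_protocol",
    "numerics_defaults",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def build_grid_and_field(cfg: dict, seed: int | None = None):
    g = cfg.get("grid", {})
    if "geometry_file" in g:
        return read_geometry(Path(g["geometry_file"]),
                             format=g.get("format", "text"))
    dims = tuple(g["dims"])
    spacing = tuple(g.get("spacing", (0.25,) * len(dims)))
    grid = StructuredGrid(dims, spacing)
    f = cfg.get("field", {"type": "idealised", "direction": [1, 0]})
    ftype = f.get("type", "idealised")
    if ftype == "idealised":
        fld = generate_idealised_field(grid, f.get("direction",
                                                   (1,) + (0,) * (len(dims) - 1)))
    else:
        fld = generate_varying_field(
            grid, ftype,
            seed=int(f.get("seed", 0) if seed is None else seed),
            **f.get("params", {}))
    return grid, fld


def build_coupling(cfg: dict, grid: StructuredGrid) -> CouplingParameters:
    c = cfg.get("coupling", {})
    scaling = bool(c.get("include_dx_scaling", True))
    if "g_a" in c:
        g_a = float(c["g_a"])
        g_t1 = float(c.get("g_t", c.get("g_t1", g_a)))
        g_t2 = c.get("g_t2")
    elif "D1" in c:
        dx = grid.spacing[0]
        if "D2" in c:
            g_a, g_t1 = diffusion_to_conductance(float(c["D1"]),
                                                 float(c["D2"]), dx)
        else:
            g_a, g_t1 = conductance_from_anisotropy(
                float(c["D1"]), float(c.get("anisotropy_ratio", 1.0)), dx)
        g_t2 = None
    else:
        raise ValueError("coupling section needs g_a or D1")
    return CouplingParameters(g_a=g_a, g_t1=g_t1,
                              g_t2=None if g_t2 is None else float(g_t2),
                              include_dx_scaling=scaling)


def build_heterogeneity(cfg: dict,
                        seed: int | None = None) -> HeterogeneitySpec | None:
    h = cfg.get("heterogeneity")
    if h is None:
        return None
    return HeterogeneitySpec(
        p_remove_axial=float(h.get("p_remove_axial", 0.0)),
        p_remove_transverse=float(h.get("p_remove_transverse", 0.0)),
        p_remove_mixed=(None if h.get("p_remove_mixed") is None
                        else float(h["p_remove_mixed"])),
        scale_distribution=h.get("scale_distribution"),
        scale_params=h.get("scale_params", {}),
        seed=int(h.get("seed", 0) if seed is None else seed),
    )


_MODELS = {"mitchell_schaeffer": MitchellSchaeffer,
           "passive": PassiveMembrane}


def build_cell_model(cfg: dict):
    c = cfg.get("cell", {})
    name = c.get("model", "mitchell_schaeffer")
    if name not in _MODELS:
        raise ValueError(f"unknown cell model {name!r}; "
                         f"expected one of {sorted(_MODELS)}")
    return _MODELS[name](**c.get("params", {}))


def build_protocol(cfg: dict, grid: StructuredGrid) -> StimulusProtocol:
    p = dict(cfg.get("protocol", {"kind": "edge"}))
    kind = p.pop("kind", "edge")
    common = {k: p[k] for k in ("amplitude", "duration") if k in p}
    if "onsets" in p:
        common["onsets"] = tuple(float(t) for t in p["onsets"])
    if kind == "edge":
        return edge_stimulus(grid, axis=int(p.get("axis", 0)),
                             side=p.get("side", "low"),
                             width=int(p.get("width", 3)), **common)
    if kind == "focal":
        centre = p.get("centre")
        return focal_stimulus(grid,
                              centre=None if centre is None
                              else tuple(centre),
                              radius=float(p.get("radius", 3.0)), **common)
    if kind == "custom-mask":
        region = np.asarray(p["region"], dtype=np.int64)
        return StimulusProtocol(region=region, kind=kind, **common)
    raise ValueError(f"unknown protocol kind {kind!r}")


def numerics_defaults(cfg: dict) -> dict:
    n = cfg.get("numerics", {})
    return {
        "dt": float(n.get("dt", 0.02)),
        "duration": float(n.get("duration", 100.0)),
        "snapshot_interval": (None if n.get("snapshot_interval") is None
                              else float(n["snapshot_interval"])),
        "activation_threshold": float(n.get("activation_threshold", -20.0)),
    }
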