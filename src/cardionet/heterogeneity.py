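"""Structural remodelling of the junction network.

Fibrosis-like media are produced by manipulating junctions directly:
per-class random removal (each connection class — axial, transverse, mixed
— has its own removal probability), continuous per-junction conductance
scaling drawn from a named distribution, or a nodal map that scales local
g_a/g_t before junction averaging (the FDM-style alternative).  Removal
deactivates a junction but never removes tissue nodes from being
excitable, which is what permits functional (and potentially
unidirectional) conduction block.

Random-number contract: one independent uniform draw per junction, consumed
in junction-id order, from numpy's counter-based Philox generator keyed by
the user seed — connection maps are therefore portable given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    JunctionSet, NodalConductances,
    CLASS_AXIAL, CLASS_TRANSVERSE, CLASS_MIXED,
)

__all__ = [
    "HeterogeneitySpec",
    "remove_connections",
    "scale_connections",
    "apply_nodal_scale_map",
]

#: distributions usable for continuous junction scaling; each validator
#: rejects parameterisations that could produce negative factors
_DISTRIBUTIONS = {
    "constant": lambda p: _require(p["value"] >= 0, "constant value >= 0"),
    "uniform": lambda p: _require(0 <= p["low"] <= p["high"],
                                  "0 <= low <= high"),
    "lognormal": lambda p: _require(p.get("sigma", 1.0) >= 0, "sigma >= 0"),
    "gamma": lambda p: _require(p["shape"] > 0 and p.get("scale", 1.0) > 0,
                                "shape > 0 and scale > 0"),
}


def _require(cond, what):
    if not cond:
        raise ValueError(f"scale distribution requires {what}")


@dataclass
class HeterogeneitySpec:
    """Specification of structural remodelling to apply to a network.

    ``p_remove_mixed`` defaults to the mean of the axial and transverse
    probabilities (the class exists structurally but no separate removal
    rate is canonical for it).
    """

    p_remove_axial: float = 0.0
    p_remove_transverse: float = 0.0
    p_remove_mixed: float | None = None
    scale_distribution: str | None = None
    scale_params: dict = field(default_factory=dict)
    nodal_scale_map: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.p_remove_mixed is None:
            self.p_remove_mixed = 0.5 * (self.p_remove_axial
                                         + self.p_remove_transverse)
        for name in ("p_remove_axial", "p_remove_transverse",
                     "p_remove_mixed"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.scale_distribution is not None:
            if self.scale_distribution not in _DISTRIBUTIONS:
                raise ValueError(
                    f"unknown scale distribution "
                    f"{self.scale_distribution!r}; expected one of "
                    f"{sorted(_DISTRIBUTIONS)}"
                )
            _DISTRIBUTIONS[self.scale_distribution](self.scale_params)

    @property
    def class_probabilities(self) -> np.ndarray:
        out = np.empty(3)
        out[CLASS_AXIAL] = self.p_remove_axial
        out[CLASS_TRANSVERSE] = self.p_remove_transverse
        out[CLASS_MIXED] = self.p_remove_mixed
        return out

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Philox generator for a named sub-stream (0 removal, 1 scaling)."""
        return np.random.Generator(np.random.Philox(key=self.seed + stream))


def remove_connections(junctions: JunctionSet,
                       spec: HeterogeneitySpec) -> JunctionSet:
    """Randomly deactivate junctions with per-class probabilities.

    Each junction is deactivated independently with the probability of its
    class; the output is a copy (the input is untouched) and is bit-
    identical for a fixed ``(junctions, spec.seed)``.  Deactivated
    junctions contribute exactly zero current but the tissue mask and all
    cell states are unaffected.
    """
    out = junctions.copy()
    u = spec.rng(stream=0).random(len(junctions))
    p = spec.class_probabilities[junctions.cls]
    out.active &= ~(u < p)
    return out


def scale_connections(junctions: JunctionSet,
                      spec: HeterogeneitySpec) -> JunctionSet:
    """Scale junction conductances by i.i.d. draws from a distribution.

    One factor is drawn per junction in id order (so maps are reproducible
    independent of which junctions are active); factors multiply any
    scaling already present.
    """
    if spec.scale_distribution is None:
        raise ValueError("spec has no scale distribution")
    rng = spec.rng(stream=1)
    n = len(junctions)
    p = spec.scale_params
    if spec.scale_distribution == "constant":
        factors = np.full(n, float(p["value"]))
    elif spec.scale_distribution == "uniform":
        factors = rng.uniform(p["low"], p["high"], n)
    elif spec.scale_distribution == "lognormal":
        factors = rng.lognormal(p.get("mean", 0.0), p.get("sigma", 1.0), n)
    else:  # gamma
        factors = rng.gamma(p["shape"], p.get("scale", 1.0), n)
    out = junctions.copy()
    out.scale *= factors
    return out


def apply_nodal_scale_map(nodal: NodalConductances,
                          scale_map) -> NodalConductances:
    """Scale per-node g_a/g_t before junction averaging (FDM-style).

    ``scale_map`` is either a tissue-local vector (length ``n_tissue``) or
    a full-grid array of shape ``grid.dims``; every tissue node must carry
    a finite factor >= 0.
    """
    grid = nodal.grid
    m = np.asarray(scale_map, dtype=float)
    if m.shape == grid.dims:
        factors = m.ravel(order="F")[grid.tissue_linear]
    elif m.shape == (grid.n_tissue,):
        factors = m
    else:
        raise ValueError(
            f"scale map shape {m.shape} matches neither grid dims "
            f"{grid.dims} nor tissue count ({grid.n_tissue},)"
        )
    if not np.all(np.isfinite(factors)):
        bad = int(np.flatnonzero(~np.isfinite(factors))[0])
        raise ValueError(f"non-finite scale factor at tissue node {bad}")
    if np.any(factors < 0):
        bad = int(np.flatnonzero(factors < 0)[0])
        raise ValueError(f"negative scale factor at tissue node {bad}")
    return nodal.scaled(factors)
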