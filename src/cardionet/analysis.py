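"""Activation maps, conduction velocities and map comparisons.

An activation map records, per tissue node, the first upward crossing of a
threshold voltage (default −20 mV, mid-upstroke of the bundled model),
linearly interpolated between samples; never-activated nodes carry NaN.
Conduction velocity is measured as physical transect length divided by the
activation-time difference between the transect endpoints, on interior
transects away from the stimulus and boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import StructuredGrid

__all__ = [
    "ActivationMap",
    "activation_map",
    "conduction_velocity",
    "compare_maps",
    "axial_transect",
]


@dataclass
class ActivationMap:
    """Per-tissue-node first-crossing times (ms; NaN = never activated)."""

    grid: StructuredGrid
    times: np.ndarray
    threshold: float

    @property
    def activated(self) -> np.ndarray:
        return ~np.isnan(self.times)

    @property
    def fraction_activated(self) -> float:
        return float(self.activated.mean())

    @property
    def total_activation_time(self) -> float:
        """Last minus first activation time over activated nodes (ms)."""
        t = self.times[self.activated]
        if t.size == 0:
            return np.nan
        return float(t.max() - t.min())

    def full_field(self) -> np.ndarray:
        """Times as a full-grid array (NaN off tissue), shape ``dims``."""
        out = self.grid.tissue_field(np.nan)
        out[self.grid.tissue_linear] = self.times
        return out.reshape(self.grid.dims, order="F")

    def write_text(self, path) -> None:
        """Write the 2D map as a text matrix (rows = y); VTK covers 3D."""
        field = self.full_field()
        if field.ndim != 2:
            raise ValueError("text export is 2D-only; use the VTK writer")
        np.savetxt(path, field.T, fmt="%.6g",
                   header=f"activation time (ms); threshold "
                          f"{self.threshold} mV; NaN = not activated")


def activation_map(times, voltages, threshold: float,
                   grid: StructuredGrid | None = None) -> ActivationMap:
    """First-crossing activation map from a sampled voltage series.

    ``voltages`` has shape ``(n_samples, n_nodes)`` sampled at ``times``
    (temporal resolution should be at most ~1 ms for meaningful maps).
    Crossings are linearly interpolated between the bracketing samples.
    A threshold outside the recorded voltage range yields an all-sentinel
    map with a warning.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(voltages, dtype=float)
    if V.ndim != 2 or V.shape[0] != times.size:
        raise ValueError("voltages must be (n_samples, n_nodes)")
    n = V.shape[1]
    act = np.full(n, np.nan)
    if V.size and (threshold > V.max() or threshold < V.min()):
        warnings.warn(
            f"threshold {threshold} mV outside recorded voltage range "
            f"[{V.min():.3g}, {V.max():.3g}]; activation map is empty",
            stacklevel=2)
    else:
        below = V[:-1] < threshold
        above = V[1:] >= threshold
        crossing = below & above
        for s in range(crossing.shape[0]):
            nodes = np.flatnonzero(crossing[s] & np.isnan(act))
            if nodes.size == 0:
                continue
            v0, v1 = V[s, nodes], V[s + 1, nodes]
            frac = (threshold - v0) / (v1 - v0)
            act[nodes] = times[s] + frac * (times[s + 1] - times[s])
    if grid is None:
        grid = StructuredGrid((n, 1), (1.0, 1.0))
    return ActivationMap(grid=grid, times=act, threshold=threshold)


def axial_transect(grid: StructuredGrid, axis: int = 0, margin: int = 10,
                   **fixed) -> np.ndarray:
    """Tissue-local indices of an interior straight line along ``axis``.

    The line runs through the middle of the other axes (override with
    keyword ``j=...``/``k=...``) and excludes ``margin`` nodes at each end
    to stay clear of the stimulus and the boundary.
    """
    names = "ijk"[: grid.ndim]
    coords = []
    n_ax = grid.dims[axis]
    if n_ax <= 2 * margin:
        raise ValueError("grid too small for the requested margin")
    along = np.arange(margin, n_ax - margin)
    for a in range(grid.ndim):
        if a == axis:
            coords.append(along)
        else:
            coords.append(np.full(along.size,
                                  int(fixed.get(names[a],
                                               grid.dims[a] // 2))))
    lin = grid.linear_index(*coords)
    local = grid.full_to_tissue[lin]
    if (local < 0).any():
        raise ValueError("transect crosses non-tissue nodes")
    return local


def conduction_velocity(amap: ActivationMap, transect) -> float:
    """CV (mm/ms) along an ordered node transect.

    Computed as physical distance between the transect endpoints divided
    by their activation-time difference; direction-insensitive (absolute
    value).  Unactivated endpoints are an error.
    """
    transect = np.asarray(transect, dtype=np.int64)
    if transect.size < 2:
        raise ValueError("transect needs at least two nodes")
    t0, t1 = amap.times[transect[0]], amap.times[transect[-1]]
    if np.isnan(t0) or np.isnan(t1):
        raise ValueError("transect endpoint never activated")
    if t1 == t0:
        raise ValueError("zero activation-time difference along transect")
    lin = amap.grid.tissue_linear[transect[[0, -1]]]
    pos = amap.grid.node_positions(lin)
    dist = float(np.linalg.norm(pos[1] - pos[0]))
    return dist / abs(float(t1 - t0))


def compare_maps(map_a: ActivationMap, map_b: ActivationMap) -> dict:
    """Per-node and summary differences between two activation maps.

    Restricted to co-activated nodes; maps with disjoint activation
    supports are rejected.  Returns per-node ``delta`` (a − b) plus the
    mean absolute difference and the difference in total activation time.
    """
    if map_a.grid.dims != map_b.grid.dims:
        raise ValueError("maps live on different grids")
    both = map_a.activated & map_b.activated
    if not both.any():
        raise ValueError("maps have disjoint activation supports")
    delta = np.full_like(map_a.times, np.nan)
    delta[both] = map_a.times[both] - map_b.times[both]
    return {
        "delta": delta,
        "n_common": int(both.sum()),
        "mean_abs_dt": float(np.abs(delta[both]).mean()),
        "mean_dt": float(delta[both].mean()),
        "total_activation_time_a": map_a.total_activation_time,
        "total_activation_time_b": map_b.total_activation_time,
        "total_activation_time_diff": (map_a.total_activation_time
                                       - map_b.total_activation_time),
    }
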