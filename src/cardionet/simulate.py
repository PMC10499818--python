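"""Explicit integration of the coupled network tissue system.

Per time step, each junction carries the ohmic current
``I_gap = g_gap * (V+ - V-)``; the signed junction currents are summed
onto their two endpoint nodes (antisymmetrically, so total membrane
charge injected by coupling is zero by construction), the stimulus is
added, and every cell is advanced one forward-Euler step.  Because
junctions only exist between tissue nodes, no-flux boundary conditions
require no special handling: there simply are no terms to solve at a
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ActivationMap
from .cells import CellModel, MitchellSchaeffer
from .grid import StructuredGrid, OrientationField
from .heterogeneity import (HeterogeneitySpec, remove_connections,
                            scale_connections)
from .network import CouplingParameters, JunctionSet, build_network
from .stimulus import StimulusProtocol

__all__ = [
    "TissueState",
    "SimulationResult",
    "SimulationUnstableError",
    "junction_currents",
    "accumulate_node_currents",
    "step_tissue",
    "run_simulation",
]

DEFAULT_ACTIVATION_THRESHOLD = -20.0  # mV, mid-upstroke for bundled model


class SimulationUnstableError(RuntimeError):
    """Raised when a node's voltage becomes non-finite."""

    def __init__(self, node: int, time: float):
        self.node = int(node)
        self.time = float(time)
        super().__init__(
            f"non-finite voltage at tissue node {node}, t = {time:g} ms"
        )


@dataclass
class TissueState:
    """Membrane voltage and cell-model state for every tissue node."""

    V: np.ndarray
    gates: dict
    t: float = 0.0

    @classmethod
    def resting(cls, model: CellModel, n: int) -> "TissueState":
        V, gates = model.initial_state(n)
        return cls(V=V, gates=gates, t=0.0)

    def copy(self) -> "TissueState":
        return TissueState(self.V.copy(),
                           {k: v.copy() for k, v in self.gates.items()},
                           self.t)


def junction_currents(state_or_V, junctions: JunctionSet) -> np.ndarray:
    """Per-junction currents ``I_gap = g_gap (V+ - V-)`` (mV/ms).

    Inactive junctions carry exactly zero.
    """
    V = state_or_V.V if isinstance(state_or_V, TissueState) else state_or_V
    g = junctions.effective_conductance
    return g * (V[junctions.node_pos] - V[junctions.node_neg])


def accumulate_node_currents(currents: np.ndarray, junctions: JunctionSet,
                             n_nodes: int | None = None) -> np.ndarray:
    """Sum signed junction currents onto nodes.

    The positive endpoint receives ``-I_gap`` and the negative ``+I_gap``,
    so coupling contributions cancel pairwise over the whole tissue.
    """
    if n_nodes is None:
        n_nodes = junctions.grid.n_tissue
    return (np.bincount(junctions.node_neg, weights=currents,
                        minlength=n_nodes)
            - np.bincount(junctions.node_pos, weights=currents,
                          minlength=n_nodes))


def step_tissue(state: TissueState, junctions: JunctionSet,
                model: CellModel, dt: float,
                protocol: StimulusProtocol | None = None,
                check: bool = True) -> TissueState:
    """Advance the whole tissue one forward-Euler step (in place)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    I = junction_currents(state.V, junctions)
    coup = accumulate_node_currents(I, junctions, state.V.size)
    if protocol is not None and protocol.is_active(state.t):
        coup[protocol.region] += protocol.amplitude
    model.step(state.V, state.gates, coup, dt)
    state.t += dt
    if check and not np.all(np.isfinite(state.V)):
        node = int(np.flatnonzero(~np.isfinite(state.V))[0])
        raise SimulationUnstableError(node, state.t)
    return state


@dataclass
class SimulationResult:
    """Bundle of outputs from one tissue simulation."""

    grid: StructuredGrid
    activation: ActivationMap
    state: TissueState
    snapshot_times: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    snapshots: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0), dtype=np.float32))


def run_simulation(grid: StructuredGrid | None = None,
                   fld: OrientationField | None = None,
                   params: CouplingParameters | None = None,
                   heterogeneity: HeterogeneitySpec | None = None,
                   junctions: JunctionSet | None = None,
                   model: CellModel | None = None,
                   protocol: StimulusProtocol | None = None,
                   dt: float = 0.02,
                   duration: float = 100.0,
                   snapshot_interval: float | None = None,
                   activation_threshold: float = DEFAULT_ACTIVATION_THRESHOLD,
                   stop_when_activated: np.ndarray | None = None,
                   check_interval: int = 50) -> SimulationResult:
    """Run a full network-model simulation.

    Either a prebuilt ``junctions`` set is supplied, or ``(grid, fld,
    params)`` from which the network is built (with ``heterogeneity``
    applied — removal and/or scaling — if given).  Activation times are
    recorded online as the first upward crossing of
    ``activation_threshold``, linearly interpolated between steps.
    Snapshots (float32) are stored every ``snapshot_interval`` ms when
    requested.  ``stop_when_activated`` (tissue-local node indices) ends
    the run early once all listed nodes have activated.  Fully
    deterministic given its configuration and seed.
    """
    if junctions is None:
        if grid is None or fld is None or params is None:
            raise ValueError(
                "supply either junctions or (grid, fld, params)")
        _, junctions = build_network(grid, fld, params)
        if heterogeneity is not None:
            junctions = remove_connections(junctions, heterogeneity)
            if heterogeneity.scale_distribution is not None:
                junctions = scale_connections(junctions, heterogeneity)
    grid = junctions.grid
    if model is None:
        model = MitchellSchaeffer()
    if protocol is not None:
        protocol.validate_region(grid)
    if duration < 0:
        raise ValueError("duration must be >= 0")

    n = grid.n_tissue
    state = TissueState.resting(model, n)
    V = state.V
    gates = state.gates
    jp, jm = junctions.node_pos, junctions.node_neg
    g_eff = junctions.effective_conductance
    region = protocol.region if protocol is not None else None
    amp = protocol.amplitude if protocol is not None else 0.0

    act = np.full(n, np.nan)
    thr = activation_threshold
    n_steps = int(round(duration / dt))

    snaps, snap_times = [], []
    next_snap = 0.0 if snapshot_interval is not None else np.inf

    if next_snap <= 0.0:
        snaps.append(V.astype(np.float32).copy())
        snap_times.append(0.0)
        next_snap = snapshot_interval

    v_prev = V.copy()
    for s in range(n_steps):
        t = s * dt
        I = g_eff * (V[jp] - V[jm])
        coup = (np.bincount(jm, weights=I, minlength=n)
                - np.bincount(jp, weights=I, minlength=n))
        if region is not None and protocol.is_active(t):
            coup[region] += amp
        np.copyto(v_prev, V)
        model.step(V, gates, coup, dt)
        t_new = (s + 1) * dt

        crossed = np.isnan(act) & (V >= thr) & (v_prev < thr)
        if crossed.any():
            frac = (thr - v_prev[crossed]) / (V[crossed] - v_prev[crossed])
            act[crossed] = t + frac * dt
            if stop_when_activated is not None and \
                    not np.isnan(act[stop_when_activated]).any():
                state.t = t_new
                break

        if t_new + 1e-9 >= next_snap:
            snaps.append(V.astype(np.float32).copy())
            snap_times.append(t_new)
            next_snap += snapshot_interval

        if (s + 1) % check_interval == 0 and not np.all(np.isfinite(V)):
            node = int(np.flatnonzero(~np.isfinite(V))[0])
            raise SimulationUnstableError(node, t_new)
        state.t = t_new

    if not np.all(np.isfinite(V)):
        node = int(np.flatnonzero(~np.isfinite(V))[0])
        raise SimulationUnstableError(node, state.t)

    amap = ActivationMap(grid=grid, times=act, threshold=thr)
    return SimulationResult(
        grid=grid, activation=amap, state=state,
        snapshot_times=np.asarray(snap_times),
        snapshots=(np.asarray(snaps) if snaps
                   else np.empty((0, n), dtype=np.float32)),
    )
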