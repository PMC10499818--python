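"""Assembly of nodal directional conductances and the junction network.

Each tissue node distributes its axial conductance ``g_a`` and transverse
conductance(s) ``g_t1``/``g_t2`` (all in nS/pF, membrane capacitance
absorbed) over the lattice coupling directions using the orientation
weights.  A junction forms between *every* pair of adjacent tissue nodes in
every coupling direction, with conductance equal to the mean of the two
nodal directional conductances; junctions never form into non-tissue, which
is how no-flux boundaries arise without any special-casing.

Junctions are classified as axial (both sides' contribution comes from the
primary fibre vector), transverse (both from transverse vectors) or mixed,
so that structural-remodelling rules can target each class separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StructuredGrid, OrientationField
from .weights import (
    DIRECTION_LABELS_2D, DIRECTION_LABELS_3D,
    DIRECTION_OFFSETS_2D, DIRECTION_OFFSETS_3D,
    direction_weights_2d, transverse_weights_2d,
    direction_weights_3d, transverse_vectors_from_primary,
)

__all__ = [
    "CouplingParameters",
    "NodalConductances",
    "JunctionSet",
    "CLASS_AXIAL", "CLASS_TRANSVERSE", "CLASS_MIXED", "CLASS_NAMES",
    "diffusion_to_conductance",
    "conductance_from_anisotropy",
    "nodal_conductances",
    "build_junctions",
    "classify_connection",
    "build_network",
]

CLASS_AXIAL, CLASS_TRANSVERSE, CLASS_MIXED = 0, 1, 2
CLASS_NAMES = ("axial", "transverse", "mixed")


def diffusion_to_conductance(D1: float, D2: float, dx: float):
    """Convert monodomain diffusion coefficients to junction conductances.

    ``g_a = D1 / dx`` and ``g_t = D2 / dx``; with this conversion the
    network model reproduces the conduction velocities of a matched
    finite-difference monodomain solver in simple conditions.
    """
    if dx <= 0:
        raise ValueError(f"spatial step must be > 0, got {dx}")
    if not (D1 >= D2 >= 0):
        raise ValueError(f"need D1 >= D2 >= 0, got D1={D1}, D2={D2}")
    return D1 / dx, D2 / dx


def conductance_from_anisotropy(D1: float, anisotropy_ratio: float,
                                dx: float):
    """Alternative entry point: ``g_a = D1/dx``, ``g_t = g_a / AR``."""
    if dx <= 0:
        raise ValueError(f"spatial step must be > 0, got {dx}")
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy ratio must be >= 1")
    g_a = D1 / dx
    return g_a, g_a / anisotropy_ratio


@dataclass(frozen=True)
class CouplingParameters:
    """Axial/transverse junction conductances (nS/pF).

    ``g_t2`` defaults to ``g_t1`` (no sheet/sheet-normal distinction).
    ``include_dx_scaling`` controls whether the nodal conductances carry
    the 1/dx (axis), 1/sqrt(dx^2+dy^2) (diagonal) and
    1/sqrt(dx^2+dy^2+dz^2) (corner) geometric prefactors; when off, the
    relative factors 1, 1/sqrt(2), 1/sqrt(3) are retained for geometric
    consistency across direction classes.
    """

    g_a: float
    g_t1: float
    g_t2: float | None = None
    include_dx_scaling: bool = True

    def __post_init__(self):
        if self.g_t2 is None:
            object.__setattr__(self, "g_t2", self.g_t1)
        if not (self.g_a >= self.g_t1 >= self.g_t2 >= 0):
            raise ValueError(
                f"need g_a >= g_t1 >= g_t2 >= 0, got "
                f"({self.g_a}, {self.g_t1}, {self.g_t2})"
            )


def _direction_prefactors(grid: StructuredGrid,
                          include_dx_scaling: bool) -> np.ndarray:
    """Geometric 1/distance prefactor per direction label."""
    offsets = DIRECTION_OFFSETS_2D if grid.ndim == 2 else DIRECTION_OFFSETS_3D
    if include_dx_scaling:
        sp = np.asarray(grid.spacing)
    else:
        sp = np.ones(grid.ndim)
    return np.array([
        1.0 / np.sqrt(np.sum((np.asarray(off) * sp) ** 2))
        for off in offsets
    ])


@dataclass
class NodalConductances:
    """Per-tissue-node directional conductances, split by origin.

    ``axial`` holds the primary-vector contribution and ``transverse`` the
    transverse-vector contribution per direction (tissue-local node order,
    shape ``(n_tissue, n_directions)``); ``total`` is their sum.  Both
    parts already include the geometric spacing prefactor.
    """

    grid: StructuredGrid
    labels: tuple[str, ...]
    axial: np.ndarray
    transverse: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.axial + self.transverse

    def scaled(self, factors: np.ndarray) -> "NodalConductances":
        """Return a copy with every node's conductances scaled."""
        f = np.asarray(factors, dtype=float)[:, None]
        return NodalConductances(self.grid, self.labels,
                                 self.axial * f, self.transverse * f)


def nodal_conductances(fld: OrientationField,
                       params: CouplingParameters,
                       grid: StructuredGrid | None = None
                       ) -> NodalConductances:
    """Directional conductances for every tissue node.

    For each direction the nodal conductance is the geometric prefactor
    times the weighted sum of the axial and transverse gap-junction
    conductances, e.g. in 2D along x::

        g_xx = (1/dx) * (g_a * W_xx + g_t * Wt_xx)

    In 3D the transverse weights come from the sheet/sheet-normal vectors
    when supplied, otherwise from the two constructed transverse vectors
    (with ``g_t1 = g_t2`` they are interchangeable).
    """
    if grid is None:
        grid = fld.grid
    elif grid is not fld.grid and grid.dims != fld.grid.dims:
        raise ValueError("grid does not match the orientation field")
    v = fld.tissue_vectors("primary")
    if grid.ndim == 2:
        labels = DIRECTION_LABELS_2D
        w_ax = direction_weights_2d(v)
        w_tr = params.g_t1 * transverse_weights_2d(v)
    else:
        labels = DIRECTION_LABELS_3D
        w_ax = direction_weights_3d(v)
        if fld.has_transverse:
            t1 = fld.tissue_vectors("transverse1")
            t2 = fld.tissue_vectors("transverse2")
        else:
            t1, t2 = transverse_vectors_from_primary(v)
        w_tr = (params.g_t1 * direction_weights_3d(t1)
                + params.g_t2 * direction_weights_3d(t2))
    pref = _direction_prefactors(grid, params.include_dx_scaling)
    return NodalConductances(grid, labels,
                             axial=pref * params.g_a * w_ax,
                             transverse=pref * w_tr)


@dataclass
class JunctionSet:
    """The inter-nodal connection network as parallel arrays.

    One entry per unordered pair of adjacent tissue nodes per coupling
    direction.  ``node_pos``/``node_neg`` are tissue-local node indices
    (positive endpoint = lower linear index; the convention is arbitrary —
    currents are antisymmetric).  ``conductance`` is the built junction
    conductance ``(g_i + g_j)/2``; structural remodelling acts through
    ``scale`` and ``active`` so that connection maps can be toggled and
    exported without rebuilding.
    """

    grid: StructuredGrid
    labels: tuple[str, ...]
    node_pos: np.ndarray
    node_neg: np.ndarray
    direction: np.ndarray
    cls: np.ndarray
    conductance: np.ndarray
    scale: np.ndarray = None  # type: ignore[assignment]
    active: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.node_pos)
        if self.scale is None:
            self.scale = np.ones(n)
        if self.active is None:
            self.active = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.node_pos)

    @property
    def effective_conductance(self) -> np.ndarray:
        """Conductance actually used by the solver: inactive -> exactly 0."""
        return np.where(self.active, self.conductance * self.scale, 0.0)

    def copy(self) -> "JunctionSet":
        return JunctionSet(self.grid, self.labels,
                           self.node_pos.copy(), self.node_neg.copy(),
                           self.direction.copy(), self.cls.copy(),
                           self.conductance.copy(), self.scale.copy(),
                           self.active.copy())

    def degree(self) -> np.ndarray:
        """Number of junctions per tissue node (active or not)."""
        n = self.grid.n_tissue
        return (np.bincount(self.node_pos, minlength=n)
                + np.bincount(self.node_neg, minlength=n))

    def class_counts(self) -> dict:
        return {name: int(np.sum(self.cls == code))
                for code, name in enumerate(CLASS_NAMES)}

    def write_table(self, path) -> None:
        """Export as text: id node+ node- direction class g_gap active scale."""
        with open(path, "w") as fh:
            fh.write("# id node_pos node_neg direction class "
                     "g_gap active scale\n")
            tl = self.grid.tissue_linear
            for n in range(len(self)):
                fh.write(
                    f"{n} {tl[self.node_pos[n]]} {tl[self.node_neg[n]]} "
                    f"{self.labels[self.direction[n]]} "
                    f"{CLASS_NAMES[self.cls[n]]} "
                    f"{self.conductance[n]:.17g} {int(self.active[n])} "
                    f"{self.scale[n]:.17g}\n"
                )


def classify_connection(axial_i: float, transverse_i: float,
                        axial_j: float, transverse_j: float) -> int:
    """Classify one junction from its two nodal contributions.

    Axial if every non-zero contribution comes from the primary vector,
    transverse if every non-zero contribution comes from a transverse
    vector; a side contributing nothing defers to the other side; anything
    else (including a zero-conductance junction) is mixed.
    """
    code = _classify(np.asarray([axial_i]), np.asarray([transverse_i]),
                     np.asarray([axial_j]), np.asarray([transverse_j]))
    return int(code[0])


def _side_type(ax, tr, eps):
    # 0 = axial-only, 1 = transverse-only, 2 = both, 3 = none
    has_a, has_t = ax > eps, tr > eps
    return np.select(
        [has_a & ~has_t, ~has_a & has_t, has_a & has_t], [0, 1, 2], default=3
    )


def _classify(ax_i, tr_i, ax_j, tr_j, eps=None):
    if eps is None:
        # ignore float-noise weights (an exactly-diagonal orientation
        # leaves O(1e-16) residue on the axes through arcsin rounding)
        eps = 1e-9 * max(float(np.max(ax_i, initial=0.0)),
                         float(np.max(tr_i, initial=0.0)),
                         float(np.max(ax_j, initial=0.0)),
                         float(np.max(tr_j, initial=0.0)))
    si = _side_type(ax_i, tr_i, eps)
    sj = _side_type(ax_j, tr_j, eps)
    out = np.full(si.shape, CLASS_MIXED, dtype=np.int8)
    both_axial = ((si == 0) & ((sj == 0) | (sj == 3))) | \
                 ((sj == 0) & (si == 3))
    both_trans = ((si == 1) & ((sj == 1) | (sj == 3))) | \
                 ((sj == 1) & (si == 3))
    out[both_axial] = CLASS_AXIAL
    out[both_trans] = CLASS_TRANSVERSE
    return out


def build_junctions(nodal: NodalConductances,
                    grid: StructuredGrid | None = None) -> JunctionSet:
    """Create one junction per adjacent tissue pair per coupling direction.

    The junction conductance is the mean of the two nodal directional
    conductances (independent of connection class); a junction where one
    side contributes zero still forms, carrying half the other side's
    value.  Empty tissue yields an empty set.
    """
    if grid is None:
        grid = nodal.grid
    offsets = DIRECTION_OFFSETS_2D if grid.ndim == 2 else DIRECTION_OFFSETS_3D
    mask = grid.mask
    f2t = grid.full_to_tissue.reshape(grid.dims, order="F")
    total, axial, trans = nodal.total, nodal.axial, nodal.transverse
    eps = 1e-9 * float(np.max(total, initial=0.0))

    def _pair_slices(o):
        if o > 0:
            return slice(None, -o), slice(o, None)
        if o < 0:
            return slice(-o, None), slice(None, o)
        return slice(None), slice(None)

    jp, jm, dirs, gs, cls = [], [], [], [], []
    for d, off in enumerate(offsets):
        # slices selecting base nodes and their offset neighbours
        pairs = [_pair_slices(o) for o in off]
        src = tuple(p[0] for p in pairs)
        dst = tuple(p[1] for p in pairs)
        both = mask[src] & mask[dst]
        if not both.any():
            continue
        ti = f2t[src][both]
        tj = f2t[dst][both]
        li = grid.tissue_linear[ti]
        lj = grid.tissue_linear[tj]
        # positive endpoint = lower linear index
        swap = li > lj
        pos = np.where(swap, tj, ti)
        neg = np.where(swap, ti, tj)
        jp.append(pos)
        jm.append(neg)
        dirs.append(np.full(len(pos), d, dtype=np.int8))
        gs.append(0.5 * (total[ti, d] + total[tj, d]))
        cls.append(_classify(axial[ti, d], trans[ti, d],
                             axial[tj, d], trans[tj, d], eps))

    if jp:
        node_pos = np.concatenate(jp).astype(np.int64)
        node_neg = np.concatenate(jm).astype(np.int64)
        direction = np.concatenate(dirs)
        conductance = np.concatenate(gs)
        classes = np.concatenate(cls)
    else:
        node_pos = node_neg = np.empty(0, dtype=np.int64)
        direction = classes = np.empty(0, dtype=np.int8)
        conductance = np.empty(0)
    return JunctionSet(grid, nodal.labels, node_pos, node_neg,
                       direction, classes, conductance)


def build_network(grid: StructuredGrid, fld: OrientationField,
                  params: CouplingParameters):
    """Convenience: orientation field + coupling -> (nodal, junctions)."""
    nodal = nodal_conductances(fld, params, grid)
    return nodal, build_junctions(nodal, grid)
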