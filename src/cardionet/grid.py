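"""Structured-grid tissue geometries and myocyte-orientation vector fields.

Tissue is represented on a square (2D) or cuboid (3D) lattice.  Nodes are
addressed by integer indices ``(i, j[, k])`` with x fastest-varying in the
linear ordering (``idx = i + nx*(j + ny*k)``, 0-based).  Each tissue node
carries a unit myocyte-orientation vector; in 3D two further unit vectors
(sheet and sheet-normal) may be supplied, forming a mutually orthogonal
triad.  Non-tissue nodes carry no orientation, and any vector data stored
there is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuredGrid",
    "OrientationField",
    "generate_idealised_field",
    "generate_varying_field",
    "read_geometry",
    "write_geometry",
]

_UNIT_TOL = 1e-9
_ORTHO_TOL = 1e-6
_DEGENERATE_NORM = 1e-6


@dataclass(frozen=True)
class StructuredGrid:
    """A 2D/3D lattice of nodes with physical spacing and a tissue mask.

    Parameters
    ----------
    dims
        Integer extents ``(nx, ny[, nz])``; every extent must be >= 1.
    spacing
        Physical step per axis in mm ``(dx, dy[, dz])``; all > 0.
    mask
        Boolean tissue indicator of shape ``dims`` (``None`` = all tissue).
    """

    dims: tuple[int, ...]
    spacing: tuple[float, ...]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        if len(dims) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got dims={dims}")
        if len(spacing) != len(dims):
            raise ValueError("spacing and dims must have the same length")
        if any(d < 1 for d in dims):
            raise ValueError(f"all extents must be >= 1, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        if self.mask is None:
            mask = np.ones(dims, dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != dims:
                raise ValueError(
                    f"mask shape {mask.shape} does not match dims {dims}"
                )
        object.__setattr__(self, "mask", mask)

    # -- basic queries -------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.dims))

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_linear(self) -> np.ndarray:
        """Tissue mask in linear (x fastest) node order."""
        return self.mask.ravel(order="F")

    @property
    def tissue_linear(self) -> np.ndarray:
        """Linear indices of tissue nodes, ascending."""
        return np.flatnonzero(self.mask_linear)

    @property
    def full_to_tissue(self) -> np.ndarray:
        """Map linear node index -> tissue-local index (-1 off tissue)."""
        out = np.full(self.n_nodes, -1, dtype=np.int64)
        out[self.tissue_linear] = np.arange(self.n_tissue)
        return out

    def multi_index(self, linear: np.ndarray) -> tuple[np.ndarray, ...]:
        return np.unravel_index(np.asarray(linear), self.dims, order="F")

    def linear_index(self, *ijk) -> np.ndarray:
        return np.ravel_multi_index(tuple(np.asarray(a) for a in ijk),
                                    self.dims, order="F")

    def node_positions(self, linear: np.ndarray | None = None) -> np.ndarray:
        """Physical coordinates (mm) of nodes, shape (n, ndim)."""
        if linear is None:
            linear = np.arange(self.n_nodes)
        idx = self.multi_index(linear)
        return np.stack(
            [np.asarray(i) * s for i, s in zip(idx, self.spacing)], axis=-1
        ).astype(float)

    def tissue_field(self, fill=np.nan, dtype=float) -> np.ndarray:
        """Full linear-order array pre-filled with ``fill``."""
        return np.full(self.n_nodes, fill, dtype=dtype)


@dataclass
class OrientationField:
    """Per-node orientation unit vectors on a :class:`StructuredGrid`.

    ``primary`` holds the myocyte (fibre) direction for every node in the
    grid's full shape ``dims + (ndim,)``; values on non-tissue nodes are
    ignored.  ``transverse1``/``transverse2`` (3D only) hold the sheet and
    sheet-normal directions when available.
    """

    grid: StructuredGrid
    primary: np.ndarray
    transverse1: np.ndarray | None = None
    transverse2: np.ndarray | None = None

    def __post_init__(self):
        nd = self.grid.ndim
        shape = self.grid.dims + (nd,)
        self.primary = np.asarray(self.primary, dtype=float)
        if self.primary.shape != shape:
            raise ValueError(
                f"primary field shape {self.primary.shape} != {shape}"
            )
        if (self.transverse1 is None) != (self.transverse2 is None):
            raise ValueError("supply both transverse vectors or neither")
        if self.transverse1 is not None and nd != 3:
            raise ValueError("transverse vectors are only meaningful in 3D")
        for name in ("transverse1", "transverse2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != shape:
                    raise ValueError(f"{name} shape {v.shape} != {shape}")
                setattr(self, name, v)
        self._validate()

    @property
    def has_transverse(self) -> bool:
        return self.transverse1 is not None

    def _validate(self):
        mask = self.grid.mask
        for name in ("primary", "transverse1", "transverse2"):
            v = getattr(self, name)
            if v is None:
                continue
            norms = np.linalg.norm(v[mask], axis=-1)
            if norms.size and norms.min() < _DEGENERATE_NORM:
                bad = int(np.argmin(norms))
                raise ValueError(
                    f"{name} vector on tissue node (tissue-local index {bad}) "
                    f"has norm {norms.min():.3g} < {_DEGENERATE_NORM}"
                )
            # re-normalise in place; reject only truly degenerate vectors
            v[mask] = v[mask] / norms[:, None]
        if self.has_transverse:
            p = self.primary[mask]
            t1 = self.transverse1[mask]
            t2 = self.transverse2[mask]
            for a, b, names in ((p, t1, "primary/transverse1"),
                                (p, t2, "primary/transverse2"),
                                (t1, t2, "transverse1/transverse2")):
                dots = np.abs(np.einsum("ij,ij->i", a, b))
                if dots.size and dots.max() > _ORTHO_TOL:
                    raise ValueError(
                        f"{names} not orthogonal: max |dot| = {dots.max():.3g}"
                    )

    def vectors_linear(self, name: str = "primary") -> np.ndarray:
        """Vectors of all nodes in linear order, shape (n_nodes, ndim)."""
        v = getattr(self, name)
        return v.reshape(-1, self.grid.ndim, order="F")

    def tissue_vectors(self, name: str = "primary") -> np.ndarray:
        """Vectors on tissue nodes only, tissue-local order."""
        return self.vectors_linear(name)[self.grid.tissue_linear]


# ---------------------------------------------------------------------------
# Synthetic field generators
# ---------------------------------------------------------------------------

def generate_idealised_field(grid: StructuredGrid,
                             direction) -> OrientationField:
    """Globally uniform orientation field pointing along ``direction``.

    The direction is normalised; a zero vector is rejected.
    """
    d = np.asarray(direction, dtype=float)
    if d.shape != (grid.ndim,):
        raise ValueError(
            f"direction must be a {grid.ndim}-vector, got shape {d.shape}"
        )
    n = np.linalg.norm(d)
    if n < _DEGENERATE_NORM:
        raise ValueError("direction must be a nonzero vector")
    d = d / n
    primary = np.broadcast_to(d, grid.dims + (grid.ndim,)).copy()
    return OrientationField(grid, primary)


_PATTERNS = ("ramp", "circular", "smoothed_random")


def generate_varying_field(grid: StructuredGrid, pattern: str,
                           seed: int = 0, **params) -> OrientationField:
    """Parametric spatially varying orientation fields.

    Patterns (deterministic for a fixed ``(pattern, params, seed)``):

    ``ramp``
        In-plane angle varies linearly from ``start_angle`` (default 0) to
        ``end_angle`` (default pi/2) along ``axis`` (default 0, i.e. x).
    ``circular``
        Rotor-like field tangential around ``centre`` (defaults to the grid
        midpoint); degenerate at the exact centre, where the x-axis is used.
    ``smoothed_random``
        I.i.d. Gaussian vector components smoothed with a Gaussian kernel of
        width ``sigma`` nodes (default 4.0) and re-normalised; emulates a
        smoothly varying but disordered fibre field.
    """
    if pattern not in _PATTERNS:
        raise ValueError(
            f"unknown pattern {pattern!r}; expected one of {_PATTERNS}"
        )
    nd = grid.ndim
    shape = grid.dims + (nd,)
    v = np.zeros(shape)

    if pattern == "ramp":
        start = float(params.get("start_angle", 0.0))
        end = float(params.get("end_angle", np.pi / 2))
        axis = int(params.get("axis", 0))
        n_ax = grid.dims[axis]
        frac = (np.arange(n_ax) / (n_ax - 1)) if n_ax > 1 else np.zeros(1)
        ang = start + (end - start) * frac
        sl = [None] * nd
        sl[axis] = slice(None)
        ang = np.broadcast_to(ang[tuple(sl)], grid.dims)
        v[..., 0] = np.cos(ang)
        v[..., 1] = np.sin(ang)
        # ramp rotates within the x-y plane; z-component (3D) stays zero

    elif pattern == "circular":
        centre = params.get("centre")
        if centre is None:
            centre = tuple((d - 1) / 2 for d in grid.dims[:2])
        ii = np.arange(grid.dims[0], dtype=float)
        jj = np.arange(grid.dims[1], dtype=float)
        if nd == 2:
            gi, gj = np.meshgrid(ii, jj, indexing="ij")
        else:
            gi, gj, _ = np.meshgrid(ii, jj,
                                    np.arange(grid.dims[2], dtype=float),
                                    indexing="ij")
        vx = -(gj - centre[1])
        vy = gi - centre[0]
        r = np.hypot(vx, vy)
        deg = r < _DEGENERATE_NORM
        vx = np.where(deg, 1.0, vx)
        vy = np.where(deg, 0.0, vy)
        v[..., 0] = vx
        v[..., 1] = vy

    else:  # smoothed_random
        sigma = float(params.get("sigma", 4.0))
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(shape)
        for c in range(nd):
            v[..., c] = ndimage.gaussian_filter(raw[..., c], sigma,
                                                mode="reflect")
        norms = np.linalg.norm(v, axis=-1)
        # smoothing a Gaussian field essentially never cancels exactly, but
        # guard the degenerate case deterministically
        bad = norms < _DEGENERATE_NORM
        if bad.any():
            v[bad] = 0.0
            v[bad, 0] = 1.0

    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / np.where(norms == 0, 1.0, norms)
    return OrientationField(grid, v)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
#
# Text format: header "NX NY [NZ] DX DY [DZ]", then one whitespace-delimited
# record per node in linear (x fastest) order:
#     mask Ox Oy [Oz] [Sx Sy Sz Nx Ny Nz]
# HDF5 format: datasets "dims", "spacing", "mask", "primary"
# [, "transverse1", "transverse2"] with identical conventions.

def write_geometry(path, grid: StructuredGrid, fld: OrientationField,
                   format: str = "text") -> None:
    path = Path(path)
    if format == "text":
        _write_text(path, grid, fld)
    elif format == "hdf5":
        _write_hdf5(path, grid, fld)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_geometry(path, format: str = "text"):
    """Read a geometry/field file; returns ``(grid, orientation_field)``.

    Vectors are re-normalised on load; a tissue node whose stored vector
    has norm < 1e-6 is an error, not silently defaulted.
    """
    path = Path(path)
    if format == "text":
        return _read_text(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _write_text(path, grid, fld):
    nd = grid.ndim
    mask_lin = grid.mask_linear
    cols = [mask_lin.astype(int)[:, None],
            np.where(mask_lin[:, None], fld.vectors_linear("primary"), 0.0)]
    if fld.has_transverse:
        cols.append(np.where(mask_lin[:, None],
                             fld.vectors_linear("transverse1"), 0.0))
        cols.append(np.where(mask_lin[:, None],
                             fld.vectors_linear("transverse2"), 0.0))
    data = np.hstack(cols)
    header = " ".join(str(d) for d in grid.dims) + " " + \
        " ".join(repr(s) for s in grid.spacing)
    fmt = ["%d"] + ["%.17g"] * (data.shape[1] - 1)
    np.savetxt(path, data, fmt=fmt, header=header, comments="")


def _read_text(path):
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) == 4:
            nd = 2
        elif len(header) == 6:
            nd = 3
        else:
            raise ValueError(
                f"header must have 4 (2D) or 6 (3D) fields, got {len(header)}"
            )
        dims = tuple(int(t) for t in header[:nd])
        spacing = tuple(float(t) for t in header[nd:])
        data = np.loadtxt(fh, ndmin=2)
    n_expected = int(np.prod(dims))
    if data.shape[0] != n_expected:
        raise ValueError(
            f"expected {n_expected} node records for dims {dims}, "
            f"got {data.shape[0]} (first bad index {min(data.shape[0], n_expected)})"
        )
    ncol = data.shape[1]
    if ncol == 1 + nd:
        has_t = False
    elif nd == 3 and ncol == 10:
        has_t = True
    else:
        raise ValueError(
            f"unexpected record width {ncol} for a {nd}D file"
        )
    mask = data[:, 0].astype(bool).reshape(dims, order="F")
    grid = StructuredGrid(dims, spacing, mask)

    def vecs(lo):
        return data[:, lo:lo + nd].reshape(dims + (nd,), order="F")

    primary = vecs(1)
    t1 = t2 = None
    if has_t:
        t1, t2 = vecs(4), vecs(7)
    fld = OrientationField(grid, primary, t1, t2)  # validates + renormalises
    return grid, fld


def _write_hdf5(path, grid, fld):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("dims", data=np.asarray(grid.dims))
        f.create_dataset("spacing", data=np.asarray(grid.spacing))
        f.create_dataset("mask", data=grid.mask)
        f.create_dataset("primary", data=fld.primary)
        if fld.has_transverse:
            f.create_dataset("transverse1", data=fld.transverse1)
            f.create_dataset("transverse2", data=fld.transverse2)


def _read_hdf5(path):
    import h5py

    with h5py.File(path, "r") as f:
        dims = tuple(int(d) for d in f["dims"][()])
        spacing = tuple(float(s) for s in f["spacing"][()])
        mask = f["mask"][()]
        grid = StructuredGrid(dims, spacing, mask)
        primary = f["primary"][()]
        t1 = f["transverse1"][()] if "transverse1" in f else None
        t2 = f["transverse2"][()] if "transverse2" in f else None
    return grid, OrientationField(grid, primary, t1, t2)
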