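"""Orientation-dependent direction weights for inter-nodal coupling.

The network model distributes each node's axial (along-fibre) and
transverse (cross-fibre) conductance over the independent coupling
directions of the lattice — 4 in 2D (x, y and the two diagonals), 13 in 3D
(3 axes, 6 plane diagonals, 4 corners).  The distribution is linear in the
in-plane angles: a vector exactly along an axis or diagonal puts all of its
weight there, and the weight interpolates linearly with angle in between.
Binary "pointing parameters" select the segment (2D) or quadrant (3D) that
contains the vector, collapsing the case analysis into products; at most 2
(2D) or 4 (3D) directions per vector receive non-zero weight, and the
weights always sum to 1.

All functions accept arrays of vectors with the component axis last and
broadcast over leading dimensions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DIRECTION_LABELS_2D",
    "DIRECTION_LABELS_3D",
    "DIRECTION_OFFSETS_2D",
    "DIRECTION_OFFSETS_3D",
    "plane_angle",
    "axis_weight",
    "pointing_parameters",
    "direction_weights_2d",
    "transverse_weights_2d",
    "quadrant_weights_3d",
    "direction_weights_3d",
    "transverse_vectors_from_primary",
]

#: Independent coupling directions and their lattice offsets.  The +/-
#: senses of a direction are indifferent, so only one offset is listed.
DIRECTION_LABELS_2D = ("xx", "yy", "xy++", "xy+-")
DIRECTION_OFFSETS_2D = ((1, 0), (0, 1), (1, 1), (1, -1))

DIRECTION_LABELS_3D = (
    "xx", "yy", "zz",
    "xy++", "xy+-", "xz++", "xz+-", "yz++", "yz+-",
    "xyz+++", "xyz++-", "xyz+-+", "xyz+--",
)
DIRECTION_OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def plane_angle(a, b):
    """In-plane angle ``arcsin(|b| / sqrt(a^2 + b^2))`` in [0, pi/2].

    Measures how far a vector's projection into the (a, b) plane tilts from
    the a-axis.  When both components vanish (the vector is orthogonal to
    the plane) the angle is *defined* as 0 — the associated plane weight is
    then 1, but the pointing parameters zero out every term this could
    wrongly enable, so the choice is immaterial.

    Returns
    -------
    theta, degenerate
        The angle(s) and a boolean flag marking the degenerate case.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h = np.hypot(a, b)
    degenerate = h == 0.0
    theta = np.arcsin(np.abs(b) / np.where(degenerate, 1.0, h))
    theta = np.where(degenerate, 0.0, theta)
    if theta.ndim == 0:
        return float(theta), bool(degenerate)
    return theta, degenerate


def axis_weight(theta):
    """Linear axis/diagonal weights ``(W_axis, W_diagonal)`` for an angle.

    ``W_axis = |(theta - pi/4) / (pi/4)|`` is 1 exactly on an axis
    (theta = 0 or pi/2), 0 exactly on the diagonal (theta = pi/4), and
    linear in between; ``W_diagonal = 1 - W_axis``.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi / 2 + 1e-12)):
        raise ValueError("angle must lie in [0, pi/2]")
    w_axis = np.abs((theta - np.pi / 4) / (np.pi / 4))
    w_axis = np.minimum(w_axis, 1.0)  # clip rounding at the endpoints
    if w_axis.ndim == 0:
        return float(w_axis), float(1.0 - w_axis)
    return w_axis, 1.0 - w_axis


def pointing_parameters(v) -> dict:
    """Binary pointing parameters for a unit vector (2D or 3D).

    ``P_x = 1`` iff the vector points closer to the x-axis than to any
    other axis (``x^2 >= y^2`` in 2D; ``x^2 >= y^2 and x^2 >= z^2`` in 3D),
    and analogously for y and z; exactly one of them is 1, with ties broken
    in the fixed priority x > y > z (the printed ">=" rule — the choice is
    immaterial because the competing weights vanish at a tie).  The
    diagonal parameters are sign indicators: ``P_xy+ = 1`` iff ``x*y >= 0``.
    """
    v = np.asarray(v, dtype=float)
    nd = v.shape[-1]
    x, y = v[..., 0], v[..., 1]
    if nd == 2:
        px = (x * x >= y * y)
        return {
            "P_x": px.astype(int), "P_y": (~px).astype(int),
            "P_xy+": (x * y >= 0).astype(int),
        }
    if nd == 3:
        z = v[..., 2]
        x2, y2, z2 = x * x, y * y, z * z
        px = (x2 >= y2) & (x2 >= z2)
        py = ~px & (y2 >= z2)
        pz = ~px & ~py
        return {
            "P_x": px.astype(int), "P_y": py.astype(int),
            "P_z": pz.astype(int),
            "P_xy+": (x * y >= 0).astype(int),
            "P_xz+": (x * z >= 0).astype(int),
            "P_yz+": (y * z >= 0).astype(int),
        }
    raise ValueError(f"vectors must be 2D or 3D, got {nd} components")


# ---------------------------------------------------------------------------
# 2D
# ---------------------------------------------------------------------------

def direction_weights_2d(v) -> np.ndarray:
    """Axial weight of one vector over the 4 directions (2D).

    Returns weights in :data:`DIRECTION_LABELS_2D` order; exactly the axis
    weight on the pointed axis and the diagonal weight on the pointed
    diagonal, zero elsewhere.  Weights sum to 1, with at most two non-zero.
    """
    v = np.asarray(v, dtype=float)
    theta, _ = plane_angle(v[..., 0], v[..., 1])
    w_axis, w_diag = axis_weight(theta)
    p = pointing_parameters(v)
    out = np.empty(v.shape[:-1] + (4,))
    out[..., 0] = p["P_x"] * w_axis
    out[..., 1] = p["P_y"] * w_axis
    out[..., 2] = p["P_xy+"] * w_diag
    out[..., 3] = (1 - p["P_xy+"]) * w_diag
    return out


def transverse_weights_2d(v) -> np.ndarray:
    """Transverse weights from the *primary* vector (2D).

    In 2D the direction orthogonal to the fibre is implied, so the
    transverse weights are the axial formulae with every pointing
    parameter swapped (x <-> y segment, ++ <-> +- diagonal).
    """
    v = np.asarray(v, dtype=float)
    theta, _ = plane_angle(v[..., 0], v[..., 1])
    w_axis, w_diag = axis_weight(theta)
    p = pointing_parameters(v)
    out = np.empty(v.shape[:-1] + (4,))
    out[..., 0] = (1 - p["P_x"]) * w_axis
    out[..., 1] = p["P_x"] * w_axis
    out[..., 2] = (1 - p["P_xy+"]) * w_diag
    out[..., 3] = p["P_xy+"] * w_diag
    return out


# ---------------------------------------------------------------------------
# 3D
# ---------------------------------------------------------------------------

def _plane_axis_weights(v):
    """W_axis^xy, W_axis^xz, W_axis^yz for 3-vectors."""
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    wxy, _ = axis_weight(plane_angle(x, y)[0])
    wxz, _ = axis_weight(plane_angle(x, z)[0])
    wyz, _ = axis_weight(plane_angle(y, z)[0])
    return np.asarray(wxy), np.asarray(wxz), np.asarray(wyz)


def quadrant_weights_3d(v):
    """Quadrant weights ``(W_axis, W_diag_plane, W_diag_elevation, W_corner)``.

    A 3D orientation falls in a quadrant on the cube surface bounded by one
    axis, two diagonals and a corner.  The weight toward each of those four
    directions is a product of the two in-plane angle weights (the planes
    depending on which axis the vector points primarily toward); the four
    weights sum to 1.
    """
    v = np.asarray(v, dtype=float)
    wxy, wxz, wyz = _plane_axis_weights(v)
    p = pointing_parameters(v)
    px, py, pz = p["P_x"], p["P_y"], p["P_z"]
    w_axis = px * wxy * wxz + py * wxy * wyz + pz * wxz * wyz
    w_dplane = (px * (1 - wxy) * wxz + py * (1 - wxy) * wyz
                + pz * (1 - wxz) * wyz)
    w_delev = (px * wxy * (1 - wxz) + py * wxy * (1 - wyz)
               + pz * wxz * (1 - wyz))
    w_corner = (px * (1 - wxy) * (1 - wxz) + py * (1 - wxy) * (1 - wyz)
                + pz * (1 - wxz) * (1 - wyz))
    return w_axis, w_dplane, w_delev, w_corner


def direction_weights_3d(v) -> np.ndarray:
    """Weight of one vector over the 13 directions (3D).

    Returns weights in :data:`DIRECTION_LABELS_3D` order.  At most four
    entries are non-zero — one axis, the in-plane diagonal, the elevation
    diagonal, and one corner of the pointed quadrant — and they sum to 1.

    Convention: when pointing primarily toward z the xz diagonal is the
    "in-plane" one and yz the "elevation" one; toward x or y, xy is
    in-plane and xz/yz are elevation.  Corners are selected by the signs of
    the xz and yz component products.
    """
    v = np.asarray(v, dtype=float)
    w_axis, w_dplane, w_delev, w_corner = quadrant_weights_3d(v)
    p = pointing_parameters(v)
    px, py, pz = p["P_x"], p["P_y"], p["P_z"]
    pxy, pxz, pyz = p["P_xy+"], p["P_xz+"], p["P_yz+"]

    out = np.zeros(v.shape[:-1] + (13,))
    out[..., 0] = px * w_axis
    out[..., 1] = py * w_axis
    out[..., 2] = pz * w_axis
    out[..., 3] = (px + py) * pxy * w_dplane
    out[..., 4] = (px + py) * (1 - pxy) * w_dplane
    out[..., 5] = px * pxz * w_delev + pz * pxz * w_dplane
    out[..., 6] = px * (1 - pxz) * w_delev + pz * (1 - pxz) * w_dplane
    out[..., 7] = (py + pz) * pyz * w_delev
    out[..., 8] = (py + pz) * (1 - pyz) * w_delev
    out[..., 9] = pxz * pyz * w_corner
    out[..., 10] = (1 - pxz) * (1 - pyz) * w_corner
    out[..., 11] = pxz * (1 - pyz) * w_corner
    out[..., 12] = (1 - pxz) * pyz * w_corner
    return out


def transverse_vectors_from_primary(v):
    """Construct two transverse unit vectors from the primary orientation.

    ``t1`` is the primary vector rotated by pi/2 toward the +z axis within
    the plane spanned by the vector and z; ``t2 = v x t1`` (renormalised)
    then always lies in the x-y plane.  When ``v`` is parallel to z the
    rotation plane is degenerate and the fixed convention ``t1 = (1, 0, 0)``
    is used (any in-plane orthogonal pair is equivalent when the two
    transverse conductances are equal).

    Broadcasts over leading dimensions; returns ``(t1, t2)``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("primary vector must have 3 components")
    vx, vy, vz = v[..., 0], v[..., 1], v[..., 2]
    r = np.hypot(vx, vy)
    degenerate = r < 1e-12
    r_safe = np.where(degenerate, 1.0, r)
    # horizontal unit vector under v; rotate (r, vz) -> (-vz, r) toward +z
    hx, hy = vx / r_safe, vy / r_safe
    t1 = np.empty_like(v)
    t1[..., 0] = np.where(degenerate, 1.0, -vz * hx)
    t1[..., 1] = np.where(degenerate, 0.0, -vz * hy)
    t1[..., 2] = np.where(degenerate, 0.0, r)
    t1 /= np.linalg.norm(t1, axis=-1, keepdims=True)
    t2 = np.cross(v, t1)
    t2 /= np.linalg.norm(t2, axis=-1, keepdims=True)
    return t1, t2
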