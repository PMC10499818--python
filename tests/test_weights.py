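"""Orientation-weight computation: examples, oracles and symmetries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardionet.weights import (
    DIRECTION_LABELS_2D,
    DIRECTION_LABELS_3D,
    DIRECTION_OFFSETS_2D,
    DIRECTION_OFFSETS_3D,
    plane_angle,
    axis_weight,
    pointing_parameters,
    direction_weights_2d,
    transverse_weights_2d,
    quadrant_weights_3d,
    direction_weights_3d,
    transverse_vectors_from_primary,
)

L2 = {lab: i for i, lab in enumerate(DIRECTION_LABELS_2D)}
L3 = {lab: i for i, lab in enumerate(DIRECTION_LABELS_3D)}


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def unit_vec_strategy(dim):
    return st.lists(
        st.floats(-1, 1, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
        min_size=dim, max_size=dim,
    ).map(unit)


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

class TestPlaneAngle:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 0.0, 0.0),
        (1.0, 1.0, np.pi / 4),
        (0.6, 0.8, 0.9272952180016123),  # arcsin(0.8)
        (0.0, 1.0, np.pi / 2),
    ])
    def test_values(self, a, b, expected):
        theta, degenerate = plane_angle(a, b)
        assert theta == pytest.approx(expected, abs=1e-12)
        assert not degenerate

    def test_degenerate_flagged_as_zero(self):
        theta, degenerate = plane_angle(0.0, 0.0)
        assert theta == 0.0 and degenerate

    def test_sign_insensitive(self):
        assert plane_angle(-0.6, 0.8)[0] == plane_angle(0.6, -0.8)[0]


class TestAxisWeight:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, (1.0, 0.0)),
        (np.pi / 4, (0.0, 1.0)),
        (np.pi / 8, (0.5, 0.5)),
        (np.pi / 2, (1.0, 0.0)),
    ])
    def test_linear_in_angle(self, theta, expected):
        w_axis, w_diag = axis_weight(theta)
        assert (w_axis, w_diag) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            axis_weight(-0.1)
        with pytest.raises(ValueError):
            axis_weight(np.pi)


class TestPointingParameters:
    def test_2d_generic(self):
        p = pointing_parameters([0.6, 0.8])
        assert (p["P_x"], p["P_y"], p["P_xy+"]) == (0, 1, 1)

    def test_2d_tie_follows_printed_rule(self):
        p = pointing_parameters(unit([1.0, -1.0]))
        assert p["P_x"] == 1  # x^2 >= y^2 at the tie
        assert p["P_xy+"] == 0  # xy < 0

    def test_3d_axis_case(self):
        p = pointing_parameters([0.0, 0.0, 1.0])
        assert (p["P_x"], p["P_y"], p["P_z"]) == (0, 0, 1)
        # products are 0 and the printed ">= 0" applies
        assert p["P_xz+"] == 1 and p["P_yz+"] == 1

    @given(unit_vec_strategy(3))
    def test_exactly_one_axis_parameter(self, v):
        p = pointing_parameters(v)
        assert p["P_x"] + p["P_y"] + p["P_z"] == 1


# ---------------------------------------------------------------------------
# 2D weights
# ---------------------------------------------------------------------------

class TestWeights2D:
    @pytest.mark.parametrize("v,expected", [
        ((1, 0), {"xx": 1.0}),
        (unit((1, 1)), {"xy++": 1.0}),
        ((np.cos(np.pi / 8), np.sin(np.pi / 8)), {"xx": 0.5, "xy++": 0.5}),
    ])
    def test_axial_examples(self, v, expected):
        w = direction_weights_2d(np.asarray(v, dtype=float))
        for lab, idx in L2.items():
            assert w[idx] == pytest.approx(expected.get(lab, 0.0),
                                           abs=1e-12)

    @pytest.mark.parametrize("v,expected", [
        ((1, 0), {"yy": 1.0}),
        (unit((1, 1)), {"xy+-": 1.0}),
        ((np.cos(np.pi / 8), np.sin(np.pi / 8)), {"yy": 0.5, "xy+-": 0.5}),
    ])
    def test_transverse_examples(self, v, expected):
        w = transverse_weights_2d(np.asarray(v, dtype=float))
        for lab, idx in L2.items():
            assert w[idx] == pytest.approx(expected.get(lab, 0.0),
                                           abs=1e-12)

    @given(unit_vec_strategy(2))
    def test_partition_of_unity_and_support(self, v):
        for w in (direction_weights_2d(v), transverse_weights_2d(v)):
            assert abs(w.sum() - 1.0) < 1e-12
            assert np.all((w >= 0) & (w <= 1))
            assert (w > 1e-12).sum() <= 2


# ---------------------------------------------------------------------------
# 3D: independent conditional-algorithm oracle
# ---------------------------------------------------------------------------

def oracle_weights_3d(v):
    """Direct conditional evaluation of the angle-weight scheme.

    Chooses the dominant axis explicitly and assigns the quadrant weights
    to the four named directions with if/else logic, independent of the
    pointing-parameter product formulation under test.
    """
    x, y, z = v
    ths = {}
    for (a, b, key) in ((x, y, "xy"), (x, z, "xz"), (y, z, "yz")):
        h = np.hypot(a, b)
        th = 0.0 if h == 0 else np.arcsin(abs(b) / h)
        ths[key] = abs((th - np.pi / 4) / (np.pi / 4))
    w = {lab: 0.0 for lab in DIRECTION_LABELS_3D}
    sxy = "++" if x * y >= 0 else "+-"
    sxz = "++" if x * z >= 0 else "+-"
    syz = "++" if y * z >= 0 else "+-"
    if x * x >= y * y and x * x >= z * z:
        axis, plane_diag, elev_diag = "xx", "xy" + sxy, "xz" + sxz
        wp, we = ths["xy"], ths["xz"]
    elif y * y >= z * z:
        axis, plane_diag, elev_diag = "yy", "xy" + sxy, "yz" + syz
        wp, we = ths["xy"], ths["yz"]
    else:
        axis, plane_diag, elev_diag = "zz", "xz" + sxz, "yz" + syz
        wp, we = ths["xz"], ths["yz"]
    corner = "xyz" + {"++": "+", "+-": "-"}[sxz] + {"++": "+", "+-": "-"}[syz]
    corner = {"xyz++": "xyz+++", "xyz--": "xyz++-",
              "xyz+-": "xyz+-+", "xyz-+": "xyz+--"}[corner]
    w[axis] = wp * we
    w[plane_diag] = (1 - wp) * we
    w[elev_diag] = wp * (1 - we)
    w[corner] = (1 - wp) * (1 - we)
    return np.array([w[lab] for lab in DIRECTION_LABELS_3D])


class TestWeights3D:
    @pytest.mark.parametrize("v,expected_idx", [
        ((0.0, 0.0, 1.0), L3["zz"]),
        (unit((1, 0, 1)), L3["xz++"]),
        ((1.0, 0.0, 0.0), L3["xx"]),
        (unit((1, 1, 1)), L3["xyz+++"]),
    ])
    def test_pure_directions(self, v, expected_idx):
        w = direction_weights_3d(np.asarray(v, dtype=float))
        assert w[expected_idx] == pytest.approx(1.0, abs=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadrant_weights_examples(self):
        assert quadrant_weights_3d([1.0, 0.0, 0.0]) == \
            pytest.approx((1, 0, 0, 0), abs=1e-12)
        assert quadrant_weights_3d(unit((1, 1, 1))) == \
            pytest.approx((0, 0, 0, 1), abs=1e-12)

    def test_generic_vector_against_oracle(self):
        v = unit((0.8, 0.36, 0.48))
        w = direction_weights_3d(v)
        assert np.allclose(w, oracle_weights_3d(v), atol=1e-12)
        # +x quadrant with xy, xz > 0: support is axis + two diags + corner
        nz = {DIRECTION_LABELS_3D[i] for i in np.flatnonzero(w > 1e-12)}
        assert nz == {"xx", "xy++", "xz++", "xyz+++"}

    @given(unit_vec_strategy(3))
    def test_matches_oracle_everywhere(self, v):
        assert np.allclose(direction_weights_3d(v), oracle_weights_3d(v),
                           atol=1e-12)

    @given(unit_vec_strategy(3))
    def test_partition_of_unity_and_support(self, v):
        w = direction_weights_3d(v)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all((w >= 0) & (w <= 1))
        assert (w > 1e-12).sum() <= 4

    def test_3d_reduces_to_2d_in_plane(self, rng):
        v2 = rng.standard_normal((200, 2))
        v2 /= np.linalg.norm(v2, axis=1, keepdims=True)
        v3 = np.concatenate([v2, np.zeros((200, 1))], axis=1)
        w3 = direction_weights_3d(v3)
        w2 = direction_weights_2d(v2)
        has_z = [i for i, lab in enumerate(DIRECTION_LABELS_3D)
                 if "z" in lab]
        assert np.allclose(w3[:, has_z], 0.0, atol=1e-12)
        for lab in DIRECTION_LABELS_2D:
            assert np.allclose(w3[:, L3[lab]], w2[:, L2[lab]], atol=1e-12)


# ---------------------------------------------------------------------------
# lattice symmetries
# ---------------------------------------------------------------------------

def _canonical(off):
    off = tuple(off)
    for o in off:
        if o > 0:
            return off
        if o < 0:
            return tuple(-x for x in off)
    raise AssertionError


def _offset_index(offsets):
    return {_canonical(o): i for i, o in enumerate(offsets)}


@pytest.mark.parametrize("dim,offsets,weight_fn", [
    (2, DIRECTION_OFFSETS_2D, direction_weights_2d),
    (3, DIRECTION_OFFSETS_3D, direction_weights_3d),
])
def test_signed_permutation_symmetry(dim, offsets, weight_fn, rng):
    """Relabelling axes (any signed permutation) permutes the weight map."""
    idx = _offset_index(offsets)
    vs = rng.standard_normal((20, dim))
    vs /= np.linalg.norm(vs, axis=1, keepdims=True)
    for perm in itertools.permutations(range(dim)):
        for signs in itertools.product([1, -1], repeat=dim):
            P = np.zeros((dim, dim))
            for i, (p, s) in enumerate(zip(perm, signs)):
                P[i, p] = s
            for v in vs:
                w = weight_fn(v)
                w_t = weight_fn(P @ v)
                for d, off in enumerate(offsets):
                    d_t = idx[_canonical(P @ np.asarray(off))]
                    assert w_t[d_t] == pytest.approx(w[d], abs=1e-12)


# ---------------------------------------------------------------------------
# transverse triad construction
# ---------------------------------------------------------------------------

class TestTransverseVectors:
    def test_hand_example(self):
        t1, t2 = transverse_vectors_from_primary(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(t1, [0, 0, 1], atol=1e-12)
        assert np.allclose(t2, [0, -1, 0], atol=1e-12)

    @given(unit_vec_strategy(3))
    def test_orthonormal_triad_with_planar_t2(self, v):
        t1, t2 = transverse_vectors_from_primary(v)
        assert abs(np.dot(v, t1)) < 1e-9
        assert abs(np.dot(v, t2)) < 1e-9
        assert abs(np.dot(t1, t2)) < 1e-9
        assert abs(t2[2]) < 1e-9
        assert np.linalg.norm(t1) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(t2) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("vz", [1.0, -1.0])
    def test_degenerate_polar_convention(self, vz):
        v = np.array([0.0, 0.0, vz])
        t1, t2 = transverse_vectors_from_primary(v)
        assert np.allclose(t1, [1, 0, 0])
        assert abs(np.dot(v, t2)) < 1e-12 and abs(np.dot(t1, t2)) < 1e-12
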