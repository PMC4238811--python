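"""Rotation representation conversions, checked against closed forms and
scipy.spatial.transform.Rotation as an independent implementation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from rotent.rotations import (
    SymmetryMode,
    axis_angle_to_quaternion,
    c2v_image,
    canonicalize_sign,
    euler_to_quaternion,
    matrix_to_quaternion,
    quaternion_multiply,
    quaternion_to_euler,
    quaternion_to_matrix,
    water_body_frame,
    wrap_euler,
)
from rotent.metrics import delta3

from conftest import random_quaternions


def scipy_from_wxyz(q):
    q = np.asarray(q)
    return ScipyRotation.from_quat(np.concatenate([q[..., 1:], q[..., :1]], axis=-1))


@pytest.mark.parametrize(
    "axis,theta,expected",
    [
        ((0, 0, 1), 0.0, (1, 0, 0, 0)),
        ((0, 0, 1), np.pi, (0, 0, 0, 1)),
        ((0, 0, 1), np.pi / 2, (np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2)),
    ],
)
def test_axis_angle_to_quaternion_closed_forms(axis, theta, expected):
    np.testing.assert_allclose(
        axis_angle_to_quaternion(axis, theta), expected, atol=1e-15
    )


def test_axis_angle_rejects_non_unit_axis():
    with pytest.raises(ValueError):
        axis_angle_to_quaternion((0, 0, 2), 0.5)


@pytest.mark.parametrize(
    "q,expected",
    [
        ((1, 0, 0, 0), np.eye(3)),
        ((0, 0, 0, 1), np.diag([-1.0, -1.0, 1.0])),
    ],
)
def test_quaternion_to_matrix_closed_forms(q, expected):
    np.testing.assert_allclose(quaternion_to_matrix(q), expected, atol=1e-15)


def test_matrix_invariants_and_double_cover(rng):
    q = random_quaternions(rng, 200)
    m = quaternion_to_matrix(q)
    np.testing.assert_allclose(
        np.swapaxes(m, -1, -2) @ m, np.broadcast_to(np.eye(3), m.shape), atol=1e-10
    )
    np.testing.assert_allclose(np.linalg.det(m), 1.0, atol=1e-10)
    np.testing.assert_array_equal(m, quaternion_to_matrix(-q))


def test_matrix_round_trip(rng):
    q = canonicalize_sign(random_quaternions(rng, 1000))
    np.testing.assert_allclose(matrix_to_quaternion(quaternion_to_matrix(q)), q, atol=1e-9)


def test_matrix_against_scipy(rng):
    q = random_quaternions(rng, 200)
    np.testing.assert_allclose(
        quaternion_to_matrix(q), scipy_from_wxyz(q).as_matrix(), atol=1e-12
    )


def test_matrix_to_quaternion_rejects_improper():
    with pytest.raises(ValueError):
        matrix_to_quaternion(np.diag([1.0, 1.0, -1.0]))


def test_composition_consistency(rng):
    q1 = random_quaternions(rng, 1000)
    q2 = random_quaternions(rng, 1000)
    np.testing.assert_allclose(
        quaternion_to_matrix(quaternion_multiply(q1, q2)),
        quaternion_to_matrix(q1) @ quaternion_to_matrix(q2),
        atol=1e-10,
    )


def test_euler_identity_and_pure_z_spin():
    np.testing.assert_allclose(euler_to_quaternion((0, 0, 0)), (1, 0, 0, 0), atol=1e-15)
    gamma = 1.2
    np.testing.assert_allclose(
        euler_to_quaternion((0, 0, gamma)),
        axis_angle_to_quaternion((0, 0, 1), gamma),
        atol=1e-15,
    )


def test_euler_against_scipy(rng):
    e = np.column_stack(
        [
            rng.uniform(0, 2 * np.pi, 300),
            rng.uniform(0.05, np.pi - 0.05, 300),
            rng.uniform(0, 2 * np.pi, 300),
        ]
    )
    ours = canonicalize_sign(euler_to_quaternion(e))
    theirs = ScipyRotation.from_euler("ZYZ", e).as_quat()  # x, y, z, w
    theirs = canonicalize_sign(np.column_stack([theirs[:, 3], theirs[:, :3]]))
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_euler_round_trip(rng):
    e = np.column_stack(
        [
            rng.uniform(0, 2 * np.pi, 1000),
            rng.uniform(1e-3, np.pi - 1e-3, 1000),
            rng.uniform(0, 2 * np.pi, 1000),
        ]
    )
    back = quaternion_to_euler(euler_to_quaternion(e))
    np.testing.assert_allclose(back[:, 0], e[:, 0], atol=1e-9)
    np.testing.assert_allclose(np.cos(back[:, 1]), np.cos(e[:, 1]), atol=1e-9)
    np.testing.assert_allclose(back[:, 2], e[:, 2], atol=1e-9)


def test_gimbal_lock_convention():
    np.testing.assert_allclose(quaternion_to_euler((1, 0, 0, 0)), (0, 0, 0), atol=1e-12)
    # beta = 0: the whole spin folds into alpha, gamma = 0
    q = axis_angle_to_quaternion((0, 0, 1), np.pi / 2)
    a, b, g = quaternion_to_euler(q)
    assert b == 0.0 and g == 0.0
    assert a == pytest.approx(np.pi / 2, abs=1e-12)
    # beta = pi: alpha - gamma survives, gamma = 0
    q = euler_to_quaternion((1.0, np.pi, 0.7))
    a, b, g = quaternion_to_euler(q)
    assert b == pytest.approx(np.pi) and g == 0.0
    assert a == pytest.approx(0.3, abs=1e-9)


def test_wrap_euler_ranges():
    e = wrap_euler((7.0, 2.0, -1.0), SymmetryMode.C1)
    assert 0 <= e[0] < 2 * np.pi and 0 <= e[2] < 2 * np.pi
    e = wrap_euler((0.5, 2.0, 4.0), SymmetryMode.C2V)
    assert 0 <= e[2] < np.pi


def _ideal_water(rotation_q=None):
    """O at origin, H-O-H bisector along +z, H->H along +y (104.5 deg)."""
    half = np.deg2rad(104.5 / 2)
    bond = 0.9572
    o = np.zeros(3)
    h1 = bond * np.array([0.0, -np.sin(half), np.cos(half)])
    h2 = bond * np.array([0.0, np.sin(half), np.cos(half)])
    if rotation_q is not None:
        m = quaternion_to_matrix(rotation_q)
        o, h1, h2 = m @ o, m @ h1, m @ h2
    return o, h1, h2


def test_water_body_frame_reference_orientation():
    np.testing.assert_allclose(water_body_frame(*_ideal_water()), (1, 0, 0, 0), atol=1e-12)


def test_water_body_frame_recovers_applied_rotation(rng):
    for q in random_quaternions(rng, 20):
        got = water_body_frame(*_ideal_water(q))
        assert delta3(got, q) < 1e-9
    # pi about z maps to the (0,0,0,1) quaternion up to sign
    got = water_body_frame(*_ideal_water(np.array([0.0, 0.0, 0.0, 1.0])))
    np.testing.assert_allclose(np.abs(got), (0, 0, 0, 1), atol=1e-12)


def test_water_body_frame_hydrogen_swap_is_c2v_image():
    o, h1, h2 = _ideal_water(np.array([0.3, 0.5, -0.2, 0.787]) / np.linalg.norm([0.3, 0.5, -0.2, 0.787]))
    q = water_body_frame(o, h1, h2)
    q_swapped = water_body_frame(o, h2, h1)
    assert delta3(q, q_swapped, SymmetryMode.C2V) < 1e-9
    assert delta3(q, c2v_image(q_swapped)) < 1e-9


def test_water_body_frame_rejects_collinear():
    with pytest.raises(ValueError):
        water_body_frame((0, 0, 0), (0, 0, 1.0), (0, 0, -1.0))
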