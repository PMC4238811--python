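"""Rotation representations and conversions.

Conventions used throughout the package
---------------------------------------
* **Quaternions** are scalar-first arrays ``(w, x, y, z)`` on the unit 3-sphere.
  ``q`` and ``-q`` encode the same rotation (double cover); every consumer in
  this package is sign-invariant, and :func:`canonicalize_sign` provides a
  deterministic representative (``w >= 0``, ties broken by the first non-zero
  component) for serialization.
* **Euler angles** use the z-y'-z'' (intrinsic ZYZ) chart: ``alpha`` about the
  laboratory z axis, ``beta`` about the new y axis, ``gamma`` about the final
  z axis, with ranges ``alpha, gamma in [0, 2*pi)`` and ``beta in [0, pi]``.
  Under this convention the invariant (Haar) measure on rotations is
  ``d(alpha) d(cos beta) d(gamma)``, which is what makes the chart convenient
  for uniform sampling and histogramming.
* **Reference orientation** for a water-like molecule: primary (C2) axis along
  +z, secondary in-plane axis along +y.

All functions broadcast over leading axes; quaternion arguments have shape
``(..., 4)``, Euler triples ``(..., 3)``, matrices ``(..., 3, 3)``.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "SymmetryMode",
    "normalize_quaternion",
    "canonicalize_sign",
    "quaternion_multiply",
    "c2v_image",
    "axis_angle_to_quaternion",
    "quaternion_to_matrix",
    "matrix_to_quaternion",
    "euler_to_quaternion",
    "quaternion_to_euler",
    "wrap_euler",
    "water_body_frame",
]

TWO_PI = 2.0 * np.pi

#: |q| must be within this of 1 after construction/normalization.
QUAT_NORM_TOL = 1e-12
#: axis vectors are rejected when ||axis| - 1| exceeds this.
AXIS_NORM_TOL = 1e-6
#: sin(beta/2) / cos(beta/2) below this triggers the gimbal-lock convention.
GIMBAL_TOL = 1e-7
#: cross-product norm (A^2) below which water geometry is considered collinear.
COLLINEAR_TOL = 1e-8


class SymmetryMode(str, enum.Enum):
    """Molecular symmetry handling for orientation space.

    ``C1``: no symmetry; orientation space is the full rotation group,
    angular volume 8*pi**2.

    ``C2V``: two-fold symmetry about the body primary axis (water): rotations
    differing by a pi spin about that axis are identified, gamma is defined
    modulo pi and the angular volume halves to 4*pi**2.
    """

    C1 = "c1"
    C2V = "c2v"


def _as_array(x, last_dim: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape[-1:] != (last_dim,):
        raise ValueError(f"{name} must have shape (..., {last_dim}), got {a.shape}")
    return a


def normalize_quaternion(q) -> np.ndarray:
    """Return ``q`` scaled to unit norm (does not fix the sign)."""
    q = _as_array(q, 4, "quaternion")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def canonicalize_sign(q) -> np.ndarray:
    """Pick the representative of {q, -q} whose first non-zero component is > 0."""
    q = _as_array(q, 4, "quaternion")
    sign = np.zeros(q.shape[:-1], dtype=float)
    for i in range(4):
        sign = np.where(sign == 0.0, np.sign(q[..., i]), sign)
    sign = np.where(sign == 0.0, 1.0, sign)
    return q * sign[..., None]


def quaternion_multiply(q1, q2) -> np.ndarray:
    """Hamilton product ``q1 (x) q2`` (apply q2 first, then q1)."""
    q1 = _as_array(q1, 4, "q1")
    q2 = _as_array(q2, 4, "q2")
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def c2v_image(q) -> np.ndarray:
    """Compose with a pi spin about the *body* primary axis: ``q (x) (0,0,0,1)``.

    For a molecule with C2v symmetry this maps an orientation to its physically
    indistinguishable image; symmetrized distances minimize over the pair.
    """
    q = _as_array(q, 4, "quaternion")
    w, x, y, z = (q[..., i] for i in range(4))
    return np.stack([-z, y, -x, w], axis=-1)


def axis_angle_to_quaternion(axis, theta) -> np.ndarray:
    """Quaternion ``(cos(t/2), i sin(t/2), j sin(t/2), k sin(t/2))`` for a
    rotation by ``theta`` about the unit vector ``axis``."""
    axis = _as_array(axis, 3, "axis")
    theta = np.asarray(theta, dtype=float)
    norm = np.linalg.norm(axis, axis=-1)
    if np.any(np.abs(norm - 1.0) > AXIS_NORM_TOL):
        raise ValueError("rotation axis must be a unit vector")
    axis = axis / norm[..., None]
    half = theta / 2.0
    q = np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )
    return normalize_quaternion(q)


def quaternion_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a unit quaternion (identical for ``q`` and ``-q``)."""
    q = normalize_quaternion(q)
    w, x, y, z = (q[..., i] for i in range(4))
    row0 = np.stack(
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1
    )
    row1 = np.stack(
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1
    )
    row2 = np.stack(
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1
    )
    return np.stack([row0, row1, row2], axis=-2)


def matrix_to_quaternion(m, tol: float = 1e-8) -> np.ndarray:
    """Unit quaternion (sign-canonicalized) of a proper rotation matrix.

    Uses Shepperd's method: the largest of the four squared components is used
    as the pivot, which is numerically stable for all rotations.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"rotation matrix must have shape (..., 3, 3), got {m.shape}")
    ident = np.eye(3)
    mtm = np.swapaxes(m, -1, -2) @ m
    if np.any(np.abs(mtm - ident) > 1e-6) or np.any(
        np.abs(np.linalg.det(m) - 1.0) > 1e-6
    ):
        raise ValueError("matrix is not a proper rotation (orthogonal, det=+1)")

    batch = m.reshape(-1, 3, 3)
    out = np.empty((batch.shape[0], 4))
    for i, r in enumerate(batch):
        tr = np.trace(r)
        # squared components (up to 1/4 factor); pick the largest as pivot
        cand = np.array(
            [1.0 + tr, 1.0 + 2 * r[0, 0] - tr, 1.0 + 2 * r[1, 1] - tr, 1.0 + 2 * r[2, 2] - tr]
        )
        j = int(np.argmax(cand))
        s = 2.0 * np.sqrt(max(cand[j], 0.0))
        if j == 0:
            q = np.array(
                [s / 4, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
            )
        elif j == 1:
            q = np.array(
                [(r[2, 1] - r[1, 2]) / s, s / 4, (r[0, 1] + r[1, 0]) / s, (r[0, 2] + r[2, 0]) / s]
            )
        elif j == 2:
            q = np.array(
                [(r[0, 2] - r[2, 0]) / s, (r[0, 1] + r[1, 0]) / s, s / 4, (r[1, 2] + r[2, 1]) / s]
            )
        else:
            q = np.array(
                [(r[1, 0] - r[0, 1]) / s, (r[0, 2] + r[2, 0]) / s, (r[1, 2] + r[2, 1]) / s, s / 4]
            )
        out[i] = q
    out = canonicalize_sign(normalize_quaternion(out))
    return out.reshape(m.shape[:-2] + (4,))


def wrap_euler(euler, symmetry: SymmetryMode = SymmetryMode.C1) -> np.ndarray:
    """Wrap ``(alpha, beta, gamma)`` into their canonical ranges.

    ``alpha`` into [0, 2pi); ``beta`` is clipped to [0, pi] (it is only ever
    produced in range); ``gamma`` into [0, 2pi), or [0, pi) under C2v.
    """
    e = _as_array(euler, 3, "euler").copy()
    e[..., 0] %= TWO_PI
    e[..., 1] = np.clip(e[..., 1], 0.0, np.pi)
    gwrap = np.pi if symmetry is SymmetryMode.C2V else TWO_PI
    e[..., 2] %= gwrap
    return e


def euler_to_quaternion(euler) -> np.ndarray:
    """Quaternion of the ZYZ Euler triple ``(alpha, beta, gamma)``."""
    e = _as_array(euler, 3, "euler")
    a, b, g = e[..., 0] / 2.0, e[..., 1] / 2.0, e[..., 2] / 2.0
    cb, sb = np.cos(b), np.sin(b)
    return np.stack(
        [
            cb * np.cos(a + g),
            -sb * np.sin(a - g),
            sb * np.cos(a - g),
            cb * np.sin(a + g),
        ],
        axis=-1,
    )


def quaternion_to_euler(q) -> np.ndarray:
    """ZYZ Euler triple of a unit quaternion.

    At gimbal lock (``|cos beta| = 1``) only ``alpha ± gamma`` is determined;
    the convention here is ``gamma = 0`` with the full spin folded into
    ``alpha``, which keeps the inverse deterministic.
    """
    q = normalize_quaternion(q)
    w, x, y, z = (q[..., i] for i in range(4))
    sxy = np.hypot(x, y)  # |sin(beta/2)|
    swz = np.hypot(w, z)  # |cos(beta/2)|
    beta = 2.0 * np.arctan2(sxy, swz)
    half_sum = np.arctan2(z, w)  # (alpha + gamma)/2, undefined at beta=pi
    half_diff = np.arctan2(-x, y)  # (alpha - gamma)/2, undefined at beta=0

    alpha = (half_sum + half_diff) % TWO_PI
    gamma = (half_sum - half_diff) % TWO_PI
    # gimbal lock: fold the surviving degree of freedom into alpha
    lock_lo = sxy < GIMBAL_TOL  # beta ~ 0: only alpha+gamma survives
    lock_hi = swz < GIMBAL_TOL  # beta ~ pi: only alpha-gamma survives
    alpha = np.where(lock_lo, (2.0 * half_sum) % TWO_PI, alpha)
    alpha = np.where(lock_hi, (2.0 * half_diff) % TWO_PI, alpha)
    gamma = np.where(lock_lo | lock_hi, 0.0, gamma)
    beta = np.where(lock_lo, 0.0, np.where(lock_hi, np.pi, beta))
    return np.stack([alpha, beta, gamma], axis=-1)


def water_body_frame(o, h1, h2) -> np.ndarray:
    """Orientation quaternion of a water-like molecule from its atom positions.

    The body frame is built from the oxygen position ``o`` and the two
    hydrogen positions: primary axis = unit bisector of the H-O-H angle
    (mapped from +z of the reference orientation), secondary axis = in-plane
    unit vector along H1->H2 orthogonalized against the bisector (mapped from
    +y). Returns the rotation carrying the reference orientation onto the body
    frame. Swapping ``h1`` and ``h2`` yields the C2v symmetry image.

    Raises ``ValueError`` for (near-)collinear geometries, detected when the
    cross product of the two O-H bond directions has norm below
    ``COLLINEAR_TOL``.
    """
    o = _as_array(o, 3, "o")
    h1 = _as_array(h1, 3, "h1")
    h2 = _as_array(h2, 3, "h2")
    b1 = h1 - o
    b2 = h2 - o
    n1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    n2 = np.linalg.norm(b2, axis=-1, keepdims=True)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("degenerate water geometry: zero-length O-H bond")
    u1 = b1 / n1
    u2 = b2 / n2
    if np.any(np.linalg.norm(np.cross(u1, u2), axis=-1) < COLLINEAR_TOL):
        raise ValueError("degenerate water geometry: collinear atoms")
    zb = u1 + u2  # bisector
    zb = zb / np.linalg.norm(zb, axis=-1, keepdims=True)
    yb = u2 - u1  # along H1 -> H2, already orthogonal to the bisector
    yb = yb - np.sum(yb * zb, axis=-1, keepdims=True) * zb
    yb = yb / np.linalg.norm(yb, axis=-1, keepdims=True)
    xb = np.cross(yb, zb)
    # columns are the images of the reference axes
    mat = np.stack([xb, yb, zb], axis=-1)
    return matrix_to_quaternion(mat)
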