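"""Distance metrics on 3D rotations and nearest-neighbor search.

Four metrics are provided, all sign-invariant under the quaternion double
cover (``q`` ~ ``-q``):

* ``D1`` — Euclidean distance in the Euler chart: wrapped differences of
  ``alpha`` and ``gamma`` plus the difference of ``cos beta``; range
  [0, sqrt(4 + 2 pi^2)].
* ``D2`` — twice the Euclidean norm of the quaternion difference,
  ``2 sqrt(2 - 2 |<q1,q2>|)``; range [0, 2 sqrt(2)].
* ``D3`` — geodesic (natural Riemannian) distance, the relative rotation
  angle ``theta = 2 arccos |<q1,q2>|``; range [0, pi].
* ``D4`` — deviation from the identity matrix, ``|I - R1 R2^T|_F / sqrt(2)
  = 2 sin(theta/2)``; range [0, 2].

D2, D3 and D4 are monotone decreasing functions of the absolute quaternion
inner product, so they share nearest-neighbor graphs and the search ranks
neighbors by ``|<q1,q2>|`` alone, applying the transcendental function only
to the selected neighbor (the paper's efficiency trick). D1 is ranked by the
squared chart distance. Under ``C2V`` symmetry every distance is minimized
over the pi-spin image of one argument (equivalently gamma is compared
modulo pi for D1).

The search is an exhaustive, chunked O(n^2) scan — exact, deterministic
(ties broken by lowest sample index) and fast enough for the sample sizes
used here; optional numba kernels accelerate the common k=1 case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .rotations import SymmetryMode, c2v_image, quaternion_to_euler, wrap_euler

__all__ = [
    "Metric",
    "MetricSpec",
    "METRIC_MAX",
    "delta1",
    "delta2",
    "delta3",
    "delta4",
    "rotation_distance",
    "symmetrize",
    "nearest_neighbor_distances",
    "knn_absdot",
    "distance_from_absdot",
]

try:  # optional acceleration; the numpy path below is the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

TWO_PI = 2.0 * np.pi


class Metric(str, enum.Enum):
    D1 = "d1"
    D2 = "d2"
    D3 = "d3"
    D4 = "d4"


#: maximum attainable distance for each metric (C1 mode)
METRIC_MAX = {
    Metric.D1: np.sqrt(4.0 + 2.0 * np.pi**2),
    Metric.D2: 2.0 * np.sqrt(2.0),
    Metric.D3: np.pi,
    Metric.D4: 2.0,
}

QUATERNION_METRICS = (Metric.D2, Metric.D3, Metric.D4)


@dataclass(frozen=True)
class MetricSpec:
    """A distance metric plus the symmetry mode it is evaluated under."""

    metric: Metric
    symmetry: SymmetryMode = SymmetryMode.C1

    def __post_init__(self):
        object.__setattr__(self, "metric", Metric(self.metric))
        object.__setattr__(self, "symmetry", SymmetryMode(self.symmetry))


def _wrapped_diff(a, b, period):
    d = np.abs(a - b) % period
    return np.minimum(d, period - d)


def delta1(e1, e2, symmetry: SymmetryMode = SymmetryMode.C1) -> np.ndarray:
    """Euclidean distance in the Euler chart (alpha, cos beta, gamma).

    alpha differences wrap modulo 2 pi, gamma modulo 2 pi (or pi under C2v),
    and the second coordinate is the plain difference of cos(beta).
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    da = _wrapped_diff(e1[..., 0], e2[..., 0], TWO_PI)
    dc = np.abs(np.cos(e1[..., 1]) - np.cos(e2[..., 1]))
    gwrap = np.pi if SymmetryMode(symmetry) is SymmetryMode.C2V else TWO_PI
    dg = _wrapped_diff(e1[..., 2], e2[..., 2], gwrap)
    return np.sqrt(da * da + dc * dc + dg * dg)


def _absdot(q1, q2, symmetry: SymmetryMode) -> np.ndarray:
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    d = np.abs(np.sum(q1 * q2, axis=-1))
    if SymmetryMode(symmetry) is SymmetryMode.C2V:
        d = np.maximum(d, np.abs(np.sum(q1 * c2v_image(q2), axis=-1)))
    return np.clip(d, 0.0, 1.0)


#: inner products this close to 1 are snapped to 1 exactly, so identical
#: rotations (and bitwise-duplicate samples) sit at distance zero despite
#: the sqrt/arccos cancellation near |<q1,q2>| = 1.
_DOT_ONE_SNAP = 1.0 - 5e-15


def distance_from_absdot(absdot, metric: Metric) -> np.ndarray:
    """Map the absolute quaternion inner product to a D2/D3/D4 distance."""
    m = np.clip(np.asarray(absdot, dtype=float), 0.0, 1.0)
    m = np.where(m >= _DOT_ONE_SNAP, 1.0, m)
    metric = Metric(metric)
    if metric is Metric.D2:
        return 2.0 * np.sqrt(2.0 - 2.0 * m)
    if metric is Metric.D3:
        return 2.0 * np.arccos(m)
    if metric is Metric.D4:
        return 2.0 * np.sqrt((1.0 - m) * (1.0 + m))
    raise ValueError(f"{metric} is not a quaternion-inner-product metric")


def delta2(q1, q2, symmetry: SymmetryMode = SymmetryMode.C1) -> np.ndarray:
    """Twice the Euclidean distance between unit quaternions, minimized over
    the double cover: ``2 sqrt(2 - 2 |<q1,q2>|)``."""
    return distance_from_absdot(_absdot(q1, q2, symmetry), Metric.D2)


def delta3(q1, q2, symmetry: SymmetryMode = SymmetryMode.C1) -> np.ndarray:
    """Geodesic distance ``2 arccos |<q1,q2>|`` — the relative rotation angle."""
    return distance_from_absdot(_absdot(q1, q2, symmetry), Metric.D3)


def delta4(q1, q2, symmetry: SymmetryMode = SymmetryMode.C1) -> np.ndarray:
    """Deviation from the identity matrix, ``|I - R1 R2^T|_F / sqrt(2) =
    2 sin(theta/2) = 2 sqrt(1 - <q1,q2>^2)``."""
    return distance_from_absdot(_absdot(q1, q2, symmetry), Metric.D4)


def rotation_distance(q1, q2, spec: MetricSpec, e1=None, e2=None) -> np.ndarray:
    """Distance between rotations under ``spec``.

    For ``D1`` the Euler triples are derived from the quaternions unless
    supplied explicitly (samplers that generate angles directly can pass them
    through and skip the chart round-trip).
    """
    if spec.metric is Metric.D1:
        if e1 is None:
            e1 = quaternion_to_euler(q1)
        if e2 is None:
            e2 = quaternion_to_euler(q2)
        return delta1(e1, e2, spec.symmetry)
    return distance_from_absdot(_absdot(q1, q2, spec.symmetry), spec.metric)


def symmetrize(q) -> tuple[np.ndarray, np.ndarray]:
    """Return the C2v image pair ``(q, q (x) s)`` with ``s`` the pi spin about
    the body primary axis. Symmetrized distances minimize over the pair."""
    q = np.asarray(q, dtype=float)
    return q, c2v_image(q)


# ---------------------------------------------------------------------------
# nearest-neighbor search
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(fastmath=True, cache=True)
    def _nn1_absdot(q, qs, use_sym):  # pragma: no cover - exercised via wrapper
        n = q.shape[0]
        out = np.empty(n)
        for i in range(n):
            w, x, y, z = q[i, 0], q[i, 1], q[i, 2], q[i, 3]
            best = -1.0
            for j in range(n):
                if j == i:
                    continue
                d = abs(w * q[j, 0] + x * q[j, 1] + y * q[j, 2] + z * q[j, 3])
                if use_sym:
                    d2 = abs(w * qs[j, 0] + x * qs[j, 1] + y * qs[j, 2] + z * qs[j, 3])
                    if d2 > d:
                        d = d2
                if d > best:
                    best = d
            out[i] = best
        return out

    @numba.njit(fastmath=True, cache=True)
    def _nn1_chart_sq(alpha, cosb, gamma, gwrap):  # pragma: no cover
        n = alpha.shape[0]
        out = np.empty(n)
        tau = 2.0 * np.pi
        for i in range(n):
            ai, ci, gi = alpha[i], cosb[i], gamma[i]
            best = 1e300
            for j in range(n):
                if j == i:
                    continue
                da = abs(ai - alpha[j])
                if da > np.pi:
                    da = tau - da
                dg = abs(gi - gamma[j])
                if dg > 0.5 * gwrap:
                    dg = gwrap - dg
                dc = ci - cosb[j]
                d = da * da + dc * dc + dg * dg
                if d < best:
                    best = d
            out[i] = best
        return out


def _chunked_kth_absdot(q, qs, kmax: int, block: int) -> np.ndarray:
    """k-th largest |inner product| per point (k = 1..kmax), excluding self."""
    n = q.shape[0]
    out = np.empty((kmax, n))
    qt = np.ascontiguousarray(q.T)
    qst = np.ascontiguousarray(qs.T) if qs is not None else None
    for s in range(0, n, block):
        e = min(s + block, n)
        g = np.abs(q[s:e] @ qt)
        if qst is not None:
            np.maximum(g, np.abs(q[s:e] @ qst), out=g)
        g[np.arange(e - s), np.arange(s, e)] = -1.0  # exclude self
        if kmax == 1:
            out[0, s:e] = g.max(axis=1)
        else:
            part = np.partition(g, n - kmax, axis=1)[:, n - kmax:]
            part.sort(axis=1)
            out[:, s:e] = part[:, ::-1].T
    return out


def _chunked_kth_chart(e3, gwrap: float, kmax: int, block: int) -> np.ndarray:
    """k-th smallest squared chart distance per point, excluding self."""
    alpha, cosb, gamma = e3
    n = alpha.shape[0]
    out = np.empty((kmax, n))
    for s in range(0, n, block):
        e = min(s + block, n)
        da = np.abs(alpha[s:e, None] - alpha[None, :])
        np.minimum(da, TWO_PI - da, out=da)
        da *= da
        dc = cosb[s:e, None] - cosb[None, :]
        da += dc * dc
        dg = np.abs(gamma[s:e, None] - gamma[None, :])
        np.minimum(dg, gwrap - dg, out=dg)
        da += dg * dg
        da[np.arange(e - s), np.arange(s, e)] = np.inf  # exclude self
        if kmax == 1:
            out[0, s:e] = da.min(axis=1)
        else:
            part = np.partition(da, kmax - 1, axis=1)[:, :kmax]
            part.sort(axis=1)
            out[:, s:e] = part.T
    return out


def knn_absdot(q, k, symmetry: SymmetryMode = SymmetryMode.C1, block: int = 2048):
    """Absolute inner product with the k-th nearest neighbor of each point.

    ``k`` may be an int or a sequence of ints; the returned array has shape
    ``(n,)`` or ``(len(k), n)`` accordingly. This is the shared monotone
    surrogate for D2/D3/D4: their k-NN graphs coincide.
    """
    q = np.ascontiguousarray(q, dtype=float)
    ks = np.atleast_1d(np.asarray(k, dtype=int))
    if np.any(ks < 1):
        raise ValueError("k must be >= 1")
    n = q.shape[0]
    kmax = int(ks.max())
    if n <= kmax:
        raise ValueError(f"need at least k+1 = {kmax + 1} samples, got {n}")
    sym = SymmetryMode(symmetry) is SymmetryMode.C2V
    qs = np.ascontiguousarray(c2v_image(q)) if sym else None
    if kmax == 1 and _HAVE_NUMBA:
        res = _nn1_absdot(q, qs if sym else q, sym)[None, :]
    else:
        res = _chunked_kth_absdot(q, qs, kmax, block)
    res = res[ks - 1]
    return res[0] if np.isscalar(k) or np.ndim(k) == 0 else res


def nearest_neighbor_distances(
    sample,
    k,
    spec: MetricSpec,
    *,
    euler=None,
    block: int = 2048,
) -> np.ndarray:
    """Distance from each sample point to its k-th nearest other point.

    Parameters
    ----------
    sample : (n, 4) array of unit quaternions.
    k : int or sequence of ints (k >= 1; requires n >= k+1).
    spec : metric and symmetry mode.
    euler : optional (n, 3) Euler triples for D1, to skip the chart conversion.
    block : row-chunk size bounding the working memory of the O(n^2) scan.

    Returns
    -------
    (n,) array for scalar ``k``, else ``(len(k), n)``.
    """
    q = np.ascontiguousarray(sample, dtype=float)
    ks = np.atleast_1d(np.asarray(k, dtype=int))
    if np.any(ks < 1):
        raise ValueError("k must be >= 1")
    n = q.shape[0]
    kmax = int(ks.max())
    if n <= kmax:
        raise ValueError(f"need at least k+1 = {kmax + 1} samples, got {n}")

    if spec.metric is Metric.D1:
        e = quaternion_to_euler(q) if euler is None else np.asarray(euler, float)
        e = wrap_euler(e, spec.symmetry)
        gwrap = np.pi if spec.symmetry is SymmetryMode.C2V else TWO_PI
        coords = (
            np.ascontiguousarray(e[:, 0]),
            np.ascontiguousarray(np.cos(e[:, 1])),
            np.ascontiguousarray(e[:, 2]),
        )
        if kmax == 1 and _HAVE_NUMBA:
            sq = _nn1_chart_sq(*coords, gwrap)[None, :]
        else:
            sq = _chunked_kth_chart(coords, gwrap, kmax, block)
        res = np.sqrt(sq[ks - 1])
    else:
        absdot = knn_absdot(q, ks, spec.symmetry, block=block)
        res = distance_from_absdot(absdot, spec.metric)
    return res[0] if np.isscalar(k) or np.ndim(k) == 0 else res
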