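"""Entropy estimators for orientation samples.

Both estimators report the *relative* orientational entropy in nats: the
Shannon entropy relative to the uniform (Haar) distribution over rotation
space, i.e. minus the Kullback-Leibler divergence from uniform. It is zero
for a uniform distribution and negative for any ordering.

KNN estimator
-------------
The Kozachenko-Leonenko-type estimator of the absolute differential entropy
from k-th nearest-neighbor distances ``R_{i,k}`` in ``p = 3`` rotational
degrees of freedom::

    H_abs = (p/n) sum_i ln R_{i,k} + ln V_p + ln n + gamma - L_{k-1}

with ``V_p = pi^{p/2} / Gamma(p/2 + 1)`` the unit-ball volume (``4 pi / 3``
for p=3, using ``Gamma(5/2) = (3/4) sqrt(pi)``), ``gamma`` Euler's constant
and ``L_m`` the m-th harmonic number (``L_0 = 0``). The relative entropy
subtracts the log angular volume of rotation space, ``ln(8 pi^2)`` (C1) or
``ln(4 pi^2)`` (C2v). The geodesic metric D3 is calibrated so that small
balls of radius r have Haar volume ``V_3 r^3``, which is what makes the
Euclidean-ball constant correct on the curved rotation group.

Histogram estimator
-------------------
Equal-volume binning of the Euler chart ``(alpha, cos beta, gamma)`` with
8 x 4 x 8 bins of 45 degrees (C1; 256 bins) or 8 x 4 x 4 (C2v, gamma modulo
pi; 128 bins)::

    H_rel = - sum_b f_b ln(f_b N_bins)        (0 ln 0 := 0)

which is <= 0 with equality iff all bins are equally occupied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .metrics import Metric, MetricSpec, nearest_neighbor_distances
from .rotations import SymmetryMode, wrap_euler

__all__ = [
    "EULER_GAMMA",
    "KnnConstants",
    "DuplicateSampleError",
    "angular_volume",
    "harmonic_number",
    "knn_entropy_absolute",
    "knn_entropy_relative",
    "HistogramSpec",
    "histogram_entropy",
    "EntropyEstimate",
]

EULER_GAMMA = float(np.euler_gamma)


def harmonic_number(m: int) -> float:
    """L_m = sum_{j=1..m} 1/j, with L_0 = 0."""
    if m < 0:
        raise ValueError("harmonic number defined for m >= 0")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def _unit_ball_log(p: int) -> float:
    return float(p / 2.0 * np.log(np.pi) - gammaln(p / 2.0 + 1.0))


@dataclass(frozen=True)
class KnnConstants:
    """Constants of the KNN entropy formula for p rotational degrees of freedom."""

    p: int = 3
    gamma_euler: float = EULER_GAMMA
    unit_ball_log: float = field(default_factory=lambda: _unit_ball_log(3))


DEFAULT_KNN_CONSTANTS = KnnConstants()


class DuplicateSampleError(ValueError):
    """Raised when a zero nearest-neighbor distance makes ln R undefined.

    Zero distances signal duplicated (perfectly correlated) orientations,
    for which the KNN density estimate diverges; callers working with
    time-series data should deduplicate or subsample instead of flooring.
    """

    def __init__(self, indices):
        self.indices = np.asarray(indices)
        super().__init__(
            f"zero nearest-neighbor distance at sample indices {self.indices[:10].tolist()}"
            + ("..." if self.indices.size > 10 else "")
        )


def angular_volume(symmetry: SymmetryMode) -> float:
    """Total angular volume of rotation space: 8 pi^2 (C1) or 4 pi^2 (C2v)."""
    if SymmetryMode(symmetry) is SymmetryMode.C2V:
        return 4.0 * np.pi**2
    return 8.0 * np.pi**2


@dataclass(frozen=True)
class EntropyEstimate:
    """A relative-entropy estimate (nats) with estimator metadata."""

    h_rel: float
    estimator: str  # "knn" or "histogram"
    n: int
    k: int | None = None
    spec: MetricSpec | None = None
    symmetry: SymmetryMode = SymmetryMode.C1


def knn_entropy_absolute(
    distances,
    n: int | None = None,
    k: int = 1,
    constants: KnnConstants = DEFAULT_KNN_CONSTANTS,
) -> float:
    """Absolute entropy (nats) from k-th nearest-neighbor distances.

    ``distances`` holds R_{i,k} for every sample point i; ``n`` defaults to
    ``len(distances)``. Raises :class:`DuplicateSampleError` if any distance
    is zero.
    """
    r = np.asarray(distances, dtype=float)
    if n is None:
        n = r.size
    if n < 2:
        raise ValueError("need at least two samples")
    zero = np.flatnonzero(r == 0.0)
    if zero.size:
        raise DuplicateSampleError(zero)
    return float(
        constants.p * np.mean(np.log(r))
        + constants.unit_ball_log
        + np.log(n)
        + constants.gamma_euler
        - harmonic_number(k - 1)
    )


def knn_entropy_relative(
    sample,
    k: int = 1,
    spec: MetricSpec = MetricSpec(Metric.D3),
    *,
    euler=None,
    distances=None,
) -> EntropyEstimate:
    """Relative entropy of an orientation sample by the KNN method.

    ``H_rel = H_abs - ln(Omega)`` with Omega fixed by the symmetry mode of
    ``spec``. Precomputed ``distances`` (e.g. shared across metrics or k
    values) can be passed to skip the search.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.shape[0]
    if distances is None:
        distances = nearest_neighbor_distances(sample, k, spec, euler=euler)
    h_abs = knn_entropy_absolute(distances, n=n, k=k)
    h_rel = h_abs - np.log(angular_volume(spec.symmetry))
    return EntropyEstimate(
        h_rel=float(h_rel), estimator="knn", n=n, k=k, spec=spec, symmetry=spec.symmetry
    )


@dataclass(frozen=True)
class HistogramSpec:
    """Equal-volume Euler-chart binning (45-degree bins by default)."""

    bins_alpha: int = 8
    bins_cosbeta: int = 4
    bins_gamma: int | None = None  # default: 8 (C1) or 4 (C2v)

    def gamma_bins(self, symmetry: SymmetryMode) -> int:
        if self.bins_gamma is not None:
            return self.bins_gamma
        return 4 if SymmetryMode(symmetry) is SymmetryMode.C2V else 8

    def n_bins(self, symmetry: SymmetryMode) -> int:
        return self.bins_alpha * self.bins_cosbeta * self.gamma_bins(symmetry)


def histogram_entropy(
    euler,
    symmetry: SymmetryMode = SymmetryMode.C1,
    spec: HistogramSpec = HistogramSpec(),
) -> EntropyEstimate:
    """Relative entropy of an orientation sample by equal-volume histogramming.

    ``euler`` is an (n, 3) array of ZYZ triples; gamma is reduced modulo pi
    before binning in C2v mode. Bins are half-open ``[low, high)`` with the
    topmost bin closed (numpy's histogramdd convention), so boundary samples
    bin deterministically.
    """
    symmetry = SymmetryMode(symmetry)
    e = wrap_euler(np.asarray(euler, dtype=float), symmetry)
    n = e.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    gmax = np.pi if symmetry is SymmetryMode.C2V else 2.0 * np.pi
    nb = (spec.bins_alpha, spec.bins_cosbeta, spec.gamma_bins(symmetry))
    coords = np.column_stack([e[:, 0], np.cos(e[:, 1]), e[:, 2]])
    counts, _ = np.histogramdd(
        coords,
        bins=nb,
        range=((0.0, 2.0 * np.pi), (-1.0, 1.0), (0.0, gmax)),
    )
    f = counts.ravel() / n
    occ = f > 0
    n_bins = int(np.prod(nb))
    h_rel = -float(np.sum(f[occ] * np.log(f[occ] * n_bins)))
    return EntropyEstimate(
        h_rel=h_rel, estimator="histogram", n=n, k=None, spec=None, symmetry=symmetry
    )
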