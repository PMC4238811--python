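"""Synthetic rotation samplers with known true entropies.

These generators define the benchmark conditions for the estimators:

* :func:`sample_uniform` — Haar-uniform rotations, true relative entropy 0.
  Drawn through the Euler chart: ``alpha = 2 pi r1``, ``cos beta = 2 r2 - 1``,
  ``gamma = 2 pi r3`` (``pi r3`` in C2v mode), whose pushforward is the
  invariant measure.
* :func:`sample_biased_A` — the divisor bias: ``r2`` is divided by ``A >= 1``
  before the map, compressing ``cos beta`` into ``[-1, -1 + 2/A]``. The
  density is A-fold inside 1/A of the space and zero elsewhere, so the true
  relative entropy is exactly ``-ln A`` in either symmetry mode.
* :func:`sample_cap_B` — rejection sampling onto a geodesic cap: uniform
  rotations farther than ``Delta_max = pi / B`` (geodesic metric D3) from a
  reference orientation are discarded. The true relative entropy is the log
  of the contained probability fraction, from the S^3 hypersphere cap area:
  with ``phi = pi / (2B)``, ``fraction = (2/pi) (phi - sin phi cos phi)``,
  equivalently the regularized incomplete beta ``I(sin^2 phi; 3/2, 1/2)``.
* :func:`sample_correlated_series` — a rotational random walk standing in for
  molecular-dynamics snapshots: each step composes a rotation about a uniform
  random axis by a half-normal angle. Consecutive orientations are strongly
  correlated, which is the failure mode of KNN entropy estimation on time
  series; only qualitative properties are asserted against this generator.

All samplers take a seed or ``numpy.random.Generator``; identical seeds
reproduce identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .rotations import (
    SymmetryMode,
    euler_to_quaternion,
    axis_angle_to_quaternion,
    quaternion_multiply,
)

__all__ = [
    "BiasSpecA",
    "BiasSpecB",
    "CorrelationSpec",
    "as_rng",
    "sample_uniform",
    "sample_biased_A",
    "true_entropy_A",
    "cap_fraction",
    "sample_cap_B",
    "true_entropy_B",
    "sample_correlated_series",
    "subsample",
]

TWO_PI = 2.0 * np.pi
IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def as_rng(stream) -> np.random.Generator:
    """Coerce a seed, SeedSequence or Generator into a Generator."""
    if isinstance(stream, np.random.Generator):
        return stream
    return np.random.default_rng(stream)


@dataclass(frozen=True)
class BiasSpecA:
    """Divisor bias of the uniform generator; true entropy is ``-ln A``."""

    divisor_a: float

    def __post_init__(self):
        if self.divisor_a < 1.0:
            raise ValueError("divisor A must be >= 1")

    @property
    def true_h(self) -> float:
        return -float(np.log(self.divisor_a))


@dataclass(frozen=True)
class BiasSpecB:
    """Geodesic-cap restriction to distance ``pi / B`` of a reference."""

    divisor_b: float

    def __post_init__(self):
        if self.divisor_b < 1.0:
            raise ValueError("divisor B must be >= 1")

    @property
    def delta_max(self) -> float:
        return float(np.pi / self.divisor_b)


@dataclass(frozen=True)
class CorrelationSpec:
    """Rotational random walk: per-step geodesic scale and series length."""

    step_sigma: float = 0.05
    n_steps: int = 25600
    subsample_interval: int = 1

    def __post_init__(self):
        if self.step_sigma < 0:
            raise ValueError("step_sigma must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.subsample_interval < 1:
            raise ValueError("subsample_interval must be >= 1")


def _euler_from_uniform(r1, r2, r3, symmetry: SymmetryMode) -> np.ndarray:
    gmax = np.pi if SymmetryMode(symmetry) is SymmetryMode.C2V else TWO_PI
    return np.column_stack(
        [TWO_PI * r1, np.arccos(np.clip(2.0 * r2 - 1.0, -1.0, 1.0)), gmax * r3]
    )


def sample_uniform(n, stream=None, symmetry=SymmetryMode.C1, return_euler=False):
    """``n`` Haar-uniform rotations as (n, 4) quaternions.

    With ``return_euler=True`` also returns the (n, 3) Euler triples the
    quaternions were drawn through (used by the chart-based estimators).
    """
    return sample_biased_A(n, BiasSpecA(1.0), stream, symmetry, return_euler)


def sample_biased_A(
    n, spec, stream=None, symmetry=SymmetryMode.C1, return_euler=False
):
    """``n`` rotations with the divisor-A bias (A=1 reduces to uniform)."""
    if not isinstance(spec, BiasSpecA):
        spec = BiasSpecA(float(spec))
    rng = as_rng(stream)
    r = rng.random((3, int(n)))
    e = _euler_from_uniform(r[0], r[1] / spec.divisor_a, r[2], symmetry)
    q = euler_to_quaternion(e)
    return (q, e) if return_euler else q


def true_entropy_A(spec) -> float:
    """Analytic relative entropy ``-ln A`` of the divisor bias (nats)."""
    if not isinstance(spec, BiasSpecA):
        spec = BiasSpecA(float(spec))
    return spec.true_h


def cap_fraction(spec) -> float:
    """Probability mass of the uniform rotation distribution within geodesic
    distance ``pi / B`` of a reference: ``(2/pi) (phi - sin phi cos phi)``
    with ``phi = pi / (2B)`` (the S^3 two-cap area over the half-sphere area
    pi^2)."""
    if not isinstance(spec, BiasSpecB):
        spec = BiasSpecB(float(spec))
    phi = 0.5 * spec.delta_max
    return float((2.0 / np.pi) * (phi - np.sin(phi) * np.cos(phi)))


def cap_fraction_betainc(spec) -> float:
    """Same cap fraction via the regularized incomplete beta function
    ``I(sin^2 phi; 3/2, 1/2)`` (equivalent closed form)."""
    if not isinstance(spec, BiasSpecB):
        spec = BiasSpecB(float(spec))
    phi = 0.5 * spec.delta_max
    return float(betainc(1.5, 0.5, np.sin(phi) ** 2))


def true_entropy_B(spec) -> float:
    """Analytic relative entropy ``ln(cap fraction)`` of the cap bias (nats)."""
    return float(np.log(cap_fraction(spec)))


def sample_cap_B(
    n,
    spec,
    stream=None,
    symmetry=SymmetryMode.C1,
    reference=None,
    return_euler=False,
):
    """``n`` uniform rotations restricted to the geodesic cap of radius
    ``pi / B`` about ``reference`` (identity by default).

    Rejection sampling with the plain (non-symmetrized) geodesic metric:
    a proposal ``q`` is kept when ``|<q, reference>| >= cos(pi / (2B))``.
    """
    if not isinstance(spec, BiasSpecB):
        spec = BiasSpecB(float(spec))
    rng = as_rng(stream)
    ref = IDENTITY_Q if reference is None else np.asarray(reference, float)
    cos_thresh = np.cos(0.5 * spec.delta_max)
    accept_p = cap_fraction(spec)
    n = int(n)
    got_q, got_e = [], []
    remaining = n
    while remaining > 0:
        batch = int(remaining / accept_p * 1.2) + 16
        q, e = sample_uniform(batch, rng, symmetry, return_euler=True)
        keep = np.abs(q @ ref) >= cos_thresh
        got_q.append(q[keep])
        got_e.append(e[keep])
        remaining -= int(keep.sum())
    q = np.concatenate(got_q)[:n]
    e = np.concatenate(got_e)[:n]
    return (q, e) if return_euler else q


def sample_correlated_series(spec: CorrelationSpec, stream=None) -> np.ndarray:
    """Time-ordered rotational random walk of ``spec.n_steps`` orientations.

    The initial orientation is Haar-uniform (so every marginal is exactly
    uniform); each subsequent orientation composes the previous one with a
    rotation about a fresh uniform random axis by a half-normal angle of
    scale ``step_sigma``. Applies ``subsample_interval`` before returning.
    """
    rng = as_rng(stream)
    n = spec.n_steps
    series = np.empty((n, 4))
    series[0] = sample_uniform(1, rng)[0]
    if n > 1:
        if spec.step_sigma == 0.0:
            series[1:] = series[0]
        else:
            axes = rng.normal(size=(n - 1, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            angles = np.abs(rng.normal(0.0, spec.step_sigma, size=n - 1))
            steps = axis_angle_to_quaternion(axes, angles)
            for t in range(1, n):
                series[t] = quaternion_multiply(steps[t - 1], series[t - 1])
            # renormalize against drift from repeated products
            series /= np.linalg.norm(series, axis=1, keepdims=True)
    return subsample(series, spec.subsample_interval)


def subsample(series, interval: int):
    """Every ``interval``-th element of a time-ordered series (order kept)."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    return np.asarray(series)[::interval]
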