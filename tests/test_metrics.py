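"""The four rotation metrics: closed-form values, metric axioms, the
matrix-based oracles, symmetry handling, and equivalence of the
monotone-surrogate nearest-neighbor search with a naive exhaustive search."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from rotent.metrics import (
    METRIC_MAX,
    Metric,
    MetricSpec,
    _chunked_kth_absdot,
    _chunked_kth_chart,
    delta1,
    delta2,
    delta3,
    delta4,
    distance_from_absdot,
    nearest_neighbor_distances,
    symmetrize,
)
from rotent.rotations import (
    SymmetryMode,
    axis_angle_to_quaternion,
    c2v_image,
    quaternion_to_euler,
    quaternion_to_matrix,
    wrap_euler,
)

from conftest import random_quaternions

C1, C2V = SymmetryMode.C1, SymmetryMode.C2V
Q_ID = np.array([1.0, 0.0, 0.0, 0.0])
Q_ZPI = np.array([0.0, 0.0, 0.0, 1.0])
Q_Z90 = axis_angle_to_quaternion((0, 0, 1), np.pi / 2)


def naive_knn_distances(q, euler, k, spec):
    """Independent oracle: full pairwise evaluation + sort, per point."""
    n = len(q)
    out = np.empty(n)
    for i in range(n):
        if spec.metric is Metric.D1:
            d = delta1(euler[i], euler, spec.symmetry)
        elif spec.metric is Metric.D2:
            d = delta2(q[i], q, spec.symmetry)
        elif spec.metric is Metric.D3:
            d = delta3(q[i], q, spec.symmetry)
        else:
            d = delta4(q[i], q, spec.symmetry)
        d[i] = np.inf
        out[i] = np.sort(d)[k - 1]
    return out


class TestClosedForms:
    def test_identical_rotations_are_at_zero(self, rng):
        q = random_quaternions(rng, 20)
        e = quaternion_to_euler(q)
        assert np.all(delta1(e, e) == 0)
        assert np.all(delta2(q, q) == 0)
        assert np.all(delta3(q, q) == 0)
        assert np.all(delta4(q, q) == 0)
        # double cover: q and -q are the same rotation
        assert np.all(delta2(q, -q) == 0)
        assert np.all(delta3(q, -q) == 0)

    def test_printed_maxima_attained(self):
        assert delta1((0, 0, 0), (np.pi, np.pi, np.pi)) == pytest.approx(
            np.sqrt(4 + 2 * np.pi**2), abs=1e-12
        )
        assert delta2(Q_ID, Q_ZPI) == pytest.approx(2 * np.sqrt(2), abs=1e-12)
        assert delta3(Q_ID, Q_ZPI) == pytest.approx(np.pi, abs=1e-12)
        assert delta4(Q_ID, Q_ZPI) == pytest.approx(2.0, abs=1e-12)

    def test_quarter_turn_values(self):
        assert delta2(Q_ID, Q_Z90) == pytest.approx(2 * np.sqrt(2 - np.sqrt(2)), abs=1e-12)
        assert delta3(Q_ID, Q_Z90) == pytest.approx(np.pi / 2, abs=1e-12)
        assert delta4(Q_ID, Q_Z90) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_delta1_alpha_wraparound(self):
        assert delta1((0.1, 1.0, 2.0), (2 * np.pi - 0.1, 1.0, 2.0)) == pytest.approx(
            0.2, abs=1e-12
        )

    def test_delta1_c2v_wraps_gamma_mod_pi(self):
        assert delta1((1.0, 1.0, 0.05), (1.0, 1.0, np.pi - 0.05), C2V) == pytest.approx(
            0.1, abs=1e-12
        )


class TestMetricAxioms:
    @pytest.mark.parametrize("sym", [C1, C2V])
    def test_symmetry_range_and_identity(self, rng, sym):
        q1 = random_quaternions(rng, 500)
        q2 = random_quaternions(rng, 500)
        e1, e2 = quaternion_to_euler(q1), quaternion_to_euler(q2)
        for metric, d12, d21 in [
            (Metric.D1, delta1(e1, e2, sym), delta1(e2, e1, sym)),
            (Metric.D2, delta2(q1, q2, sym), delta2(q2, q1, sym)),
            (Metric.D3, delta3(q1, q2, sym), delta3(q2, q1, sym)),
            (Metric.D4, delta4(q1, q2, sym), delta4(q2, q1, sym)),
        ]:
            np.testing.assert_allclose(d12, d21, atol=1e-12)
            assert np.all(d12 >= 0)
            assert np.all(d12 <= METRIC_MAX[metric] + 1e-12)

    def test_geodesic_matches_matrix_logarithm_oracle(self, rng):
        q1 = random_quaternions(rng, 1000)
        q2 = random_quaternions(rng, 1000)
        r1 = ScipyRotation.from_matrix(quaternion_to_matrix(q1))
        r2 = ScipyRotation.from_matrix(quaternion_to_matrix(q2))
        theta = (r1 * r2.inv()).magnitude()  # |log(R1 R2^T)|_F / sqrt(2)
        np.testing.assert_allclose(delta3(q1, q2), theta, atol=1e-8)

    def test_delta4_matches_frobenius_deviation(self, rng):
        q1 = random_quaternions(rng, 1000)
        q2 = random_quaternions(rng, 1000)
        m1, m2 = quaternion_to_matrix(q1), quaternion_to_matrix(q2)
        frob = np.linalg.norm(
            np.eye(3) - m1 @ np.swapaxes(m2, -1, -2), axis=(-2, -1)
        )
        np.testing.assert_allclose(delta4(q1, q2) * np.sqrt(2), frob, atol=1e-10)

    def test_small_angle_equivalence(self):
        thetas = np.array([1e-5, 1e-4, 1e-3])
        q2 = axis_angle_to_quaternion(
            np.tile([0, 0, 1.0], (3, 1)) / 1.0, thetas
        )
        d3 = delta3(Q_ID, q2)
        for d in (delta2(Q_ID, q2), delta4(Q_ID, q2)):
            ratio = d / d3
            assert np.all(ratio <= 1.0 + 1e-12)
            assert np.all(ratio >= 1 - 1e-6)


class TestSymmetrize:
    def test_image_pair_is_a_pi_body_spin(self, rng):
        q = random_quaternions(rng, 50)
        base, image = symmetrize(q)
        np.testing.assert_array_equal(base, q)
        # under C2v every metric sees the image at distance zero
        assert np.all(delta2(q, image, C2V) == 0)
        assert np.all(delta3(q, image, C2V) == 0)
        assert np.all(delta4(q, image, C2V) == 0)
        e, ei = quaternion_to_euler(q), quaternion_to_euler(image)
        np.testing.assert_allclose(delta1(e, ei, C2V), 0, atol=1e-7)

    def test_image_of_identity_is_a_pi_rotation_under_c1(self):
        assert delta3(Q_ID, c2v_image(Q_ID), C1) == pytest.approx(np.pi)

    def test_symmetrized_distance_never_exceeds_plain(self, rng):
        q1 = random_quaternions(rng, 2000)
        q2 = random_quaternions(rng, 2000)
        sym = delta3(q1, q2, C2V)
        assert np.all(sym <= delta3(q1, q2, C1) + 1e-12)
        # the quotient diameter stays pi: a pi flip about a lab axis in the
        # molecular plane is equidistant from both identity images
        q_flip = np.array([0.0, 1.0, 0.0, 0.0])
        assert delta3(Q_ID, q_flip, C2V) == pytest.approx(np.pi)


class TestNearestNeighborSearch:
    def test_three_point_z_spin_example(self):
        q = axis_angle_to_quaternion(np.tile([0, 0, 1.0], (3, 1)), np.array([0.0, 0.1, 0.3]))
        d = nearest_neighbor_distances(q, 1, MetricSpec(Metric.D3))
        np.testing.assert_allclose(d, [0.1, 0.1, 0.2], atol=1e-12)

    def test_duplicate_point_has_zero_nn_distance(self, rng):
        q = random_quaternions(rng, 10)
        q[7] = q[2]
        d = nearest_neighbor_distances(q, 1, MetricSpec(Metric.D2))
        assert d[2] == 0.0 and d[7] == 0.0

    def test_requires_more_than_k_samples(self, rng):
        q = random_quaternions(rng, 5)
        with pytest.raises(ValueError):
            nearest_neighbor_distances(q, 5, MetricSpec(Metric.D3))

    def test_quaternion_metrics_share_the_nn_graph(self, rng):
        q = random_quaternions(rng, 300)
        idx = {}
        for metric, fn in [(Metric.D2, delta2), (Metric.D3, delta3), (Metric.D4, delta4)]:
            d = np.array([fn(qi, q) for qi in q])
            np.fill_diagonal(d, np.inf)
            idx[metric] = d.argmin(axis=1)
        np.testing.assert_array_equal(idx[Metric.D2], idx[Metric.D3])
        np.testing.assert_array_equal(idx[Metric.D2], idx[Metric.D4])

    @pytest.mark.parametrize("metric", list(Metric))
    @pytest.mark.parametrize("sym", [C1, C2V])
    @pytest.mark.parametrize("k", [1, 3])
    def test_surrogate_search_equals_naive_search(self, rng, metric, sym, k):
        q = random_quaternions(rng, 500)
        e = wrap_euler(quaternion_to_euler(q), sym)
        spec = MetricSpec(metric, sym)
        got = nearest_neighbor_distances(q, k, spec, euler=e)
        want = naive_knn_distances(q, e, k, spec)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_k_list_matches_individual_k(self, rng):
        q = random_quaternions(rng, 200)
        spec = MetricSpec(Metric.D3, C2V)
        many = nearest_neighbor_distances(q, [1, 4], spec)
        np.testing.assert_array_equal(many[0], nearest_neighbor_distances(q, 1, spec))
        np.testing.assert_allclose(many[1], nearest_neighbor_distances(q, 4, spec), atol=1e-12)

    def test_chunked_fallback_agrees_with_fast_path(self, rng):
        """The numpy chunked scan (used for k>1 and when numba is absent)
        agrees with the k=1 fast path and survives small block sizes."""
        q = random_quaternions(rng, 150)
        qs = c2v_image(q)
        fast = nearest_neighbor_distances(q, 1, MetricSpec(Metric.D3, C2V))
        absdot = _chunked_kth_absdot(q, qs, 1, block=7)[0]
        np.testing.assert_allclose(distance_from_absdot(absdot, Metric.D3), fast, atol=1e-12)
        e = wrap_euler(quaternion_to_euler(q), C1)
        coords = (e[:, 0].copy(), np.cos(e[:, 1]), e[:, 2].copy())
        sq = _chunked_kth_chart(coords, 2 * np.pi, 1, block=7)[0]
        np.testing.assert_allclose(
            np.sqrt(sq),
            nearest_neighbor_distances(q, 1, MetricSpec(Metric.D1), euler=e),
            rtol=1e-10,
            atol=1e-12,
        )
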