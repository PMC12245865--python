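"""Scene-model unit tests: quaternions, covariance construction,
activations and spherical-harmonic color."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from endosplat import sh
from endosplat.scene import (GaussianCloud, InvalidParameterError,
                             activate_parameters, build_covariance,
                             eval_sh_color, quaternion_to_rotation,
                             rotation_to_quaternion, sigmoid)


class TestQuaternionToRotation:
    def test_identity(self):
        np.testing.assert_allclose(quaternion_to_rotation([1, 0, 0, 0]),
                                   np.eye(3), atol=1e-15)

    def test_180_about_z(self):
        # cross-checked against the axis-angle (Rodrigues) construction
        np.testing.assert_allclose(quaternion_to_rotation([0, 0, 0, 1]),
                                   np.diag([-1.0, -1.0, 1.0]), atol=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(0, 1, 4)
        R = quaternion_to_rotation(q)
        # scipy uses (x, y, z, w) ordering
        R_ref = ScipyRotation.from_quat(np.r_[q[1:], q[0]]).as_matrix()
        np.testing.assert_allclose(R, R_ref, atol=1e-12)

    def test_double_cover(self, rng):
        q = rng.normal(0, 1, 4)
        np.testing.assert_allclose(quaternion_to_rotation(q),
                                   quaternion_to_rotation(-q), atol=1e-14)

    def test_orthonormal_det_one(self, rng):
        q = rng.normal(0, 1, (20, 4))
        R = quaternion_to_rotation(q)
        np.testing.assert_allclose(R @ R.transpose(0, 2, 1),
                                   np.broadcast_to(np.eye(3), (20, 3, 3)),
                                   atol=1e-12)
        np.testing.assert_allclose(np.linalg.det(R), 1.0, atol=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(InvalidParameterError):
            quaternion_to_rotation([0.0, 0.0, 0.0, 0.0])

    def test_round_trip_through_matrix(self, rng):
        for _ in range(10):
            q = rng.normal(0, 1, 4)
            q /= np.linalg.norm(q)
            q2 = rotation_to_quaternion(quaternion_to_rotation(q))
            assert (np.allclose(q, q2, atol=1e-9)
                    or np.allclose(q, -q2, atol=1e-9))


class TestBuildCovariance:
    def test_identity_rotation_direct_multiply(self):
        A = build_covariance([1, 0, 0, 0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(A, np.diag([1.0, 4.0, 9.0]), atol=1e-12)

    def test_isotropic_rotation_invariant(self, rng):
        q = rng.normal(0, 1, 4)
        A = build_covariance(q, [0.7, 0.7, 0.7])
        np.testing.assert_allclose(A, 0.49 * np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalues_are_squared_scales(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(0, 1, 4)
        s = rng.uniform(0.1, 2.0, 3)
        A = build_covariance(q, s)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(A)),
                                   np.sort(s ** 2), atol=1e-9)

    def test_round_trip_via_eigendecomposition(self, rng):
        q = rng.normal(0, 1, 4)
        s = rng.uniform(0.2, 1.5, 3)
        A = build_covariance(q, s)
        w, V = np.linalg.eigh(A)
        np.testing.assert_allclose(V @ np.diag(w) @ V.T, A, atol=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_covariance([1, 0, 0, 0], [1.0, -0.1, 1.0])

    def test_density_maximal_at_mean_and_log_concave(self, rng):
        # N(x) = exp(-0.5 (x-mu)^T A^-1 (x-mu)) along random rays
        q = rng.normal(0, 1, 4)
        s = rng.uniform(0.3, 1.0, 3)
        A = build_covariance(q, s)
        Ainv = np.linalg.inv(A)
        mu = np.array([0.3, -0.2, 1.0])

        def logdens(x):
            d = x - mu
            return -0.5 * d @ Ainv @ d

        for _ in range(5):
            direction = rng.normal(0, 1, 3)
            ts = np.linspace(-2, 2, 41)
            vals = np.array([logdens(mu + t * direction) for t in ts])
            assert vals.argmax() == 20  # maximal at the mean
            second = np.diff(vals, 2)
            assert np.all(second <= 1e-12)  # concave along the ray


class TestActivation:
    def test_sigmoid_midpoint_and_exp_zero(self):
        cloud = GaussianCloud(np.zeros((1, 3)), [[1, 0, 0, 0]],
                              np.zeros((1, 3)), np.zeros(1),
                              np.zeros((1, 1, 3)), sh_degree=0)
        act = activate_parameters(cloud)
        assert act.opacities[0] == 0.5
        np.testing.assert_allclose(act.scales[0], 1.0)

    def test_extreme_logit_stays_open_interval(self):
        assert 0.0 < sigmoid(np.array([-20.0]))[0] < 1e-8
        assert 1.0 - 1e-8 < sigmoid(np.array([20.0]))[0] < 1.0

    def test_activated_invariants(self, rng):
        n = 30
        cloud = GaussianCloud(rng.normal(0, 1, (n, 3)),
                              rng.normal(0, 1, (n, 4)),
                              rng.normal(0, 1, (n, 3)),
                              rng.normal(0, 3, n),
                              rng.normal(0, 1, (n, 4, 3)), sh_degree=1)
        act = activate_parameters(cloud)
        assert np.all(act.scales > 0)
        assert np.all((act.opacities > 0) & (act.opacities < 1))
        np.testing.assert_allclose(np.linalg.norm(act.quats, axis=1), 1.0,
                                   atol=1e-6)
        A = act.covariances()
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(A), axis=1),
            np.sort(act.scales ** 2, axis=1), atol=1e-9)


class TestSphericalHarmonics:
    def test_degree0_is_view_independent(self, rng):
        coeffs = rng.normal(0, 1, (1, 3))
        d1 = rng.normal(0, 1, 3)
        d2 = rng.normal(0, 1, 3)
        c1 = eval_sh_color(coeffs, d1 / np.linalg.norm(d1), 0)
        c2 = eval_sh_color(coeffs, d2 / np.linalg.norm(d2), 0)
        np.testing.assert_allclose(c1, c2)

    def test_even_degree_parity(self, rng):
        # only even-degree bands nonzero -> color identical for d and -d
        coeffs = np.zeros((9, 3))
        coeffs[0] = rng.normal(0, 0.3, 3)
        coeffs[4:9] = rng.normal(0, 0.3, (5, 3))
        d = rng.normal(0, 1, 3)
        d /= np.linalg.norm(d)
        np.testing.assert_allclose(eval_sh_color(coeffs, d, 2),
                                   eval_sh_color(coeffs, -d, 2), atol=1e-12)

    def test_basis_orthonormality_monte_carlo(self):
        # int Y_i Y_j over the sphere = delta_ij, up to degree 3
        rng = np.random.default_rng(7)
        n = 400_000
        v = rng.normal(0, 1, (n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        Y = sh.eval_basis(v, 3)  # (n, 16)
        gram = 4 * np.pi * (Y.T @ Y) / n
        np.testing.assert_allclose(gram, np.eye(16), atol=0.05)

    def test_basis_gradient_matches_finite_differences(self, rng):
        d = rng.normal(0, 1, 3)
        g = sh.eval_basis_grad(d, 3)
        h = 1e-6
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = h
            fd = (sh.eval_basis(d + e, 3) - sh.eval_basis(d - e, 3)) / (2 * h)
            np.testing.assert_allclose(g[:, axis], fd, atol=1e-6)

    def test_coefficient_count_mismatch_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            eval_sh_color(rng.normal(0, 1, (4, 3)), np.array([0, 0, 1.0]), 2)

    def test_color_clamped_nonnegative(self):
        coeffs = np.full((1, 3), -10.0)
        c = eval_sh_color(coeffs, np.array([0, 0, 1.0]), 0)
        np.testing.assert_array_equal(c, 0.0)
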