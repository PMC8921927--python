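"""Extended Kalman filter: Jacobians, Taylor linearization, recursion,
and angle-trajectory smoothing."""

import numpy as np
import pytest

import emgangle as eg


def textbook_linear_kf(F, H, Q, R, x0, P0, zs):
    """Independent reference: standard linear Kalman predict/update."""
    x, P = np.asarray(x0, float).copy(), np.asarray(P0, float).copy()
    means = []
    for z in zs:
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.atleast_1d(z) - H @ x)
        P = (np.eye(P.shape[0]) - K @ H) @ P
        means.append(x.copy())
    return np.array(means)


def linear_model(F, H, analytic=True):
    kwargs = {}
    if analytic:
        kwargs = dict(
            f_jac_x=lambda x, u, w: F,
            f_jac_w=lambda x, u, w: np.eye(F.shape[0]),
            h_jac_x=lambda x, r: H,
            h_jac_v=lambda x, v: np.eye(H.shape[0]),
        )
    return eg.NonlinearModel(
        f=lambda x, u, w: F @ x + w,
        h=lambda x, v: H @ x + v,
        state_dim=F.shape[0],
        meas_dim=H.shape[0],
        **kwargs,
    )


def random_linear_system(rng, dim):
    F = rng.uniform(-1, 1, (dim, dim)) * 0.9 / dim + np.eye(dim) * 0.5
    H = rng.uniform(-1, 1, (1, dim))
    A = rng.uniform(-0.5, 0.5, (dim, dim))
    Q = A @ A.T + 0.01 * np.eye(dim)
    R = np.array([[rng.uniform(0.5, 2.0)]])
    return F, H, Q, R


class TestJacobian:
    def test_square_function_at_two(self):
        J = eg.jacobian(lambda x: x**2, np.array([2.0]))
        assert J[0, 0] == pytest.approx(4.0, rel=1e-8)

    def test_linear_map_recovered_exactly(self):
        A = np.array([[1.0, 2.0], [3.0, -4.0]])
        J = eg.jacobian(lambda x: A @ x, np.array([0.3, -0.7]))
        assert np.allclose(J, A, atol=1e-8)

    def test_constant_function_gives_zero_matrix(self):
        J = eg.jacobian(lambda x: np.array([5.0]), np.array([1.0, 2.0]))
        assert np.allclose(J, 0.0)

    def test_nan_near_point_raises(self):
        with pytest.raises(ValueError):
            eg.jacobian(lambda x: np.sqrt(x), np.array([0.0]))


class TestLinearization:
    def test_linear_state_model_is_exact(self):
        F = np.array([[1.0, 0.5], [0.0, 1.0]])
        B = np.array([[0.2], [0.1]])
        model = eg.NonlinearModel(
            f=lambda x, u, w: F @ x + B @ u + w,
            h=lambda x, v: x[:1] + v,
            state_dim=2,
            meas_dim=1,
            input_dim=1,
        )
        noise = eg.NoiseModel(Q=np.eye(2), R=np.eye(1))
        est = eg.StateEstimate(np.array([1.0, -1.0]), np.eye(2))
        Phi, Gamma, U = eg.linearize_state(model, est, np.array([2.0]), noise)
        assert np.allclose(Phi, F, atol=1e-8)
        assert np.allclose(Gamma, np.eye(2), atol=1e-8)
        assert np.allclose(U, (B @ np.array([2.0])), atol=1e-7)

    def test_quadratic_state_hand_expansion(self):
        model = eg.NonlinearModel(
            f=lambda x, u, w: x**2 + w,
            h=lambda x, v: x + v,
            state_dim=1,
            meas_dim=1,
        )
        noise = eg.NoiseModel(Q=np.eye(1), R=np.eye(1))
        est = eg.StateEstimate(np.array([2.0]), np.eye(1))
        Phi, _, U = eg.linearize_state(model, est, None, noise)
        assert Phi[0, 0] == pytest.approx(4.0, rel=1e-6)
        assert U[0] == pytest.approx(4.0 - 4.0 * 2.0, rel=1e-6)
        # expansion reproduces f at the expansion point
        assert Phi @ est.mean + U == pytest.approx(4.0, rel=1e-9)

    def test_cubic_measurement_hand_expansion(self):
        model = eg.NonlinearModel(
            f=lambda x, u, w: x + w,
            h=lambda x, v: x**3 + v,
            state_dim=1,
            meas_dim=1,
        )
        noise = eg.NoiseModel(Q=np.eye(1), R=np.eye(1))
        pred = eg.StateEstimate(np.array([1.0]), np.eye(1))
        H, y, Lam = eg.linearize_measurement(model, pred, noise)
        assert H[0, 0] == pytest.approx(3.0, rel=1e-6)
        assert y[0] == pytest.approx(1.0 - 3.0, rel=1e-6)
        assert np.allclose(Lam, np.eye(1), atol=1e-8)
        assert H @ pred.mean + y == pytest.approx(1.0, rel=1e-9)


class TestEkfStep:
    def test_hand_computed_scalar_update(self):
        model = linear_model(np.eye(1), np.eye(1))
        noise = eg.NoiseModel(Q=np.zeros((1, 1)), R=np.eye(1))
        est = eg.StateEstimate(np.zeros(1), np.eye(1))
        post = eg.ekf_step(model, noise, est, None, 2.0)
        assert post.mean[0] == pytest.approx(1.0)
        assert post.cov[0, 0] == pytest.approx(0.5)

    def test_huge_measurement_noise_leaves_prediction(self):
        model = linear_model(np.eye(1), np.eye(1))
        noise = eg.NoiseModel(Q=np.zeros((1, 1)), R=np.array([[1e12]]))
        est = eg.StateEstimate(np.array([3.0]), np.eye(1))
        post = eg.ekf_step(model, noise, est, None, 100.0)
        assert post.mean[0] == pytest.approx(3.0, abs=1e-6)

    def test_matches_textbook_linear_kf_to_1e12(self):
        rng = np.random.default_rng(0)
        for dim in (1, 2, 3):
            F, H, Q, R = random_linear_system(rng, dim)
            model = linear_model(F, H)
            noise = eg.NoiseModel(Q=Q, R=R)
            x0, P0 = np.zeros(dim), np.eye(dim)
            zs = rng.standard_normal(100)
            expected = textbook_linear_kf(F, H, Q, R, x0, P0, zs)
            est = eg.StateEstimate(x0, P0)
            for k, z in enumerate(zs):
                est = eg.ekf_step(model, noise, est, None, z)
                assert np.max(np.abs(est.mean - expected[k])) <= 1e-12

    def test_covariance_stays_psd_over_many_steps(self):
        model = linear_model(np.array([[1.0, 0.1], [0.0, 1.0]]), np.array([[1.0, 0.0]]))
        noise = eg.NoiseModel(Q=0.01 * np.eye(2), R=np.eye(1))
        est = eg.StateEstimate(np.zeros(2), 100 * np.eye(2))
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            est = eg.ekf_step(model, noise, est, None, rng.standard_normal())
            assert np.allclose(est.cov, est.cov.T)
        assert np.min(np.linalg.eigvalsh(est.cov)) >= -1e-9

    def test_taylor_identities_along_nonlinear_run(self):
        model = eg.NonlinearModel(
            f=lambda x, u, w: np.array([np.sin(x[0]) + 0.1 * x[1], 0.9 * x[1]]) + w,
            h=lambda x, v: np.array([x[0] ** 2]) + v,
            state_dim=2,
            meas_dim=1,
        )
        noise = eg.NoiseModel(Q=0.01 * np.eye(2), R=np.eye(1))
        est = eg.StateEstimate(np.array([0.5, 0.2]), np.eye(2))
        rng = np.random.default_rng(2)
        for _ in range(50):
            Phi, _, U = eg.linearize_state(model, est, None, noise)
            fx = model.f(est.mean, None, noise.q)
            assert np.max(np.abs(Phi @ est.mean + U - fx)) <= 1e-10
            pred_mean = Phi @ est.mean + U
            pred = eg.StateEstimate(pred_mean, est.cov)
            H, y, _ = eg.linearize_measurement(model, pred, noise)
            hx = model.h(pred.mean, noise.r)
            assert np.max(np.abs(H @ pred.mean + y - hx)) <= 1e-10
            est = eg.ekf_step(model, noise, est, None, rng.standard_normal())

    def test_joseph_form_agrees_with_standard_update(self):
        model = linear_model(np.eye(1), np.eye(1))
        noise = eg.NoiseModel(Q=np.eye(1) * 0.1, R=np.eye(1))
        est = eg.StateEstimate(np.zeros(1), np.eye(1))
        a = eg.ekf_step(model, noise, est, None, 1.0, joseph_form=False)
        b = eg.ekf_step(model, noise, est, None, 1.0, joseph_form=True)
        assert np.allclose(a.mean, b.mean) and np.allclose(a.cov, b.cov, atol=1e-12)


class TestNoiseModel:
    def test_indefinite_matrices_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            eg.NoiseModel(Q=np.eye(1), R=-np.eye(1))
        with pytest.raises(ValueError, match="non-negative"):
            eg.NoiseModel(Q=-np.eye(1), R=np.eye(1))
        with pytest.raises(ValueError, match="symmetric"):
            eg.NoiseModel(Q=np.array([[1.0, 0.5], [0.0, 1.0]]), R=np.eye(1))


class TestSmoothAngles:
    def test_static_model_recovers_closed_form_sample_mean(self):
        # static scalar state, Q=0, diffuse prior: the posterior after k
        # measurements is their sample mean with variance ~ R/k (closed form)
        rng = np.random.default_rng(3)
        z = 90.0 + rng.normal(0, 5.0, 200)
        model = linear_model(np.eye(1), np.eye(1))
        noise = eg.NoiseModel(Q=np.zeros((1, 1)), R=25.0 * np.eye(1))
        est = eg.StateEstimate(np.array([z[0]]), np.array([[1e12]]))
        for zk in z:
            est = eg.ekf_step(model, noise, est, None, zk)
        assert est.mean[0] == pytest.approx(np.mean(z), abs=1e-6)
        assert est.cov[0, 0] == pytest.approx(25.0 / 200, rel=1e-3)

    def test_constant_angle_error_shrinks_with_more_samples(self):
        rng = np.random.default_rng(3)
        ts = np.arange(200) * 0.125
        z = 90.0 + rng.normal(0, 5.0, 200)
        traj = eg.AngleTrajectory(ts, z)
        out = eg.smooth_angles(traj, eg.KalmanConfig(q_diag=(0.0, 0.0)))
        early = np.mean(np.abs(out.angles[5:20] - 90.0))
        late = np.mean(np.abs(out.angles[150:] - 90.0))
        assert late < early
        assert np.std(out.angles[50:]) < np.std(z[50:])

    def test_noise_free_ramp_tracked_after_ten_steps(self):
        ts = np.arange(40) * 0.125
        truth = 36.0 * ts
        out = eg.smooth_angles(eg.AngleTrajectory(ts, truth))
        assert np.max(np.abs(out.angles[10:] - truth[10:])) <= 0.1

    def test_single_sample_returned_unchanged(self):
        traj = eg.AngleTrajectory(np.array([0.0]), np.array([45.0]))
        assert eg.smooth_angles(traj) is traj

    def test_smoothing_reduces_mse_on_white_noise(self):
        ts = 0.125 * (1 + np.arange(39))
        truth = 36.0 * ts
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = truth + rng.normal(0, 4.0, ts.size)
            out = eg.smooth_angles(eg.AngleTrajectory(ts, z))
            wins += np.mean((out.angles - truth) ** 2) < np.mean((z - truth) ** 2)
        assert wins >= 18

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            eg.AngleTrajectory(np.array([0.0, 0.0, 1.0]), np.zeros(3))
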