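"""Extended Kalman filter: first-order Taylor linearization of nonlinear
state/measurement models and the discrete filter recursion, used to correct
the regressor's angle sequence.

Model form
----------
State transition and measurement are general nonlinear maps

    x_k = f_{k-1}(x_{k-1}, u_{k-1}, w_{k-1})
    z_k = h_k(x_k, v_k)

with mutually uncorrelated Gaussian noises w (mean q, covariance Q, PSD) and
v (mean r, covariance R, positive definite).  Expanding f around the last
filtered state (and h around the prediction) and dropping second and higher
orders gives the linearized forms

    x_k ~ Phi x_{k-1} + U + Gamma (w - q),      Phi = df/dx, Gamma = df/dw,
                                                U = f(x^, u, q) - Phi x^
    z_k ~ H x_k + y + Lambda (v - r),           H = dh/dx, Lambda = dh/dv,
                                                y = h(x^-, r) - H x^-

on which the standard discrete Kalman recursion runs.

For angle correction the default model is a constant-velocity random walk on
[theta, theta_dot] with the network output as a direct, noisy angle
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .signal_core import AngleTrajectory

__all__ = [
    "NonlinearModel",
    "NoiseModel",
    "StateEstimate",
    "LinearizedStep",
    "KalmanConfig",
    "jacobian",
    "linearize_state",
    "linearize_measurement",
    "ekf_step",
    "constant_velocity_model",
    "smooth_angles",
]

VecFun = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class NonlinearModel:
    """Nonlinear state-space model.

    ``f(x, u, w)`` and ``h(x, v)`` must accept and return 1-D arrays.
    Analytic Jacobians are optional; when absent, central finite differences
    are used.
    """

    f: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    h: Callable[[np.ndarray, np.ndarray], np.ndarray]
    state_dim: int
    meas_dim: int
    input_dim: int = 0
    process_noise_dim: int | None = None
    meas_noise_dim: int | None = None
    f_jac_x: Callable[..., np.ndarray] | None = None
    f_jac_w: Callable[..., np.ndarray] | None = None
    h_jac_x: Callable[..., np.ndarray] | None = None
    h_jac_v: Callable[..., np.ndarray] | None = None

    @property
    def w_dim(self) -> int:
        return self.process_noise_dim if self.process_noise_dim is not None else self.state_dim

    @property
    def v_dim(self) -> int:
        return self.meas_noise_dim if self.meas_noise_dim is not None else self.meas_dim


@dataclass(frozen=True)
class NoiseModel:
    """Process/measurement noise statistics (means q, r; covariances Q, R)."""

    Q: np.ndarray
    R: np.ndarray
    q: np.ndarray | None = None
    r: np.ndarray | None = None

    def __post_init__(self) -> None:
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)
        q = np.zeros(Q.shape[0]) if self.q is None else np.asarray(self.q, float).reshape(-1)
        r = np.zeros(R.shape[0]) if self.r is None else np.asarray(self.r, float).reshape(-1)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "r", r)
        if not np.allclose(Q, Q.T):
            raise ValueError("Q must be symmetric")
        if not np.allclose(R, R.T):
            raise ValueError("R must be symmetric")
        if np.min(np.linalg.eigvalsh(Q)) < -1e-12:
            raise ValueError("Q must be non-negative definite")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("R must be positive definite") from exc


@dataclass(frozen=True)
class StateEstimate:
    """Filtered state mean and covariance at time index k."""

    mean: np.ndarray
    cov: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(-1)
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape must match state dimension")


@dataclass(frozen=True)
class LinearizedStep:
    """Coefficients of one Taylor-linearized transition/measurement pair."""

    Phi: np.ndarray
    Gamma: np.ndarray
    U: np.ndarray
    H: np.ndarray
    y: np.ndarray
    Lambda: np.ndarray


def jacobian(
    fn: VecFun,
    at: np.ndarray,
    mode: str = "finite_difference",
    analytic: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Matrix of partial derivatives of ``fn`` at ``at``.

    Finite-difference mode uses central differences with per-component step
    ``1e-6 * (1 + |at_i|)``; analytic mode evaluates the supplied callable.
    """
    at = np.asarray(at, dtype=float).reshape(-1)
    if mode == "analytic":
        if analytic is None:
            raise ValueError("analytic mode requires an analytic Jacobian callable")
        return np.atleast_2d(np.asarray(analytic(at), dtype=float))
    if mode != "finite_difference":
        raise ValueError(f"unknown jacobian mode {mode!r}")
    f0 = np.asarray(fn(at), dtype=float).reshape(-1)
    if not np.all(np.isfinite(f0)):
        raise ValueError("function is not finite at the evaluation point")
    J = np.empty((f0.size, at.size))
    for i in range(at.size):
        step = 1e-6 * (1.0 + abs(at[i]))
        lo, hi = at.copy(), at.copy()
        lo[i] -= step
        hi[i] += step
        f_lo = np.asarray(fn(lo), dtype=float).reshape(-1)
        f_hi = np.asarray(fn(hi), dtype=float).reshape(-1)
        if not (np.all(np.isfinite(f_lo)) and np.all(np.isfinite(f_hi))):
            raise ValueError("function is not finite near the evaluation point")
        J[:, i] = (f_hi - f_lo) / (2.0 * step)
    return J


def _jac(fn, at, analytic):
    if analytic is not None:
        return np.atleast_2d(np.asarray(analytic(at), dtype=float))
    return jacobian(fn, at)


def linearize_state(
    model: NonlinearModel,
    est: StateEstimate,
    u: np.ndarray | None,
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Taylor-expand f around the filtered state at the noise mean.

    Returns ``(Phi, Gamma, U)`` with ``Phi = df/dx``, ``Gamma = df/dw`` and
    ``U = f(x^, u, q) - Phi x^``, so ``Phi x^ + U`` reproduces ``f`` exactly
    at the expansion point.
    """
    u = np.zeros(model.input_dim) if u is None else np.asarray(u, float).reshape(-1)
    x_hat = est.mean
    q = noise.q
    Phi = _jac(
        lambda x: model.f(x, u, q),
        x_hat,
        (lambda x: model.f_jac_x(x, u, q)) if model.f_jac_x else None,
    )
    Gamma = _jac(
        lambda w: model.f(x_hat, u, w),
        q,
        (lambda w: model.f_jac_w(x_hat, u, w)) if model.f_jac_w else None,
    )
    U = np.asarray(model.f(x_hat, u, q), float).reshape(-1) - Phi @ x_hat
    return Phi, Gamma, U


def linearize_measurement(
    model: NonlinearModel,
    pred: StateEstimate,
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Taylor-expand h around the predicted state at the noise mean.

    Returns ``(H, y, Lambda)`` with ``H = dh/dx``, ``Lambda = dh/dv`` and
    ``y = h(x^-, r) - H x^-``.
    """
    x_pred = pred.mean
    r = noise.r
    H = _jac(
        lambda x: model.h(x, r),
        x_pred,
        (lambda x: model.h_jac_x(x, r)) if model.h_jac_x else None,
    )
    Lambda = _jac(
        lambda v: model.h(x_pred, v),
        r,
        (lambda v: model.h_jac_v(x_pred, v)) if model.h_jac_v else None,
    )
    y = np.asarray(model.h(x_pred, r), float).reshape(-1) - H @ x_pred
    return H, y, Lambda


def ekf_step(
    model: NonlinearModel,
    noise: NoiseModel,
    est: StateEstimate,
    u: np.ndarray | None,
    z: np.ndarray | float,
    joseph_form: bool = False,
) -> StateEstimate:
    """One predict/update cycle of the extended Kalman filter.

    Predict:  x^- = Phi x^ + U,  P^- = Phi P Phi' + Gamma Q Gamma'
    Update:   K = P^- H' (H P^- H' + Lambda R Lambda')^{-1}
              x^+ = x^- + K (z - H x^- - y),  P^+ = (I - K H) P^-

    The posterior covariance is symmetrized each step (Joseph form behind a
    flag for extra numerical robustness).
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    Phi, Gamma, U = linearize_state(model, est, u, noise)
    x_pred = Phi @ est.mean + U
    P_pred = Phi @ est.cov @ Phi.T + Gamma @ noise.Q @ Gamma.T
    pred = StateEstimate(x_pred, P_pred, est.k + 1)

    H, y, Lam = linearize_measurement(model, pred, noise)
    S = H @ P_pred @ H.T + Lam @ noise.R @ Lam.T
    try:
        K = np.linalg.solve(S.T, (P_pred @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular innovation covariance") from exc
    innovation = z - H @ x_pred - y
    x_post = x_pred + K @ innovation
    I = np.eye(est.mean.size)
    if joseph_form:
        A = I - K @ H
        P_post = A @ P_pred @ A.T + K @ (Lam @ noise.R @ Lam.T) @ K.T
    else:
        P_post = (I - K @ H) @ P_pred
    P_post = 0.5 * (P_post + P_post.T)
    return StateEstimate(x_post, P_post, est.k + 1)


# ---------------------------------------------------------------------------
# Angle-trajectory correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KalmanConfig:
    """Constant-velocity angle smoother parameters.

    ``q_diag`` is the per-step process-noise variance on [theta (deg^2),
    theta_dot (deg^2/s^2)]; ``r`` the measurement-noise variance (deg^2) of
    the network's angle output; ``p0_diag`` the diffuse initial covariance.
    """

    q_diag: tuple[float, float] = (0.01, 1.0)
    r: float = 25.0
    p0_diag: tuple[float, float] = (100.0, 10_000.0)
    joseph_form: bool = False


def constant_velocity_model(dt: float) -> NonlinearModel:
    """Constant-velocity state [theta, theta_dot] with direct angle measurement.

    Linear, so the supplied analytic Jacobians make the EKF coincide with
    the ordinary Kalman filter.
    """
    F = np.array([[1.0, dt], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    return NonlinearModel(
        f=lambda x, u, w: F @ x + w,
        h=lambda x, v: H @ x + v,
        state_dim=2,
        meas_dim=1,
        process_noise_dim=2,
        meas_noise_dim=1,
        f_jac_x=lambda x, u, w: F,
        f_jac_w=lambda x, u, w: np.eye(2),
        h_jac_x=lambda x, r: H,
        h_jac_v=lambda x, v: np.array([[1.0]]),
    )


def smooth_angles(
    raw: AngleTrajectory, config: KalmanConfig | None = None
) -> AngleTrajectory:
    """Run the constant-velocity EKF over a raw angle sequence.

    Initialization is diffuse: x0 = [first measurement, 0] with covariance
    diag(p0_diag), forgotten within roughly ten steps.  The output has the
    same length, timestamps, and convention as the input; the first sample
    is the initialization itself.
    """
    config = config or KalmanConfig()
    ts = raw.timestamps
    z = raw.angles
    if ts.size > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    if ts.size <= 1:
        return raw
    noise = NoiseModel(Q=np.diag(config.q_diag), R=np.array([[config.r]]))
    est = StateEstimate(np.array([z[0], 0.0]), np.diag(config.p0_diag), k=0)
    out = np.empty_like(z)
    out[0] = est.mean[0]
    for k in range(1, ts.size):
        model = constant_velocity_model(float(ts[k] - ts[k - 1]))
        est = ekf_step(model, noise, est, None, z[k], joseph_form=config.joseph_form)
        out[k] = est.mean[0]
    return replace(raw, angles=out)
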