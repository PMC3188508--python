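"""Disturbance estimation: a relevance-gated extended Kalman filter over the
body and world rotation parameters.

The state is p = [theta_b, theta_w] (rad) with covariance P.  Between updates
the parameters follow a decaying random walk p <- A p + w, A = diag(a_b, a_w),
w ~ N(0, Q).  Both parameters enter the observation as a summed visual
rotation of the predicted cursor path, so the measurement Jacobian has two
identical columns.  The update is gated by the posterior probability that the
world parameter is relevant: at relevance 1 it is the standard EKF update; at
relevance 0 the world estimate and its covariance row/column are left
untouched (guarded); in between, the parameter vector and covariance are the
relevance-weighted convex combination of the two branch updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DisturbanceEstimate",
    "CompensationCommand",
    "expected_world",
    "propagate",
    "measurement_jacobian",
    "gated_update",
]


@dataclass(frozen=True)
class DisturbanceEstimate:
    """Parameter vector [theta_b, theta_w] (rad) with covariance and dynamics."""

    p: np.ndarray  # (2,) rad
    cov: np.ndarray  # (2,2) rad^2
    a_b: float = 0.98
    a_w: float = 0.99999
    q_b: float = 0.0
    q_w: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float).reshape(2))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float).reshape(2, 2))
        if not (0.0 < self.a_b <= 1.0 and 0.0 < self.a_w <= 1.0):
            raise ValueError("forgetting factors must lie in (0, 1]")

    @property
    def theta_b(self) -> float:
        return float(self.p[0])

    @property
    def theta_w(self) -> float:
        return float(self.p[1])

    @property
    def decay(self) -> np.ndarray:
        return np.diag([self.a_b, self.a_w])

    @property
    def process_noise(self) -> np.ndarray:
        return np.diag([self.q_b, self.q_w])

    @classmethod
    def initial(
        cls,
        a_b: float,
        a_w: float,
        sigma_b: float,
        sigma_w: float,
        p0_scale: float = 100.0,
    ) -> "DisturbanceEstimate":
        """Fresh estimate at (0, 0) with P0 = p0_scale * Q."""
        q = np.array([sigma_b**2, sigma_w**2])
        return cls(p=np.zeros(2), cov=np.diag(p0_scale * q), a_b=a_b, a_w=a_w,
                   q_b=q[0], q_w=q[1])


@dataclass(frozen=True)
class CompensationCommand:
    """Rotation used for planning, split into body and expected-world parts."""

    body: float  # rad
    world_expected: float  # rad

    @property
    def total(self) -> float:
        return self.body + self.world_expected


def expected_world(theta_w: float, prior_relevance: float) -> float:
    """Expected world rotation used for control: prior relevance times the
    estimate (an irrelevant world contributes zero rotation)."""
    if not 0.0 <= prior_relevance <= 1.0:
        raise ValueError("prior relevance must lie in [0, 1]")
    return prior_relevance * theta_w


def propagate(est: DisturbanceEstimate) -> DisturbanceEstimate:
    """One step of the decaying random walk: p <- A p, P <- A P A^T + Q."""
    a = est.decay
    p = a @ est.p
    cov = a @ est.cov @ a.T + est.process_noise
    return replace(est, p=p, cov=cov)


def measurement_jacobian(points: np.ndarray, angle: float, origin) -> np.ndarray:
    """Sensitivity of the rotated predicted path to the rotation parameters.

    `points` are the (k,2) predicted samples (positions, or velocities with
    origin (0,0)); the derivative of rotating (x, y) by theta about the origin
    is (-x sin - y cos, x cos - y sin).  Both parameters enter as a summed
    rotation, so the two columns are identical; the result is (2k, 2) with
    the x/y derivatives interleaved row-wise.
    """
    pts = np.asarray(points, dtype=float) - origin
    c, s = np.cos(angle), np.sin(angle)
    dx = -pts[:, 0] * s - pts[:, 1] * c
    dy = pts[:, 0] * c - pts[:, 1] * s
    col = np.column_stack([dx, dy]).reshape(-1)
    return np.column_stack([col, col])


def _psd_guard(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and, if materially indefinite, floor eigenvalues at zero.

    Rounding-level negative eigenvalues (>-1e-13) are left alone so exact
    no-update branches pass through bit-identically.
    """
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w[0] < -1e-13:
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        cov = 0.5 * (cov + cov.T)
    return cov


def gated_update(
    est: DisturbanceEstimate,
    residual: np.ndarray,
    jacobian: np.ndarray,
    obs_var: np.ndarray,
    posterior_relevance: float,
) -> DisturbanceEstimate:
    """Relevance-gated measurement update.

    Parameters
    ----------
    residual : (m,) observation minus predicted observation.
    jacobian : (m, 2) measurement Jacobian.
    obs_var : scalar or (m,) diagonal of the observation noise covariance R.
    posterior_relevance : gate weight in [0, 1].
    """
    if not 0.0 <= posterior_relevance <= 1.0:
        raise ValueError("posterior relevance must lie in [0, 1]")
    r = np.asarray(residual, dtype=float).reshape(-1)
    h = np.asarray(jacobian, dtype=float).reshape(len(r), 2)
    rv = np.broadcast_to(np.asarray(obs_var, dtype=float), (len(r),))

    s = h @ est.cov @ h.T + np.diag(rv)
    try:
        sinv_ht = np.linalg.solve(s, h).T  # (2, m) = (S^-1 H)^T
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(f"singular innovation covariance: {exc}") from exc
    gain = est.cov @ sinv_ht  # (2, m)

    eye = np.eye(2)
    # full EKF branch (world relevant)
    p_full = est.p + gain @ r
    cov_full = (eye - gain @ h) @ est.cov

    # guarded branch: world row of the gain zeroed; world covariance
    # row/column left untouched
    gain0 = gain.copy()
    gain0[1, :] = 0.0
    p_guard = est.p + gain0 @ r
    cov_guard = (eye - gain0 @ h) @ est.cov
    cov_guard[1, :] = est.cov[1, :]
    cov_guard[:, 1] = est.cov[:, 1]
    # keep the guarded branch PSD without touching the world row/column: the
    # body variance cannot drop below what the retained cross-covariance allows
    if est.cov[1, 1] > 0.0:
        cov_guard[0, 0] = max(cov_guard[0, 0], est.cov[0, 1] ** 2 / est.cov[1, 1])

    lam = posterior_relevance
    if lam == 1.0:
        p_new, cov_new = p_full, 0.5 * (cov_full + cov_full.T)
    elif lam == 0.0:
        p_new, cov_new = p_guard, 0.5 * (cov_guard + cov_guard.T)
    else:
        p_new = lam * p_full + (1.0 - lam) * p_guard
        cov_new = _psd_guard(lam * cov_full + (1.0 - lam) * cov_guard)
    return replace(est, p=p_new, cov=cov_new)
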