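"""Movement generation: minimum-jerk references, two-link arm control, the
visuomotor display transform and noisy observations.

The plant is the "world" of the simulator.  A reach is planned as a
minimum-jerk Cartesian trajectory, converted to joint space, driven by
inverse-dynamics feedforward torques plus PD feedback, and integrated with a
fixed-step RK4 scheme.  The displayed cursor is the hand path rotated about
the movement start by the imposed visuomotor rotation; the observation adds
zero-mean Gaussian noise (or, on error-clamp trials, is replaced by the
noiseless straight reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import simulate_arm
from .config import ArmParams, ControllerConfig

__all__ = [
    "ReachSpec",
    "Path",
    "ReachRealization",
    "SimulationError",
    "minimum_jerk",
    "via_points",
    "plan_compensated_reach",
    "simulate_reach",
    "angular_error",
    "rotate_about",
    "rotation_derivative",
]


class SimulationError(RuntimeError):
    """Integrator divergence or other unrecoverable plant failure."""


@dataclass(frozen=True)
class ReachSpec:
    """One point-to-point reach: start/target (m, Cartesian), duration (s)."""

    start: tuple[float, float]
    target: tuple[float, float]
    duration: float = 0.5
    n_via: int = 8

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("movement duration must be positive")
        if self.n_via < 2:
            raise ValueError("need at least 2 via points")
        if np.allclose(self.start, self.target):
            raise ValueError("start and target coincide")


@dataclass
class Path:
    """Cartesian position+velocity samples on a uniform time grid."""

    t: np.ndarray  # (N,)
    pos: np.ndarray  # (N, 2) m
    vel: np.ndarray  # (N, 2) m/s

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ReachRealization:
    """One simulated movement: reference, executed hand, displayed cursor and
    noise-corrupted observed cursor paths, all on the same time grid."""

    reference: Path
    hand: Path
    cursor: Path
    observed: Path
    rotation: float  # applied visuomotor rotation (rad)
    clamp: bool
    obs_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def rotate_about(points: np.ndarray, angle: float, origin) -> np.ndarray:
    """Rotate (N,2) points CCW by `angle` about `origin` (for velocities pass
    origin=(0,0))."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (np.asarray(points) - origin) @ rot.T + origin


def rotation_derivative(points: np.ndarray, angle: float, origin) -> np.ndarray:
    """d/dtheta of rotate_about(points, theta, origin) at theta=angle."""
    c, s = np.cos(angle), np.sin(angle)
    drot = np.array([[-s, -c], [c, -s]])
    return (np.asarray(points) - origin) @ drot.T


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------

def minimum_jerk(spec: ReachSpec, dt: float = 0.001) -> Path:
    """Minimum-jerk point-to-point reference on a uniform time grid.

    The fifth-order profile has zero velocity and acceleration at both ends;
    for a point-to-point reach the spatial path is the straight segment
    through the equally spaced via points.
    """
    n = int(round(spec.duration / dt))
    t = np.linspace(0.0, spec.duration, n + 1)
    tau = t / spec.duration
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sd = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / spec.duration
    start = np.asarray(spec.start, dtype=float)
    disp = np.asarray(spec.target, dtype=float) - start
    pos = start + s[:, None] * disp
    vel = sd[:, None] * disp
    return Path(t=t, pos=pos, vel=vel)


def via_points(spec: ReachSpec) -> np.ndarray:
    """The spec's equally spaced spatial waypoints from start to target."""
    frac = np.linspace(0.0, 1.0, spec.n_via)
    start = np.asarray(spec.start, dtype=float)
    return start + frac[:, None] * (np.asarray(spec.target) - start)


def plan_compensated_reach(reference: Path, total_estimated_rotation: float) -> Path:
    """Counter-rotate the desired cursor path by the estimated total rotation.

    If the true rotation equals the estimate, the displayed cursor then lands
    exactly on the reference.  Rotation is about the movement start.
    """
    if not np.isfinite(total_estimated_rotation):
        raise ValueError("estimated rotation must be finite")
    origin = reference.pos[0]
    pos = rotate_about(reference.pos, -total_estimated_rotation, origin)
    vel = rotate_about(reference.vel, -total_estimated_rotation, (0.0, 0.0))
    return Path(t=reference.t, pos=pos, vel=vel)


# --------------------------------------------------------------------------
# arm kinematics / dynamics
# --------------------------------------------------------------------------

def _inertia_constants(arm: ArmParams) -> tuple[float, float, float]:
    a1 = arm.i1 + arm.i2 + arm.m1 * arm.r1**2 + arm.m2 * (arm.l1**2 + arm.r2**2)
    a2 = arm.i2 + arm.m2 * arm.r2**2
    a3 = arm.m2 * arm.l1 * arm.r2
    return a1, a2, a3


def inverse_kinematics(pos: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Joint angles (N,2) for hand positions (N,2); elbow-flexed branch."""
    rel = np.atleast_2d(pos) - np.asarray(arm.shoulder)
    d2 = np.einsum("ij,ij->i", rel, rel)
    c2 = (d2 - arm.l1**2 - arm.l2**2) / (2 * arm.l1 * arm.l2)
    if np.any(np.abs(c2) > 1 + 1e-9):
        raise SimulationError("reach target outside the arm workspace")
    q2 = np.arccos(np.clip(c2, -1.0, 1.0))
    q1 = np.arctan2(rel[:, 1], rel[:, 0]) - np.arctan2(
        arm.l2 * np.sin(q2), arm.l1 + arm.l2 * np.cos(q2)
    )
    return np.column_stack([q1, q2])


def forward_kinematics(q: np.ndarray, arm: ArmParams) -> np.ndarray:
    q = np.atleast_2d(q)
    x = arm.l1 * np.cos(q[:, 0]) + arm.l2 * np.cos(q[:, 0] + q[:, 1])
    y = arm.l1 * np.sin(q[:, 0]) + arm.l2 * np.sin(q[:, 0] + q[:, 1])
    return np.column_stack([x, y]) + np.asarray(arm.shoulder)


def jacobian_dot_q(q: np.ndarray, qd: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Hand velocity (N,2) from joint state."""
    q = np.atleast_2d(q)
    qd = np.atleast_2d(qd)
    s1 = np.sin(q[:, 0]); c1 = np.cos(q[:, 0])
    s12 = np.sin(q[:, 0] + q[:, 1]); c12 = np.cos(q[:, 0] + q[:, 1])
    vx = -(arm.l1 * s1 + arm.l2 * s12) * qd[:, 0] - arm.l2 * s12 * qd[:, 1]
    vy = (arm.l1 * c1 + arm.l2 * c12) * qd[:, 0] + arm.l2 * c12 * qd[:, 1]
    return np.column_stack([vx, vy])


def inverse_dynamics(q: np.ndarray, qd: np.ndarray, qdd: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Torques (N,2) realizing a joint trajectory (planar, no gravity)."""
    a1, a2, a3 = _inertia_constants(arm)
    c2 = np.cos(q[:, 1]); s2 = np.sin(q[:, 1])
    m11 = a1 + 2 * a3 * c2
    m12 = a2 + a3 * c2
    m22 = np.full_like(c2, a2)
    h = a3 * s2
    tau1 = (
        m11 * qdd[:, 0] + m12 * qdd[:, 1]
        - h * qd[:, 1] * (2 * qd[:, 0] + qd[:, 1])
        + arm.viscosity * qd[:, 0]
    )
    tau2 = m22 * qdd[:, 1] + m12 * qdd[:, 0] + h * qd[:, 0] ** 2 + arm.viscosity * qd[:, 1]
    return np.column_stack([tau1, tau2])


def _plan_to_joint(plan: Path, arm: ArmParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint trajectory and derivatives for a Cartesian plan (central diffs)."""
    q = inverse_kinematics(plan.pos, arm)
    q = np.unwrap(q, axis=0)
    dt = plan.t[1] - plan.t[0]
    qd = np.gradient(q, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    return q, qd, qdd


# --------------------------------------------------------------------------
# closed-loop simulation
# --------------------------------------------------------------------------

def simulate_reach(
    plan: Path,
    reference: Path,
    arm: ArmParams,
    controller: ControllerConfig,
    true_rotation: float,
    clamp: bool,
    rng: np.random.Generator | None,
    sigma_pos: float = 0.01,
    sigma_vel: float = 0.04,
    obs_stride: int = 17,
    feedback: bool = True,
    trial: int | None = None,
) -> ReachRealization:
    """Execute a planned reach on the arm and produce all four paths.

    Feedforward torques come from the inverse dynamics of the plan; PD
    feedback acts about the plan.  The cursor is the hand path rotated by
    ``true_rotation`` about the movement start.  Observations are taken every
    ``obs_stride`` integration samples with Gaussian noise, except on clamp
    trials where the observation is the noiseless straight reference.
    """
    q_ref, qd_ref, qdd_ref = _plan_to_joint(plan, arm)
    tau_ff = inverse_dynamics(q_ref, qd_ref, qdd_ref, arm)
    a1, a2, a3 = _inertia_constants(arm)
    kp = controller.kp if feedback else 0.0
    kd = controller.kd if feedback else 0.0
    dt = plan.t[1] - plan.t[0]
    q, qd = simulate_arm(
        q_ref[0].copy(), qd_ref[0].copy(), tau_ff, q_ref, qd_ref,
        a1, a2, a3, arm.viscosity, kp, kd, dt,
    )
    if not np.all(np.isfinite(q)):
        where = f" on trial {trial}" if trial is not None else ""
        raise SimulationError(f"arm integration diverged{where}; check controller gains")

    hand_pos = forward_kinematics(q, arm)
    hand_vel = jacobian_dot_q(q, qd, arm)
    hand = Path(t=plan.t, pos=hand_pos, vel=hand_vel)

    origin = reference.pos[0]
    cursor = Path(
        t=plan.t,
        pos=rotate_about(hand_pos, true_rotation, origin),
        vel=rotate_about(hand_vel, true_rotation, (0.0, 0.0)),
    )

    obs_idx = np.arange(0, len(plan.t), obs_stride)
    if clamp:
        obs = Path(t=plan.t.copy(), pos=reference.pos.copy(), vel=reference.vel.copy())
    else:
        obs_pos = cursor.pos.copy()
        obs_vel = cursor.vel.copy()
        if rng is not None:
            obs_pos[obs_idx] += rng.normal(0.0, sigma_pos, size=(len(obs_idx), 2))
            obs_vel[obs_idx] += rng.normal(0.0, sigma_vel, size=(len(obs_idx), 2))
        obs = Path(t=plan.t, pos=obs_pos, vel=obs_vel)

    return ReachRealization(
        reference=reference, hand=hand, cursor=cursor, observed=obs,
        rotation=float(true_rotation), clamp=bool(clamp), obs_idx=obs_idx,
    )


# --------------------------------------------------------------------------
# error metric
# --------------------------------------------------------------------------

def angular_error(
    path: Path,
    spec_start,
    spec_target,
    sample: str = "peak_speed",
) -> float:
    """Signed angular reach error in degrees (CCW positive).

    Angle between the start->target direction and the start->cursor direction,
    read out either at the sample of peak tangential speed or at the endpoint.
    Returns NaN for a degenerate (zero-displacement) path.
    """
    start = np.asarray(spec_start, dtype=float)
    target = np.asarray(spec_target, dtype=float)
    if sample == "peak_speed":
        speed = np.linalg.norm(path.vel, axis=1)
        idx = int(np.argmax(speed))
        if speed[idx] == 0.0:
            idx = len(path) - 1
    elif sample == "endpoint":
        idx = len(path) - 1
    else:
        raise ValueError(f"unknown error sample point {sample!r}")
    disp = path.pos[idx] - start
    if np.linalg.norm(disp) < 1e-12:
        return float("nan")
    ref = target - start
    ang = np.arctan2(disp[1], disp[0]) - np.arctan2(ref[1], ref[0])
    return float(np.degrees((ang + np.pi) % (2 * np.pi) - np.pi))
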