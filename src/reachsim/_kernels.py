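"""Numba-compiled inner loops for the two-link arm integrator.

Kept separate from the public plant API so the compiled functions stay
signature-stable and cache-friendly.  All quantities are SI; joint state is
(q1, q2, qd1, qd2) with q1 the shoulder angle and q2 the elbow angle.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _accel(q2, qd1, qd2, tau1, tau2, a1, a2, a3, b):
    # inertia matrix entries for a planar 2-link chain:
    #   M11 = a1 + 2*a3*cos(q2), M12 = a2 + a3*cos(q2), M22 = a2
    c2 = np.cos(q2)
    s2 = np.sin(q2)
    m11 = a1 + 2.0 * a3 * c2
    m12 = a2 + a3 * c2
    m22 = a2
    # Coriolis/centripetal vector
    h = a3 * s2
    c1 = -h * qd2 * (2.0 * qd1 + qd2)
    c2v = h * qd1 * qd1
    t1 = tau1 - c1 - b * qd1
    t2 = tau2 - c2v - b * qd2
    det = m11 * m22 - m12 * m12
    qdd1 = (m22 * t1 - m12 * t2) / det
    qdd2 = (m11 * t2 - m12 * t1) / det
    return qdd1, qdd2


@njit(cache=True)
def simulate_arm(q0, qd0, tau_ff, q_ref, qd_ref, a1, a2, a3, b, kp, kd, dt):
    """RK4 integration of the closed-loop arm over the planned trajectory.

    tau_ff, q_ref, qd_ref are (N, 2) arrays sampled on the integration grid;
    inputs are linearly interpolated at RK4 half steps.  Returns (q, qd) as
    (N, 2) arrays.  The PD feedback acts about the planned joint trajectory.
    """
    n = tau_ff.shape[0]
    q = np.empty((n, 2))
    qd = np.empty((n, 2))
    q[0, 0], q[0, 1] = q0[0], q0[1]
    qd[0, 0], qd[0, 1] = qd0[0], qd0[1]
    for i in range(n - 1):
        x1, x2 = q[i, 0], q[i, 1]
        v1, v2 = qd[i, 0], qd[i, 1]
        # inputs at t, t+dt/2, t+dt
        f1a, f2a = tau_ff[i, 0], tau_ff[i, 1]
        f1c, f2c = tau_ff[i + 1, 0], tau_ff[i + 1, 1]
        f1b, f2b = 0.5 * (f1a + f1c), 0.5 * (f2a + f2c)
        r1a, r2a = q_ref[i, 0], q_ref[i, 1]
        r1c, r2c = q_ref[i + 1, 0], q_ref[i + 1, 1]
        r1b, r2b = 0.5 * (r1a + r1c), 0.5 * (r2a + r2c)
        s1a, s2a = qd_ref[i, 0], qd_ref[i, 1]
        s1c, s2c = qd_ref[i + 1, 0], qd_ref[i + 1, 1]
        s1b, s2b = 0.5 * (s1a + s1c), 0.5 * (s2a + s2c)

        # k1
        t1 = f1a + kp * (r1a - x1) + kd * (s1a - v1)
        t2 = f2a + kp * (r2a - x2) + kd * (s2a - v2)
        a1k, a2k = _accel(x2, v1, v2, t1, t2, a1, a2, a3, b)
        k1q1, k1q2, k1v1, k1v2 = v1, v2, a1k, a2k
        # k2
        y1, y2 = x1 + 0.5 * dt * k1q1, x2 + 0.5 * dt * k1q2
        w1, w2 = v1 + 0.5 * dt * k1v1, v2 + 0.5 * dt * k1v2
        t1 = f1b + kp * (r1b - y1) + kd * (s1b - w1)
        t2 = f2b + kp * (r2b - y2) + kd * (s2b - w2)
        a1k, a2k = _accel(y2, w1, w2, t1, t2, a1, a2, a3, b)
        k2q1, k2q2, k2v1, k2v2 = w1, w2, a1k, a2k
        # k3
        y1, y2 = x1 + 0.5 * dt * k2q1, x2 + 0.5 * dt * k2q2
        w1, w2 = v1 + 0.5 * dt * k2v1, v2 + 0.5 * dt * k2v2
        t1 = f1b + kp * (r1b - y1) + kd * (s1b - w1)
        t2 = f2b + kp * (r2b - y2) + kd * (s2b - w2)
        a1k, a2k = _accel(y2, w1, w2, t1, t2, a1, a2, a3, b)
        k3q1, k3q2, k3v1, k3v2 = w1, w2, a1k, a2k
        # k4
        y1, y2 = x1 + dt * k3q1, x2 + dt * k3q2
        w1, w2 = v1 + dt * k3v1, v2 + dt * k3v2
        t1 = f1c + kp * (r1c - y1) + kd * (s1c - w1)
        t2 = f2c + kp * (r2c - y2) + kd * (s2c - w2)
        a1k, a2k = _accel(y2, w1, w2, t1, t2, a1, a2, a3, b)
        k4q1, k4q2, k4v1, k4v2 = w1, w2, a1k, a2k

        q[i + 1, 0] = x1 + dt / 6.0 * (k1q1 + 2.0 * k2q1 + 2.0 * k3q1 + k4q1)
        q[i + 1, 1] = x2 + dt / 6.0 * (k1q2 + 2.0 * k2q2 + 2.0 * k3q2 + k4q2)
        qd[i + 1, 0] = v1 + dt / 6.0 * (k1v1 + 2.0 * k2v1 + 2.0 * k3v1 + k4v1)
        qd[i + 1, 1] = v2 + dt / 6.0 * (k1v2 + 2.0 * k2v2 + 2.0 * k3v2 + k4v2)
    return q, qd
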