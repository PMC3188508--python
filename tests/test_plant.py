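"""Plant tests: reference generation, arm dynamics, display transform, error metric."""

import math

import numpy as np
import pytest

from reachsim import (
    ReachSpec,
    angular_error,
    minimum_jerk,
    plan_compensated_reach,
    simulate_reach,
    via_points,
)
from reachsim.plant import (
    Path,
    SimulationError,
    _inertia_constants,
    forward_kinematics,
    inverse_kinematics,
    jacobian_dot_q,
    rotate_about,
)
from reachsim._kernels import simulate_arm


SPEC = ReachSpec(start=(0.0, 0.45), target=(0.0, 0.55), duration=0.5)


class TestMinimumJerk:
    def test_boundary_conditions(self):
        ref = minimum_jerk(SPEC)
        np.testing.assert_allclose(ref.pos[0], SPEC.start, atol=1e-15)
        np.testing.assert_allclose(ref.pos[-1], SPEC.target, atol=1e-15)
        np.testing.assert_allclose(ref.vel[0], 0.0, atol=1e-15)
        np.testing.assert_allclose(ref.vel[-1], 0.0, atol=1e-12)
        # endpoint acceleration is zero up to the one-sided finite-difference
        # truncation (~ jerk * dt / 2 at the boundary)
        acc = np.gradient(ref.vel, ref.t, axis=0)
        dt = ref.t[1] - ref.t[0]
        jerk0 = 60 * 0.1 / SPEC.duration**3  # peak boundary jerk of the profile
        assert np.all(np.abs(acc[0]) < jerk0 * dt) and np.all(np.abs(acc[-1]) < jerk0 * dt)

    def test_midpoint_and_speed_symmetry(self):
        ref = minimum_jerk(SPEC)
        mid = 0.5 * (np.asarray(SPEC.start) + np.asarray(SPEC.target))
        n = len(ref) // 2
        np.testing.assert_allclose(ref.pos[n], mid, atol=1e-12)
        speed = np.linalg.norm(ref.vel, axis=1)
        np.testing.assert_allclose(speed, speed[::-1], atol=1e-9)

    def test_via_points_lie_on_path(self):
        ref = minimum_jerk(SPEC)
        seg = np.asarray(SPEC.target) - np.asarray(SPEC.start)
        unit = seg / np.linalg.norm(seg)
        for wp in via_points(SPEC):
            # perpendicular distance to the path is zero; the nearest sampled
            # point is within one time step at peak speed
            rel = wp - np.asarray(SPEC.start)
            perp = rel - (rel @ unit) * unit
            assert np.linalg.norm(perp) < 1e-12
            assert np.min(np.linalg.norm(ref.pos - wp, axis=1)) < 5e-4
        assert len(via_points(SPEC)) == 8

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ReachSpec(start=(0, 0.45), target=(0, 0.55), duration=-1.0)
        with pytest.raises(ValueError):
            ReachSpec(start=(0, 0.45), target=(0, 0.45))


class TestPlanning:
    def test_zero_estimate_is_identity(self):
        ref = minimum_jerk(SPEC)
        plan = plan_compensated_reach(ref, 0.0)
        np.testing.assert_array_equal(plan.pos, ref.pos)

    def test_counter_rotation_composition(self):
        ref = minimum_jerk(SPEC)
        theta = math.radians(25.0)
        plan = plan_compensated_reach(ref, theta)
        back = rotate_about(plan.pos, theta, ref.pos[0])
        np.testing.assert_allclose(back, ref.pos, atol=1e-12)


class TestSimulateReach:
    def test_tracks_feasible_reference(self, cfg):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        real = simulate_reach(ref, ref, cfg.arm, cfg.controller, 0.0, False, None)
        assert np.linalg.norm(real.hand.pos[-1] - SPEC.target) < 2e-3
        assert np.max(np.linalg.norm(real.hand.pos - ref.pos, axis=1)) < 5e-3

    def test_exact_cancellation_when_estimate_matches_truth(self, cfg):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        theta = math.radians(30.0)
        plan = plan_compensated_reach(ref, theta)
        real = simulate_reach(plan, ref, cfg.arm, cfg.controller, theta, False, None)
        err = angular_error(real.cursor, SPEC.start, SPEC.target)
        assert abs(err) < 1.0  # deg; limited by tracking, not by geometry

    def test_uncompensated_rotation_appears_in_cursor(self, cfg):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        real = simulate_reach(ref, ref, cfg.arm, cfg.controller, math.radians(30.0), False, None)
        err = angular_error(real.cursor, SPEC.start, SPEC.target)
        assert abs(err - 30.0) < 1.0

    def test_rotation_composition_property(self, cfg):
        # simulate under rotation t1 against a plan counter-rotated by t2:
        # the cursor error is t1 - t2 up to tracking tolerance
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        t1, t2 = math.radians(20.0), math.radians(-15.0)
        plan = plan_compensated_reach(ref, t2)
        real = simulate_reach(plan, ref, cfg.arm, cfg.controller, t1, False, None)
        err = angular_error(real.cursor, SPEC.start, SPEC.target)
        assert abs(err - math.degrees(t1 - t2)) < 1.0

    def test_clamp_observation_is_straight_reference(self, cfg, rng):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        plan = plan_compensated_reach(ref, math.radians(17.0))
        real = simulate_reach(plan, ref, cfg.arm, cfg.controller, math.radians(30.0), True, rng)
        np.testing.assert_array_equal(real.observed.pos, ref.pos)
        np.testing.assert_array_equal(real.observed.vel, ref.vel)

    def test_unstable_gains_raise(self, cfg):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        bad = cfg.controller.model_copy(update={"kp": 4e6, "kd": 1e-4})
        with pytest.raises(SimulationError):
            simulate_reach(ref, ref, cfg.arm, bad, 0.0, False, None, trial=7)


class TestDynamicsInternals:
    def test_forward_inverse_kinematics_roundtrip(self, cfg):
        pts = np.array([[0.0, 0.45], [0.05, 0.4], [-0.08, 0.5]])
        q = inverse_kinematics(pts, cfg.arm)
        np.testing.assert_allclose(forward_kinematics(q, cfg.arm), pts, atol=1e-12)

    def test_feedforward_alone_reproduces_plan(self, cfg):
        # inverse-dynamics torques, fed forward with feedback off and a
        # perfect model, reproduce the planned path
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        real = simulate_reach(ref, ref, cfg.arm, cfg.controller, 0.0, False, None,
                              feedback=False)
        assert np.max(np.linalg.norm(real.hand.pos - ref.pos, axis=1)) < 5e-3

    def test_energy_conservation_without_torque(self, cfg):
        # zero torque, zero viscosity, nonzero initial velocity: kinetic
        # energy is conserved by the integrator
        arm = cfg.arm.model_copy(update={"viscosity": 0.0})
        a1, a2, a3 = _inertia_constants(arm)
        n = 501
        zeros = np.zeros((n, 2))
        q0 = np.array([0.8, 1.2])
        qd0 = np.array([1.0, -2.0])
        q, qd = simulate_arm(q0, qd0, zeros, zeros, zeros, a1, a2, a3, 0.0, 0.0, 0.0, 1e-3)

        def kinetic(qi, qdi):
            c2 = np.cos(qi[1])
            m = np.array([[a1 + 2 * a3 * c2, a2 + a3 * c2], [a2 + a3 * c2, a2]])
            return 0.5 * qdi @ m @ qdi

        e0 = kinetic(q[0], qd[0])
        e1 = kinetic(q[-1], qd[-1])
        assert abs(e1 - e0) / e0 < 1e-8

    def test_hand_velocity_consistent_with_positions(self, cfg):
        ref = minimum_jerk(SPEC, cfg.sim.dt)
        real = simulate_reach(ref, ref, cfg.arm, cfg.controller, 0.0, False, None)
        v_fd = np.gradient(real.hand.pos, cfg.sim.dt, axis=0)
        assert np.max(np.abs(v_fd[5:-5] - real.hand.vel[5:-5])) < 1e-3


class TestAngularError:
    def test_straight_path_zero_error(self):
        ref = minimum_jerk(SPEC)
        assert angular_error(ref, SPEC.start, SPEC.target) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_recovered(self):
        ref = minimum_jerk(SPEC)
        rot = Path(t=ref.t, pos=rotate_about(ref.pos, math.radians(30), ref.pos[0]),
                   vel=rotate_about(ref.vel, math.radians(30), (0.0, 0.0)))
        assert angular_error(rot, SPEC.start, SPEC.target) == pytest.approx(30.0, abs=1e-9)

    def test_degenerate_path_flagged(self):
        p = Path(t=np.array([0.0, 1.0]), pos=np.full((2, 2), 0.45) * [[0, 1], [0, 1]],
                 vel=np.zeros((2, 2)))
        assert math.isnan(angular_error(p, (0.0, 0.45), (0.0, 0.55)))

    def test_noise_spread_matches_observation_covariance(self, cfg, rng):
        # Monte Carlo over >= 1e4 noise draws: the error spread at the
        # peak-speed sample equals sigma_pos mapped through the radius there
        ref = minimum_jerk(SPEC)
        speed = np.linalg.norm(ref.vel, axis=1)
        k = int(np.argmax(speed))
        r = np.linalg.norm(ref.pos[k] - ref.pos[0])
        n = 20000
        noisy = ref.pos[k] + rng.normal(0.0, cfg.noise.sigma_pos, size=(n, 2))
        disp = noisy - ref.pos[0]
        ang = np.degrees(np.arctan2(disp[:, 0], disp[:, 1]))  # target is straight ahead
        predicted = math.degrees(cfg.noise.sigma_pos / r)
        assert abs(np.mean(ang)) < 3 * predicted / math.sqrt(n) * 3 + 0.2
        assert np.std(ang) == pytest.approx(predicted, rel=0.05)
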