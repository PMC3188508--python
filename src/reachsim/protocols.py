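"""Experimental paradigms and the closed-loop trial runner.

A paradigm is an :class:`ExperimentSchedule`: an ordered list of trials, each
with a true world rotation, an error-clamp flag, a robot-held flag and a
session (day) index.  :func:`run_experiment` runs the full loop per trial —
propagate the estimates, plan a compensated reach, simulate it on the arm,
infer relevance once from the whole path, then perform the per-segment gated
parameter updates — and logs one :class:`TrialRecord` per movement.  Session
boundaries trigger an inter-session transition: a block of natural
(robot-absent) null movements during which the body estimate de-adapts while
the world estimate is guarded, followed by re-initialization of the relevance
probability to a high day-start value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import estimator as est_mod
from . import relevance as rel_mod
from .config import RunConfig
from .plant import (
    Path,
    ReachSpec,
    angular_error,
    minimum_jerk,
    plan_compensated_reach,
    rotate_about,
    simulate_reach,
)

__all__ = [
    "Trial",
    "ExperimentSchedule",
    "TrialRecord",
    "PARADIGMS",
    "build_schedule",
    "run_experiment",
    "records_to_frame",
    "paradigm_metrics",
    "Simulator",
]

NOT_ATTAINED = None  # sentinel for a criterion a block never reaches


@dataclass(frozen=True)
class Trial:
    rotation_deg: float
    clamp: bool = False
    robot_held: bool = True
    session: int = 1
    block: str = "A1"


@dataclass
class ExperimentSchedule:
    """Fully expanded per-trial schedule defining one paradigm."""

    name: str
    trials: list[Trial]

    def __post_init__(self) -> None:
        sessions = [tr.session for tr in self.trials]
        if any(b < a for a, b in zip(sessions, sessions[1:])):
            raise ValueError("session indices must be non-decreasing")
        if not all(math.isfinite(tr.rotation_deg) for tr in self.trials):
            raise ValueError("rotations must be finite")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def blocks(self) -> list[str]:
        out: list[str] = []
        for tr in self.trials:
            if not out or out[-1] != tr.block:
                out.append(tr.block)
        return out


@dataclass(frozen=True)
class TrialRecord:
    """Per-movement log of behaviour, evidence and estimates (angles in deg)."""

    trial: int
    session: int
    block: str
    rotation_deg: float
    clamp: bool
    robot_held: bool
    error_deg: float
    theta_y_deg: float
    lik_relevant: float
    lik_irrelevant: float
    relevance_prior: float
    relevance_posterior: float
    theta_b_deg: float
    theta_w_deg: float
    expected_world_deg: float
    total_compensation_deg: float


def _block(n: int, rotation: float, name: str, session: int, *, clamp=False, held=True) -> list[Trial]:
    return [Trial(rotation, clamp, held, session, name) for _ in range(n)]


def build_schedule(paradigm: str, cfg: RunConfig | None = None, **overrides) -> ExperimentSchedule:
    """Expand a named paradigm into a per-trial schedule.

    Paradigms: abrupt, washout_retest, long_term_savings, aba_interference,
    gradual, error_clamp, rebound.  Block lengths and the disturbance
    magnitude default to the protocol section of the config and can be
    overridden by keyword (e.g. ``adapt_trials=40``).
    """
    cfg = cfg or RunConfig()
    p = cfg.protocol.model_copy(update=overrides or {})
    rot = p.rotation_deg
    n = p.adapt_trials

    if paradigm == "abrupt":
        base = overrides.get("baseline_trials", 20)
        trials = _block(base, 0.0, "N1", 1) + _block(n, rot, "A1", 1)
    elif paradigm == "washout_retest":
        trials = (
            _block(20, 0.0, "N1", 1)
            + _block(n, rot, "A1", 1)
            + _block(p.washout_trials, 0.0, "W1", 1)
            + _block(n, rot, "A2", 1)
        )
    elif paradigm == "long_term_savings":
        trials = _block(n, rot, "A1", 1) + _block(n, rot, "A2", 2)
    elif paradigm == "aba_interference":
        trials = (
            _block(n, rot, "A1", 1)
            + _block(n, -rot, "B1", 1)
            + _block(n, rot, "A2", 2)
        )
    elif paradigm == "gradual":
        ramp = np.linspace(0.0, rot, p.gradual_ramp_trials + 1)[1:]
        plateau = max(n - p.gradual_ramp_trials, 0)
        trials = (
            [Trial(float(r), False, True, 1, "G1") for r in ramp]
            + _block(plateau, rot, "G1", 1)
            + _block(n, rot, "A2", 2)
        )
    elif paradigm == "error_clamp":
        trials = _block(n, rot, "A1", 1) + _block(p.clamp_trials, 0.0, "C1", 1, clamp=True)
    elif paradigm == "rebound":
        trials = (
            _block(n, rot, "A1", 1)
            + _block(p.counter_trials, -rot, "B1", 1)
            + _block(p.clamp_trials, 0.0, "C1", 1, clamp=True)
        )
    else:
        valid = "abrupt, washout_retest, long_term_savings, aba_interference, gradual, error_clamp, rebound"
        raise ValueError(f"unknown paradigm {paradigm!r}; valid names: {valid}")
    return ExperimentSchedule(name=paradigm, trials=trials)


PARADIGMS = (
    "abrupt",
    "washout_retest",
    "long_term_savings",
    "aba_interference",
    "gradual",
    "error_clamp",
    "rebound",
)


# --------------------------------------------------------------------------
# closed-loop simulator
# --------------------------------------------------------------------------

class Simulator:
    """Holds the model state and runs trials against a schedule.

    One instance corresponds to one simulated subject; everything is
    reproducible from (config, seed).
    """

    def __init__(self, cfg: RunConfig, seed: int):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        f = cfg.filter
        self.est = est_mod.DisturbanceEstimate.initial(
            f.a_b, f.a_w, cfg.sigma_b, cfg.sigma_w, f.p0_scale
        )
        r = cfg.relevance
        self.rel = rel_mod.RelevanceState(
            p_relevant=0.5, m11=r.m11, m22=r.m22, sigma_theta=cfg.sigma_theta
        )
        self._forced_prior: float | None = None
        self._trial_no = 0
        # precompute one minimum-jerk reference per target direction
        c = np.asarray(cfg.sim.workspace_center)
        angles = 2 * np.pi * np.arange(cfg.sim.n_targets) / cfg.sim.n_targets
        self.targets = c + cfg.sim.reach_distance * np.column_stack(
            [np.cos(angles), np.sin(angles)]
        )
        self.specs = [
            ReachSpec(tuple(c), tuple(t), cfg.sim.duration, cfg.sim.n_via)
            for t in self.targets
        ]
        self.references = [minimum_jerk(s, cfg.sim.dt) for s in self.specs]
        self.obs_stride = max(1, int(round(1.0 / (cfg.sim.obs_rate * cfg.sim.dt))))

    # -- one movement ------------------------------------------------------
    def run_trial(self, trial: Trial, record: bool = True) -> TrialRecord | None:
        cfg = self.cfg
        self._trial_no += 1
        k = int(self.rng.integers(len(self.specs)))
        spec, ref = self.specs[k], self.references[k]
        start = ref.pos[0]

        # planning prior for the world parameter's relevance
        if not trial.robot_held:
            prior_rel = 0.0
        elif self._forced_prior is not None:
            prior_rel = self._forced_prior
            self._forced_prior = None
        else:
            prior_rel = rel_mod.propagate_prior(self.rel)

        w_exp = est_mod.expected_world(self.est.theta_w, prior_rel)
        total = self.est.theta_b + w_exp
        plan = plan_compensated_reach(ref, total)

        real = simulate_reach(
            plan, ref, cfg.arm, cfg.controller,
            math.radians(trial.rotation_deg), trial.clamp, self.rng,
            sigma_pos=cfg.noise.sigma_pos, sigma_vel=cfg.noise.sigma_vel,
            obs_stride=self.obs_stride, trial=self._trial_no,
        )
        err = angular_error(real.cursor, spec.start, spec.target, cfg.sim.error_sample)

        # relevance: once per movement, from the whole observed path vs the
        # body-only prediction
        idx = real.obs_idx
        body_pred = Path(
            t=ref.t[idx],
            pos=rotate_about(plan.pos[idx], self.est.theta_b, start),
            vel=rotate_about(plan.vel[idx], self.est.theta_b, (0.0, 0.0)),
        )
        obs_path = Path(t=ref.t[idx], pos=real.observed.pos[idx], vel=real.observed.vel[idx])
        obs_rot = rel_mod.estimate_observed_rotation(obs_path, body_pred)
        if trial.robot_held:
            l1, l0 = rel_mod.movement_likelihoods(obs_rot, self.rel.sigma_theta, trial.clamp)
            posterior = rel_mod.posterior_from_prior(prior_rel, l1, l0)
            self.rel = replace(self.rel, p_relevant=float(posterior))
        else:
            # the robot is absent: a visuomotor rotation cannot be in play
            self.rel = replace(self.rel, p_relevant=0.0)
            posterior, l1, l0 = 0.0, math.nan, math.nan

        # gated parameter updates on equal path segments
        # the predicted observation is based on the compensation actually
        # issued at movement start; mid-movement updates shape the next
        # movement, not the prediction of this one
        segs = np.array_split(idx, cfg.filter.updates_per_movement)
        for seg in segs:
            if len(seg) == 0:
                continue
            self.est = est_mod.propagate(self.est)
            pred_pos = rotate_about(plan.pos[seg], total, start)
            pred_vel = rotate_about(plan.vel[seg], total, (0.0, 0.0))
            r_pos = (real.observed.pos[seg] - pred_pos).reshape(-1)
            r_vel = (real.observed.vel[seg] - pred_vel).reshape(-1)
            h_pos = est_mod.measurement_jacobian(plan.pos[seg], total, start)
            h_vel = est_mod.measurement_jacobian(plan.vel[seg], total, (0.0, 0.0))
            residual = np.concatenate([r_pos, r_vel])
            jac = np.vstack([h_pos, h_vel])
            var = self._seg_var(len(seg))
            self.est = est_mod.gated_update(self.est, residual, jac, var, posterior)

        if not record:
            return None
        return TrialRecord(
            trial=self._trial_no,
            session=trial.session,
            block=trial.block,
            rotation_deg=trial.rotation_deg,
            clamp=trial.clamp,
            robot_held=trial.robot_held,
            error_deg=float(err),
            theta_y_deg=math.degrees(obs_rot.theta_y),
            lik_relevant=float(l1),
            lik_irrelevant=float(l0),
            relevance_prior=float(prior_rel),
            relevance_posterior=float(posterior),
            theta_b_deg=math.degrees(self.est.theta_b),
            theta_w_deg=math.degrees(self.est.theta_w),
            expected_world_deg=math.degrees(w_exp),
            total_compensation_deg=math.degrees(total),
        )

    def _seg_var(self, n: int) -> np.ndarray:
        return np.concatenate([
            np.full(2 * n, self.cfg.noise.sigma_pos**2),
            np.full(2 * n, self.cfg.noise.sigma_vel**2),
        ])

    # -- session boundary --------------------------------------------------
    def intersession_transition(self, washout_trials: int, next_day_relevance_init: float) -> None:
        """Natural (robot-absent) null movements, then a high day-start
        relevance.  The world estimate is guarded throughout and decays only
        through its forgetting factor; the body estimate de-adapts."""
        null = Trial(0.0, clamp=False, robot_held=False, session=0, block="IS")
        for _ in range(washout_trials):
            self.run_trial(null, record=False)
        self._forced_prior = float(next_day_relevance_init)
        self.rel = replace(self.rel, p_relevant=float(next_day_relevance_init))


def run_experiment(schedule: ExperimentSchedule, cfg: RunConfig, seed: int) -> list[TrialRecord]:
    """Run a full paradigm; bit-reproducible from (cfg, seed)."""
    sim = Simulator(cfg, seed)
    records: list[TrialRecord] = []
    current_session = schedule.trials[0].session if schedule.trials else 1
    for trial in schedule.trials:
        if trial.session > current_session:
            sim.intersession_transition(
                cfg.protocol.intersession_washout,
                cfg.relevance.day_start_relevance,
            )
            current_session = trial.session
        try:
            records.append(sim.run_trial(trial))
        except Exception as exc:
            raise RuntimeError(f"trial {sim._trial_no + 1} of {schedule.name} failed: {exc}") from exc
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# --------------------------------------------------------------------------
# summary metrics
# --------------------------------------------------------------------------

def paradigm_metrics(records: list[TrialRecord], criterion_deg: float = 5.0) -> dict:
    """Savings/interference/rebound readouts from a record sequence.

    Per block: mean |error| of the first 3 trials, trials-to-criterion (first
    trial with |error| < criterion; ``None`` if never attained), end-of-block
    estimates.  Globally: savings index (first-exposure minus re-exposure
    initial error) and, when a clamp block follows a counter block, the
    rebound trace summary.
    """
    df = records_to_frame(records)
    out: dict = {"criterion_deg": criterion_deg, "blocks": {}}
    for name in df["block"].unique():
        b = df[df["block"] == name]
        err = b["error_deg"].abs().to_numpy()
        below = np.nonzero(err < criterion_deg)[0]
        out["blocks"][str(name)] = {
            "n_trials": int(len(b)),
            "rotation_deg": float(b["rotation_deg"].iloc[-1]),
            "initial_error_deg": float(np.mean(err[:3])),
            "trials_to_criterion": int(below[0]) + 1 if len(below) else NOT_ATTAINED,
            "end_theta_b_deg": float(b["theta_b_deg"].iloc[-1]),
            "end_theta_w_deg": float(b["theta_w_deg"].iloc[-1]),
            "end_compensation_deg": float(b["total_compensation_deg"].iloc[-1]),
            "mean_abs_error_deg": float(err.mean()),
        }
    blocks = out["blocks"]
    if "A1" in blocks and "A2" in blocks:
        out["savings_index_deg"] = blocks["A1"]["initial_error_deg"] - blocks["A2"]["initial_error_deg"]
    if "C1" in blocks:
        c = df[df["block"] == "C1"]
        sign_a = math.copysign(1.0, blocks.get("A1", {}).get("rotation_deg", 1.0) or 1.0)
        comp = c["total_compensation_deg"].to_numpy() * sign_a
        out["clamp_start_compensation_deg"] = float(comp[0] * sign_a)
        out["rebound_peak_deg"] = float(np.max(comp))
        out["rebound_crossed_zero"] = bool(comp[0] <= 0.0 < np.max(comp))
    return out
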