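"""Run configuration: every model constant in one validated, YAML-round-trippable object.

All angles are degrees at this boundary (and in every output file); the
simulation core works in radians.  Every field has a documented default, so an
empty config file yields a complete, runnable configuration.  Unknown keys are
rejected to catch typos in hand-edited files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ArmParams",
    "ControllerConfig",
    "SimConfig",
    "NoiseConfig",
    "FilterConfig",
    "RelevanceConfig",
    "ProtocolConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for malformed, unknown-key, or out-of-range configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArmParams(_Strict):
    """Two-link planar arm constants (upper arm = link 1, forearm+hand = link 2).

    Defaults are a standard adult human set used throughout the reaching
    literature; every value is configurable and nothing downstream depends on
    these particular numbers.
    """

    l1: float = Field(0.33, gt=0, description="upper-arm length (m)")
    l2: float = Field(0.34, gt=0, description="forearm+hand length (m)")
    m1: float = Field(1.93, gt=0, description="upper-arm mass (kg)")
    m2: float = Field(1.52, gt=0, description="forearm+hand mass (kg)")
    i1: float = Field(0.0141, gt=0, description="upper-arm moment of inertia about its COM (kg m^2)")
    i2: float = Field(0.0188, gt=0, description="forearm+hand moment of inertia about its COM (kg m^2)")
    r1: float = Field(0.165, gt=0, description="shoulder-to-COM distance, link 1 (m)")
    r2: float = Field(0.19, gt=0, description="elbow-to-COM distance, link 2 (m)")
    viscosity: float = Field(0.2, ge=0, description="joint viscous damping (N m s/rad), both joints")
    shoulder: tuple[float, float] = Field((0.0, 0.0), description="shoulder position in the Cartesian frame (m)")

    @model_validator(mode="after")
    def _com_inside_links(self) -> "ArmParams":
        if self.r1 > self.l1 or self.r2 > self.l2:
            raise ValueError("center-of-mass distances must not exceed segment lengths")
        return self


class ControllerConfig(_Strict):
    """Joint-space PD feedback about the planned trajectory.

    Defaults give critically-damped-like behaviour for the default arm
    (kd ~ 2*sqrt(kp * effective inertia)).
    """

    kp: float = Field(25.0, gt=0, description="proportional gain (N m/rad)")
    kd: float = Field(3.0, gt=0, description="derivative gain (N m s/rad)")


class SimConfig(_Strict):
    """Movement geometry, timing and integration."""

    dt: float = Field(0.001, gt=0, le=0.001, description="integration step (s); fixed-step RK4")
    duration: float = Field(0.5, gt=0, description="movement time (s)")
    obs_rate: float = Field(60.0, gt=0, description="observation sampling rate (Hz) for the filter")
    n_via: int = Field(8, ge=2, description="equally spaced via points on the reference path")
    reach_distance: float = Field(0.1, gt=0, description="centre-to-target distance (m)")
    n_targets: int = Field(8, ge=1, description="targets equally spaced on the reach circle")
    workspace_center: tuple[float, float] = Field(
        (0.0, 0.45), description="start position of every reach, in the Cartesian frame (m)"
    )
    rotation_center: Literal["start"] = Field(
        "start", description="visual rotations are applied about the movement start"
    )
    error_sample: Literal["peak_speed", "endpoint"] = Field(
        "peak_speed", description="where along the path the angular reach error is read out"
    )


class NoiseConfig(_Strict):
    """Observation noise.  sigma_pos is the paper-level 0.01 m positional scale."""

    sigma_pos: float = Field(0.01, gt=0, description="cursor position noise per observed sample (m)")
    sigma_vel: float = Field(0.04, gt=0, description="cursor velocity noise per observed sample (m/s)")
    sigma_theta_deg: float = Field(2.5, gt=0, description="angular observation noise scale sigma_theta (deg)")


class FilterConfig(_Strict):
    """Disturbance-estimator constants.

    a_b, sigma_b, sigma_w are the model's free parameters (see docs/methods.md
    for how the shipped defaults were chosen); a_w is pinned near 1 so world
    estimates are retained over long periods.
    """

    a_b: float = Field(0.98, gt=0, le=1, description="body forgetting factor per update")
    a_w: float = Field(0.99999, gt=0, le=1, description="world forgetting factor per update")
    sigma_b_deg: float = Field(0.175, gt=0, description="body process noise per update (deg)")
    sigma_w_deg: float = Field(0.033, gt=0, description="world process noise per update (deg)")
    p0_scale: float = Field(10.0, gt=0, description="initial covariance = p0_scale * Q")
    updates_per_movement: int = Field(6, ge=1, description="parameter updates per movement")


class RelevanceConfig(_Strict):
    """Markov model for the world parameter's relevance."""

    m11: float = Field(0.999, gt=0.5, lt=1, description="P(relevant -> relevant) per movement")
    m22: float = Field(0.999, gt=0.5, lt=1, description="P(irrelevant -> irrelevant) per movement")
    day_start_relevance: float = Field(
        0.75, ge=0, le=1, description="relevance posterior at the start of a later session"
    )


class ProtocolConfig(_Strict):
    """Default block sizes for the built-in paradigms; all overridable per call."""

    rotation_deg: float = Field(30.0, description="disturbance magnitude A (deg)")
    adapt_trials: int = Field(80, ge=1, description="trials per adaptation block")
    washout_trials: int = Field(80, ge=1, description="robot-held washout block length")
    counter_trials: int = Field(20, ge=1, description="brief counter-block length (rebound)")
    clamp_trials: int = Field(100, ge=1, description="error-clamp block length")
    gradual_ramp_trials: int = Field(50, ge=1, description="linear ramp length for the gradual paradigm")
    intersession_washout: int = Field(
        300, ge=0, description="robot-absent natural movements simulated between sessions"
    )
    criterion_deg: float = Field(5.0, gt=0, description="|error| criterion for trials-to-criterion")


class RunConfig(_Strict):
    """Top-level configuration: arm, controller, noise, filter, relevance, protocol."""

    arm: ArmParams = Field(default_factory=ArmParams)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    sim: SimConfig = Field(default_factory=SimConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    relevance: RelevanceConfig = Field(default_factory=RelevanceConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    seed: int = Field(0, ge=0, description="base RNG seed")

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v >= 2**31:
            raise ValueError("seed must fit in a signed 32-bit integer")
        return v

    # -- convenience accessors (radians) -------------------------------------
    @property
    def sigma_theta(self) -> float:
        return math.radians(self.noise.sigma_theta_deg)

    @property
    def sigma_b(self) -> float:
        return math.radians(self.filter.sigma_b_deg)

    @property
    def sigma_w(self) -> float:
        return math.radians(self.filter.sigma_w_deg)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML (or JSON: YAML is a superset) config file into a RunConfig.

    An empty or absent file yields the full default configuration.  Unknown
    keys and out-of-range values raise :class:`ConfigError` naming the key.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:  # pragma: no cover - depends on parser message
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = cfg.model_dump(mode="json")
    path.write_text(yaml.safe_dump(data, sort_keys=False))
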