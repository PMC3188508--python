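"""Relevance inference for the world rotation parameter.

The world disturbance is gated by a binary latent relevance variable with
Markov dynamics.  Once per movement the observed cursor path is compared with
the path predicted when compensating only with the (always relevant) body
estimate; the single rotation angle theta_y that best maps the prediction onto
the observation summarizes the evidence.  Two likelihoods over theta_y — one
for "a world rotation of some value is acting" and one for "no relevant world
rotation" — feed a Bayesian update of the relevance posterior.

Closed forms
------------
With sigma = sigma_theta (angular observation noise scale):

* relevant:    L1(theta_y) = (1 - exp(-theta_y^2 / (4 sigma^2)) / sqrt(2)) / Z
  where Z = 2*pi - sqrt(2*pi)*sigma*erf(pi / (sqrt(2) sigma)) normalizes the
  prior (1 - exp(-theta^2 / 2 sigma^2)) / Z over (-pi, pi].  The form follows
  from the Gaussian product identity
  N(theta; theta_y, s^2) * exp(-theta^2/2s^2)
  = exp(-theta_y^2/4s^2) * N(theta; theta_y/2, s^2/2) / sqrt(2),
  integrated over theta (the truncation to (-pi, pi] is negligible because
  sigma << pi); both forms are checked against numerical quadrature in the
  test suite.
* irrelevant:  L0(theta_y) = N(theta_y; 0, 2 sigma^2), the convolution of the
  zero-centred observation model with the zero-mean N(0, sigma^2) prior.

L1 grows monotonically in |theta_y| and saturates at 1/Z; L0 decays like a
Gaussian, so large observed rotations are overwhelming evidence of relevance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .plant import Path

__all__ = [
    "RelevanceState",
    "ObservedRotation",
    "estimate_observed_rotation",
    "likelihood_relevant",
    "likelihood_irrelevant",
    "prior_normalizer",
    "propagate_prior",
    "movement_likelihoods",
    "posterior_from_prior",
    "update_relevance",
]


@dataclass(frozen=True)
class RelevanceState:
    """Posterior P(relevant), the Markov transition matrix and sigma_theta."""

    p_relevant: float = 0.5
    m11: float = 0.999
    m22: float = 0.999
    sigma_theta: float = math.radians(2.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_relevant <= 1.0:
            raise ValueError("relevance probability must lie in [0, 1]")
        if self.sigma_theta <= 0:
            raise ValueError("sigma_theta must be positive")

    @property
    def transition(self) -> np.ndarray:
        return np.array([[self.m11, 1 - self.m11], [1 - self.m22, self.m22]])


@dataclass(frozen=True)
class ObservedRotation:
    """Best-fit rotation mapping the body-only prediction onto the observation."""

    theta_y: float  # rad, in (-pi, pi]
    residual: float  # m, RMSE at the optimum
    degenerate: bool = False


def estimate_observed_rotation(observed: Path, predicted: Path) -> ObservedRotation:
    """Planar Procrustes angle between two paths sharing an origin.

    theta_y minimizes the RMSE between the observed positions and the
    predicted positions rotated by theta about the movement origin; the
    closed form is atan2 of the summed cross and dot products of the
    origin-centred samples.
    """
    if len(observed) != len(predicted):
        raise ValueError("paths must share the sample grid")
    origin = predicted.pos[0]
    a = predicted.pos - origin
    b = observed.pos - origin
    dot = float(np.einsum("ij,ij->", a, b))
    cross = float(np.einsum("i,i->", a[:, 0], b[:, 1]) - np.einsum("i,i->", a[:, 1], b[:, 0]))
    norm = float(np.einsum("ij,ij->", a, a))
    if norm < 1e-20 or (dot == 0.0 and cross == 0.0):
        return ObservedRotation(theta_y=0.0, residual=0.0, degenerate=True)
    theta = math.atan2(cross, dot)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    resid = b - a @ rot.T
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ObservedRotation(theta_y=theta, residual=rmse)


def prior_normalizer(sigma_theta: float) -> float:
    """Z: integral of 1 - exp(-theta^2 / 2 sigma^2) over (-pi, pi]."""
    return 2 * math.pi - math.sqrt(2 * math.pi) * sigma_theta * math.erf(
        math.pi / (math.sqrt(2) * sigma_theta)
    )


def likelihood_relevant(theta_y: float, sigma_theta: float) -> float:
    """Density of theta_y when a world rotation of unknown size is acting."""
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    z = prior_normalizer(sigma_theta)
    return (1.0 - math.exp(-(theta_y**2) / (4 * sigma_theta**2)) / math.sqrt(2)) / z


def likelihood_irrelevant(theta_y: float, sigma_theta: float) -> float:
    """Density of theta_y when no relevant world rotation is acting."""
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    var = 2 * sigma_theta**2
    return math.exp(-(theta_y**2) / (2 * var)) / math.sqrt(2 * math.pi * var)


def propagate_prior(state: RelevanceState) -> float:
    """One step of the Markov transition: prior P(relevant) for this movement."""
    p = state.p_relevant
    return state.m11 * p + (1 - state.m22) * (1 - p)


def movement_likelihoods(
    observed: ObservedRotation | None,
    sigma_theta: float,
    clamp: bool = False,
) -> tuple[float, float]:
    """(L1, L0) for one movement; uninformative (0.5, 0.5) on clamp trials and
    for degenerate observations."""
    if clamp or observed is None or observed.degenerate:
        return 0.5, 0.5
    return (
        likelihood_relevant(observed.theta_y, sigma_theta),
        likelihood_irrelevant(observed.theta_y, sigma_theta),
    )


def posterior_from_prior(prior: float, l1: float, l0: float) -> float:
    """Bayes rule for the binary relevance variable."""
    denom = l1 * prior + l0 * (1 - prior)
    if denom <= 0.0:
        raise FloatingPointError("degenerate relevance update: both likelihoods vanish")
    return l1 * prior / denom


def update_relevance(
    state: RelevanceState,
    observed: ObservedRotation | None,
    clamp: bool = False,
) -> RelevanceState:
    """Bayesian relevance update for one movement.

    The prior is the previous posterior passed through the transition matrix.
    On error-clamp trials (or degenerate observations) the evidence is
    uninformative and both likelihoods are held at 0.5, so the posterior
    simply relaxes toward 0.5 at the transition-matrix rate.
    """
    prior = propagate_prior(state)
    l1, l0 = movement_likelihoods(observed, state.sigma_theta, clamp)
    return replace(state, p_relevant=float(posterior_from_prior(prior, l1, l0)))
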