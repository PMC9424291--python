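"""Hypothesis model, evidence sampling and sequential Bayesian updating.

Each of the n hypotheses is an isotropic Gaussian in R^(n-1) whose means sit
at the vertices of a regular simplex (equal discriminability between all
pairs of choices).  Beliefs are propagated in the log domain with a
log-sum-exp marginal; the linear-domain Bayes rule and the two-choice SPRT
recursion are retained as independent reference paths for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .belief_geometry import NORMALIZATION_TOL, simplex_vertices

__all__ = [
    "HypothesisModel",
    "EvidenceSample",
    "LogBeliefState",
    "uniform_log_prior",
    "sample_evidence",
    "log_likelihoods",
    "bayes_update",
    "sprt_log_pr_update",
]

_EQUIDISTANCE_TOL = 1e-12


@dataclass(frozen=True)
class HypothesisModel:
    """n equivariant Gaussian evidence distributions with equidistant means."""

    n: int
    means: np.ndarray  # (n, n-1)
    sigma: float
    delta_mu: float

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        if self.n < 2:
            raise ValueError(f"need n >= 2 hypotheses, got {self.n}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if means.shape != (self.n, self.n - 1):
            raise ValueError(
                f"means must have shape {(self.n, self.n - 1)}, got {means.shape}"
            )
        diff = means[:, None, :] - means[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        off = dist[~np.eye(self.n, dtype=bool)]
        if np.any(np.abs(off - self.delta_mu) > _EQUIDISTANCE_TOL * max(1.0, self.delta_mu)):
            raise ValueError("means must be pairwise equidistant at delta_mu")

    @classmethod
    def create(cls, n: int, delta_mu: float = 1.0, sigma: float = 1.0) -> "HypothesisModel":
        """Build the model with simplex-vertex means (the standard task layout)."""
        return cls(n=n, means=simplex_vertices(n, delta_mu), sigma=sigma, delta_mu=delta_mu)


@dataclass(frozen=True)
class EvidenceSample:
    """One vector-valued observation at discrete step t >= 1."""

    x: np.ndarray
    t: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.t < 1:
            raise ValueError("time step must be >= 1")


@dataclass(frozen=True)
class LogBeliefState:
    """Log posterior over the n hypotheses; exp() sums to 1."""

    log_probs: np.ndarray

    def __post_init__(self) -> None:
        lp = np.asarray(self.log_probs, dtype=float)
        object.__setattr__(self, "log_probs", lp)
        if not np.all(np.isfinite(lp) | (lp == -np.inf)):
            raise ValueError("log probabilities must not contain NaN or +inf")
        if abs(logsumexp(lp)) > NORMALIZATION_TOL:
            raise ValueError("log-sum-exp of log probabilities must be 0")

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)


def uniform_log_prior(n: int) -> LogBeliefState:
    """The uniform prior 1/n each trial starts from."""
    return LogBeliefState(np.full(n, -math.log(n)))


def sample_evidence(
    model: HypothesisModel,
    true_index: int,
    rng: np.random.Generator,
    t: int = 1,
) -> EvidenceSample:
    """Draw one observation from the true hypothesis' Gaussian."""
    if not 0 <= true_index < model.n:
        raise ValueError(f"true_index {true_index} out of range for n={model.n}")
    x = rng.normal(loc=model.means[true_index], scale=model.sigma)
    return EvidenceSample(x=np.atleast_1d(x), t=t)


def log_likelihoods(model: HypothesisModel, x) -> np.ndarray:
    """Log density of the observation under each of the n hypotheses."""
    vec = x.x if isinstance(x, EvidenceSample) else np.asarray(x, dtype=float)
    if vec.shape != (model.n - 1,):
        raise ValueError(
            f"evidence must have dimension {model.n - 1}, got shape {vec.shape}"
        )
    d = model.n - 1
    sq = ((vec[None, :] - model.means) ** 2).sum(-1)
    return -0.5 * d * math.log(2.0 * math.pi * model.sigma**2) - sq / (2.0 * model.sigma**2)


def bayes_update(state: LogBeliefState, logL) -> LogBeliefState:
    """One sequential Bayes step in the log domain.

    The prior is the preceding posterior; the marginal is removed with a
    common subtractive log-sum-exp term, which keeps the state normalized
    over arbitrarily long trajectories.
    """
    logL = np.asarray(logL, dtype=float)
    if logL.shape != state.log_probs.shape:
        raise ValueError("likelihood vector shape must match the belief state")
    if np.any(np.isnan(logL)) or np.any(logL == np.inf):
        raise ValueError("log likelihoods must not contain NaN or +inf")
    lp = state.log_probs + logL
    return LogBeliefState(lp - logsumexp(lp))


def sprt_log_pr_update(log_pr: float, log_lr: float) -> float:
    """SPRT recursion: cumulative log probability ratio plus the new log LR."""
    if not (math.isfinite(log_pr) and math.isfinite(log_lr)):
        raise ValueError("sprt_log_pr_update requires finite inputs")
    return log_pr + log_lr
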