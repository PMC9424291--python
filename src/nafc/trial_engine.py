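"""Decision episodes: run to boundary crossing, assign reward, aggregate.

Two execution paths cover the same contract:

* :func:`run_trial` — the scalar reference implementation, one evidence
  sample and one Bayes step per loop iteration.  Used by the SPRT
  equivalence tests, which replay the identical sample stream through
  :func:`sprt_trial`.
* :func:`run_batch` / :func:`estimate_reward` — a vectorized engine that
  advances all still-active trials of a batch in lockstep.  This is what
  the landscape sweeps use; it is deterministic given its seed but consumes
  the RNG in a different order than the scalar path.

Rewards follow r = -W*e - c*T for terminated trials; unterminated trials
(no crossing within ``max_steps``) are flagged, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .accumulator import (
    HypothesisModel,
    bayes_update,
    log_likelihoods,
    sample_evidence,
    uniform_log_prior,
)
from .belief_geometry import log_odds
from .boundaries import BoundarySpec, boundary_value, crossing

__all__ = [
    "CostSpec",
    "TrialOutcome",
    "RewardEstimate",
    "run_trial",
    "sprt_trial",
    "run_batch",
    "estimate_reward",
    "OUTCOME_COLUMNS",
]

OUTCOME_COLUMNS = [
    "trial_id",
    "true_index",
    "chosen",
    "error",
    "T",
    "reward",
    "crossing_belief",
    "terminated",
]

DEFAULT_MAX_STEPS = 10_000

#: algebraic identity -W*mean_error - c*mean_T == mean_reward must hold to here
REWARD_IDENTITY_TOL = 1e-10


@dataclass(frozen=True)
class CostSpec:
    """Error cost W (equal across error types) and cost c per time step."""

    W: float = 1.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.W > 0:
            raise ValueError(f"W must be positive, got {self.W}")
        if self.c < 0:
            raise ValueError(f"c must be nonnegative, got {self.c}")

    @property
    def cost_ratio(self) -> float:
        return self.c / self.W

    def reward(self, error: int, T: int) -> float:
        return -self.W * error - self.c * T


@dataclass(frozen=True)
class TrialOutcome:
    chosen: int | None
    true_index: int
    error: int | None
    T: int
    reward: float | None
    crossing_belief: float | None
    terminated: bool


@dataclass(frozen=True)
class RewardEstimate:
    """Monte-Carlo aggregates over the terminated trials of one batch."""

    mean_reward: float
    reward_std: float
    mean_error: float
    mean_T: float
    n_trials: int
    n_unterminated: int


def run_trial(
    model: HypothesisModel,
    spec: BoundarySpec,
    costs: CostSpec,
    true_index: int,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TrialOutcome:
    """One decision episode: uniform prior, sample+update per step, stop at
    the first post-update crossing (checked from t=1, never on the prior)."""
    if not 0 <= true_index < model.n:
        raise ValueError(f"true_index {true_index} out of range for n={model.n}")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = uniform_log_prior(model.n)
    for t in range(1, max_steps + 1):
        x = sample_evidence(model, true_index, rng, t=t)
        state = bayes_update(state, log_likelihoods(model, x))
        probs = state.probs
        probs = probs / probs.sum()  # guard rounding before validation
        choice = crossing(probs, spec, rng=rng)
        if choice is not None:
            error = int(choice != true_index)
            return TrialOutcome(
                chosen=choice,
                true_index=true_index,
                error=error,
                T=t,
                reward=costs.reward(error, t),
                crossing_belief=float(probs[choice]),
                terminated=True,
            )
    return TrialOutcome(
        chosen=None,
        true_index=true_index,
        error=None,
        T=max_steps,
        reward=None,
        crossing_belief=None,
        terminated=False,
    )


def sprt_trial(
    model: HypothesisModel,
    theta_post: float,
    costs: CostSpec,
    true_index: int,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TrialOutcome:
    """Two-choice SPRT reference: accumulate log likelihood ratios to the
    log-odds-transformed posterior threshold.

    Consumes the RNG exactly like :func:`run_trial` with a flat boundary
    (one Gaussian vector per step), so on a shared seed the two must agree
    sample-for-sample.
    """
    if model.n != 2:
        raise ValueError("sprt_trial is defined for n=2 only")
    bound = log_odds(theta_post)
    log_pr = 0.0
    for t in range(1, max_steps + 1):
        x = sample_evidence(model, true_index, rng, t=t)
        logL = log_likelihoods(model, x)
        log_pr += logL[0] - logL[1]
        if log_pr > bound:
            choice = 0
        elif log_pr < -bound:
            choice = 1
        else:
            continue
        error = int(choice != true_index)
        belief = 1.0 / (1.0 + math.exp(-log_pr if choice == 0 else log_pr))
        return TrialOutcome(
            chosen=choice,
            true_index=true_index,
            error=error,
            T=t,
            reward=costs.reward(error, t),
            crossing_belief=belief,
            terminated=True,
        )
    return TrialOutcome(None, true_index, None, max_steps, None, None, False)


def _resolve_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def run_batch(
    model: HypothesisModel,
    spec: BoundarySpec,
    costs: CostSpec,
    n_trials: int,
    rng,
    max_steps: int = DEFAULT_MAX_STEPS,
    true_index: int | None = None,
) -> pd.DataFrame:
    """Vectorized batch of independent trials; returns one row per trial.

    The true hypothesis is drawn uniformly per trial (symmetric task) unless
    ``true_index`` pins it.  Columns: trial_id, true_index, chosen, error,
    T, reward, crossing_belief, terminated; unterminated rows carry NaN for
    chosen/error/reward/crossing_belief.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _resolve_rng(rng)
    n = model.n
    if true_index is None:
        true_idx = rng.integers(0, n, size=n_trials)
    else:
        if not 0 <= true_index < n:
            raise ValueError(f"true_index {true_index} out of range for n={n}")
        true_idx = np.full(n_trials, true_index, dtype=np.int64)

    log_probs = np.full((n_trials, n), -math.log(n))
    active = np.arange(n_trials)
    T = np.zeros(n_trials, dtype=np.int64)
    chosen = np.full(n_trials, -1, dtype=np.int64)
    cross_belief = np.full(n_trials, np.nan)

    means = model.means
    mu_sq = (means**2).sum(1)
    inv2s2 = 1.0 / (2.0 * model.sigma**2)

    for t in range(1, max_steps + 1):
        if active.size == 0:
            break
        x = rng.normal(loc=means[true_idx[active]], scale=model.sigma)
        # log L_i up to a common additive constant (absorbed by normalization)
        sq = (x**2).sum(1)[:, None] - 2.0 * x @ means.T + mu_sq[None, :]
        lp = log_probs[active] - sq * inv2s2
        lp -= logsumexp(lp, axis=1, keepdims=True)
        log_probs[active] = lp
        P = np.exp(lp)
        F = boundary_value(P, spec)
        above = P > F[:, None]
        hit = above.any(1)
        if hit.any():
            rows = np.flatnonzero(hit)
            masked = np.where(above[rows], P[rows], -np.inf)
            ch = masked.argmax(1)  # argmax-P winner; exact ties ~ measure zero
            idx = active[rows]
            chosen[idx] = ch
            T[idx] = t
            cross_belief[idx] = P[rows, ch]
            active = active[~hit]

    terminated = chosen >= 0
    T[~terminated] = max_steps
    error = np.where(terminated, (chosen != true_idx).astype(float), np.nan)
    reward = np.where(terminated, -costs.W * error - costs.c * T, np.nan)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "true_index": true_idx,
            "chosen": np.where(terminated, chosen, np.nan),
            "error": error,
            "T": T,
            "reward": reward,
            "crossing_belief": cross_belief,
            "terminated": terminated,
        }
    )


def summarize_batch(outcomes: pd.DataFrame, costs: CostSpec) -> RewardEstimate:
    """Aggregate a batch into a :class:`RewardEstimate` (terminated trials only)."""
    term = outcomes[outcomes["terminated"]]
    n_unterm = int((~outcomes["terminated"]).sum())
    if len(term) == 0:
        return RewardEstimate(
            mean_reward=math.nan,
            reward_std=math.nan,
            mean_error=math.nan,
            mean_T=math.nan,
            n_trials=len(outcomes),
            n_unterminated=n_unterm,
        )
    mean_error = float(term["error"].mean())
    mean_T = float(term["T"].mean())
    # enforce the exact algebraic decomposition rather than re-averaging rewards
    mean_reward = -costs.W * mean_error - costs.c * mean_T
    rewards = term["reward"].to_numpy()
    reward_std = float(rewards.std(ddof=1)) if len(rewards) > 1 else 0.0
    assert abs(mean_reward - rewards.mean()) < REWARD_IDENTITY_TOL * max(1.0, abs(mean_reward))
    return RewardEstimate(
        mean_reward=mean_reward,
        reward_std=reward_std,
        mean_error=mean_error,
        mean_T=mean_T,
        n_trials=len(outcomes),
        n_unterminated=n_unterm,
    )


def estimate_reward(
    model: HypothesisModel,
    spec: BoundarySpec,
    costs: CostSpec,
    n_trials: int,
    rng,
    max_steps: int = DEFAULT_MAX_STEPS,
    true_index: int | None = None,
) -> RewardEstimate:
    """Monte-Carlo estimate of mean reward, error and decision time."""
    outcomes = run_batch(model, spec, costs, n_trials, rng, max_steps, true_index)
    return summarize_batch(outcomes, costs)
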