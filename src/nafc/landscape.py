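"""Monte-Carlo reward landscapes over boundary parameters.

A landscape is a grid over (theta, alpha, beta) for one family and one cost
ratio c/W; each cell holds the reward estimate from an independent RNG
substream.  The near-optimal ("degenerate") subset is extracted with the
delta-acceptance rule: keep every cell x with

    mean_reward_x >= r_max - delta * spread_x

where r_max is the maximum mean reward of the noisy landscape and spread_x
is the per-trial reward standard deviation of that cell (the standard error
of the mean is available as an alternative).  Smoothed one-dimensional
sections through the landscape use Gaussian-process regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel

from .accumulator import HypothesisModel
from .boundaries import BoundarySpec
from .trial_engine import DEFAULT_MAX_STEPS, CostSpec, RewardEstimate, estimate_reward

__all__ = [
    "LandscapeGrid",
    "AcceptanceSet",
    "Section",
    "SectionSummary",
    "default_axes",
    "sweep_landscape",
    "acceptance_region",
    "landscape_sections",
]

GridKey = tuple[float, float, float]  # (theta, alpha, beta)

DEFAULT_DELTA = 0.02
DEFAULT_COST_RATIOS = (0.001, 0.04, 0.1)
DEFAULT_N_TRIALS = 5_000


def default_axes(
    family: str,
    n: int,
    n_theta: int = 15,
    n_alpha: int = 9,
    n_beta: int = 5,
) -> dict[str, np.ndarray]:
    """Default parameter grids: theta in (1/n+0.01, 0.99), alpha in [-20, 20],
    beta in [0, 5] (power) or [0, 3] (oscil)."""
    theta = np.linspace(1.0 / n + 0.01, 0.99, n_theta)
    if family == "flat":
        return {"theta": theta, "alpha": np.array([0.0]), "beta": np.array([0.0])}
    alpha = np.linspace(-20.0, 20.0, n_alpha)
    if family == "curve":
        return {"theta": theta, "alpha": alpha, "beta": np.array([0.0])}
    beta_hi = 5.0 if family == "power" else 3.0
    return {"theta": theta, "alpha": alpha, "beta": np.linspace(0.0, beta_hi, n_beta)}


@dataclass
class LandscapeGrid:
    family: str
    theta_axis: np.ndarray
    alpha_axis: np.ndarray
    beta_axis: np.ndarray
    cost_ratio: float
    cells: dict[GridKey, RewardEstimate]
    n_trials_per_cell: int
    n: int
    master_seed: int | None = None

    def estimate(self, theta: float, alpha: float = 0.0, beta: float = 0.0) -> RewardEstimate:
        return self.cells[(theta, alpha, beta)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (theta, alpha, beta), est in self.cells.items():
            rows.append(
                {
                    "family": self.family,
                    "theta": theta,
                    "alpha": alpha,
                    "beta": beta,
                    "cost_ratio": self.cost_ratio,
                    "mean_reward": est.mean_reward,
                    "reward_std": est.reward_std,
                    "mean_error": est.mean_error,
                    "mean_T": est.mean_T,
                    "n_trials": est.n_trials,
                    "n_unterminated": est.n_unterminated,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AcceptanceSet:
    """The delta-acceptance (degenerate, effectively optimal) subset."""

    delta: float
    r_max: float
    members: dict[GridKey, RewardEstimate]
    family: str
    cost_ratio: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (theta, alpha, beta), est in self.members.items():
            rows.append(
                {
                    "family": self.family,
                    "theta": theta,
                    "alpha": alpha,
                    "beta": beta,
                    "cost_ratio": self.cost_ratio,
                    "delta": self.delta,
                    "mean_reward": est.mean_reward,
                    "reward_std": est.reward_std,
                    "mean_error": est.mean_error,
                    "mean_T": est.mean_T,
                }
            )
        return pd.DataFrame(rows)

    @property
    def thetas(self) -> np.ndarray:
        return np.array(sorted({k[0] for k in self.members}))

    @property
    def alphas(self) -> np.ndarray:
        return np.array(sorted({k[1] for k in self.members}))


def sweep_landscape(
    model: HypothesisModel,
    family: str,
    axes: dict,
    cost_ratio: float,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    max_steps: int = DEFAULT_MAX_STEPS,
    W: float = 1.0,
) -> LandscapeGrid:
    """Estimate mean reward at every grid cell from independent substreams.

    One child seed per cell is spawned from the master seed in a fixed cell
    order, so the full table is bitwise reproducible.
    """
    theta_axis = np.atleast_1d(np.asarray(axes.get("theta"), dtype=float))
    alpha_axis = np.atleast_1d(np.asarray(axes.get("alpha", [0.0]), dtype=float))
    beta_axis = np.atleast_1d(np.asarray(axes.get("beta", [0.0]), dtype=float))
    if family == "flat":
        alpha_axis = np.array([0.0])
        beta_axis = np.array([0.0])
    elif family == "curve":
        beta_axis = np.array([0.0])
    for name, ax in (("theta", theta_axis), ("alpha", alpha_axis), ("beta", beta_axis)):
        if ax.size == 0:
            raise ValueError(f"axis {name!r} must not be empty")

    costs = CostSpec(W=W, c=cost_ratio * W)
    keys = [
        (float(t), float(a), float(b))
        for t in theta_axis
        for a in alpha_axis
        for b in beta_axis
    ]
    children = np.random.SeedSequence(seed).spawn(len(keys))
    cells: dict[GridKey, RewardEstimate] = {}
    for key, child in zip(keys, children):
        theta, alpha, beta = key
        spec = BoundarySpec(family=family, theta=theta, alpha=alpha, beta=beta)
        cells[key] = estimate_reward(
            model, spec, costs, n_trials, np.random.default_rng(child), max_steps
        )
    return LandscapeGrid(
        family=family,
        theta_axis=theta_axis,
        alpha_axis=alpha_axis,
        beta_axis=beta_axis,
        cost_ratio=cost_ratio,
        cells=cells,
        n_trials_per_cell=n_trials,
        n=model.n,
        master_seed=seed,
    )


def acceptance_region(
    grid: LandscapeGrid, delta: float = DEFAULT_DELTA, spread: str = "std"
) -> AcceptanceSet:
    """Cells whose mean reward is within delta spreads of the landscape max.

    ``spread="std"`` uses the per-trial reward standard deviation (default);
    ``spread="sem"`` uses the standard error of the cell mean.  Membership
    uses >= so delta=0 returns exactly the argmax cell(s).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if spread not in ("std", "sem"):
        raise ValueError("spread must be 'std' or 'sem'")
    finite = {k: e for k, e in grid.cells.items() if math.isfinite(e.mean_reward)}
    if not finite:
        raise ValueError("landscape has no terminated cells to accept from")
    r_max = max(e.mean_reward for e in finite.values())
    members = {}
    for key, est in finite.items():
        s = est.reward_std
        if spread == "sem":
            n_term = est.n_trials - est.n_unterminated
            s = s / math.sqrt(max(n_term, 1))
        if est.mean_reward >= r_max - delta * s:
            members[key] = est
    return AcceptanceSet(
        delta=delta,
        r_max=r_max,
        members=members,
        family=grid.family,
        cost_ratio=grid.cost_ratio,
    )


@dataclass
class Section:
    """One smoothed theta-section of the landscape at fixed alpha (and beta)."""

    alpha: float
    theta: np.ndarray
    raw_mean: np.ndarray
    smoothed_mean: np.ndarray
    band_low: np.ndarray  # 95% band
    band_high: np.ndarray
    peak_theta: float
    peak_mean: float
    peak_interval: tuple[float, float]


@dataclass
class SectionSummary:
    sections: list[Section]
    peaks_overlap: bool
    overlap_interval: tuple[float, float] | None


def _gp_smooth(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray):
    # RBF captures the landscape's smooth structure, DotProduct the linear
    # trend (lets a noiseless line be recovered exactly), White the MC noise
    kernel = (
        ConstantKernel(1.0, (1e-4, 1e4))
        * RBF(np.ptp(x) / 4 if np.ptp(x) > 0 else 1.0, (1e-3, 1e3))
        + DotProduct(1.0)
        + WhiteKernel(1e-6, (1e-16, 1e2))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=1e-13, normalize_y=True, n_restarts_optimizer=2,
        random_state=0,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x.reshape(-1, 1), y)
    mean, std = gp.predict(x_eval.reshape(-1, 1), return_std=True)
    return mean, std


def landscape_sections(
    grid: LandscapeGrid, alpha_values, beta: float = 0.0
) -> SectionSummary:
    """GP-smoothed theta-sections at the requested alpha values, with a 95%
    band and a summary of whether all section peaks' bands overlap."""
    sections = []
    for alpha in alpha_values:
        a = float(alpha)
        keys = [k for k in grid.cells if k[1] == a and k[2] == float(beta)]
        if not keys:
            raise ValueError(f"alpha={a} (beta={beta}) is not on the landscape grid")
        keys.sort()
        theta = np.array([k[0] for k in keys])
        raw = np.array([grid.cells[k].mean_reward for k in keys])
        smoothed, std = _gp_smooth(theta, raw, theta)
        lo = smoothed - 1.96 * std
        hi = smoothed + 1.96 * std
        ipk = int(np.argmax(smoothed))
        sections.append(
            Section(
                alpha=a,
                theta=theta,
                raw_mean=raw,
                smoothed_mean=smoothed,
                band_low=lo,
                band_high=hi,
                peak_theta=float(theta[ipk]),
                peak_mean=float(smoothed[ipk]),
                peak_interval=(float(lo[ipk]), float(hi[ipk])),
            )
        )
    lo_max = max(s.peak_interval[0] for s in sections)
    hi_min = min(s.peak_interval[1] for s in sections)
    overlap = lo_max <= hi_min
    return SectionSummary(
        sections=sections,
        peaks_overlap=overlap,
        overlap_interval=(lo_max, hi_min) if overlap else None,
    )
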