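"""Derived behavioral analyses.

Speed-accuracy trade-off points and their family-balanced mean curve,
implicit threshold dynamics (boundary-crossing beliefs sorted by decision
time, displayed on a log-odds scale and classified as increasing /
collapsing / static), the log-linear choice-count fit (Hick's law), and the
closed-form normalization identities for adding an option to a two-choice
belief state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .belief_geometry import log_odds
from .landscape import AcceptanceSet

__all__ = [
    "SATPoint",
    "ImplicitThresholdSeries",
    "HickFit",
    "sat_points",
    "mean_sat_curve",
    "implicit_threshold",
    "classify_dynamics",
    "hicks_law_fit",
    "renormalize_added_option",
    "belief_gap",
    "iia_distances",
    "offset_decrease",
]

CATEGORIES = ("increasing", "collapsing", "static")


@dataclass(frozen=True)
class SATPoint:
    cost_ratio: float
    family: str
    theta: float
    alpha: float
    beta: float
    mean_error: float
    mean_T: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_error <= 1.0):
            raise ValueError("mean_error must lie in [0, 1]")
        if self.mean_T < 1.0:
            raise ValueError("mean_T must be >= 1 step")


@dataclass
class ImplicitThresholdSeries:
    """Mean boundary-crossing belief as a function of decision time."""

    times: np.ndarray
    mean_crossing_belief: np.ndarray
    transformed_threshold: np.ndarray  # log-odds scale
    counts: np.ndarray
    category: str | None = None


@dataclass(frozen=True)
class HickFit:
    a: float  # intercept, steps
    b: float  # slope, steps per natural-log choice
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def sat_points(acceptance_sets: dict[float, AcceptanceSet]) -> list[SATPoint]:
    """One SAT point per accepted cell, labeled by cost ratio and family.

    ``acceptance_sets`` maps cost ratio -> AcceptanceSet (or a list of sets,
    e.g. one per family).  Empty sets yield no points.
    """
    points: list[SATPoint] = []
    for cost_ratio, sets in sorted(acceptance_sets.items()):
        if isinstance(sets, AcceptanceSet):
            sets = [sets]
        for acc in sets:
            for (theta, alpha, beta), est in sorted(acc.members.items()):
                points.append(
                    SATPoint(
                        cost_ratio=float(cost_ratio),
                        family=acc.family,
                        theta=theta,
                        alpha=alpha,
                        beta=beta,
                        mean_error=est.mean_error,
                        mean_T=est.mean_T,
                    )
                )
    return points


def mean_sat_curve(points: list[SATPoint]) -> pd.DataFrame:
    """Piecewise-linear mean SAT curve: per cost ratio, the family-balanced
    mean of (mean_T, mean_error) — i.e. the unweighted mean of family means —
    with vertices ordered by cost ratio.

    A single cost ratio yields a one-vertex (degenerate) curve, flagged via
    the ``degenerate`` column.
    """
    if not points:
        raise ValueError("mean_sat_curve needs at least one SAT point")
    df = pd.DataFrame([p.__dict__ for p in points])
    fam_means = df.groupby(["cost_ratio", "family"])[["mean_T", "mean_error"]].mean()
    curve = fam_means.groupby("cost_ratio").mean().reset_index().sort_values("cost_ratio")
    curve["degenerate"] = len(curve) < 2
    return curve.reset_index(drop=True)


def implicit_threshold(
    outcomes, min_count: int = 5, classify: bool = True
) -> ImplicitThresholdSeries:
    """Group boundary-crossing beliefs by decision time and average.

    ``outcomes`` is a batch DataFrame (run_batch) or list of TrialOutcome;
    only terminated trials contribute.  Times supported by fewer than
    ``min_count`` trials are dropped.  The transformed threshold is the
    log-odds of the mean crossing belief.
    """
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes
    else:
        df = pd.DataFrame(
            [
                {"T": o.T, "crossing_belief": o.crossing_belief, "terminated": o.terminated}
                for o in outcomes
            ]
        )
    term = df[df["terminated"]] if "terminated" in df else df
    if len(term) == 0:
        return ImplicitThresholdSeries(
            times=np.array([]),
            mean_crossing_belief=np.array([]),
            transformed_threshold=np.array([]),
            counts=np.array([], dtype=int),
            category=None,
        )
    grouped = term.groupby("T")["crossing_belief"].agg(["mean", "count"]).reset_index()
    grouped = grouped[grouped["count"] >= min_count].sort_values("T")
    times = grouped["T"].to_numpy(dtype=float)
    beliefs = grouped["mean"].to_numpy()
    counts = grouped["count"].to_numpy(dtype=int)
    transformed = np.array([log_odds(b) for b in beliefs])
    series = ImplicitThresholdSeries(
        times=times,
        mean_crossing_belief=beliefs,
        transformed_threshold=transformed,
        counts=counts,
    )
    if classify and len(times) >= 3:
        series.category = classify_dynamics(series)
    return series


def classify_dynamics(
    series: ImplicitThresholdSeries,
    z_crit: float = 2.0,
    rel_drift_tol: float = 0.05,
) -> str:
    """Categorize threshold dynamics from the weighted trend over time.

    Weighted least squares (weights = trial counts) of the transformed
    threshold on decision time.  The series is static when the slope is
    statistically indistinguishable from zero (within ``z_crit`` standard
    errors) or practically negligible: the fitted drift over the observed
    time span is below ``rel_drift_tol`` of the threshold scale
    (max(|weighted mean|, 1) on the log-odds axis).  Otherwise the slope
    sign decides increasing vs collapsing.  The practical floor keeps the
    category from being driven purely by statistical power at large trial
    counts.
    """
    if len(series.times) < 3:
        raise ValueError("classify_dynamics needs at least 3 time points")
    X = sm.add_constant(series.times)
    fit = sm.WLS(series.transformed_threshold, X, weights=series.counts).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not math.isfinite(se):
        se = 0.0
    span = float(series.times[-1] - series.times[0])
    wmean = float(np.average(series.transformed_threshold, weights=series.counts))
    scale = max(abs(wmean), 1.0)
    if abs(slope) <= z_crit * se or abs(slope) * span <= rel_drift_tol * scale:
        return "static"
    return "increasing" if slope > 0 else "collapsing"


def hicks_law_fit(mean_T_by_n: dict[int, float]) -> HickFit:
    """OLS fit of mean decision time on the natural log of the choice count."""
    if len(mean_T_by_n) < 3:
        raise ValueError("hicks_law_fit needs at least 3 distinct choice counts")
    ns = np.array(sorted(mean_T_by_n), dtype=float)
    y = np.array([mean_T_by_n[int(n)] for n in ns], dtype=float)
    x = np.log(ns)
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0 or ss_res <= 1e-14 * max(ss_tot, 1.0):
        r2 = 1.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return HickFit(a=float(a), b=float(b), r_squared=r2)


def _check_unit_interval(name: str, value: float) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return v


def renormalize_added_option(P0: float, P1: float, P2: float) -> tuple[float, float, float]:
    """Renormalized beliefs after adding a third option P2 to a two-choice
    state with P0 + P1 = 1: each belief is divided by (1 + P2)."""
    P0 = _check_unit_interval("P0", P0)
    P1 = _check_unit_interval("P1", P1)
    P2 = _check_unit_interval("P2", P2)
    if abs(P0 + P1 - 1.0) > 1e-9:
        raise ValueError(f"P0 + P1 must equal 1, got {P0 + P1}")
    z = 1.0 + P2
    return (P0 / z, P1 / z, P2 / z)


def belief_gap(Pi: float, Pj: float, P2: float) -> float:
    """Post-normalization difference in support, |Pi - Pj| / (1 + P2)."""
    Pi = _check_unit_interval("Pi", Pi)
    Pj = _check_unit_interval("Pj", Pj)
    P2 = _check_unit_interval("P2", P2)
    return abs(Pi - Pj) / (1.0 + P2)


def iia_distances(Pi: float, P2: float, T: float) -> tuple[float, float]:
    """Distances driving the IIA/regularity violations after adding option P2:
    d_T = T - Pi/(1+P2) (to the boundary) and d = Pi/(1+P2) - 1/3 (to the
    flat prior)."""
    Pi = _check_unit_interval("Pi", Pi)
    P2 = _check_unit_interval("P2", P2)
    if not (0.0 < T < 1.0):
        raise ValueError(f"boundary level T must lie in (0, 1), got {T}")
    scaled = Pi / (1.0 + P2)
    return (T - scaled, scaled - 1.0 / 3.0)


def offset_decrease(n: int) -> float:
    """Drop in the uniform prior per choice when adding one alternative:
    1/n - 1/(n+1) = 1/(n(n+1))."""
    if n < 2:
        raise ValueError(f"offset_decrease needs n >= 2, got {n}")
    return 1.0 / (n * (n + 1))
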