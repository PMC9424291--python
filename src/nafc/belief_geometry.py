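"""Geometry of the belief simplex.

The decision variable of the n-alternative task is a probability vector
P on the (n-1)-simplex.  This module provides the simplex-vertex layout
used for the evidence means, the probability/log-odds transform that maps
posterior thresholds to SPRT thresholds, and the combinatorial structure
(triplet subspaces, componentwise max-difference) that the nonlinear
boundary parameterization is built from.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import helmert
from scipy.special import expit

__all__ = [
    "BeliefVector",
    "TripletIndex",
    "simplex_vertices",
    "log_odds",
    "inverse_log_odds",
    "triplet_subspaces",
    "delta_max",
]

#: tolerance on sum(P) == 1; trajectories are renormalized every update
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class BeliefVector:
    """A normalized belief state over n >= 2 hypotheses."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("BeliefVector needs a 1-D vector with n >= 2 entries")
        if np.any(p < -NORMALIZATION_TOL) or np.any(p > 1 + NORMALIZATION_TOL):
            raise ValueError("belief components must lie in [0, 1]")
        if abs(p.sum() - 1.0) > NORMALIZATION_TOL:
            raise ValueError(f"belief components must sum to 1 (got {p.sum()!r})")

    @property
    def n(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class TripletIndex:
    """An ordered 3-subset of choice indices, one outer 3-D belief subspace."""

    indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) != 3:
            raise ValueError("TripletIndex needs exactly 3 indices")
        if not (idx[0] < idx[1] < idx[2]):
            raise ValueError("indices must be strictly increasing")
        if idx[0] < 0:
            raise ValueError("indices must be nonnegative")


def simplex_vertices(n: int, delta_mu: float = 1.0) -> np.ndarray:
    """Vertices of a regular (n-1)-simplex in R^(n-1), edge length ``delta_mu``.

    The construction centers the standard-basis simplex and projects it onto
    the hyperplane orthogonal to the all-ones direction with the Helmert
    orthonormal basis, so the result is deterministic, has centroid at the
    origin and all pairwise distances equal to ``delta_mu``.

    Returns an ``(n, n-1)`` array, one vertex (hypothesis mean) per row.
    """
    if n < 2:
        raise ValueError(f"need at least 2 vertices, got n={n}")
    if not delta_mu > 0:
        raise ValueError(f"delta_mu must be positive, got {delta_mu}")
    centered = np.eye(n) - 1.0 / n
    coords = centered @ helmert(n).T  # (n, n-1); pairwise distances sqrt(2)
    return coords * (delta_mu / math.sqrt(2.0))


def log_odds(theta_post: float) -> float:
    """log(p / (1 - p)) for p strictly inside (0, 1).

    Maps a posterior threshold to the equivalent SPRT log-probability-ratio
    threshold; the inverse of :func:`inverse_log_odds`.
    """
    p = float(theta_post)
    if not (0.0 < p < 1.0):
        raise ValueError(f"log_odds requires p in the open interval (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def inverse_log_odds(x: float) -> float:
    """Logistic inverse of :func:`log_odds`."""
    if not math.isfinite(x):
        raise ValueError("inverse_log_odds requires a finite argument")
    return float(expit(x))


def triplet_subspaces(n: int) -> list[TripletIndex]:
    """All C(n, 3) outer 3-D belief subspaces, as sorted index triplets."""
    if n < 3:
        raise ValueError(f"triplet subspaces need n >= 3 choices, got n={n}")
    return [TripletIndex(c) for c in itertools.combinations(range(n), 3)]


def delta_max(p3) -> float:
    """Maximum absolute pairwise difference among the 3 components of ``p3``."""
    p = np.asarray(p3, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"delta_max takes exactly 3 components, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("components must lie in [0, 1]")
    return float(p.max() - p.min())
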