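"""Nonlinear decision boundaries on the belief simplex.

A boundary is a scalar function F(P; theta, alpha, beta) of the full belief
vector, built from shape functions evaluated on every 3-choice subspace:

    F = theta * [1 + alpha / C(n,3) * sum_j f(dmax(P_j); beta) * prod(P_j)]

where the sum runs over all sorted triplets j of choice indices, P_j is the
corresponding 3-component belief sub-vector and dmax is its max-min spread.
A decision for choice i triggers when P_i > F (strict).  The product term
vanishes whenever at most two components are nonzero, so F collapses to the
edge-intersection value theta on every simplex edge.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .belief_geometry import BeliefVector

__all__ = ["FAMILIES", "BoundarySpec", "shape_fn", "boundary_value", "crossing"]

FAMILIES = ("flat", "curve", "power", "oscil")


@dataclass(frozen=True)
class BoundarySpec:
    """One boundary family with its parameters.

    ``flat`` ignores alpha and beta; ``curve`` ignores beta.  F is never
    clipped: theta*(1 + ...) may exceed 1 (unreachable boundary) or fall
    below the uniform prior (immediate crossing); the trial engine handles
    both explicitly.
    """

    family: str
    theta: float
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown boundary family {self.family!r}; choose from {FAMILIES}")
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "theta": self.theta,
            "alpha": self.alpha,
            "beta": self.beta,
        }


def shape_fn(family: str, dmax, beta: float = 0.0):
    """Shape function f(dmax; beta) of each family; vectorized over ``dmax``.

    flat -> 0, curve -> 1, power -> dmax**beta (with 0**0 == 1 so beta=0
    recovers curve everywhere), oscil -> cos(2*pi*beta*dmax).
    """
    d = np.asarray(dmax, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("dmax must lie in [0, 1]")
    if family == "flat":
        out = np.zeros_like(d)
    elif family == "curve":
        out = np.ones_like(d)
    elif family == "power":
        out = d**beta  # numpy defines 0.0**0.0 == 1.0, as required
    elif family == "oscil":
        out = np.cos(2.0 * math.pi * beta * d)
    else:
        raise ValueError(f"unknown boundary family {family!r}")
    return out if out.ndim else float(out)


def _as_prob_array(P) -> np.ndarray:
    if isinstance(P, BeliefVector):
        return P.probs
    return np.asarray(P, dtype=float)


def boundary_value(P, spec: BoundarySpec):
    """Evaluate F(P) for a belief vector or a batch with shape (..., n).

    For n=2 the boundary is a point on the belief line, F = theta by
    construction.  Scalar input returns a float; batched input returns an
    array of shape ``P.shape[:-1]``.
    """
    probs = _as_prob_array(P)
    if probs.ndim == 0 or probs.shape[-1] < 2:
        raise ValueError("belief vector needs n >= 2 components")
    n = probs.shape[-1]
    scalar = probs.ndim == 1
    if scalar and not isinstance(P, BeliefVector):
        BeliefVector(probs)  # validate

    if n == 2 or spec.family == "flat" or spec.alpha == 0.0:
        F = np.full(probs.shape[:-1], spec.theta)
        return float(F) if scalar else F

    triplets = list(itertools.combinations(range(n), 3))
    acc = np.zeros(probs.shape[:-1])
    for trip in triplets:
        pj = probs[..., trip]
        dmax = pj.max(-1) - pj.min(-1)
        acc += shape_fn(spec.family, dmax, spec.beta) * pj.prod(-1)
    F = spec.theta * (1.0 + (spec.alpha / len(triplets)) * acc)
    return float(F) if scalar else F


def crossing(P, spec: BoundarySpec, rng: np.random.Generator | None = None):
    """Index of the crossing choice, or ``None`` if no component exceeds F.

    Tie policy: among components strictly above F the winner is the argmax
    of P; exact argmax ties are broken uniformly at random from ``rng``
    (first index if no generator is supplied).
    """
    probs = _as_prob_array(P)
    if probs.ndim != 1:
        raise ValueError("crossing() takes a single belief vector")
    if not isinstance(P, BeliefVector):
        BeliefVector(probs)
    F = boundary_value(probs, spec)
    above = np.flatnonzero(probs > F)
    if above.size == 0:
        return None
    cand = above[probs[above] == probs[above].max()]
    if cand.size == 1 or rng is None:
        return int(cand[0])
    return int(rng.choice(cand))
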