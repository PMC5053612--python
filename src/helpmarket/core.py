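"""Primitive quantities of the competitive-helping market.

A biological market of ``N`` individuals in which every individual dispenses
its active help ``h`` plus a common passive amount ``k`` to the others, split
in proportion to the recipients' matching weights ``(h_i + k)**z``.  ``z`` is
the degree of matching: ``z = 0`` means every source splits its help equally,
``z = 1`` is perfect proportional matching, and large ``z`` approaches a
winner-per-source allocation.  Fitness is the diminishing-returns benefit of
the help received minus the cost of the help given,
``W = m*r/(m*x + r) - h``.

This module holds the allocation and payoff primitives for both the two-type
formulation (types ``p`` and ``m`` with proportions ``S_p``, ``S_m``) and the
fully heterogeneous formulation (one help level per individual).  Everything
here is deterministic and side-effect free; the simulators and the replicator
analysis build on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "TwoTypeState",
    "AgentPopulation",
    "TypeHelp",
    "help_received_two_type",
    "help_received_agents",
    "payoff",
    "two_type_payoffs",
    "payoff_gap",
    "legacy_r_single_mutant",
]

_COUNT_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Fixed parameters of the market.

    Parameters
    ----------
    N : int
        Number of individuals in the market (>= 2).
    m : float
        Maximum fitness benefit obtainable from receiving help.
    x : float
        Rate parameter of the diminishing-returns benefit, in (0, 1].
    k : float
        Passive (costless) help every individual dispenses, >= 0.
    z : float
        Degree of matching, >= 0.
    """

    N: int
    m: float = 1.0
    x: float = 0.5
    k: float = 0.0
    z: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not self.m > 0:
            raise ValueError(f"m must be positive, got {self.m!r}")
        if not 0 < self.x <= 1:
            raise ValueError(f"x must lie in (0, 1], got {self.x!r}")
        if self.k < 0:
            raise ValueError(f"k must be nonnegative, got {self.k!r}")
        if self.z < 0:
            raise ValueError(f"z must be nonnegative, got {self.z!r}")


@dataclass(frozen=True)
class TwoTypeState:
    """Proportions and active help levels of the two strategy types."""

    S_p: float
    S_m: float
    h_p: float
    h_m: float

    def __post_init__(self) -> None:
        if not (0 <= self.S_p <= 1 and 0 <= self.S_m <= 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(self.S_p + self.S_m - 1.0) > 1e-12:
            raise ValueError(
                f"S_p + S_m must equal 1, got {self.S_p + self.S_m!r}"
            )
        if self.h_p < 0 or self.h_m < 0:
            raise ValueError("help levels must be nonnegative")

    def swapped(self) -> "TwoTypeState":
        """The same state with the two type labels exchanged."""
        return TwoTypeState(self.S_m, self.S_p, self.h_m, self.h_p)


@dataclass(frozen=True)
class AgentPopulation:
    """Per-individual active help levels plus the shared passive help."""

    h: np.ndarray
    k: float = 0.0

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ValueError("h must be a 1-d array of length >= 2")
        if np.any(h < 0):
            raise ValueError("help levels must be nonnegative")
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        object.__setattr__(self, "h", h)

    @property
    def N(self) -> int:
        return self.h.size


class TypeHelp(NamedTuple):
    """Help received per individual of each type."""

    r_p: float
    r_m: float


def matching_weight(h, k: float, z: float):
    """Matching weight ``(h + k)**z`` with the convention ``0**0 = 1``.

    The convention makes ``z = 0`` mean an unconditional equal split even for
    individuals dispensing nothing.
    """
    return (np.asarray(h, dtype=float) + k) ** z


def _type_counts(state: TwoTypeState, N: int) -> tuple[int, int]:
    n_p = state.S_p * N
    n_m = state.S_m * N
    if abs(n_p - round(n_p)) > _COUNT_TOL or abs(n_m - round(n_m)) > _COUNT_TOL:
        raise ValueError(
            f"S_p*N and S_m*N must be integers (got {n_p!r}, {n_m!r}); "
            "choose N divisible by the proportion grid"
        )
    return int(round(n_p)), int(round(n_m))


def help_received_two_type(state: TwoTypeState, params: ModelParams) -> TypeHelp:
    """Help received per individual of each type under proportional matching.

    Each of the ``S_i * N`` members of type ``i`` dispenses ``h_i + k``, split
    among the other ``N - 1`` individuals in proportion to their matching
    weights ``(h + k)**z``.  A type with zero members reports ``r = 0`` by
    convention.  A source whose recipients all carry zero weight splits its
    help equally (the ``z = 0`` limit), preserving conservation.
    """
    n_p, n_m = _type_counts(state, params.N)
    r = _two_type_r_counts(n_p, n_m, state.h_p, state.h_m, params)
    return TypeHelp(*r)


def _two_type_r_counts(
    n_p: float, n_m: float, h_p: float, h_m: float, params: ModelParams
) -> tuple[float, float]:
    """Two-type allocation with (possibly fractional) type counts.

    Fractional / off-simplex counts arise only inside the replicator Jacobian,
    where the type counts are treated as continuous coordinates.
    """
    k, z = params.k, params.z
    N = n_p + n_m
    w_p = float(matching_weight(h_p, k, z))
    w_m = float(matching_weight(h_m, k, z))
    d_p, d_m = h_p + k, h_m + k

    # recipient pool seen by a source of each type (its own weight excluded)
    pool_p = (n_p - 1) * w_p + n_m * w_m
    pool_m = n_p * w_p + (n_m - 1) * w_m

    def share(w_recipient: float, pool: float) -> float:
        if pool > 0:
            return w_recipient / pool
        # degenerate pool: every recipient has zero weight -> equal split
        return 1.0 / (N - 1)

    r_p = 0.0
    if n_p != 0:
        r_p = (n_p - 1) * d_p * share(w_p, pool_p) + n_m * d_m * share(w_p, pool_m)
    r_m = 0.0
    if n_m != 0:
        r_m = n_p * d_p * share(w_m, pool_p) + (n_m - 1) * d_m * share(w_m, pool_m)
    return r_p, r_m


def help_received_agents(pop: AgentPopulation, z: float) -> np.ndarray:
    """Per-individual help received in a fully heterogeneous population.

    ``r_i = sum_{j != i} (h_j + k) * (h_i + k)**z / sum_{l != j} (h_l + k)**z``.

    A source's recipients share it in proportion to their weights, so the
    share of recipient ``i`` in source ``j``'s pool does not depend on which
    other recipients exist; this allows an O(N) evaluation.  Degenerate pools
    (all recipients at zero weight) fall back to an equal split.
    """
    if z < 0:
        raise ValueError("z must be nonnegative")
    h, k = pop.h, pop.k
    n = pop.N
    w = matching_weight(h, k, z)
    d = h + k
    total_w = w.sum()
    pools = total_w - w  # pool of each source j

    r = np.zeros(n)
    ok = pools > 0
    # sum over non-degenerate sources of d_j / pool_j, minus own term
    coef = np.where(ok, d / np.where(ok, pools, 1.0), 0.0)
    c_all = coef.sum()
    r = w * (c_all - coef)
    # degenerate sources split equally among the other n-1 individuals
    if not ok.all():
        bad = ~ok
        equal = d[bad].sum() / (n - 1)
        r += equal
        # a degenerate source does not receive its own equal-split share
        r[bad] -= d[bad] / (n - 1)
    return r


def payoff(r: float, h: float, m: float, x: float):
    """Fitness payoff ``W = m*r/(m*x + r) - h``: diminishing-returns benefit
    of help received minus the cost of active help given."""
    if m <= 0 or not 0 < x <= 1:
        raise ValueError("require m > 0 and 0 < x <= 1")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("help received must be nonnegative")
    out = m * r / (m * x + r) - h
    return float(out) if out.ndim == 0 else out


def two_type_payoffs(state: TwoTypeState, params: ModelParams) -> tuple[float, float]:
    """(W_p, W_m); a type with zero members reports W = 0 by convention."""
    n_p, n_m = _type_counts(state, params.N)
    r_p, r_m = _two_type_r_counts(n_p, n_m, state.h_p, state.h_m, params)
    W_p = payoff(r_p, state.h_p, params.m, params.x) if n_p else 0.0
    W_m = payoff(r_m, state.h_m, params.m, params.x) if n_m else 0.0
    return W_p, W_m


def payoff_gap(state: TwoTypeState, params: ModelParams) -> float:
    """``W_m - W_p``; zero at every equilibrium with both types present."""
    W_p, W_m = two_type_payoffs(state, params)
    return W_m - W_p


def legacy_r_single_mutant(N: int, h_p: float, h_m: float) -> float:
    """Help received by a single mutant among ``N - 1`` residents.

    The original single-mutant formula at perfect matching (z = 1, k = 0):
    ``r = (N-1) * h_p * h_m / (h_m + (N-2) * h_p)``.  A market with no help at
    all returns 0.
    """
    if N < 3:
        raise ValueError("N must be >= 3")
    if h_p < 0 or h_m < 0:
        raise ValueError("help levels must be nonnegative")
    denom = h_m + (N - 2) * h_p
    if denom == 0:
        return 0.0
    return (N - 1) * h_p * h_m / denom
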