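"""Replicator dynamics of the two-type market: ODEs, closed-form equilibria,
Jacobian stability, and invasion analysis.

The proportions of the two types evolve by the replicator equations

    dS_i/dt = S_i * (W_i - (S_p W_p + S_m W_m)),    i in {p, m},

with the payoffs of :mod:`helpmarket.core` evaluated at the (fixed) help
levels ``h_p``, ``h_m``.  On the simplex ``S_p + S_m = 1`` the flow factors as
``dS_m/dt = S_m (1 - S_m)(W_m - W_p)``, so the equilibria are the two
monomorphic corners plus every state with equal payoffs.  Equal help levels
give equal payoffs at *every* proportion, so ``h_p = h_m`` is a neutral line
of equilibria rather than an isolated interior point.

Closed forms
------------
* symmetric optimum (both types at the same help, equal proportions):
  ``h* = m(-x + sqrt(x (N-2)((z+1)N - 1) / 2) / (N-1)) - k``, with large-N
  limit ``(-x + sqrt(x (z+1)/2)) m - k``;
* monomorphic optimum (a single type present):
  ``h* = (-x + sqrt(x)) m - k``, independent of ``z`` and ``N``.

At a monomorphic corner with the extinct type providing no help and ``k = 0``
the Jacobian of the two-coordinate system has the repeated eigenvalue
``h*(h* + m x - m)/(h* + m x)`` (multiplicity 2), negative exactly when
``h* < m(1 - x)``.  With the symmetric optimum this threshold is equivalent
to ``z < 2/x - 1``, which is also where the symmetric payoff changes sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    AgentPopulation,
    ModelParams,
    TwoTypeState,
    _two_type_r_counts,
    help_received_agents,
    payoff,
)

__all__ = [
    "Trajectory",
    "EquilibriumReport",
    "BoundarySolutions",
    "InvasionReport",
    "replicator_rhs",
    "integrate_replicator",
    "boundary_solutions",
    "optimal_help_symmetric",
    "optimal_help_monomorphic",
    "replicator_jacobian",
    "jacobian_stability",
    "invasion_analysis",
    "corner_eigenvalue",
]


def _payoffs_unconstrained(
    S_p: float, S_m: float, h_p: float, h_m: float, params: ModelParams
) -> tuple[float, float]:
    """Payoffs with the type counts treated as continuous coordinates.

    Used by the replicator right-hand side and its Jacobian, where
    ``(S_p, S_m)`` may sit slightly off the simplex; the benefit term is the
    smooth extension of the on-simplex payoff.
    """
    r_p, r_m = _two_type_r_counts(
        S_p * params.N, S_m * params.N, h_p, h_m, params
    )
    m, x = params.m, params.x
    W_p = m * r_p / (m * x + r_p) - h_p
    W_m = m * r_m / (m * x + r_m) - h_m
    return W_p, W_m


def _rhs(S_p, S_m, h_p, h_m, params: ModelParams) -> np.ndarray:
    W_p, W_m = _payoffs_unconstrained(S_p, S_m, h_p, h_m, params)
    mean = S_p * W_p + S_m * W_m
    return np.array([S_p * (W_p - mean), S_m * (W_m - mean)])


def replicator_rhs(state: TwoTypeState, params: ModelParams) -> tuple[float, float]:
    """Time derivatives ``(dS_p/dt, dS_m/dt)`` of the type proportions."""
    d = _rhs(state.S_p, state.S_m, state.h_p, state.h_m, params)
    return float(d[0]), float(d[1])


@dataclass
class Trajectory:
    """Time-indexed record of an integrated replicator run."""

    times: np.ndarray
    S_p: np.ndarray
    S_m: np.ndarray
    h_p: float
    h_m: float
    W_p: np.ndarray
    W_m: np.ndarray
    converged: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "S_p": self.S_p,
                "S_m": self.S_m,
                "h_p": self.h_p,
                "h_m": self.h_m,
                "W_p": self.W_p,
                "W_m": self.W_m,
            }
        )

    @property
    def terminal(self) -> TwoTypeState:
        s = self.S_m[-1]
        s = min(max(s, 0.0), 1.0)
        return TwoTypeState(1.0 - s, s, self.h_p, self.h_m)


def integrate_replicator(
    state0: TwoTypeState,
    params: ModelParams,
    horizon: float,
    tol: float = 1e-8,
    *,
    renormalize: bool = True,
    offset: tuple[float, float] = (0.0, 0.0),
    n_samples: int = 201,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the replicator ODEs from ``state0`` for ``horizon`` time.

    ``renormalize`` projects every sample back onto the simplex (drift of the
    raw integrator is already tiny).  ``offset`` shifts the initial
    ``(S_p, S_m)`` off the simplex, which together with
    ``renormalize=False`` exposes the radial eigenvalue of the
    two-coordinate system (the simplex is restored when the mean payoff is
    positive and repels when it is negative).
    """
    if horizon <= 0 or tol <= 0:
        raise ValueError("horizon and tol must be positive")
    h_p, h_m = state0.h_p, state0.h_m
    y0 = np.array([state0.S_p + offset[0], state0.S_m + offset[1]])
    sol = solve_ivp(
        lambda t, y: _rhs(y[0], y[1], h_p, h_m, params),
        (0.0, horizon),
        y0,
        method=method,
        t_eval=np.linspace(0.0, horizon, n_samples),
        rtol=min(1e-8, tol),
        atol=min(1e-10, tol * 1e-2),
    )
    S_p, S_m = sol.y
    if renormalize:
        total = S_p + S_m
        S_p, S_m = S_p / total, S_m / total
    W_p = np.empty_like(S_p)
    W_m = np.empty_like(S_m)
    for i in range(S_p.size):
        W_p[i], W_m[i] = _payoffs_unconstrained(S_p[i], S_m[i], h_p, h_m, params)
    residual = np.linalg.norm(_rhs(S_p[-1], S_m[-1], h_p, h_m, params))
    converged = bool(residual <= tol)
    if not converged:
        warnings.warn(
            f"replicator trajectory did not reach an equilibrium within "
            f"horizon={horizon} (terminal |rhs|={residual:.3g})",
            stacklevel=2,
        )
    return Trajectory(sol.t, S_p, S_m, h_p, h_m, W_p, W_m, converged)


@dataclass(frozen=True)
class BoundarySolutions:
    """Solutions of the equal-payoff condition ``W_m = W_p``.

    ``symmetric_family`` describes the continuum of equal-help solutions;
    ``points`` are the two boundary solutions where one type provides no help
    and the other provides ``m - m x`` (both payoffs are then zero, at
    perfect matching with no passive help).
    """

    symmetric_family: str
    points: tuple[tuple[float, float], tuple[float, float]]


def boundary_solutions(params: ModelParams) -> BoundarySolutions:
    b = params.m - params.m * params.x
    return BoundarySolutions(
        symmetric_family="h_p == h_m (any common help level, any proportions)",
        points=((0.0, b), (b, 0.0)),
    )


def optimal_help_symmetric(params: ModelParams, *, large_n: bool = False) -> float:
    """Optimal common help when both types match each other at equal
    proportions.

    Maximizes a type's payoff with respect to its own help, all individuals
    of both types holding the same level; clamped at 0 when passive help
    already exceeds the interior optimum.  ``large_n`` evaluates the
    ``N -> inf`` limit ``(-x + sqrt(x (z+1)/2)) m - k``.
    """
    m, x, k, z, N = params.m, params.x, params.k, params.z, params.N
    if large_n:
        root = math.sqrt(x * (z + 1) / 2)
    else:
        if N < 3:
            raise ValueError("symmetric optimum requires N >= 3")
        root = math.sqrt(x * (N - 2) * ((z + 1) * N - 1) / 2) / (N - 1)
    return max(0.0, (-x + root) * m - k)


def optimal_help_monomorphic(params: ModelParams) -> float:
    """Optimal help of a lone type (``S = 1``): ``(-x + sqrt(x)) m - k``,
    independent of the degree of matching and the population size."""
    m, x, k = params.m, params.x, params.k
    return max(0.0, (-x + math.sqrt(x)) * m - k)


def corner_eigenvalue(h_star: float, params: ModelParams) -> float:
    """The repeated corner eigenvalue ``h*(h* + m x - m)/(h* + m x)``."""
    m, x = params.m, params.x
    return h_star * (h_star + m * x - m) / (h_star + m * x)


@lru_cache(maxsize=1)
def _symbolic_jacobian():
    """Lambdified analytic Jacobian of the two-coordinate replicator system."""
    import sympy as sp

    Sp, Sm, hp, hm, N, m, x, k, z = sp.symbols(
        "S_p S_m h_p h_m N m x k z", real=True
    )
    wp, wm = (hp + k) ** z, (hm + k) ** z
    pool_p = (Sp * N - 1) * wp + Sm * N * wm
    pool_m = Sp * N * wp + (Sm * N - 1) * wm
    rp = (Sp * N - 1) * (hp + k) * wp / pool_p + Sm * N * (hm + k) * wp / pool_m
    rm = Sp * N * (hp + k) * wm / pool_p + (Sm * N - 1) * (hm + k) * wm / pool_m
    Wp = m * rp / (m * x + rp) - hp
    Wm = m * rm / (m * x + rm) - hm
    mean = Sp * Wp + Sm * Wm
    F = sp.Matrix([Sp * (Wp - mean), Sm * (Wm - mean)])
    J = F.jacobian([Sp, Sm])
    return sp.lambdify((Sp, Sm, hp, hm, N, m, x, k, z), J, modules="numpy")


def replicator_jacobian(
    state: TwoTypeState, params: ModelParams, *, method: str = "analytic"
) -> np.ndarray:
    """Jacobian of ``(dS_p/dt, dS_m/dt)`` with respect to ``(S_p, S_m)``,
    the two proportions treated as independent coordinates.

    ``method="analytic"`` differentiates the closed-form right-hand side
    symbolically (cached, lambdified); ``method="fd"`` uses central finite
    differences.
    """
    S_p, S_m, h_p, h_m = state.S_p, state.S_m, state.h_p, state.h_m
    if method == "analytic":
        J = _symbolic_jacobian()(
            S_p, S_m, h_p, h_m, params.N, params.m, params.x, params.k, params.z
        )
        return np.asarray(J, dtype=float)
    if method == "fd":
        eps = 1e-7
        J = np.zeros((2, 2))
        for col, (dp, dm) in enumerate(((eps, 0.0), (0.0, eps))):
            f_hi = _rhs(S_p + dp, S_m + dm, h_p, h_m, params)
            f_lo = _rhs(S_p - dp, S_m - dm, h_p, h_m, params)
            J[:, col] = (f_hi - f_lo) / (2 * eps)
        return J
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EquilibriumReport:
    """Located equilibrium with its eigenvalues and a stability label.

    ``eigenvalues`` come from the two-coordinate (unconstrained) Jacobian;
    ``constrained_eigenvalue`` is the single eigenvalue of the flow reduced
    to the simplex, ``d/dS_m [S_m (1 - S_m)(W_m - W_p)]``.
    """

    location: TwoTypeState
    eigenvalues: np.ndarray
    constrained_eigenvalue: float
    classification: str

    @property
    def attracting(self) -> bool:
        return self.classification in ("stable", "neutral-line")


def _classify(eigs: np.ndarray, tol: float) -> str:
    re = np.real(eigs)
    if np.any(re > tol):
        return "unstable"
    n_zero = int(np.sum(np.abs(re) <= tol))
    if n_zero == 0:
        return "stable"
    if n_zero < re.size:
        return "neutral-line"
    return "non-hyperbolic"


def jacobian_stability(
    at: TwoTypeState,
    params: ModelParams,
    *,
    equilibrium_tol: float = 1e-8,
    eig_tol: float = 1e-7,
    method: str = "analytic",
) -> EquilibriumReport:
    """Eigenvalue stability classification of an equilibrium of the
    replicator flow.

    Rejects states that are not equilibria (``|rhs| > equilibrium_tol``).
    Classification: all eigenvalue real parts negative -> ``stable``; any
    positive -> ``unstable``; a zero eigenvalue beside negative ones ->
    ``neutral-line`` (the equal-help family); only zeros ->
    ``non-hyperbolic``.
    """
    residual = np.linalg.norm(_rhs(at.S_p, at.S_m, at.h_p, at.h_m, params))
    if residual > equilibrium_tol:
        raise ValueError(
            f"state is not an equilibrium (|rhs| = {residual:.3g} > "
            f"{equilibrium_tol:.3g})"
        )
    J = replicator_jacobian(at, params, method=method)
    eigs = np.linalg.eigvals(J)

    # flow reduced to the simplex: g(S_m) = S_m (1 - S_m)(W_m - W_p)
    def g(s: float) -> float:
        W_p, W_m = _payoffs_unconstrained(1.0 - s, s, at.h_p, at.h_m, params)
        return s * (1.0 - s) * (W_m - W_p)

    eps = 1e-6
    s0 = min(max(at.S_m, eps), 1.0 - eps) if 0 < at.S_m < 1 else at.S_m
    constrained = (g(s0 + eps) - g(s0 - eps)) / (2 * eps)
    return EquilibriumReport(at, eigs, float(constrained), _classify(eigs, eig_tol))


@dataclass(frozen=True)
class InvasionReport:
    """Invasion of helping (at level ``H``) into a population of non-helpers.

    ``E_resident`` is a non-helper's payoff in the all-non-helper market,
    ``E_lone_invader`` the payoff of a single helper (equal to ``-H``: its
    help is dispensed but, with ``k = 0``, nobody reciprocates), and
    ``min_invaders`` the smallest number of simultaneous helpers that makes a
    helper's payoff positive (``None`` if no number does).  No-help is an ESS
    exactly when a lone invader does strictly worse than a resident.
    """

    H: float
    E_resident: float
    E_lone_invader: float
    min_invaders: int | None
    no_help_is_ess: bool


def invasion_analysis(H: float, params: ModelParams) -> InvasionReport:
    """Payoffs for helping at level ``H`` against an otherwise helpless
    population, computed by explicit per-source allocation (``k = 0``)."""
    if H < 0:
        raise ValueError("H must be nonnegative")
    if params.k != 0:
        raise ValueError("invasion analysis applies to the k = 0 regime")
    N, m, x, z = params.N, params.m, params.x, params.z

    def helper_payoff(j: int) -> float:
        h = np.zeros(N)
        h[:j] = H
        r = help_received_agents(AgentPopulation(h, k=0.0), z)
        return payoff(float(r[0]), H, m, x)

    resident = payoff(0.0, 0.0, m, x)  # nothing received, nothing spent
    lone = helper_payoff(1) if H > 0 else resident
    min_invaders = None
    if H > 0:
        for j in range(1, N + 1):
            if helper_payoff(j) > 0:
                min_invaders = j
                break
    return InvasionReport(
        H=H,
        E_resident=resident,
        E_lone_invader=lone,
        min_invaders=min_invaders,
        no_help_is_ess=(H == 0) or lone < resident,
    )
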