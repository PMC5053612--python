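"""Two-type simulation: homogeneous types incrementally mutate their help.

Each time step, both types simultaneously propose a change of one increment
to the help they provide and evaluate the expected payoff of the change
against the help the *other* type provided in the previous step (the lagged
snapshot); the change is adopted only if it strictly beats the current
payoff.  Proportions are either held fixed or allowed to evolve: after the
help update, members of the lower-payoff type switch to the other type with
probability proportional to the payoff difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ModelParams, TwoTypeState, two_type_payoffs

__all__ = [
    "SimConfig",
    "TypeSimResult",
    "step_types",
    "run_fixed_proportions",
    "basin_map",
    "proportion_sweep",
    "run_evolving_proportions",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings shared by the type-based and agent-based engines.

    ``mutation_increment`` is the step by which a candidate help level
    differs from the current one (default 0.001); by default one direction
    (+/-) is sampled per step, ``both_directions`` evaluates both and takes
    the best improving one.  Convergence is declared after
    ``convergence_window`` consecutive steps without an accepted change.
    ``switch_fraction_scale`` converts a payoff difference into the expected
    switching probability when proportions evolve, capped at ``switch_cap``
    of the switching type per step.
    """

    mutation_increment: float = 0.001
    max_steps: int = 200_000
    convergence_window: int = 500
    tolerance: float = 0.01
    switch_fraction_scale: float = 1.0
    switch_cap: float = 0.1
    both_directions: bool = False
    seed: int | None = None
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.mutation_increment <= 0:
            raise ValueError("mutation_increment must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.switch_fraction_scale < 0 or not 0 < self.switch_cap <= 1:
            raise ValueError("invalid switching settings")


@dataclass
class TypeSimResult:
    """Outcome of a two-type run: final state, payoffs, label, trajectory."""

    state: TwoTypeState
    W_p: float
    W_m: float
    converged: bool
    label: str
    trajectory: pd.DataFrame


def _label(h_p: float, h_m: float, tol: float) -> str:
    if h_p <= tol and h_m <= tol:
        return "collapse"
    if h_p <= tol < h_m:
        return "p-quits"
    if h_m <= tol < h_p:
        return "m-quits"
    if abs(h_p - h_m) <= tol:
        return "competitive"
    return "mixed"


def _expected_payoff_p(
    h_p: float, h_m_lagged: float, state: TwoTypeState, params: ModelParams
) -> float:
    """Type-p payoff if all its members held ``h_p`` while type m stayed at
    its lagged level (types are homogeneous, so the whole type moves)."""
    trial = TwoTypeState(state.S_p, state.S_m, h_p, h_m_lagged)
    return two_type_payoffs(trial, params)[0]


def _expected_payoff_m(
    h_m: float, h_p_lagged: float, state: TwoTypeState, params: ModelParams
) -> float:
    trial = TwoTypeState(state.S_p, state.S_m, h_p_lagged, h_m)
    return two_type_payoffs(trial, params)[1]


def _propose(
    h: float, current: float, evaluate, delta: float, both: bool, rng
) -> float:
    """Greedy acceptance of a one-increment candidate against the lagged
    snapshot; never below zero, only strict improvements accepted."""
    if both:
        candidates = [max(0.0, h + delta), max(0.0, h - delta)]
    else:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        candidates = [max(0.0, h + sign * delta)]
    best, best_val = h, current
    for c in candidates:
        if c == h:
            continue
        val = evaluate(c)
        if val > best_val:
            best, best_val = c, val
    return best


def step_types(
    state: TwoTypeState,
    prev_state: TwoTypeState,
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> TwoTypeState:
    """One simultaneous mutation step of both types.

    Each type compares a candidate help level against the *other* type's
    help in ``prev_state`` and its own current payoff evaluated against that
    same lagged snapshot; updates are simultaneous.  An extinct type (zero
    members) keeps its help frozen.
    """
    delta = config.mutation_increment
    n_p = round(state.S_p * params.N)
    n_m = round(state.S_m * params.N)

    new_h_p = state.h_p
    if n_p > 0:
        cur_p = _expected_payoff_p(state.h_p, prev_state.h_m, state, params)
        new_h_p = _propose(
            state.h_p,
            cur_p,
            lambda c: _expected_payoff_p(c, prev_state.h_m, state, params),
            delta,
            config.both_directions,
            rng,
        )
    new_h_m = state.h_m
    if n_m > 0:
        cur_m = _expected_payoff_m(state.h_m, prev_state.h_p, state, params)
        new_h_m = _propose(
            state.h_m,
            cur_m,
            lambda c: _expected_payoff_m(c, prev_state.h_p, state, params),
            delta,
            config.both_directions,
            rng,
        )
    return TwoTypeState(state.S_p, state.S_m, new_h_p, new_h_m)


def _record(rows: list, step: int, state: TwoTypeState, params: ModelParams) -> None:
    W_p, W_m = two_type_payoffs(state, params)
    rows.append(
        (step, state.S_p, state.S_m, state.h_p, state.h_m, W_p, W_m)
    )


_COLUMNS = ["step", "S_p", "S_m", "h_p", "h_m", "W_p", "W_m"]


def _finish(rows: list, state: TwoTypeState, params: ModelParams, config: SimConfig,
            converged: bool) -> TypeSimResult:
    W_p, W_m = two_type_payoffs(state, params)
    traj = pd.DataFrame(rows, columns=_COLUMNS)
    return TypeSimResult(
        state=state,
        W_p=W_p,
        W_m=W_m,
        converged=converged,
        label=_label(state.h_p, state.h_m, config.tolerance),
        trajectory=traj,
    )


def _init_state(
    S_m: float, params: ModelParams, config: SimConfig, h0, rng
) -> TwoTypeState:
    if h0 is None:
        h_p0, h_m0 = rng.uniform(0.0, params.m, size=2)
    else:
        h_p0, h_m0 = h0
    return TwoTypeState(1.0 - S_m, S_m, float(h_p0), float(h_m0))


def run_fixed_proportions(
    S_m: float,
    params: ModelParams,
    config: SimConfig,
    h0: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> TypeSimResult:
    """Iterate the two-type mutation dynamics at fixed proportions until no
    change is accepted for a full convergence window (or ``max_steps``)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = _init_state(S_m, params, config, h0, rng)
    # an absent type carries no meaningful help level
    if round(state.S_m * params.N) == 0:
        state = replace(state, h_m=0.0)
    elif round(state.S_p * params.N) == 0:
        state = replace(state, h_p=0.0)
    prev = state
    rows: list = []
    _record(rows, 0, state, params)
    quiet = 0
    for step in range(1, config.max_steps + 1):
        new = step_types(state, prev, params, config, rng)
        quiet = quiet + 1 if (new.h_p == state.h_p and new.h_m == state.h_m) else 0
        prev, state = state, new
        if step % config.record_every == 0:
            _record(rows, step, state, params)
        if quiet >= config.convergence_window:
            break
    converged = quiet >= config.convergence_window
    return _finish(rows, state, params, config, converged)


def basin_map(
    initial_grid: tuple[np.ndarray, np.ndarray],
    S_m: float,
    params: ModelParams,
    config: SimConfig,
) -> pd.DataFrame:
    """Label every initial ``(h_p, h_m)`` grid point by the equilibrium its
    run reaches.  Long-format columns: ``h_p0, h_m0, label``."""
    h_p0s, h_m0s = initial_grid
    rows = []
    base = 0 if config.seed is None else config.seed
    idx = 0
    for hp0 in np.asarray(h_p0s, dtype=float):
        for hm0 in np.asarray(h_m0s, dtype=float):
            rng = np.random.default_rng(base + idx)
            res = run_fixed_proportions(
                S_m, params, config, h0=(hp0, hm0), rng=rng
            )
            rows.append((hp0, hm0, res.label))
            idx += 1
    return pd.DataFrame(rows, columns=["h_p0", "h_m0", "label"])


def proportion_sweep(
    params: ModelParams,
    config: SimConfig,
    grid: np.ndarray | None = None,
    h0: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Equilibrium help and payoffs for fixed ``S_m`` on a grid (default
    0 to 1 in steps of 0.1).  ``N`` must make every ``S_m * N`` integral."""
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    rows = []
    base = 0 if config.seed is None else config.seed
    for i, S_m in enumerate(np.asarray(grid, dtype=float)):
        rng = np.random.default_rng(base + i)
        res = run_fixed_proportions(S_m, params, config, h0=h0, rng=rng)
        rows.append(
            (
                S_m,
                res.state.h_p,
                res.state.h_m,
                res.W_p,
                res.W_m,
                res.label,
                res.converged,
            )
        )
    return pd.DataFrame(
        rows, columns=["S_m", "h_p", "h_m", "W_p", "W_m", "label", "converged"]
    )


def run_evolving_proportions(
    params: ModelParams,
    config: SimConfig,
    S_m0: float = 0.5,
    h0: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> TypeSimResult:
    """Two-type dynamics with both help levels and proportions evolving.

    After each help-mutation step, members of the lower-payoff type switch
    to the other type: the number of switchers is binomial with probability
    ``switch_fraction_scale * |W_m - W_p|``, capped at ``switch_cap``.  An
    extinct type has its (now meaningless) help frozen at zero.  Convergence
    requires a full window with neither accepted help changes nor switches.
    """
    if not 0 < S_m0 < 1:
        raise ValueError("initial S_m must lie in (0, 1)")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = _init_state(S_m0, params, config, h0, rng)
    n_m = round(state.S_m * params.N)
    prev = state
    rows: list = []
    _record(rows, 0, state, params)
    quiet = 0
    N = params.N
    for step in range(1, config.max_steps + 1):
        new = step_types(state, prev, params, config, rng)
        changed = not (new.h_p == state.h_p and new.h_m == state.h_m)

        W_p, W_m = two_type_payoffs(new, params)
        gap = W_m - W_p
        p_switch = min(config.switch_fraction_scale * abs(gap), config.switch_cap)
        movers = 0
        if gap > 0 and n_m < N:  # p-members switch to m
            movers = rng.binomial(N - n_m, p_switch)
            n_m += movers
        elif gap < 0 and n_m > 0:  # m-members switch to p
            movers = rng.binomial(n_m, p_switch)
            n_m -= movers

        h_p, h_m = new.h_p, new.h_m
        if n_m == 0:
            h_m = 0.0
        if n_m == N:
            h_p = 0.0
        new = TwoTypeState(1.0 - n_m / N, n_m / N, h_p, h_m)

        quiet = quiet + 1 if (not changed and movers == 0) else 0
        prev, state = state, new
        if step % config.record_every == 0:
            _record(rows, step, state, params)
        if quiet >= config.convergence_window:
            break
    converged = quiet >= config.convergence_window
    return _finish(rows, state, params, config, converged)
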