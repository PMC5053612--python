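"""The N-person heterogeneous game: every individual controls its own help.

Each step all agents simultaneously evaluate a one-increment change of their
personal help level against everyone else's help from the previous step and
adopt it only on strict expected improvement — the individual-granularity
mirror of the two-type engine.  Typical outcomes are bimodal: a cluster of
competitive helpers at a common high level and the rest providing nothing.
A passive-help sweep measures how often the all-compete outcome arises as
``k`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AgentPopulation, ModelParams, help_received_agents, matching_weight
from .abm_types import SimConfig

__all__ = [
    "AgentSimResult",
    "SweepResult",
    "step_agents",
    "run_heterogeneous",
    "passive_help_sweep",
]


def _r_own_values(v: np.ndarray, h_prev: np.ndarray, k: float, z: float) -> np.ndarray:
    """Help agent ``i`` would receive holding own level ``v[i]`` while all
    others hold their lagged levels ``h_prev``.

    Vectorized over agents: the pool of source ``j`` from ``i``'s viewpoint
    is the lagged total weight with ``j``'s and ``i``'s lagged weights
    removed and ``i``'s trial weight added.  Zero-weight pools fall back to
    an equal split, as in :func:`helpmarket.core.help_received_agents`.
    """
    n = h_prev.size
    w_prev = matching_weight(h_prev, k, z)
    d_prev = h_prev + k
    w_v = matching_weight(v, k, z)
    totals = w_prev.sum() - w_prev + w_v  # per-agent total weight under trial
    pools = totals[:, None] - w_prev[None, :]
    ok = pools > 0
    contrib = np.where(ok, w_v[:, None] / np.where(ok, pools, 1.0), 1.0 / (n - 1))
    np.fill_diagonal(contrib, 0.0)
    return contrib @ d_prev


def _benefit(r: np.ndarray, m: float, x: float) -> np.ndarray:
    return m * r / (m * x + r)


def step_agents(
    pop: AgentPopulation,
    prev_pop: AgentPopulation,
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> AgentPopulation:
    """One simultaneous update: every agent tests one candidate ``h +/- d``
    (or both with ``config.both_directions``) against the lagged snapshot and
    keeps it only on strict improvement; help never drops below zero."""
    h = pop.h
    h_prev = prev_pop.h
    m, x, k, z = params.m, params.x, params.k, params.z
    delta = config.mutation_increment

    W_cur = _benefit(_r_own_values(h, h_prev, k, z), m, x) - h

    def trial(c: np.ndarray) -> np.ndarray:
        return _benefit(_r_own_values(c, h_prev, k, z), m, x) - c

    if config.both_directions:
        up = np.minimum(h + delta, np.inf)
        down = np.maximum(h - delta, 0.0)
        W_up, W_down = trial(up), trial(down)
        best = np.where(W_up >= W_down, up, down)
        W_best = np.maximum(W_up, W_down)
        h_new = np.where(W_best > W_cur, best, h)
    else:
        sign = rng.choice((-1.0, 1.0), size=h.size)
        cand = np.maximum(h + sign * delta, 0.0)
        W_cand = trial(cand)
        h_new = np.where((W_cand > W_cur) & (cand != h), cand, h)
    return AgentPopulation(h_new, k=k)


@dataclass
class AgentSimResult:
    """Final state and bimodal summary of a heterogeneous run.

    ``helper_level`` is the common level of the competitive cluster (the
    agents within two increments of the top helper), ``NaN`` if nobody
    helps.  Labels: ``competitive`` — the whole population in one positive
    cluster; ``collapse`` — nobody helps; ``mixed`` — helpers and
    non-helpers coexist.
    """

    h: np.ndarray
    r: np.ndarray
    W: np.ndarray
    converged: bool
    steps: int
    label: str
    helper_count: int
    nonhelper_count: int
    helper_level: float
    helper_payoff: float


def _summarize(
    pop: AgentPopulation, params: ModelParams, config: SimConfig,
    converged: bool, steps: int,
) -> AgentSimResult:
    h = pop.h
    tol = 2 * config.mutation_increment
    r = help_received_agents(pop, params.z)
    W = _benefit(r, params.m, params.x) - h

    nonhelpers = h <= tol
    helpers = ~nonhelpers
    n_help = int(helpers.sum())
    if n_help == 0:
        label = "collapse"
        level, pay = float("nan"), float("nan")
    else:
        top = h.max()
        cluster = helpers & (h >= top - tol)
        level = float(h[cluster].mean())
        pay = float(W[cluster].mean())
        all_in_cluster = bool(np.all(cluster))
        label = "competitive" if (n_help >= 2 and all_in_cluster) else "mixed"
    return AgentSimResult(
        h=h,
        r=r,
        W=W,
        converged=converged,
        steps=steps,
        label=label,
        helper_count=n_help,
        nonhelper_count=int(nonhelpers.sum()),
        helper_level=level,
        helper_payoff=pay,
    )


def run_heterogeneous(
    params: ModelParams,
    config: SimConfig,
    h0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> AgentSimResult:
    """Iterate the heterogeneous dynamics to convergence.

    Convergence: either no agent accepts a change for a full window, or every
    agent's help stays within two increments over a window (stationary
    jitter).  Initial help defaults to independent uniform draws on
    ``[0, m]``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if h0 is None:
        h0 = rng.uniform(0.0, params.m, size=params.N)
    pop = AgentPopulation(np.asarray(h0, dtype=float), k=params.k)
    if pop.N != params.N:
        raise ValueError("h0 length must equal params.N")
    prev = pop

    window = config.convergence_window
    tol = 2 * config.mutation_increment
    quiet = 0
    lo = pop.h.copy()
    hi = pop.h.copy()
    since_reset = 0
    converged = False
    step = 0
    for step in range(1, config.max_steps + 1):
        new = step_agents(pop, prev, params, config, rng)
        quiet = quiet + 1 if np.array_equal(new.h, pop.h) else 0
        prev, pop = pop, new
        np.minimum(lo, pop.h, out=lo)
        np.maximum(hi, pop.h, out=hi)
        since_reset += 1
        if quiet >= window:
            converged = True
            break
        if since_reset >= window:
            if float((hi - lo).max()) <= tol:
                converged = True
                break
            lo = pop.h.copy()
            hi = pop.h.copy()
            since_reset = 0
    return _summarize(pop, params, config, converged, step)


@dataclass
class SweepResult:
    """Replicated passive-help sweep over a ``(k, z)`` grid.

    ``runs`` holds one row per replicate; ``frequency`` the per-cell fraction
    of replicates ending in the competitive (all-compete) outcome.
    """

    runs: pd.DataFrame
    frequency: pd.DataFrame
    replicates: int


def passive_help_sweep(
    k_grid: np.ndarray,
    z_grid: np.ndarray,
    replicates: int,
    params: ModelParams,
    config: SimConfig,
) -> SweepResult:
    """Frequency of the competitive outcome as passive help ``k`` grows, for
    each degree of matching ``z``.  Replicate seeds derive from the config
    seed and are recorded in the output."""
    k_grid = np.asarray(k_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if k_grid.size == 0 or z_grid.size == 0 or replicates < 1:
        raise ValueError("grids must be nonempty and replicates >= 1")
    base = 0 if config.seed is None else config.seed
    rows = []
    cell = 0
    for z in z_grid:
        for k in k_grid:
            for rep in range(replicates):
                seed = base + cell * replicates + rep
                p = ModelParams(N=params.N, m=params.m, x=params.x, k=float(k), z=float(z))
                res = run_heterogeneous(
                    p, config, rng=np.random.default_rng(seed)
                )
                rows.append(
                    (
                        float(k),
                        float(z),
                        rep,
                        seed,
                        res.label,
                        res.helper_count,
                        res.helper_level,
                        res.helper_payoff,
                        res.converged,
                    )
                )
            cell += 1
    runs = pd.DataFrame(
        rows,
        columns=[
            "k", "z", "replicate", "seed", "label",
            "helper_count", "helper_level", "helper_payoff", "converged",
        ],
    )
    freq = (
        runs.assign(competitive=runs["label"] == "competitive")
        .groupby(["z", "k"], as_index=False)["competitive"]
        .mean()
        .rename(columns={"competitive": "frequency"})
    )
    return SweepResult(runs=runs, frequency=freq, replicates=replicates)
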