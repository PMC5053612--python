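# Methods

## The model

A biological market holds `N` individuals. Individual `i` actively provides
help at rate `h_i ≥ 0` and, in addition, passively (at no cost) dispenses a
common amount `k ≥ 0`. Every individual is a *source*: its dispensed help
`h_j + k` is divided among the other `N − 1` individuals in proportion to
their matching weights `(h_i + k)^z`,

    r_i = Σ_{j≠i} (h_j + k) · (h_i + k)^z / Σ_{l≠j} (h_l + k)^z .

The *degree of matching* `z` interpolates between an unconditional equal
split (`z = 0`), perfect proportional matching (`z = 1`), and a
winner-per-source allocation (`z → ∞`). In that limit each source gives
everything to its highest-weight recipient, so the top helper collects all
other help while its own contribution lands on the runner-up — "winner takes
all" never holds exactly.

Fitness is the diminishing-returns benefit of help received minus the cost
of help given,

    W_i = m·r_i / (m·x + r_i) − h_i ,

with `m > 0` the maximum benefit and `x ∈ (0, 1]` the saturation rate.

In the two-type reduction the population splits into proportions `S_p` and
`S_m = 1 − S_p` of individuals helping at `h_p` and `h_m`; the allocation
above collapses to closed-form expressions in the type counts `S_i·N`
(which the public API requires to be integers — the sweep grids choose `N`
accordingly; the replicator analysis relaxes them to continuous
coordinates).

## Closed-form equilibria

Equal payoffs (`W_m = W_p`) hold along the equal-help family `h_p = h_m`
(any proportions) and at the two boundary pairs `(0, m − mx)` and
`(m − mx, 0)`, where each type's benefit exactly cancels its cost and both
payoffs are zero. The latter computation applies at perfect matching
(`z = 1`, `k = 0`); at `z = 0` a non-helping type still receives shares, so
the boundary value shifts — the package evaluates the condition rather than
assuming it.

Two optima are exposed in closed form, both derived by solving
`dW/dh = 0` for a *type* moving as a block:

* symmetric (`h_p = h_m`, forced `S_p = S_m`):

      h* = m·(−x + sqrt(x (N−2)((z+1)N − 1) / 2) / (N−1)) − k ,

  with large-`N` limit `(−x + sqrt(x(z+1)/2))·m − k`. (The symbolic
  derivation was re-done with sympy; the two anchors fixing it are the limit
  reduction to the monomorphic optimum at `z = 1` and the stability
  threshold below.) The symmetric optimum is a *local* Nash optimum of the
  deviant type's payoff: near the clamp (strong saturation, undermatching)
  its basin in own-help space can be very narrow, with a better reply far
  away — the same bistability the basin maps chart. Tests therefore verify
  it by stationarity and local concavity everywhere, and as a global best
  reply in the overmatching regime `z ≥ 1`.

* monomorphic (`S_p = 1` or `S_m = 1`):

      h* = (−x + sqrt(x))·m − k ,

  independent of both `z` and `N`. Both forms clamp at 0 when passive help
  exceeds the interior optimum: passive help displaces active help
  one-for-one.

## Replicator dynamics and stability

Proportions evolve by `dS_i/dt = S_i (W_i − (S_p W_p + S_m W_m))`, which on
the simplex factors to `dS_m/dt = S_m(1 − S_m)(W_m − W_p)`. Because equal
help gives equal payoffs at *every* proportion, `h_p = h_m` is a neutral
line of equilibria, not an isolated interior point; the corners `S_i = 1`
are the hyperbolic equilibria.

Stability is reported from the Jacobian of the two-coordinate system with
`(S_p, S_m)` treated as independent coordinates (matching the closed-form
eigenvalue), alongside the single constrained eigenvalue of the
simplex-reduced flow. Both an analytic (sympy-lambdified) and a central
finite-difference Jacobian are available and are cross-checked against each
other in the tests. At a monomorphic corner with the extinct type providing
no help and `k = 0`, the eigenvalue

    λ = h*(h* + mx − m)/(h* + mx)

appears with algebraic multiplicity 2 — once for the radial direction
(−W of the survivor) and once for the invasion direction (`W_extinct −
W_survivor = 0 − W`). If instead the extinct type is imagined at the same
positive help level as the survivor, the invasion direction is neutral and
the spectrum is `{λ, 0}`; the package computes whichever location it is
given and the tests cover both conventions. λ < 0 exactly when
`h* < m(1 − x)`; with the symmetric `h*` this is equivalent to
`z < 2/x − 1`, which is also where the symmetric payoff changes sign. On
the simplex the interior flow with `h_p = h_m` vanishes identically, so the
flip across `z = 2/x − 1` is exhibited under numerical integration by
starting the unconstrained system slightly off-simplex: the simplex is
restored when the mean payoff is positive and repels when negative.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e−8) with
optional post-sampling renormalisation onto the simplex; renormalisation
can be disabled for the radial experiment above.

## The simulators

**Two-type engine.** Each step both types simultaneously propose a change
of one mutation increment (default 0.001;
direction sampled uniformly, or both directions greedily as an option) and
accept it only if the expected payoff — computed against the *other type's
previous-step help* (a one-step information lag) and with the whole
homogeneous type moving together — strictly exceeds the current payoff.
Help is clamped at zero. Convergence is declared after 500 consecutive
steps without an accepted change; lagged best-response oscillation can
occasionally persist near asymmetric equilibria, in which case the run is
flagged unconverged with its partial result. With evolving proportions, a
binomially drawn fraction of the lower-payoff type switches sides each
step with probability `scale·|W_m − W_p|` (default scale 1.0), capped at
10% of the switching type per step; an extinct type has its help frozen at
zero.

**Heterogeneous engine.** The same rule at individual granularity: each
agent tests one candidate `h_i ± δ` against everyone else's lagged help.
The per-candidate allocation is computed in O(N) via the identity
`r_i = w_i (Σ_j d_j/(T − w_j) − d_i/(T − w_i))` (a source's recipients'
shares do not depend on which other recipients exist), with an equal-split
fallback for degenerate (all-zero-weight) pools — the unique choice that
preserves conservation and continuity with `z = 0`, together with the
`0^0 = 1` convention that makes `z = 0` an unconditional equal split.
Convergence is a full window (default 200 steps) with either no accepted
move or all agents confined within two increments (stationary jitter).

Initial help defaults to independent uniform draws on `[0, m]`. Outcome
labels: *competitive* — every agent within two increments of one common
positive level; *collapse* — nobody above two increments; *mixed* —
helpers and non-helpers coexist. The all-compete reading of "competitive"
is what makes the passive-help sweep meaningful: at `k = 0` and `z > 1`
the typical outcome is mixed (a cluster of competitive helpers, the rest
at zero), and passive help forces the holdouts in.

## What the simulations emulate, and what they do not

The generators implement the reference conditions: defaults `m = 1`, `x = 0.5`,
`k = 0`, increment 0.001, two-type aggregate `N = 100000` and heterogeneous
`N = 200` (the `paper-defaults` preset). They are deterministic given a
seed; any high-quality seedable generator is acceptable and no attempt is
made to reproduce any particular historical RNG stream. The model has no
spatial or kin structure, no memory or reputation, no birth–death
demography, and a passive-help level common to all individuals; passing
tests say nothing about settings with those features.

Two emergent observations worth noting. First, a lone helper in a helpless
market earns `−H` and winds down — but once others may respond, a
one-increment deviation by a bystander captures the lone helper's entire
dispensation, so helping *does* take off from a single helper under the
lagged simultaneous dynamics; the two-helper invasion threshold applies to
a market that never reciprocates. Second, the type-level and
individual-level optima coincide only at `z = 1`; at `z > 1` heterogeneous
clusters settle near the individual-deviation level `(−x + sqrt(zx))m − k`,
above the type-level symmetric value — competition overshoots, and the
cluster payoff turns negative for large `z`. In these dynamics the
helper payoff at the passive-help forcing threshold is negative only once
`z` is large enough that cost exceeds saturated benefit; at moderate `z`
the threshold lies above that point and near-threshold payoffs are already
positive.

## Numerical choices and test scales

* Conservation of help holds to 1e−9 by construction; simplex drift of
  integrated trajectories is ≤ 1e−9 after renormalisation.
* Equilibrium acceptance for stability reports: `|rhs| ≤ 1e−8`;
  eigenvalue zero-classification tolerance 1e−7.
* Matching weights `(h+k)^z` underflow for very large `z`; the
  winner-per-source limit is validated at `z = 200` with help levels of
  order one, where shares are still representable.
* Test and acceptance runs use reduced sizes chosen for the suite:
  two-type engines at `N = 1000` (the evolving-proportions check follows
  its stated reduced-population design), basin maps on 4×4 grids at
  `N = 100` with deterministic both-direction updates, the
  size-independence comparison at `N = 200` vs `400`, and the passive-help
  sweep at `N = 60` with small replicate counts; the sweep thresholds were
  verified to be insensitive to `N` in this range.
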