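# helpmarket

Competitive helping in a biological market: who helps, how much, and when
does competition over being helped run away?

`helpmarket` implements a market of `N` individuals in which each
individual `i` dispenses its help (an active amount `h_i` plus a costless
passive amount `k`) to the others, split in proportion to the recipients'
matching weights `(h_j + k)^z` — the matching-law allocation of operant
conditioning, with `z` the degree of matching (`z = 0` equal split, `z = 1`
perfect proportionality, `z → ∞` winner-per-source). Fitness is
diminishing-returns benefit minus cost:

    W_i = m·r_i / (m·x + r_i) − h_i ,

where `r_i` is the help received. The package is for behavioural ecologists
and evolutionary game theorists who want to analyse or simulate this market:

* **`helpmarket.core`** — allocation and payoff primitives, two-type and
  fully heterogeneous, with exact conservation of help;
* **`helpmarket.replicator`** — replicator ODEs for the two-type
  proportions, closed-form optima, Jacobian/eigenvalue stability reports,
  and invasion (ESS) analysis;
* **`helpmarket.abm_types`** — two homogeneous types that incrementally
  mutate their help against lagged information, with fixed or evolving
  proportions, basin maps and proportion sweeps;
* **`helpmarket.abm_agents`** — the N-person heterogeneous game, plus the
  passive-help sweep;
* **`helpmarket.experiments`** — scenario configs, seeded byte-reproducible
  runs, CSV/JSON output, and the `helpmarket` command-line interface.

Key closed forms (see `docs/methods.md` for derivations): the symmetric
competitive optimum `h* = (−x + sqrt(x(z+1)/2))·m − k` (large `N`), the
monomorphic optimum `h* = (−x + sqrt(x))·m − k` (independent of `z` and
`N`), the corner eigenvalue `h*(h* + mx − m)/(h* + mx)` with multiplicity
2, and the interior stability threshold `z < 2/x − 1`.

## Worked example

Closed-form analysis at the defaults (`m = 1`, `x = 0.5`, `k = 0`,
`z = 1`):

```sh
$ helpmarket analyze --N 1000
{
  ...
  "optimal_help_monomorphic": 0.20710678118654757,
  "optimal_help_symmetric": 0.20692962821556626,
  "corner_eigenvalue": -0.08578643762690495,
  "corner_eigenvalues": [-0.08578643762690497, -0.08578643762690497],
  "corner_classification": "stable",
  "interior_stability_threshold_z": 3.0,
  "invasion": {"H": 0.1, "E_lone_invader": -0.1, "min_invaders": 2,
               "no_help_is_ess": true}
}
```

Reading this: a population of non-helpers is an ESS (a lone helper at
`H = 0.1` nets `−0.1`; it takes two simultaneous helpers for helping to
pay), yet once helping exists the stable level is `h* ≈ 0.207` per
individual, and the all-helping corner is asymptotically stable (repeated
eigenvalue `≈ −0.0858 < 0`).

The same market simulated with two types mutating their help in increments
of 0.001 at `z = 2`:

```python
>>> import helpmarket as hm
>>> params = hm.ModelParams(N=1000, m=1.0, x=0.5, k=0.0, z=2.0)
>>> res = hm.run_fixed_proportions(0.5, params,
...     hm.SimConfig(seed=42, max_steps=60_000), h0=(0.45, 0.40))
>>> res.state.h_p, res.state.h_m, res.W_p, res.label
(0.36599999999999994, 0.366, 0.05663279445727487, 'competitive')
```

Both types escalate to `h ≈ 0.366` — the `z = 2` symmetric optimum, well
above the monomorphic 0.207 — while each earns only 0.057: sharper matching
makes everyone help more for less. Start the two types far enough apart
(`h0=(0.8, 0.1)`) and one of them quits instead (`label = 'm-quits'`,
survivor at 0.207). The heterogeneous simulator
(`hm.run_heterogeneous`) shows the same bifurcation agent by agent, and
`hm.passive_help_sweep` maps how passive help forces every agent into
competition.

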