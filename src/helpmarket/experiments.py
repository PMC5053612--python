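"""Reproducible experiment layer: scenario configs, seeded dispatch,
CSV/JSON serialization and run manifests.

A :class:`Scenario` bundles model parameters, simulation settings and the
experiment kind.  The ``paper-defaults`` preset carries the reference
conditions: ``m = 1``, ``x = 0.5``, ``k = 0``, mutation increment 0.001,
aggregate two-type population 100000 and heterogeneous population 200.
Identical scenario + seed reproduce result files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import ModelParams, TwoTypeState
from .replicator import integrate_replicator
from .abm_types import (
    SimConfig,
    basin_map,
    proportion_sweep,
    run_evolving_proportions,
    run_fixed_proportions,
)
from .abm_agents import passive_help_sweep, run_heterogeneous

__all__ = ["Scenario", "load_scenario", "run_scenario", "PRESETS", "KINDS"]

log = logging.getLogger("helpmarket")

KINDS = ("replicator", "abm-types", "abm-agents", "basin", "sweep")

#: Named parameter presets.  ``N`` is resolved per kind at load time:
#: two-type experiments use ``N_types``, heterogeneous ones ``N_agents``.
PRESETS: dict[str, dict] = {
    "paper-defaults": {
        "m": 1.0,
        "x": 0.5,
        "k": 0.0,
        "z": 1.0,
        "N_types": 100_000,
        "N_agents": 200,
        "mutation_increment": 0.001,
    }
}

_PARAM_KEYS = {"N", "m", "x", "k", "z"}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_OPTION_KEYS = {
    "S_m", "S_m0", "h_p0", "h_m0", "horizon", "evolve_proportions",
    "grid_max", "grid_points", "k_grid", "z_grid", "replicates", "sweep_proportions",
}
_TOP_KEYS = {"name", "kind", "preset", "params", "config", "options"}


@dataclass(frozen=True)
class Scenario:
    """A fully specified, runnable experiment."""

    name: str
    kind: str
    params: ModelParams
    config: SimConfig
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "params": dataclasses.asdict(self.params),
            "config": dataclasses.asdict(self.config),
            "options": dict(self.options),
        }


def _reject_unknown(section: dict, allowed: set, path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        keys = ", ".join(f"{path}.{k}" for k in sorted(unknown))
        raise ValueError(f"unknown configuration key(s): {keys}")


def load_scenario(source) -> Scenario:
    """Build a validated Scenario from a mapping, YAML text, or a file path.

    Unknown keys are rejected with their key paths; missing values are
    filled from the named preset (default ``paper-defaults``).
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = yaml.safe_load(text)
    else:
        doc = source
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("scenario document must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "scenario")

    preset_name = doc.get("preset", "paper-defaults")
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}")
    preset = PRESETS[preset_name]

    kind = doc.get("kind", "abm-types")
    if kind not in KINDS:
        raise ValueError(f"scenario.kind must be one of {KINDS}, got {kind!r}")

    raw_params = dict(doc.get("params") or {})
    _reject_unknown(raw_params, _PARAM_KEYS, "scenario.params")
    n_default = preset["N_agents"] if kind in ("abm-agents", "sweep") else preset["N_types"]
    params = ModelParams(
        N=int(raw_params.get("N", n_default)),
        m=float(raw_params.get("m", preset["m"])),
        x=float(raw_params.get("x", preset["x"])),
        k=float(raw_params.get("k", preset["k"])),
        z=float(raw_params.get("z", preset["z"])),
    )

    raw_config = dict(doc.get("config") or {})
    _reject_unknown(raw_config, _CONFIG_KEYS, "scenario.config")
    raw_config.setdefault("mutation_increment", preset["mutation_increment"])
    config = SimConfig(**raw_config)

    options = dict(doc.get("options") or {})
    _reject_unknown(options, _OPTION_KEYS, "scenario.options")
    return Scenario(
        name=str(doc.get("name", "unnamed")),
        kind=kind,
        params=params,
        config=config,
        options=options,
    )


def _write_csv(frame, path: Path) -> None:
    frame.to_csv(path, index=False)


def _dispatch(s: Scenario, rng_seed: int | None):
    """Run the scenario's experiment; returns (tables, diagnostics)."""
    params, opts = s.params, s.options
    config = replace(s.config, seed=rng_seed)
    if s.kind == "replicator":
        state0 = TwoTypeState(
            1.0 - opts.get("S_m0", 0.5),
            opts.get("S_m0", 0.5),
            opts.get("h_p0", 0.1),
            opts.get("h_m0", 0.1),
        )
        traj = integrate_replicator(
            state0, params, horizon=opts.get("horizon", 500.0), tol=1e-8
        )
        return {"trajectory": traj.to_frame()}, {"converged": traj.converged}
    if s.kind == "abm-types":
        h0 = None
        if "h_p0" in opts or "h_m0" in opts:
            h0 = (opts.get("h_p0", 0.0), opts.get("h_m0", 0.0))
        if opts.get("sweep_proportions"):
            table = proportion_sweep(params, config, h0=h0)
            return {"proportion_sweep": table}, {}
        if opts.get("evolve_proportions"):
            res = run_evolving_proportions(
                params, config, S_m0=opts.get("S_m0", 0.5), h0=h0
            )
        else:
            res = run_fixed_proportions(
                opts.get("S_m", 0.5), params, config, h0=h0
            )
        diag = {
            "converged": res.converged,
            "label": res.label,
            "steps": int(res.trajectory["step"].iloc[-1]),
        }
        return {"trajectory": res.trajectory}, diag
    if s.kind == "basin":
        grid = np.linspace(
            0.0, opts.get("grid_max", params.m), int(opts.get("grid_points", 5))
        )
        table = basin_map((grid, grid), opts.get("S_m", 0.5), params, config)
        return {"basin": table}, {"labels": sorted(table["label"].unique())}
    if s.kind == "abm-agents":
        res = run_heterogeneous(params, config)
        import pandas as pd

        agents = pd.DataFrame(
            {
                "agent_id": np.arange(params.N),
                "h": res.h,
                "r": res.r,
                "W": res.W,
            }
        )
        diag = {
            "converged": res.converged,
            "label": res.label,
            "helper_count": res.helper_count,
            "steps": res.steps,
        }
        return {"agents": agents}, diag
    if s.kind == "sweep":
        sweep = passive_help_sweep(
            np.asarray(opts.get("k_grid", [0.0, 0.05, 0.1]), dtype=float),
            np.asarray(opts.get("z_grid", [2.0]), dtype=float),
            int(opts.get("replicates", 5)),
            params,
            config,
        )
        return {"sweep": sweep.runs, "sweep_frequency": sweep.frequency}, {}
    raise ValueError(f"unknown scenario kind {s.kind!r}")


def run_scenario(
    s: Scenario, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute a scenario, writing one CSV per result table plus a JSON
    manifest (seed, parameter echo, version, wall time).

    Partial outputs are removed if the run fails.  The same scenario and
    seed always produce byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = seed if seed is not None else s.config.seed
    t0 = time.perf_counter()
    written: list[Path] = []
    try:
        tables, diag = _dispatch(s, rng_seed)
        for stem, frame in tables.items():
            path = out / f"{s.name}.{stem}.csv"
            _write_csv(frame, path)
            written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        log.error("scenario %r failed; partial outputs removed", s.name)
        raise
    manifest = {
        "scenario": s.to_dict(),
        "seed": rng_seed,
        "version": __version__,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": [p.name for p in written],
        "diagnostics": diag,
    }
    manifest_path = out / f"{s.name}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    log.info(
        "scenario %s (%s) finished in %.2fs: %s",
        s.name, s.kind, manifest["wall_time_s"], ", ".join(manifest["outputs"]),
    )
    return manifest


def read_table(path: str | Path, expected_columns: list[str]):
    """Read a result CSV back, rejecting files whose header does not match
    the documented column order."""
    import pandas as pd

    frame = pd.read_csv(path)
    if list(frame.columns) != list(expected_columns):
        raise ValueError(
            f"{path}: header {list(frame.columns)} does not match expected "
            f"{list(expected_columns)}"
        )
    return frame
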