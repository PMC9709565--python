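"""Reproducible end-to-end runs with deterministic on-disk outputs.

Ties the solver, simulator and analyses into single-call runs that write
plain CSV/JSON artifacts plus a manifest (config echo, derived seeds,
SHA-256 checksums).  Re-running with the same config reproduces identical
checksums; the DP stage is RNG-free, so policy and value files never depend
on the seed.

CSV column orders are fixed and rows are emitted in deterministic state
order (t, then n0, then x); there is no domain-standard format for DP
policy tables, so plain headered CSV is used throughout, with JSON for
scalar summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    distribution_summary,
    phase_diagram,
    reliability_sweep,
    threshold_curve_from_policy,
    threshold_curve_from_simulation,
)
from .core import FitnessSpec, ModelConfig
from .simulate import PopulationResult, empirical_mean_path, simulate_population
from .solver import PolicyTable, ValueTable, solve

__all__ = [
    "RunManifest",
    "policy_frame",
    "values_frame",
    "trajectories_frame",
    "run_solve",
    "run_pipeline",
    "run_figures",
    "run_sweep",
]

_ACTION_NAMES = {0: "y0", 1: "y1", 2: "tie"}
_CUE_NAMES = {0: "c0", 1: "c1"}


@dataclass
class RunManifest:
    """Provenance record for one run: config, seeds, output checksums."""

    config: dict
    version: str
    master_seed: int
    derived_seeds: dict
    checksums: dict

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "master_seed": self.master_seed,
            "derived_seeds": self.derived_seeds,
            "checksums": self.checksums,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % 2**31)


def policy_frame(policy: PolicyTable) -> pd.DataFrame:
    """Long-format policy table: one row per state (t, n0, x)."""
    rows = []
    for t in range(1, policy.T + 1):
        codes = policy.action_codes(t)
        d = policy.deltas[t - 1]
        p = policy.posterior[t]
        for n0 in range(t):
            for x in range(t + 1):
                rows.append((t, n0, x, p[x], d[n0, x], _ACTION_NAMES[int(codes[n0, x])]))
    return pd.DataFrame(rows, columns=["t", "n0", "x", "posterior", "delta", "action"])


def values_frame(values: ValueTable, policy: PolicyTable) -> pd.DataFrame:
    rows = []
    for t in range(1, values.T + 1):
        v = values.tables[t - 1]
        p = policy.posterior[t]
        for n0 in range(t):
            for x in range(t + 1):
                rows.append((t, n0, x, p[x], v[n0, x]))
    return pd.DataFrame(rows, columns=["t", "n0", "x", "posterior", "value"])


def trajectories_frame(result: PopulationResult) -> pd.DataFrame:
    """Long-format trajectories: one row per (individual, timestep)."""
    N, T = result.N, result.T
    ind = np.repeat(np.arange(N), T)
    t = np.tile(np.arange(1, T + 1), N)
    n0 = result.n0_path[:, 1:].ravel()
    return pd.DataFrame(
        {
            "individual": ind,
            "t": t,
            "cue": [_CUE_NAMES[c] for c in result.cues.ravel()],
            "posterior": result.posteriors.ravel(),
            "action": [_ACTION_NAMES[a] for a in result.actions.ravel()],
            "n0": n0,
            "n1": t - n0,
        }
    )


def run_solve(config: ModelConfig, out_dir: str | Path) -> RunManifest:
    """Solve the DP and write policy.csv, values.csv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values, policy, root = solve(config)
    policy_frame(policy).to_csv(out / "policy.csv", index=False)
    values_frame(values, policy).to_csv(out / "values.csv", index=False)
    (out / "root_value.json").write_text(json.dumps({"root_value": root}) + "\n")
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        master_seed=config.seed,
        derived_seeds={},
        checksums={p.name: _sha256(out / p.name) for p in
                   [out / "policy.csv", out / "values.csv", out / "root_value.json"]},
    )
    manifest.write(out / "manifest.json")
    return manifest


def run_pipeline(
    config: ModelConfig, out_dir: str | Path, timesteps: tuple[int, ...] | None = None
) -> RunManifest:
    """Full run for one (shape, q) setting: solve, simulate, analyse, write.

    Outputs: policy.csv, values.csv, trajectories.csv, thresholds.csv,
    phase.csv, distributions.csv, summary.json, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values, policy, root = solve(config)
    result = simulate_population(config, policy)

    if timesteps is None:
        marks = sorted({max(1, config.T // 4), max(1, config.T // 2), config.T})
        timesteps = tuple(marks)

    policy_frame(policy).to_csv(out / "policy.csv", index=False)
    values_frame(values, policy).to_csv(out / "values.csv", index=False)
    trajectories_frame(result).to_csv(out / "trajectories.csv", index=False)

    pol_curve = threshold_curve_from_policy(policy)
    sim_curve = threshold_curve_from_simulation(result)
    thresholds = pd.DataFrame(
        {
            "n0": np.tile(np.arange(config.T), 2),
            "tau": np.concatenate([pol_curve.tau, sim_curve.tau]),
            "source": ["policy"] * config.T + ["simulation"] * config.T,
        }
    )
    thresholds.to_csv(out / "thresholds.csv", index=False)

    phase = phase_diagram(result)
    n0g, n1g = np.nonzero(phase.count)
    pd.DataFrame(
        {
            "n0": n0g,
            "n1": n1g,
            "count": phase.count[n0g, n1g],
            "p_y0": phase.p_y0[n0g, n1g],
        }
    ).to_csv(out / "phase.csv", index=False)

    summary = distribution_summary(result, timesteps)
    dist_rows = []
    for ts in summary.timesteps:
        hist = summary.histograms[ts]
        for n0v, cnt in enumerate(hist):
            if cnt:
                dist_rows.append((ts, n0v, int(cnt)))
    pd.DataFrame(dist_rows, columns=["timestep", "n0", "count"]).to_csv(
        out / "distributions.csv", index=False
    )

    mean_path = empirical_mean_path(result)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "root_value": root,
                "terminal_n0_counts": np.bincount(
                    result.terminal_n0, minlength=config.T + 1
                ).tolist(),
                "mean_path": mean_path.tolist(),
                "moments": json.loads(summary.moments.to_json(orient="index")),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    files = [
        "policy.csv",
        "values.csv",
        "trajectories.csv",
        "thresholds.csv",
        "phase.csv",
        "distributions.csv",
        "summary.json",
    ]
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        master_seed=config.seed,
        derived_seeds={"simulation": config.seed},
        checksums={name: _sha256(out / name) for name in files},
    )
    manifest.write(out / "manifest.json")
    return manifest


def run_figures(
    out_dir: str | Path,
    seed: int = 0,
    q: float = 0.55,
    T: int = 20,
    n_trajectories: int = 200,
    n_thresholds: int = 10_000,
) -> dict[str, RunManifest]:
    """Produce the data behind the three headline analyses for each landscape.

    For each fitness shape (concave 0.5, linear, convex 2) at the stated cue
    reliability, runs the full pipeline twice: a small population for
    trajectory plots (N = 200) and a large one for threshold estimation
    (N = 10,000), writing each under ``<out_dir>/<shape>/<size>/``.  A
    single master seed derives every per-run seed.
    """
    out = Path(out_dir)
    manifests: dict[str, RunManifest] = {}
    k = 0
    for shape in ("concave", "linear", "convex"):
        for label, n in (("trajectories", n_trajectories), ("thresholds", n_thresholds)):
            cfg = ModelConfig(
                T=T,
                q=q,
                fitness=FitnessSpec.from_shape(shape),
                N=n,
                seed=_derive_seed(seed, k),
            )
            manifests[f"{shape}/{label}"] = run_pipeline(cfg, out / shape / label)
            k += 1
    return manifests


def run_sweep(
    base: ModelConfig,
    out_dir: str | Path,
    q_grid: tuple[float, ...] = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0),
) -> pd.DataFrame:
    """Run the cue-reliability sweep and write sweep.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = reliability_sweep(base, q_grid=q_grid)
    table.to_csv(out / "sweep.csv", index=False)
    return table
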