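"""Sweep driver over (g, rho, rho_g) and the micropost traction utility.

`run_sweep` reproduces the in-silico phase-diagram protocol: for every
parameter combination and seed it initializes a confined pattern, relaxes
to equilibrium, summarizes per-cell morphometrics and aggregates
inner-vs-boundary group statistics (mean +/- s.e.m.).  Runs already found
on disk are skipped, so an interrupted sweep resumes where it stopped.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .mechanics import PHASE_MAIN, ConfinementSpec, initialize_pattern, relax
from .morphometrics import summarize_state

log = logging.getLogger("voromech")


@dataclass
class SweepConfig:
    """Grid of model parameters, patterns and seeds for a sweep."""

    g_values: tuple = (0.5, 0.75, 1.0)
    rho_values: tuple = (0.4, 0.7, 1.0)
    rho_g_values: tuple = (1.0,)
    patterns: tuple = (ConfinementSpec(),)
    n_seeds: int = 5
    solver: dict = field(default_factory=dict)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for name in ("g_values", "rho_values", "rho_g_values"):
            vals = getattr(self, name)
            if not vals or any(not 0 < v <= 1 for v in vals):
                raise InvalidConfigurationError(f"{name} must lie in (0, 1]")
        if self.n_seeds < 1:
            raise InvalidConfigurationError("n_seeds must be >= 1")

    def conditions(self):
        for ip, spec in enumerate(self.patterns):
            for g in self.g_values:
                for rho in self.rho_values:
                    for rho_g in self.rho_g_values:
                        yield ip, spec, g, rho, rho_g


def _run_tag(ip: int, g: float, rho: float, rho_g: float, seed: int) -> str:
    return f"p{ip}_g{g:g}_rho{rho:g}_rhog{rho_g:g}_s{seed}"


def run_sweep(config: SweepConfig, base_seed: int = 0) -> pd.DataFrame:
    """Run the full sweep; returns the per-condition group-summary table.

    Per-run per-cell tables are written to ``<output_dir>/cells_<tag>.csv``
    when an output directory is configured (and reloaded instead of re-run
    when already present); a manifest JSON records seeds and convergence
    flags.  Non-convergent runs are kept, flagged in the manifest.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"base_seed": base_seed, "runs": {}}
    summaries = []
    solver = {"dt": 0.02, "tol": 1e-4, "max_steps": 16_000, "stall_rtol": 1e-10}
    solver.update(config.solver)
    init_kwargs = solver.pop("init_kwargs", {})
    # the rounded-up pattern depends only on (pattern, seed): initialize once
    # per seed and share across the parameter grid
    init_cache: dict = {}

    def _base_state(ip, spec, seed):
        key = (ip, seed)
        if key not in init_cache:
            init_cache[key] = initialize_pattern(spec, seed=seed, **init_kwargs)
        return copy.deepcopy(init_cache[key])

    for ip, spec, g, rho, rho_g in config.conditions():
        per_seed = []
        for k in range(config.n_seeds):
            seed = base_seed + k
            tag = _run_tag(ip, g, rho, rho_g, seed)
            cells_path = outdir / f"cells_{tag}.csv" if outdir else None
            if cells_path is not None and cells_path.exists():
                cells = pd.read_csv(cells_path)
                manifest["runs"][tag] = {"resumed": True}
            else:
                state = _base_state(ip, spec, seed)
                state.params = replace(state.params, g=g, rho=rho, rho_g=rho_g)
                state.energy_trace = []
                relax(state, PHASE_MAIN, **solver)
                cells = summarize_state(state)
                trace = np.asarray(state.energy_trace)
                manifest["runs"][tag] = {
                    "resumed": False,
                    "converged": bool(state.converged),
                    "warning": state.warning,
                    "steps": int(state.step_count),
                    "energy": float(state.energy),
                    "energy_monotone": bool(np.all(np.diff(trace) <= 0)),
                }
                if state.warning:
                    log.warning("run %s: %s", tag, state.warning)
                if cells_path is not None:
                    cells.to_csv(cells_path, index=False)
            per_seed.append(cells.assign(seed=seed))
            log.debug("finished %s", tag)
        seed_means = (
            pd.concat(per_seed)
            .groupby(["seed", "cell_class"])[
                ["area", "elongation", "angle_deviation_deg"]
            ]
            .mean()
            .reset_index()
        )
        for cls_name, grp in seed_means.groupby("cell_class"):
            row = {
                "pattern": ip,
                "g": g,
                "rho": rho,
                "rho_g": rho_g,
                "cell_class": cls_name,
                "n_seeds": len(grp),
            }
            for col in ("area", "elongation", "angle_deviation_deg"):
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_sem"] = grp[col].sem()
            summaries.append(row)
        log.info("condition g=%g rho=%g rho_g=%g done", g, rho, rho_g)
    summary = pd.DataFrame(summaries)
    if outdir:
        summary.to_csv(outdir / "condition_summary.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return summary


# ---------------------------------------------------------------------------
# micropost traction
# ---------------------------------------------------------------------------


@dataclass
class MicropostSpec:
    """Elastic micropost (cantilever) geometry and tip deflection.

    Units are SI: modulus in Pa, diameter/height/deflection in metres.
    """

    elastic_modulus: float  # Pa
    diameter: float  # m
    height: float  # m
    deflection: float  # m

    def __post_init__(self) -> None:
        for name in ("elastic_modulus", "diameter", "height"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be positive")
        if self.deflection < 0:
            raise InvalidConfigurationError("deflection must be >= 0")


def micropost_force(spec: MicropostSpec) -> float:
    """Traction force (N) from cantilever beam bending: F = (3 E I / L^3) x
    with the solid circular cross-section moment I = pi d^4 / 64."""
    I = np.pi * spec.diameter**4 / 64.0
    return float(
        3.0 * spec.elastic_modulus * I / spec.height**3 * spec.deflection
    )


def fig4_default_config(output_dir=None, n_seeds: int = 5, **solver) -> SweepConfig:
    """The default phase-diagram grid: g in {0.5, 0.75, 1.0} x
    rho in {0.4, 0.7, 1.0} at rho_g = 1, circular pattern."""
    return SweepConfig(
        g_values=(0.5, 0.75, 1.0),
        rho_values=(0.4, 0.7, 1.0),
        rho_g_values=(1.0,),
        patterns=(ConfinementSpec(),),
        n_seeds=n_seeds,
        solver=solver,
        output_dir=output_dir,
    )
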