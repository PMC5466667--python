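"""Chained experiment drivers behind the CLI.

Each experiment is a pure function of (config, seed) writing tidy CSVs; the
CSV outputs are the contract, any figures are convenience.  Four drivers
mirror the computational studies the package exists for: fixed-compartment
steady-state maps, stationary growth-and-division dynamics, the
division-time selection sweep over the membrane-conversion parameter k_d,
and the leakage-assay fitting pipeline whose output curve closes the loop
back into the simulator.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .assay import (
    AssayGeometry,
    fit_permeability_curve,
    fit_release_rate,
    permeability_from_rate,
    traces_from_dataframe,
)
from .deterministic import Trajectory, bistability_scan, integrate
from .networks import (
    DEFAULT_NUTRIENT_PERMEABILITY,
    NetworkModel,
    add_lipid_synthesis,
    build_pm1,
    build_pm2,
)
from .physics import PhysicsParams
from .stochastic import division_stats, project_population, run_ssa
from .synthetic import (
    DEFAULT_K_SYN,
    DEFAULT_REPRODUCING_INIT,
    default_parameter_set,
    gen_composition_series,
)

log = logging.getLogger("protocell")

__all__ = [
    "ExperimentConfig",
    "exp_steady_map",
    "exp_reproduction",
    "exp_selection",
    "exp_assay",
    "stationary_from_trajectory",
]

_BUILDERS = {"pm1": build_pm1, "pm2": build_pm2}

DEFAULT_DECAY_GRID = tuple(np.geomspace(0.05, 5.0, 10))
DEFAULT_PERM_GRID = tuple(np.geomspace(0.2, 5.0, 10))
DEFAULT_KD_SWEEP = (0.0, 0.005, 0.02, 0.08, 0.3)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    experiment: str
    model: str = "pm2"
    engine: str = "ode"  # "ode" | "ssa"
    seed: int = 0
    out_dir: Optional[Path] = None
    overrides: dict = field(default_factory=dict)
    k_d_sweep: Sequence[float] = DEFAULT_KD_SWEEP
    perm_multipliers: Sequence[float] = (0.5, 0.75, 1.0, 1.5, 2.0)
    decay_grid: Sequence[float] = DEFAULT_DECAY_GRID
    perm_grid: Sequence[float] = DEFAULT_PERM_GRID

    def __post_init__(self) -> None:
        if self.model not in _BUILDERS and self.model != "both":
            raise ValueError(f"unknown model {self.model!r}")
        if self.engine not in ("ode", "ssa"):
            raise ValueError(f"unknown engine {self.engine!r}")
        for name in ("k_d_sweep", "perm_multipliers", "decay_grid", "perm_grid"):
            if len(list(getattr(self, name))) == 0:
                raise ValueError(f"{name} must be non-empty")


def _out(cfg: ExperimentConfig) -> Optional[Path]:
    if cfg.out_dir is None:
        return None
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


#: nominal specific growth rate (1/h) used only to pre-position the initial
#: membrane composition near its stationary value for a given k_d
G_NOMINAL = 0.03


def chi0_estimate(k_d: float, physics: PhysicsParams, g_nominal: float = G_NOMINAL) -> float:
    """Stationary-composition estimate chi* = aL / (aL + al * k_d / g), clipped."""
    chi = physics.alpha_L / (physics.alpha_L + physics.alpha_l * k_d / g_nominal) if g_nominal > 0 else 1.0
    return float(min(0.85, max(0.15, chi)))


def _reproducing_setup(
    model_name: str, k_d: float, overrides: Mapping
) -> tuple[NetworkModel, PhysicsParams, dict]:
    cfg = default_parameter_set(model_name, "reproducing")
    phys_d = {**cfg["physics"], **{k: v for k, v in overrides.items() if k in cfg["physics"]}}
    physics = PhysicsParams.from_dict(phys_d)
    if "chi0" not in overrides:
        physics = replace(physics, chi0=chi0_estimate(k_d, physics))
    k_syn = overrides.get("k_syn", DEFAULT_K_SYN[model_name])
    perm_mult = overrides.get("perm_multiplier", 1.0)
    rates = overrides.get("rates")
    base = _BUILDERS[model_name](
        rates, nutrient_permeability=DEFAULT_NUTRIENT_PERMEABILITY * perm_mult
    )
    model = add_lipid_synthesis(
        base,
        k_syn=k_syn,
        k_d=k_d,
        precursor_permeability=DEFAULT_NUTRIENT_PERMEABILITY * perm_mult,
    )
    init = dict(DEFAULT_REPRODUCING_INIT[model_name])
    init.update(overrides.get("init_conc", {}))
    scen = dict(cfg["scenario"])
    scen["init_conc"] = init
    if "t_end" in overrides:
        scen["t_end"] = overrides["t_end"]
    return model, physics, scen


SETTLE_EPSILON = 0.6
SETTLE_HORIZON = 2500.0


def settle_reproducing(
    model: NetworkModel,
    physics: PhysicsParams,
    init_conc: Mapping[str, float],
    horizon: float = SETTLE_HORIZON,
) -> tuple[Optional[dict], Optional[float], Trajectory]:
    """Relax onto the balanced growth-and-division attractor.

    Runs with a very tolerant burst threshold so entry transients (the
    approach to the stationary size and composition) do not kill the
    lineage, and returns the settled concentrations and membrane
    composition as a clean starting point for production runs under the
    strict threshold.  Returns (None, None, trajectory) if no reproductive
    attractor was reached (burst or too few divisions).
    """
    relaxed = replace(physics, epsilon_burst=SETTLE_EPSILON)
    traj = integrate(model, relaxed, init_conc, t_end=horizon, n_samples=60)
    if traj.outcome != "ok" or len(traj.division_times) < 3:
        return None, None, traj
    conc = {
        sp: float(traj.concentration(sp)[-1])
        for sp in traj.species
        if sp != "X" and traj.counts[-1, traj.species.index(sp)] > 0
    }
    settled = {
        "chi": float(traj.chi[-1]),
        "phi": float(traj.phi[-1]),
        "r_nm": float((3.0 * traj.volume[-1] / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e9),
    }
    return conc, settled, traj


def run_reproducing(
    model_name: str,
    k_d: float,
    overrides: Mapping,
    t_end: float,
) -> tuple[Trajectory, PhysicsParams]:
    """Settle onto the attractor, then continue from the settled cell.

    The production run restarts exactly at the settled intensive state
    (concentrations, membrane composition) *and* extensive state (cell size
    and reduced surface), so the strict burst threshold applies only to the
    stationary regime, not to entry transients.
    """
    model, physics, scen = _reproducing_setup(model_name, k_d, overrides)
    conc, settled, settle_traj = settle_reproducing(model, physics, scen["init_conc"])
    if conc is None:
        return settle_traj, physics
    physics2 = replace(
        physics, chi0=settled["chi"], phi0=settled["phi"], r0=settled["r_nm"]
    )
    traj = integrate(model, physics2, conc, t_end=t_end)
    return traj, physics2


# ---------------------------------------------------------------------------
# steady-map
# ---------------------------------------------------------------------------


def exp_steady_map(cfg: ExperimentConfig) -> dict:
    """Two-parameter steady-state scan; returns the map and writes tidy CSV."""
    model = _BUILDERS[cfg.model]()
    physics = PhysicsParams.from_dict(
        {**default_parameter_set(cfg.model, "fixed_compartment")["physics"], **cfg.overrides}
    )
    smap = bistability_scan(model, physics, cfg.decay_grid, cfg.perm_grid)
    out = _out(cfg)
    summary = {
        "model": cfg.model,
        "bistable_fraction": smap.bistable_fraction,
        "n_cells": int(smap.n_attractors.size),
    }
    if out:
        smap.to_dataframe().to_csv(out / "steady_map.csv", index=False)
        (out / "steady_map_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("steady-map %s: bistable fraction %.3f", cfg.model, smap.bistable_fraction)
    return {"map": smap, "summary": summary}


# ---------------------------------------------------------------------------
# reproduce
# ---------------------------------------------------------------------------


def stationary_from_trajectory(traj: Trajectory, window: int = 10) -> dict:
    """Stationary division diagnostics from a deterministic trajectory."""
    times = np.asarray(traj.division_times)
    if times.size < 2:
        return {"n_divisions": int(times.size), "stationary": False}
    intervals = np.diff(times)
    tail = intervals[-window:] if intervals.size >= window else intervals
    chi_at_div = np.interp(times, traj.t, traj.chi)
    d_chi = np.abs(np.diff(chi_at_div[-(window + 1):]))
    rel_chi_change = float(np.max(d_chi / np.maximum(chi_at_div[-window:], 1e-12))) if times.size > window else np.nan
    last_rel_step = abs(intervals[-1] - intervals[-2]) / intervals[-1]
    return {
        "n_divisions": int(times.size),
        "mean_T_div": float(np.mean(tail)),
        "sd_T_div": float(np.std(tail, ddof=1)) if tail.size > 1 else 0.0,
        "last_T_div": float(intervals[-1]),
        "last_T_div_rel_change": float(last_rel_step),
        "chi_stationary": float(chi_at_div[-1]),
        "chi_rel_change": rel_chi_change,
        "stationary": bool(last_rel_step < 0.01),
    }


def exp_reproduction(cfg: ExperimentConfig) -> dict:
    """Growth-and-division run with lipid synthesis; burst is reported, not raised."""
    k_d = cfg.overrides.get("k_d", 0.02)
    model, physics, scen = _reproducing_setup(cfg.model, k_d, cfg.overrides)
    t_end = cfg.overrides.get("t_end", scen.get("t_end", 6000.0))
    out = _out(cfg)
    if cfg.engine == "ode":
        traj, _phys = run_reproducing(cfg.model, k_d, cfg.overrides, t_end)
        stats = stationary_from_trajectory(traj)
        stats["outcome"] = traj.outcome
        if out:
            traj.to_dataframe().to_csv(out / "trajectory.csv", index=False)
            pd.DataFrame({"t_division": traj.division_times}).to_csv(
                out / "divisions.csv", index=False
            )
        result: dict = {"trajectory": traj, "stats": stats}
    else:
        conc, settled, _settle = settle_reproducing(model, physics, scen["init_conc"])
        if conc is not None:
            physics = replace(
                physics, chi0=settled["chi"], phi0=settled["phi"], r0=settled["r_nm"]
            )
            scen["init_conc"] = conc
        res = run_ssa(model, physics, scen["init_conc"], t_end=t_end, seed=cfg.seed)
        stats = {"outcome": res.outcome, "n_divisions": len(res.records)}
        try:
            stats.update(division_stats(res.records))
        except ValueError:
            stats["stationary"] = False
        if out:
            res.to_dataframe().to_csv(out / "trajectory.csv", index=False)
            res.records_dataframe().to_csv(out / "divisions.csv", index=False)
            (out / "run_meta.json").write_text(
                json.dumps({"seed": cfg.seed, "engine": "ssa", "model": cfg.model})
            )
        result = {"ssa": res, "stats": stats}
    if out:
        (out / "summary.json").write_text(json.dumps(stats, indent=2, default=float))
    log.info("reproduce %s/%s: %s", cfg.model, cfg.engine, stats)
    return result


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _run_kd_point(model_name: str, k_d: float, overrides: Mapping, t_end: float) -> dict:
    traj, physics = run_reproducing(model_name, k_d, overrides, t_end)
    stats = stationary_from_trajectory(traj)
    row = {"model": model_name, "k_d": k_d, "outcome": traj.outcome, **stats}
    if stats.get("mean_T_div") and traj.outcome == "ok":
        chi = stats["chi_stationary"]
        curve = physics.curve()
        f = curve(chi) if curve is not None else 1.0
        p_base = DEFAULT_NUTRIENT_PERMEABILITY * overrides.get("perm_multiplier", 1.0)
        row["mean_permeability"] = p_base * f
        row["diffusion_rate"] = p_base * f * physics.thickness * 1e-9
    return row


def exp_selection(cfg: ExperimentConfig) -> dict:
    """Division time vs stationary membrane composition across a k_d sweep."""
    t_end = cfg.overrides.get("t_end", 6000.0)
    rows = []
    for model_name in (["pm1", "pm2"] if cfg.model == "both" else [cfg.model]):
        for k_d in cfg.k_d_sweep:
            try:
                rows.append(_run_kd_point(model_name, float(k_d), cfg.overrides, t_end))
            except ValueError as exc:
                rows.append({"model": model_name, "k_d": k_d, "error": str(exc)})
    table = pd.DataFrame(rows)
    fits = {}
    for model_name, grp in table.groupby("model"):
        ok = grp.dropna(subset=["mean_T_div", "diffusion_rate"]) if "diffusion_rate" in grp else grp.iloc[0:0]
        if len(ok) >= 3:
            lr = linregress(ok["diffusion_rate"], np.log(ok["mean_T_div"]))
            fits[model_name] = {
                "slope": float(lr.slope),
                "intercept": float(lr.intercept),
                "r_squared": float(lr.rvalue**2),
            }
    pops = []
    if "mean_T_div" in table:
        t_grid = np.linspace(0.0, 40.0 * 24.0, 100)  # 40 days, hours
        for _, row in table.dropna(subset=["mean_T_div"]).iterrows():
            curve = project_population(row["mean_T_div"], t_grid)
            pops.append(
                pd.DataFrame(
                    {
                        "model": row["model"],
                        "k_d": row["k_d"],
                        "t_h": curve.times,
                        "population": curve.population,
                    }
                )
            )
    pop_df = pd.concat(pops, ignore_index=True) if pops else pd.DataFrame()
    out = _out(cfg)
    if out:
        table.to_csv(out / "selection_table.csv", index=False)
        if not pop_df.empty:
            pop_df.to_csv(out / "population_curves.csv", index=False)
        (out / "sensitivity_fits.json").write_text(json.dumps(fits, indent=2))
    return {"table": table, "fits": fits, "population": pop_df}


# ---------------------------------------------------------------------------
# assay
# ---------------------------------------------------------------------------


def exp_assay(cfg: ExperimentConfig, traces_csv: Optional[Path] = None) -> dict:
    """Full leakage pipeline: traces -> rates -> P, D -> exact-matching curve.

    Emits the permeability-curve config block consumable by the simulator.
    """
    scen = default_parameter_set("pm1", "assay")["scenario"]
    scen.update(cfg.overrides)
    geometry = AssayGeometry(**scen["geometry"])
    if traces_csv is not None:
        df = pd.read_csv(traces_csv)
        traces = traces_from_dataframe(df)
        chis = [float(t.composition.split("=")[1]) for t in traces]
    else:
        _, traces, _ = gen_composition_series(
            scen["chis"],
            peak_chi=scen["peak_chi"],
            peak_factor=scen["peak_factor"],
            end_factor=scen["end_factor"],
            base_k=scen["base_k"],
            noise_sd=scen["noise_sd"],
            seed=cfg.seed if cfg.seed else scen["seed"],
            times=scen["times"],
            geometry=geometry,
        )
        chis = [float(t.composition.split("=")[1]) for t in traces]
    rows = []
    failures = []
    for chi, trace in zip(chis, traces):
        try:
            fit = fit_release_rate(trace, method="exponential")
        except Exception as exc:  # propagated per composition
            failures.append({"composition": trace.composition, "error": str(exc)})
            continue
        p, d = permeability_from_rate(fit.k, geometry)
        rows.append(
            {
                "composition": trace.composition,
                "chi_S": chi,
                "k": fit.k,
                "R2": fit.r_squared,
                "P_m_per_s": p,
                "D_m2_per_s": d,
            }
        )
    table = pd.DataFrame(rows).sort_values("chi_S")
    curve = fit_permeability_curve(list(zip(table["chi_S"], table["P_m_per_s"])))
    out = _out(cfg)
    curve_block = {"curve_points": [list(p) for p in curve.control_points]}
    if out:
        table.to_csv(out / "assay_fits.csv", index=False)
        (out / "permeability_curve.json").write_text(json.dumps(curve_block, indent=2))
    return {"table": table, "curve": curve, "curve_block": curve_block, "failures": failures}
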