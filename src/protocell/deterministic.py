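"""ODE integration, fixed-compartment steady states and bistability scans.

Two integration modes exist.  ``protocell`` mode evolves molecule counts
plus the membrane lipid census with the isotonic volume recomputed inside
the right-hand side at every evaluation; division is detected by a
sign-change event on Phi - phi_divide and executed as a deterministic
halving of all extensive state (partition noise belongs to the stochastic
engine).  ``fixed`` mode freezes geometry (sphere of radius r0, pure-l
membrane) and is the setting for steady-state analysis: trajectories are
relaxed and then root-polished in concentration space over the dynamical
core (species that feed back into some rate law or transport), excluding
pure accumulating products such as the trapped acd end-product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from ._compile import (
    FILLER_SPECIES,
    CompiledSystem,
    compile_system,
    initial_state,
    state_vector,
)
from .networks import NetworkModel, ReactionSpec, reaction_rate
from .physics import N_AVOGADRO, PhysicsParams, sphere_volume

__all__ = [
    "Trajectory",
    "SteadyStateMap",
    "integrate",
    "steady_state",
    "bistability_scan",
]

S_PER_H = 3600.0


@dataclass
class Trajectory:
    """Sampled deterministic trajectory with geometry and event bookkeeping."""

    species: list[str]
    t: np.ndarray
    counts: np.ndarray  # (n_t, n_species)
    n_l: np.ndarray
    n_L: np.ndarray
    volume: np.ndarray
    surface: np.ndarray
    phi: np.ndarray
    chi: np.ndarray
    division_times: list[float]
    outcome: str  # "ok" | "burst"

    def concentration(self, name: str) -> np.ndarray:
        j = self.species.index(name)
        return self.counts[:, j] / (self.volume * N_AVOGADRO)

    def division_intervals(self) -> np.ndarray:
        return np.diff(np.asarray(self.division_times))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "t", self.t)
        df["V_in"] = self.volume
        df["S_mu"] = self.surface
        df["phi"] = self.phi
        df["chi_L"] = self.chi
        df["n_l"] = self.n_l
        df["n_L"] = self.n_L
        return df


def _protocell_rhs(sys: CompiledSystem):
    phys = sys.physics
    osmotic = sys.osmotic
    n_sp = sys.n_species
    na_cout = N_AVOGADRO * phys.c_out
    curve = phys.curve()

    def rhs(t, y):
        N = np.maximum(y[:n_sp], 0.0)
        n_l, n_L = max(y[n_sp], 0.0), max(y[n_sp + 1], 0.0)
        v = (N @ osmotic) / na_cout
        s = sys.surface_of(n_l, n_L)
        chi = sys.chi_of(n_l, n_L)
        f = curve(min(max(chi, 0.0), 1.0)) if curve is not None else 1.0
        c = N / (v * N_AVOGADRO)
        rates = sys.rate_k.copy()
        for j in range(len(rates)):
            for i in sys.react_idx[j]:
                if i >= 0:
                    rates[j] *= c[i]
            if sys.cat_idx[j] >= 0:
                rates[j] *= c[sys.cat_idx[j]]
        dN = (rates @ sys.stoich) * (v * N_AVOGADRO)
        for i in range(n_sp):
            if sys.perm_class[i] == 0:
                continue
            p = sys.perm_base[i] * (f if sys.perm_class[i] == 2 else 1.0)
            dN[i] += p * s * (sys.env_conc[i] - c[i]) * N_AVOGADRO
        dn_l = sys.u_l * s - sys.k_out * n_l
        dn_L = 0.0
        if sys.has_membrane_L:
            ins = sys.k_ins * s * c[sys.iL] * N_AVOGADRO
            dN[sys.iL] -= ins
            dn_L = ins - sys.k_d * n_L
            dn_l += sys.k_d * n_L
        return np.concatenate([dN, [dn_l, dn_L]])

    def phi_of(y):
        v = (np.maximum(y[:n_sp], 0.0) @ osmotic) / na_cout
        s = sys.surface_of(max(y[n_sp], 0.0), max(y[n_sp + 1], 0.0))
        return s / (36.0 * math.pi * v**2) ** (1.0 / 3.0)

    return rhs, phi_of


def integrate(
    model: NetworkModel,
    physics: PhysicsParams,
    init_conc: Optional[Mapping[str, float]] = None,
    t_end: float = 1000.0,
    n_samples: int = 400,
    mode: str = "protocell",
    max_divisions: int = 10_000,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> Trajectory:
    """Integrate the model over ``[0, t_end]`` hours.

    In ``protocell`` mode divisions halve all extensive quantities when Phi
    crosses phi_divide (event times recorded); a burst (Phi <= 1 - epsilon)
    terminates the trajectory.  In ``fixed`` mode the compartment geometry is
    frozen at the initial sphere.
    """
    sys = compile_system(model, physics)
    state0 = initial_state(model, physics, init_conc)
    y0 = state_vector(sys, state0)
    rhs, phi_of = _protocell_rhs(sys)

    if mode == "fixed":
        return _integrate_fixed(sys, y0, t_end, n_samples, rtol, atol)
    if mode != "protocell":
        raise ValueError(f"unknown mode {mode!r}")

    rule = physics.event_rule()

    def ev_divide(t, y):
        return phi_of(y) - rule.phi_divide

    def ev_burst(t, y):
        return phi_of(y) - (1.0 - rule.epsilon_burst)

    ev_divide.terminal = True
    ev_divide.direction = 1.0
    ev_burst.terminal = True
    ev_burst.direction = -1.0

    sample_t = np.linspace(0.0, t_end, n_samples)
    ts, ys = [], []
    division_times: list[float] = []
    outcome = "ok"
    t0, y = 0.0, y0
    while t0 < t_end:
        sol = solve_ivp(
            rhs,
            (t0, t_end),
            y,
            method="LSODA",
            events=[ev_divide, ev_burst],
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integrator failure at t={sol.t[-1]:.3f} h: {sol.message}; y={sol.y[:, -1]}")
        seg = sample_t[(sample_t >= t0) & (sample_t <= sol.t[-1])]
        if seg.size:
            ts.append(seg)
            ys.append(sol.sol(seg).T)
        t0 = sol.t[-1]
        y = sol.y[:, -1]
        if sol.t_events[1].size:  # burst
            outcome = "burst"
            break
        if sol.t_events[0].size:  # divide: halve every extensive quantity
            division_times.append(float(sol.t_events[0][0]))
            y = 0.5 * sol.y_events[0][0]
            if len(division_times) >= max_divisions:
                break
        elif sol.status == 0:
            break

    t_arr = np.concatenate(ts) if ts else np.array([0.0])
    y_arr = np.vstack(ys) if ys else y0[None, :]
    return _finish_trajectory(sys, t_arr, y_arr, division_times, outcome)


def _integrate_fixed(sys, y0, t_end, n_samples, rtol, atol) -> Trajectory:
    phys = sys.physics
    v0 = sphere_volume(phys.r0)
    s0 = 4.0 * math.pi * (phys.r0 * 1e-9) ** 2
    n_sp = sys.n_species

    def rhs(t, y):
        N = np.maximum(y, 0.0)
        c = N / (v0 * N_AVOGADRO)
        rates = sys.rate_k.copy()
        for j in range(len(rates)):
            for i in sys.react_idx[j]:
                if i >= 0:
                    rates[j] *= c[i]
            if sys.cat_idx[j] >= 0:
                rates[j] *= c[sys.cat_idx[j]]
        dN = (rates @ sys.stoich) * (v0 * N_AVOGADRO)
        for i in range(n_sp):
            if sys.perm_class[i] == 0:
                continue
            dN[i] += sys.perm_base[i] * s0 * (sys.env_conc[i] - c[i]) * N_AVOGADRO
        return dN

    sample_t = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), y0[:n_sp], method="LSODA", t_eval=sample_t, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    n_t = sol.t.size
    y_arr = np.hstack([sol.y.T, np.full((n_t, 1), y0[n_sp]), np.full((n_t, 1), y0[n_sp + 1])])
    return _finish_trajectory(sys, sol.t, y_arr, [], "ok", fixed_volume=v0, fixed_surface=s0)


def _finish_trajectory(
    sys, t_arr, y_arr, division_times, outcome, fixed_volume=None, fixed_surface=None
) -> Trajectory:
    n_sp = sys.n_species
    counts = y_arr[:, :n_sp]
    n_l = y_arr[:, n_sp]
    n_L = y_arr[:, n_sp + 1]
    if fixed_volume is not None:
        volume = np.full(t_arr.size, fixed_volume)
        surface = np.full(t_arr.size, fixed_surface)
    else:
        volume = (counts @ sys.osmotic) / (N_AVOGADRO * sys.physics.c_out)
        surface = 0.5 * (n_l * sys.alpha_l_m2 + n_L * sys.alpha_L_m2)
    phi = surface / (36.0 * math.pi * volume**2) ** (1.0 / 3.0)
    total_area = n_l * sys.alpha_l_m2 + n_L * sys.alpha_L_m2
    chi = np.divide(n_L * sys.alpha_L_m2, total_area, out=np.zeros_like(total_area), where=total_area > 0)
    return Trajectory(
        species=list(sys.species),
        t=t_arr,
        counts=counts,
        n_l=n_l,
        n_L=n_L,
        volume=volume,
        surface=surface,
        phi=phi,
        chi=chi,
        division_times=list(division_times),
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# Fixed-compartment steady states
# ---------------------------------------------------------------------------


def _core_species(model: NetworkModel) -> list[str]:
    """Species with dynamical feedback: rate-law inputs or permeable solutes.

    Pure accumulating products (impermeable, never consumed, never
    catalysing) have no steady state in a fixed compartment and are left out
    of the root problem.
    """
    in_rate: set[str] = set()
    for rxn in model.reactions:
        in_rate |= set(rxn.reactants)
        if rxn.catalyst:
            in_rate.add(rxn.catalyst)
    out = []
    for s in model.species:
        if s.role == "membrane_lipid":
            continue
        if s.name in in_rate or s.permeability_class != "impermeable":
            out.append(s.name)
    return out


def _conc_rhs(model: NetworkModel, physics: PhysicsParams, perm_multiplier: float = 1.0):
    core = _core_species(model)
    idx = {n: i for i, n in enumerate(core)}
    smap = model.species_map
    rho = 3.0 / (physics.r0 * 1e-9)  # S/V of the sphere, 1/m

    transport = []  # (i, coeff 1/h, env conc)
    for name in core:
        s = smap[name]
        if s.permeability_class == "impermeable":
            continue
        p = s.base_permeability * S_PER_H
        if s.permeability_class == "composition_dependent":
            p *= perm_multiplier
        transport.append((idx[name], rho * p, s.env_concentration or 0.0))

    rxns: list[tuple[ReactionSpec, list[tuple[int, float]]]] = []
    for rxn in model.reactions:
        net: dict[int, float] = {}
        for sp, nu in rxn.reactants.items():
            if sp in idx:
                net[idx[sp]] = net.get(idx[sp], 0.0) - nu
        for sp, nu in rxn.products.items():
            if sp in idx:
                net[idx[sp]] = net.get(idx[sp], 0.0) + nu
        rxns.append((rxn, sorted(net.items())))

    def rhs(c_vec):
        conc = {n: max(c_vec[i], 0.0) for n, i in idx.items()}
        dc = np.zeros(len(core))
        for rxn, net in rxns:
            r = reaction_rate(rxn, conc)
            for i, nu in net:
                dc[i] += nu * r
        for i, coeff, env in transport:
            dc[i] += coeff * (env - max(c_vec[i], 0.0))
        return dc

    return core, rhs


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]
    residual: float
    converged: bool

    def is_dead(self, model: NetworkModel, tol: float = 1e-6) -> bool:
        mets = [s.name for s in model.species if s.role == "metabolite"]
        return all(self.concentrations.get(m, 0.0) < tol for m in mets)


def steady_state(
    model: NetworkModel,
    physics: PhysicsParams,
    init_conc: Mapping[str, float],
    perm_multiplier: float = 1.0,
    t_relax: float = 4000.0,
    max_rounds: int = 5,
    residual_tol: float = 1e-10,
) -> SteadyStateResult:
    """Relax by long integration, then root-polish the concentration RHS."""
    core, rhs = _conc_rhs(model, physics, perm_multiplier)
    smap = model.species_map
    c0 = np.array(
        [
            init_conc.get(
                n,
                (smap[n].env_concentration or 0.0) if smap[n].role == "nutrient" else 0.0,
            )
            for n in core
        ]
    )
    c = c0
    horizon = t_relax
    root, residual, converged = c0, float(np.linalg.norm(rhs(c0))), False
    for _ in range(max_rounds):
        sol = solve_ivp(
            lambda t, y: rhs(y), (0.0, horizon), c, method="LSODA", rtol=1e-10, atol=1e-12
        )
        c = np.maximum(sol.y[:, -1], 0.0)
        cand, _info, ier, _msg = fsolve(rhs, c, full_output=True, xtol=1e-13)
        cand = np.where(np.abs(cand) < 1e-14, 0.0, cand)
        res_cand = float(np.linalg.norm(rhs(cand)))
        if ier == 1 and res_cand < residual_tol and np.all(cand > -1e-9):
            root, residual, converged = cand, res_cand, True
            break
        res_relax = float(np.linalg.norm(rhs(c)))
        root, residual = (cand, res_cand) if res_cand < res_relax else (c, res_relax)
        converged = residual < residual_tol
        if converged:
            break
        horizon *= 4.0  # slow transients near marginal cells need longer relaxation
    return SteadyStateResult(
        concentrations={n: float(max(v, 0.0)) for n, v in zip(core, root)},
        residual=residual,
        converged=converged,
    )


DEFAULT_LOW_START = 1e-4  # mol/m^3 seed for the near-dead branch
DEFAULT_HIGH_START = 10.0  # mol/m^3 seed for the elevated branch


@dataclass
class SteadyStateMap:
    """Gridded two-branch steady-state classification."""

    decay_grid: np.ndarray
    perm_grid: np.ndarray
    branch_names: list[str]
    results: dict  # (i, j, branch) -> SteadyStateResult
    n_attractors: np.ndarray  # (n_decay, n_perm)
    model_name: str = ""
    attractor_tol: float = 1e-2

    @property
    def bistable_fraction(self) -> float:
        return float(np.mean(self.n_attractors >= 2))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (i, j, branch), res in self.results.items():
            for sp, val in res.concentrations.items():
                rows.append(
                    {
                        "decay_rate": self.decay_grid[i],
                        "permeability": self.perm_grid[j],
                        "branch": branch,
                        "species": sp,
                        "steady_value": val,
                        "n_attractors": int(self.n_attractors[i, j]),
                        "converged": res.converged,
                    }
                )
        return pd.DataFrame(rows)


def _distinct(a: Mapping[str, float], b: Mapping[str, float], mets: Sequence[str], tol: float) -> bool:
    for m in mets:
        x, y = a.get(m, 0.0), b.get(m, 0.0)
        if abs(x - y) / max(abs(x), abs(y), 1e-6) > tol:
            return True
    return False


def _scaled_model(model: NetworkModel, decay_scale: float) -> NetworkModel:
    rxns = [
        ReactionSpec(
            r.name,
            dict(r.reactants),
            dict(r.products),
            r.rate_constant * (decay_scale if r.name.startswith("D") else 1.0),
            r.catalyst,
        )
        for r in model.reactions
    ]
    return NetworkModel(model.name, list(model.species), rxns, dict(model.membrane_params))


def bistability_scan(
    model: NetworkModel,
    physics: PhysicsParams,
    decay_grid: Sequence[float],
    perm_grid: Sequence[float],
    branch_starts: Optional[Mapping[str, Mapping[str, float]]] = None,
    attractor_tol: float = 1e-2,
) -> SteadyStateMap:
    """Two-parameter scan: decay-rate multiplier x nutrient-permeability multiplier.

    Each grid cell is probed from every branch start (by default a near-zero
    and an elevated metabolite seed); per cell the distinct attractors among
    converged branches are counted, with the all-dead cell reported as 0.
    """
    decay_grid = np.asarray(list(decay_grid), dtype=float)
    perm_grid = np.asarray(list(perm_grid), dtype=float)
    if np.any(np.diff(decay_grid) <= 0) or np.any(np.diff(perm_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    mets = [s.name for s in model.species if s.role == "metabolite"]
    if branch_starts is None:
        branch_starts = {
            "low": {m: DEFAULT_LOW_START for m in mets},
            "high": {m: DEFAULT_HIGH_START for m in mets},
        }
    if len(branch_starts) < 2:
        raise ValueError("need at least two branch starts")

    results: dict = {}
    n_att = np.zeros((decay_grid.size, perm_grid.size), dtype=int)
    for i, ds in enumerate(decay_grid):
        scaled = _scaled_model(model, ds)
        for j, pm in enumerate(perm_grid):
            cell = []
            for branch, start in branch_starts.items():
                res = steady_state(scaled, physics, start, perm_multiplier=pm)
                results[(i, j, branch)] = res
                if res.converged:
                    cell.append(res)
            dead = [r for r in cell if r.is_dead(model)]
            alive = [r for r in cell if not r.is_dead(model)]
            distinct_alive: list[SteadyStateResult] = []
            for r in alive:
                if all(
                    _distinct(r.concentrations, q.concentrations, mets, attractor_tol)
                    for q in distinct_alive
                ):
                    distinct_alive.append(r)
            if not alive:
                n_att[i, j] = 0
            else:
                n_att[i, j] = len(distinct_alive) + (1 if dead else 0)
    return SteadyStateMap(
        decay_grid=decay_grid,
        perm_grid=perm_grid,
        branch_names=list(branch_starts),
        results=results,
        n_attractors=n_att,
        model_name=model.name,
        attractor_tol=attractor_tol,
    )
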