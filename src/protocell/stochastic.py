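"""Exact stochastic simulation of the full protocell.

Gillespie's direct method over reaction, transport and membrane-exchange
channels.  After every firing the isotonic volume, surface area and reduced
surface are recomputed; crossing the division threshold triggers a binomial
partition with one daughter followed (seeded choice), crossing the burst
threshold terminates the lineage.  Identical seeds give bit-identical event
sequences (per backend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _ssa
from ._compile import CompiledSystem, compile_system, initial_state, state_vector
from .networks import NetworkModel
from .physics import N_AVOGADRO, PhysicsParams, sphere_volume

__all__ = [
    "DivisionRecord",
    "PopulationCurve",
    "SSAResult",
    "run_ssa",
    "division_stats",
    "project_population",
]

_OUTCOMES = {
    _ssa.OUT_OK: "ok",
    _ssa.OUT_BURST: "burst",
    _ssa.OUT_MAX_EVENTS: "max_events",
    _ssa.OUT_MAX_DIV: "max_divisions",
}


@dataclass(frozen=True)
class DivisionRecord:
    """Mother-cell snapshot at a division event."""

    generation: int
    t_division: float  # h
    T_div: float  # h since previous division (or since t=0 for the first)
    chi_L: float
    volume: float
    surface: float
    counts: Mapping[str, int]  # mother, at the division threshold
    kept_counts: Mapping[str, int] = None  # followed daughter, post-partition


@dataclass
class PopulationCurve:
    times: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.population) < 0):
            raise ValueError("population curve must be non-decreasing")


@dataclass
class SSAResult:
    species: list[str]
    t: np.ndarray
    counts: np.ndarray  # (n_t, n_species)
    n_l: np.ndarray
    n_L: np.ndarray
    volume: np.ndarray
    surface: np.ndarray
    phi: np.ndarray
    chi: np.ndarray
    records: list[DivisionRecord]
    outcome: str
    n_events: int
    max_isotonic_dev: float
    seed: int

    def concentration(self, name: str) -> np.ndarray:
        j = self.species.index(name)
        return self.counts[:, j] / (self.volume * N_AVOGADRO)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "t", self.t)
        df["n_l"] = self.n_l
        df["n_L"] = self.n_L
        df["V_in"] = self.volume
        df["S_mu"] = self.surface
        df["phi"] = self.phi
        df["chi_L"] = self.chi
        return df

    def records_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "generation": r.generation,
                    "t_division": r.t_division,
                    "T_div": r.T_div,
                    "chi_L": r.chi_L,
                    "V_in": r.volume,
                    "S_mu": r.surface,
                }
                for r in self.records
            ]
        )


def _kernel(backend: str):
    if backend == "python":
        return _ssa.direct_ssa_py
    if backend == "numba":
        if _ssa.direct_ssa_jit is None:
            raise RuntimeError("numba backend requested but numba is not importable")
        return _ssa.direct_ssa_jit
    if backend == "auto":
        return _ssa.direct_ssa_jit or _ssa.direct_ssa_py
    raise ValueError(f"unknown backend {backend!r}")


def run_ssa(
    model: NetworkModel,
    physics: PhysicsParams,
    init_conc: Optional[Mapping[str, float]] = None,
    t_end: float = 100.0,
    seed: int = 0,
    n_samples: int = 200,
    mode: str = "protocell",
    max_events: int = 200_000_000,
    max_divisions: int = 10_000,
    backend: str = "auto",
) -> SSAResult:
    """Run one exact-SSA lineage to ``t_end`` hours.

    ``mode='fixed'`` freezes the compartment geometry (no membrane exchange,
    no division/burst), which is the setting for ODE cross-validation.
    """
    sys = compile_system(model, physics)
    state0 = initial_state(model, physics, init_conc)
    y0 = state_vector(sys, state0)
    N0 = np.round(y0[: sys.n_species]).astype(np.int64)
    cx, cw, cf, use_curve = sys.curve_arrays()
    sample_times = np.linspace(0.0, t_end, n_samples)
    protocell = mode == "protocell"
    if mode not in ("protocell", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    v_fixed = sphere_volume(physics.r0)
    s_fixed = 4.0 * math.pi * (physics.r0 * 1e-9) ** 2

    kern = _kernel(backend)
    (
        samples,
        outcome,
        n_events,
        max_iso_dev,
        div_t,
        div_stats,
        div_counts,
        div_kept,
        n_div,
        _t_final,
    ) = kern(
        N0.copy(),
        np.int64(round(y0[-2])),
        np.int64(round(y0[-1])),
        sys.osmotic,
        sys.perm_base,
        (sys.perm_class == 2).astype(np.int64),
        sys.env_conc,
        sys.stoich.astype(np.int64),
        sys.react_idx,
        sys.cat_idx,
        sys.rate_k,
        sys.rxn_order,
        sys.alpha_l_m2,
        sys.alpha_L_m2,
        sys.u_l,
        sys.k_out,
        sys.k_ins,
        sys.k_d,
        np.int64(sys.iL),
        physics.c_out,
        N_AVOGADRO,
        physics.phi_divide,
        1.0 - physics.epsilon_burst,
        cx,
        cw,
        cf,
        use_curve,
        float(t_end),
        sample_times,
        np.int64(seed),
        np.int64(max_events),
        protocell,
        v_fixed,
        s_fixed,
        np.int64(max_divisions),
    )

    if outcome == _ssa.OUT_ERROR:
        raise RuntimeError("SSA internal consistency error: negative count fired")

    counts = samples[:, : sys.n_species]
    n_l = samples[:, sys.n_species]
    n_L = samples[:, sys.n_species + 1]
    if protocell:
        volume = (counts @ sys.osmotic) / (N_AVOGADRO * physics.c_out)
        surface = 0.5 * (n_l * sys.alpha_l_m2 + n_L * sys.alpha_L_m2)
    else:
        volume = np.full(sample_times.size, v_fixed)
        surface = np.full(sample_times.size, s_fixed)
    phi = surface / (36.0 * math.pi * volume**2) ** (1.0 / 3.0)
    area = n_l * sys.alpha_l_m2 + n_L * sys.alpha_L_m2
    chi = np.divide(n_L * sys.alpha_L_m2, area, out=np.zeros_like(area), where=area > 0)

    records = [
        DivisionRecord(
            generation=g + 1,
            t_division=float(div_t[g]),
            T_div=float(div_stats[g, 0]),
            chi_L=float(div_stats[g, 1]),
            volume=float(div_stats[g, 2]),
            surface=float(div_stats[g, 3]),
            counts={sp: int(div_counts[g, i]) for i, sp in enumerate(sys.species)},
            kept_counts={sp: int(div_kept[g, i]) for i, sp in enumerate(sys.species)},
        )
        for g in range(int(n_div))
    ]
    return SSAResult(
        species=list(sys.species),
        t=sample_times,
        counts=counts,
        n_l=n_l,
        n_L=n_L,
        volume=volume,
        surface=surface,
        phi=phi,
        chi=chi,
        records=records,
        outcome=_OUTCOMES[int(outcome)],
        n_events=int(n_events),
        max_isotonic_dev=float(max_iso_dev),
        seed=seed,
    )


def division_stats(
    records: Sequence[DivisionRecord] | Sequence[float], window: int = 10
) -> dict[str, float]:
    """Mean and SD of the division interval over the last ``window`` generations.

    Accepts either DivisionRecord sequences or raw interval lists.  The first
    record of a lineage (interval measured from t=0) is excluded when records
    are given.
    """
    if len(records) and isinstance(records[0], DivisionRecord):
        recs = list(records)[1:] if len(records) > 1 else list(records)
        intervals = [r.T_div for r in recs]
        chis = [r.chi_L for r in recs]
    else:
        intervals = [float(x) for x in records]
        chis = []
    if len(intervals) < window:
        raise ValueError(
            f"insufficient data: {len(intervals)} intervals available, window={window}"
        )
    tail = np.asarray(intervals[-window:])
    out = {
        "mean_T_div": float(np.mean(tail)),
        "sd_T_div": float(np.std(tail, ddof=1)) if window > 1 else 0.0,
        "n": window,
    }
    if chis:
        out["mean_chi_L"] = float(np.mean(np.asarray(chis[-window:])))
    return out


def project_population(mean_T_div: float, t_grid: Sequence[float]) -> PopulationCurve:
    """N(t) = 2^(t / T_div) from a single ancestor under non-limiting resources."""
    if not mean_T_div > 0:
        raise ValueError("mean division time must be positive")
    t = np.asarray(list(t_grid), dtype=float)
    return PopulationCurve(times=t, population=np.power(2.0, t / mean_T_div))
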