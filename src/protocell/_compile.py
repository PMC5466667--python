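"""Flat-array encoding of a network + physics block, shared by both engines.

Internal engine units: time in hours, volume m^3, surface m^2, counts in
molecules, concentrations mol/m^3.  Config-level permeabilities (m/s) are
converted to m/h here, once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .networks import NetworkModel
from .physics import (
    N_AVOGADRO,
    PhysicsParams,
    MembraneState,
    ProtocellState,
    initial_membrane,
    sphere_volume,
)

S_PER_H = 3600.0
NM2_TO_M2 = 1.0e-18

#: implicit inert internal osmolyte used to fill the initial isotonic budget
FILLER_SPECIES = "X"

PERM_NONE, PERM_CONST, PERM_COMPDEP = 0, 1, 2


@dataclass
class CompiledSystem:
    """Arrays describing one protocell system; see module docstring for units."""

    model: NetworkModel
    physics: PhysicsParams
    species: list[str]
    index: dict[str, int]
    osmotic: np.ndarray
    perm_class: np.ndarray
    perm_base: np.ndarray  # m/h
    env_conc: np.ndarray
    stoich: np.ndarray  # (n_rxn, n_sp)
    react_idx: np.ndarray  # (n_rxn, 3), -1 padded
    cat_idx: np.ndarray
    rate_k: np.ndarray
    rxn_order: np.ndarray
    has_membrane_L: bool
    iL: int
    alpha_l_m2: float
    alpha_L_m2: float
    u_l: float  # molecules / m^2 / h
    k_out: float  # 1/h
    k_ins: float  # m/h
    k_d: float  # 1/h

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- geometry helpers -------------------------------------------------
    def volume_of(self, counts: np.ndarray) -> float:
        return float(counts @ self.osmotic) / (N_AVOGADRO * self.physics.c_out)

    def surface_of(self, n_l: float, n_L: float) -> float:
        return 0.5 * (n_l * self.alpha_l_m2 + n_L * self.alpha_L_m2)

    def chi_of(self, n_l: float, n_L: float) -> float:
        tot = n_l * self.alpha_l_m2 + n_L * self.alpha_L_m2
        return n_L * self.alpha_L_m2 / tot if tot > 0 else 0.0

    def curve_arrays(self):
        curve = self.physics.curve()
        if curve is None:
            return (
                np.array([0.0, 1.0]),
                np.array([-1.0, 1.0]),
                np.array([1.0, 1.0]),
                False,
            )
        return curve._x, curve._w, curve._f, True

    def eval_curve(self, chi: float) -> float:
        curve = self.physics.curve()
        return 1.0 if curve is None else curve(chi)


def compile_system(model: NetworkModel, physics: PhysicsParams) -> CompiledSystem:
    aqueous = [s for s in model.species if s.role != "membrane_lipid"]
    names = [s.name for s in aqueous] + [FILLER_SPECIES]
    index = {n: i for i, n in enumerate(names)}
    n_sp = len(names)

    osmotic = np.zeros(n_sp)
    perm_class = np.zeros(n_sp, dtype=np.int64)
    perm_base = np.zeros(n_sp)
    env_conc = np.zeros(n_sp)
    for i, s in enumerate(aqueous):
        osmotic[i] = 1.0 if s.osmotically_active else 0.0
        if s.permeability_class == "constant":
            perm_class[i] = PERM_CONST
        elif s.permeability_class == "composition_dependent":
            perm_class[i] = PERM_COMPDEP
        perm_base[i] = s.base_permeability * S_PER_H
        env_conc[i] = s.env_concentration or 0.0
    osmotic[index[FILLER_SPECIES]] = 1.0  # inert, impermeable filler

    n_rxn = len(model.reactions)
    stoich = np.zeros((n_rxn, n_sp))
    react_idx = -np.ones((n_rxn, 3), dtype=np.int64)
    cat_idx = -np.ones(n_rxn, dtype=np.int64)
    rate_k = np.zeros(n_rxn)
    rxn_order = np.zeros(n_rxn, dtype=np.int64)
    for j, rxn in enumerate(model.reactions):
        slot = 0
        for sp, nu in rxn.reactants.items():
            stoich[j, index[sp]] -= nu
            for _ in range(nu):
                react_idx[j, slot] = index[sp]
                slot += 1
        for sp, nu in rxn.products.items():
            stoich[j, index[sp]] += nu
        if rxn.catalyst is not None:
            cat_idx[j] = index[rxn.catalyst]
        rate_k[j] = rxn.rate_constant
        rxn_order[j] = rxn.order

    membrane_names = {s.name for s in model.species if s.role == "membrane_lipid"}
    has_L = "L_mem" in membrane_names
    iL = index.get("L", -1)
    k_d = float(model.membrane_params.get("k_d", physics.k_d))

    return CompiledSystem(
        model=model,
        physics=physics,
        species=names,
        index=index,
        osmotic=osmotic,
        perm_class=perm_class,
        perm_base=perm_base,
        env_conc=env_conc,
        stoich=stoich,
        react_idx=react_idx,
        cat_idx=cat_idx,
        rate_k=rate_k,
        rxn_order=rxn_order,
        has_membrane_L=has_L,
        iL=iL,
        alpha_l_m2=physics.alpha_l * NM2_TO_M2,
        alpha_L_m2=physics.alpha_L * NM2_TO_M2,
        u_l=physics.k_in_l * S_PER_H * physics.c_l_env * N_AVOGADRO,
        k_out=physics.k_out_l,
        k_ins=physics.k_ins_L * S_PER_H,
        k_d=k_d,
    )


def initial_state(
    model: NetworkModel,
    physics: PhysicsParams,
    init_conc: Optional[Mapping[str, float]] = None,
) -> ProtocellState:
    """Spherical, isotonic initial protocell.

    Metabolite (and any other) initial concentrations come from
    ``init_conc`` (mol/m^3); nutrients default to transport equilibrium with
    the environment.  The inert filler osmolyte tops the census up to the
    exact isotonic budget of the initial sphere.
    """
    sys = compile_system(model, physics)
    v0 = sphere_volume(physics.r0)
    budget = round(v0 * N_AVOGADRO * physics.c_out)
    conc = {}
    for s in model.species:
        if s.role == "membrane_lipid":
            continue
        if s.role == "nutrient" or s.role == "lipid_precursor":
            conc[s.name] = s.env_concentration or 0.0
        else:
            conc[s.name] = 0.0
    if init_conc:
        conc.update(init_conc)
    counts = {sp: round(c * v0 * N_AVOGADRO) for sp, c in conc.items()}
    used = sum(counts[sp] for sp in counts if sys.osmotic[sys.index[sp]] > 0)
    filler = budget - used
    if filler < 0:
        if -filler <= 1e-3 * budget:  # rounding slack only
            filler = 0
        else:
            raise ValueError(
                "initial solute load exceeds the isotonic budget; lower init_conc or raise c_out"
            )
    counts[FILLER_SPECIES] = filler
    return ProtocellState(t=0.0, counts=counts, membrane=initial_membrane(physics))


def state_vector(sys: CompiledSystem, state: ProtocellState) -> np.ndarray:
    """[aqueous counts..., n_l, n_L] as floats."""
    y = np.zeros(sys.n_species + 2)
    for sp, n in state.counts.items():
        y[sys.index[sp]] = n
    y[-2] = state.membrane.n_l
    y[-1] = state.membrane.n_L
    return y
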