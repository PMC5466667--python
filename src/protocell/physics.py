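"""Compartment physics: geometry, osmosis, membrane composition and events.

The compartment is a topologically closed lipid bilayer of fixed thickness.
Its surface area follows from the lipid head-area census; its internal
volume is an exact algebraic projection enforcing the isotonic condition
after every state change (water equilibrates much faster than any chemistry
here, so no explicit water-flux kinetics).  The dimensionless reduced
surface Phi = S / (36 pi V^2)^(1/3) classifies the shape: Phi = 1 is a
sphere, Phi >= 2^(1/3) provides enough surface for two equal spheres of
half the volume (division), Phi < 1 means osmotic tension (burst when
Phi <= 1 - epsilon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
from scipy.constants import Avogadro as N_AVOGADRO

from .networks import SpeciesSpec

__all__ = [
    "N_AVOGADRO",
    "PHI_DIVIDE_DEFAULT",
    "MembraneState",
    "ProtocellState",
    "PermeabilityCurve",
    "EventRule",
    "PhysicsParams",
    "surface_area",
    "surface_fraction_L",
    "isotonic_volume",
    "reduced_surface",
    "effective_permeability",
    "transport_fluxes",
    "lipid_exchange_propensities",
    "check_event",
    "divide",
]

PHI_DIVIDE_DEFAULT = 2.0 ** (1.0 / 3.0)
NM2_TO_M2 = 1.0e-18


@dataclass
class MembraneState:
    """Bilayer census: molecule counts and head areas of the two lipids.

    ``n_l``/``n_L`` are total molecule counts over both leaflets, head areas
    in nm^2, ``thickness`` in nm.  ``min_lipids`` is the smallest census for
    which a closed bilayer is still assumed to exist.
    """

    n_l: float
    n_L: float = 0.0
    alpha_l: float = 0.2
    alpha_L: float = 0.6
    thickness: float = 3.0
    min_lipids: int = 1000

    def __post_init__(self) -> None:
        if self.n_l < 0 or self.n_L < 0:
            raise ValueError("negative membrane lipid count")
        if self.n_l + self.n_L < self.min_lipids:
            raise ValueError(
                f"membrane census {self.n_l + self.n_L:.0f} below closure minimum "
                f"{self.min_lipids}"
            )
        if self.alpha_l <= 0 or self.alpha_L <= 0 or self.thickness <= 0:
            raise ValueError("head areas and thickness must be positive")


def surface_area(m: MembraneState) -> float:
    """Bilayer surface area S (m^2): total head area shared by two leaflets."""
    total_nm2 = m.n_l * m.alpha_l + m.n_L * m.alpha_L
    if total_nm2 <= 0:
        raise ValueError("empty membrane has no surface")
    return 0.5 * total_nm2 * NM2_TO_M2


def surface_fraction_L(m: MembraneState) -> float:
    """Fraction of membrane surface covered by the synthesized lipid L."""
    total = m.n_l * m.alpha_l + m.n_L * m.alpha_L
    if total <= 0:
        raise ValueError("empty membrane")
    return m.n_L * m.alpha_L / total


def isotonic_volume(counts: Union[Mapping[str, float], float], c_out: float) -> float:
    """Internal volume (m^3) that makes the compartment isotonic with outside.

    ``counts`` is either the summed count of osmotically active internal
    molecules or a mapping whose values are summed; membrane lipids must be
    excluded by the caller.  ``c_out`` is the total external osmolarity in
    mol/m^3.
    """
    if c_out <= 0:
        raise ValueError("external osmolarity must be positive")
    total = float(sum(counts.values())) if isinstance(counts, Mapping) else float(counts)
    if total <= 0:
        raise ValueError("no internal osmolytes: isotonic volume is degenerate")
    return total / (N_AVOGADRO * c_out)


def reduced_surface(surface: float, volume: float) -> float:
    """Phi = S / (36 pi V^2)^(1/3): actual surface over equal-volume sphere surface."""
    if surface <= 0 or volume <= 0:
        raise ValueError("surface and volume must be positive")
    return surface / (36.0 * math.pi * volume**2) ** (1.0 / 3.0)


@dataclass
class PermeabilityCurve:
    """Composition -> permeability multiplier, exact-matching polynomial.

    Control points are (surface fraction chi, multiplier f); the evaluant is
    the unique interpolating polynomial through all of them (barycentric
    Lagrange form), so every control point is reproduced exactly.
    """

    control_points: tuple

    def __init__(self, control_points) -> None:
        pts = sorted((float(x), float(f)) for x, f in control_points)
        xs = [p[0] for p in pts]
        if len(xs) != len(set(xs)):
            raise ValueError("duplicate chi values in control points")
        if len(pts) < 2 or xs[0] != 0.0 or xs[-1] != 1.0:
            raise ValueError("control points must span chi = 0 and chi = 1")
        if any(p[1] <= 0 for p in pts):
            raise ValueError("multipliers must be positive")
        self.control_points = tuple(pts)
        x = np.array(xs)
        # barycentric weights w_j = 1 / prod_{k != j} (x_j - x_k)
        w = np.ones_like(x)
        for j in range(len(x)):
            w[j] = 1.0 / np.prod(x[j] - np.delete(x, j))
        self._x = x
        self._w = w
        self._f = np.array([p[1] for p in pts])

    def __call__(self, chi: float) -> float:
        if not 0.0 <= chi <= 1.0:
            raise ValueError(f"chi = {chi} outside [0, 1]: extrapolation refused")
        diff = chi - self._x
        exact = np.where(diff == 0.0)[0]
        if exact.size:
            return float(self._f[exact[0]])
        t = self._w / diff
        return float(np.sum(t * self._f) / np.sum(t))

    def coefficients(self) -> np.ndarray:
        """Monomial coefficients (highest degree first) of the interpolant."""
        return np.polyfit(self._x, self._f, len(self._x) - 1)

    def to_dict(self) -> dict:
        return {"control_points": [list(p) for p in self.control_points]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PermeabilityCurve":
        return cls(d["control_points"])


DEFAULT_CURVE_POINTS = ((0.0, 1.0), (0.375, 10.0), (1.0, 2.0))


@dataclass(frozen=True)
class EventRule:
    """Shape thresholds for division and osmotic burst."""

    phi_divide: float = PHI_DIVIDE_DEFAULT
    epsilon_burst: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon_burst < 1.0 and self.phi_divide > 1.0):
            raise ValueError("need 1 - epsilon < 1 < phi_divide")


@dataclass
class ProtocellState:
    """Full protocell state: internal counts, membrane census, clock."""

    t: float
    counts: dict[str, float]
    membrane: MembraneState
    lineage_id: int = 0
    generation: int = 0

    def copy(self) -> "ProtocellState":
        return ProtocellState(
            t=self.t,
            counts=dict(self.counts),
            membrane=replace(self.membrane),
            lineage_id=self.lineage_id,
            generation=self.generation,
        )


def effective_permeability(
    species: SpeciesSpec, chi: float, curve: Optional[PermeabilityCurve]
) -> float:
    """Permeability (m/s) of ``species`` at membrane composition ``chi``."""
    if species.permeability_class == "impermeable":
        return 0.0
    if species.permeability_class == "constant" or curve is None:
        return species.base_permeability
    return species.base_permeability * curve(chi)


def transport_fluxes(
    species_list: list[SpeciesSpec],
    counts: Mapping[str, float],
    volume: float,
    surface: float,
    chi: float,
    curve: Optional[PermeabilityCurve],
) -> dict[str, tuple[float, float]]:
    """Per-species (influx, efflux) in molecules/s.

    Influx is P * S * c_env * N_A, efflux P * S * (N/V); both are reported
    separately and non-negative so they can serve directly as stochastic
    propensities.
    """
    out: dict[str, tuple[float, float]] = {}
    for sp in species_list:
        if sp.role == "membrane_lipid":
            continue
        p = effective_permeability(sp, chi, curve)
        if p == 0.0:
            out[sp.name] = (0.0, 0.0)
            continue
        c_env = sp.env_concentration or 0.0
        influx = p * surface * c_env * N_AVOGADRO
        efflux = p * surface * counts.get(sp.name, 0.0) / volume
        out[sp.name] = (influx, efflux)
    return out


def lipid_exchange_propensities(
    state: ProtocellState,
    volume: float,
    surface: float,
    c_l_env: float,
    k_in: float,
    k_out: float,
    k_ins: float,
    k_d: float,
    aqueous_L: float = 0.0,
) -> dict[str, float]:
    """Event propensities (1/s) of the four membrane-exchange channels.

    1. ``l_uptake``   primitive lipid adsorbs from the bath: k_in * S * c_l_env * N_A
    2. ``l_release``  primitive lipid desorbs: k_out * N_l
    3. ``L_insert``   aqueous synthesized lipid inserts: k_ins * S * (N_L_aq / V)
    4. ``displacement`` one membrane L leaves to an external sink while one l
       enters from the bath, atomically: k_d * N_L_mem (conserves the census)

    ``k_in``/``k_ins`` in m/s, ``k_out``/``k_d`` in 1/s.
    """
    return {
        "l_uptake": k_in * surface * c_l_env * N_AVOGADRO,
        "l_release": k_out * state.membrane.n_l,
        "L_insert": k_ins * surface * aqueous_L / volume,
        "displacement": k_d * state.membrane.n_L,
    }


def check_event(phi: float, rule: EventRule) -> str:
    """Classify the current shape: 'divide', 'burst' or 'none'.

    Division takes precedence (unreachable simultaneously with defaults).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if phi >= rule.phi_divide:
        return "divide"
    if phi <= 1.0 - rule.epsilon_burst:
        return "burst"
    return "none"


def divide(
    state: ProtocellState, rng: np.random.Generator
) -> tuple[ProtocellState, ProtocellState]:
    """Split a protocell into two daughters.

    Membrane lipids split evenly per species (odd remainder to a random
    daughter); every internal count is partitioned binomially with p = 1/2.
    Daughter sums equal the mother exactly for every species.
    """
    counts1: dict[str, float] = {}
    counts2: dict[str, float] = {}
    for sp, n in state.counts.items():
        n_int = int(round(n))
        a = int(rng.binomial(n_int, 0.5)) if n_int > 0 else 0
        counts1[sp] = a
        counts2[sp] = n_int - a
    halves = []
    for n in (state.membrane.n_l, state.membrane.n_L):
        n_int = int(round(n))
        a = n_int // 2
        if n_int % 2 == 1 and rng.random() < 0.5:
            a += 1
        halves.append((a, n_int - a))
    mk = lambda nl, nL: replace(state.membrane, n_l=nl, n_L=nL)
    d1 = ProtocellState(
        t=state.t,
        counts=counts1,
        membrane=mk(halves[0][0], halves[1][0]),
        lineage_id=2 * state.lineage_id + 1,
        generation=state.generation + 1,
    )
    d2 = ProtocellState(
        t=state.t,
        counts=counts2,
        membrane=mk(halves[0][1], halves[1][1]),
        lineage_id=2 * state.lineage_id + 2,
        generation=state.generation + 1,
    )
    return d1, d2


@dataclass
class PhysicsParams:
    """Compartment parameter block shared by both engines.

    Permeability-like constants (``k_in_l``, ``k_ins_L``) are in m/s, rate
    constants (``k_out_l``, ``k_d``) in 1/h; head areas and lengths in nm;
    concentrations in mol/m^3.
    """

    alpha_l: float = 0.2
    alpha_L: float = 0.6
    thickness: float = 3.0
    c_out: float = 100.0
    r0: float = 200.0
    chi0: float = 0.0
    phi0: float = 1.1
    c_l_env: float = 0.5
    k_in_l: float = 1.85e-13
    k_out_l: float = 2.0e-5
    k_ins_L: float = 2.8e-11
    k_d: float = 0.0
    phi_divide: float = PHI_DIVIDE_DEFAULT
    epsilon_burst: float = 0.1
    composition_dependent: bool = True
    curve_points: tuple = DEFAULT_CURVE_POINTS
    min_lipids: int = 1000

    def curve(self) -> Optional[PermeabilityCurve]:
        return PermeabilityCurve(self.curve_points) if self.composition_dependent else None

    def event_rule(self) -> EventRule:
        return EventRule(self.phi_divide, self.epsilon_burst)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "alpha_l", "alpha_L", "thickness", "c_out", "r0", "chi0", "phi0", "c_l_env",
                "k_in_l", "k_out_l", "k_ins_L", "k_d", "phi_divide",
                "epsilon_burst", "composition_dependent", "min_lipids",
            )
        }
        d["curve_points"] = [list(p) for p in self.curve_points]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhysicsParams":
        d = dict(d)
        if "curve_points" in d:
            d["curve_points"] = tuple(tuple(p) for p in d["curve_points"])
        return cls(**d)


def initial_membrane(params: PhysicsParams) -> MembraneState:
    """Membrane enclosing an r0 (nm) sphere at composition ``chi0``.

    The lipid census is scaled by ``phi0`` so the initial reduced surface is
    phi0 (>1 starts the vesicle slightly deflated, with surface in reserve).
    """
    s0_nm2 = 4.0 * math.pi * params.r0**2 * params.phi0
    n_l = round(2.0 * s0_nm2 * (1.0 - params.chi0) / params.alpha_l)
    n_L = round(2.0 * s0_nm2 * params.chi0 / params.alpha_L)
    return MembraneState(
        n_l=n_l,
        n_L=n_L,
        alpha_l=params.alpha_l,
        alpha_L=params.alpha_L,
        thickness=params.thickness,
        min_lipids=params.min_lipids,
    )


def sphere_volume(r_nm: float) -> float:
    """Volume (m^3) of a sphere of radius ``r_nm`` nanometres."""
    return 4.0 / 3.0 * math.pi * (r_nm * 1e-9) ** 3
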