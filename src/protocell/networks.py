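"""Declarative mass-action reaction networks for minimal proto-metabolisms.

Two hypothetical proto-metabolic schemes are provided: a "heterotrophic"
two-cycle network (PM1) in which the catalysts AB and ACD mutually promote
each other's condensation, and an "autotrophic" variant (PM2) in which the
ACD-forming step is split through an additional reinforcing cycle producing
the AC intermediate.  Both networks take up energy-rich nutrients (A, B, C,
D) from the environment, release a small permeable by-product ``w`` per
condensation bond, and lose catalysts through first-order decay.  An optional
extension adds endogenous lipid synthesis (P -> L, catalysed by AB).

Networks are purely declarative: species carry transport/osmotic metadata,
reactions carry irreversible mass-action stoichiometry plus an optional
catalyst that enters the rate law only.  The simulation engines compile a
``NetworkModel`` into flat arrays; nothing here integrates anything.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "NetworkModel",
    "ConfigurationError",
    "StructuralError",
    "build_pm1",
    "build_pm2",
    "add_lipid_synthesis",
    "reaction_rate",
    "moiety_content",
    "reaction_moiety_delta",
    "closed_variant",
    "DEFAULT_PM1_RATES",
    "DEFAULT_PM2_RATES",
    "DEFAULT_NUTRIENT_ENV",
    "DEFAULT_NUTRIENT_PERMEABILITY",
    "DEFAULT_W_PERMEABILITY",
]

ROLES = frozenset(
    {
        "nutrient",
        "metabolite",
        "waste",
        "lipid_precursor",
        "aqueous_lipid",
        "membrane_lipid",
        "inert_osmolyte",
    }
)
PERMEABILITY_CLASSES = frozenset({"composition_dependent", "constant", "impermeable"})


class ConfigurationError(ValueError):
    """A parameter table is incomplete or inconsistent."""


class StructuralError(ValueError):
    """A network modification is incompatible with the model's structure."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Chemical species with transport and osmotic metadata.

    ``base_permeability`` is in m/s; ``head_area`` (membrane lipids only) in
    nm^2; ``env_concentration`` (environment-buffered species) in mol/m^3.
    """

    name: str
    role: str
    permeability_class: str = "impermeable"
    base_permeability: float = 0.0
    osmotically_active: bool = True
    head_area: Optional[float] = None
    env_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for species {self.name!r}")
        if self.permeability_class not in PERMEABILITY_CLASSES:
            raise ConfigurationError(
                f"unknown permeability class {self.permeability_class!r} for {self.name!r}"
            )
        if self.permeability_class == "impermeable" and self.base_permeability != 0.0:
            raise ConfigurationError(
                f"impermeable species {self.name!r} must have base_permeability 0"
            )
        if self.base_permeability < 0.0:
            raise ConfigurationError(f"negative permeability for {self.name!r}")
        if (self.head_area is not None) != (self.role == "membrane_lipid"):
            raise ConfigurationError(
                f"head_area must be given iff role is membrane_lipid ({self.name!r})"
            )
        if self.head_area is not None and self.head_area <= 0.0:
            raise ConfigurationError(f"non-positive head area for {self.name!r}")
        if self.env_concentration is not None and self.env_concentration < 0.0:
            raise ConfigurationError(f"negative environment concentration for {self.name!r}")


@dataclass(frozen=True)
class ReactionSpec:
    """Irreversible mass-action reaction with an optional catalyst.

    The catalyst may appear on neither side; it multiplies the rate law only.
    ``rate_constant`` is in (mol/m^3)^(1-order) / h, order counting reactant
    molecularity plus one if a catalyst is present.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    catalyst: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", MappingProxyType(dict(self.reactants)))
        object.__setattr__(self, "products", MappingProxyType(dict(self.products)))
        for side in (self.reactants, self.products):
            for sp, nu in side.items():
                if not isinstance(nu, int) or nu <= 0:
                    raise ConfigurationError(
                        f"stoichiometry of {sp!r} in {self.name!r} must be a positive integer"
                    )
        if self.catalyst is not None and (
            self.catalyst in self.reactants or self.catalyst in self.products
        ):
            raise ConfigurationError(
                f"catalyst {self.catalyst!r} appears in the stoichiometry of {self.name!r}"
            )
        if not self.rate_constant > 0.0:
            raise ConfigurationError(f"rate constant of {self.name!r} must be > 0")

    @property
    def order(self) -> int:
        """Total molecularity of the rate law (reactants + catalyst)."""
        return sum(self.reactants.values()) + (1 if self.catalyst else 0)


@dataclass
class NetworkModel:
    """A named set of species and reactions, plus membrane-coupling metadata.

    ``membrane_params`` holds rate constants that belong to the membrane
    exchange machinery rather than to any bulk reaction (currently the lipid
    displacement constant ``k_d``).
    """

    name: str
    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    membrane_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate species names in model {self.name!r}")
        declared = set(names)
        for rxn in self.reactions:
            referenced = set(rxn.reactants) | set(rxn.products)
            if rxn.catalyst:
                referenced.add(rxn.catalyst)
            missing = referenced - declared
            if missing:
                raise StructuralError(
                    f"reaction {rxn.name!r} references undeclared species {sorted(missing)}"
                )
        roles = {s.role for s in self.species}
        if self.reactions and not ({"nutrient", "metabolite"} <= roles):
            raise StructuralError(
                f"model {self.name!r} must declare at least one nutrient and one metabolite"
            )

    @property
    def species_map(self) -> dict[str, SpeciesSpec]:
        return {s.name: s for s in self.species}

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def get_reaction(self, name: str) -> ReactionSpec:
        for rxn in self.reactions:
            if rxn.name == name:
                return rxn
        raise KeyError(name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {k: v for k, v in dataclasses.asdict(s).items() if v is not None}
                for s in self.species
            ],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "rate_constant": r.rate_constant,
                    **({"catalyst": r.catalyst} if r.catalyst else {}),
                }
                for r in self.reactions
            ],
            "membrane_params": dict(self.membrane_params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkModel":
        return cls(
            name=d["name"],
            species=[SpeciesSpec(**s) for s in d["species"]],
            reactions=[ReactionSpec(**r) for r in d["reactions"]],
            membrane_params=dict(d.get("membrane_params", {})),
        )


# ---------------------------------------------------------------------------
# Rate law
# ---------------------------------------------------------------------------

def reaction_rate(rxn: ReactionSpec, concentrations: Mapping[str, float]) -> float:
    """Mass-action rate (mol/m^3/h) of ``rxn`` at the given concentrations."""
    rate = rxn.rate_constant
    if rxn.catalyst is not None:
        c = concentrations[rxn.catalyst]
        if c < 0.0:
            raise ValueError(f"negative concentration for catalyst {rxn.catalyst!r}")
        rate *= c
    for sp, nu in rxn.reactants.items():
        c = concentrations[sp]
        if c < 0.0:
            raise ValueError(f"negative concentration for reactant {sp!r}")
        rate *= c**nu
    return rate


# ---------------------------------------------------------------------------
# Network constructors
# ---------------------------------------------------------------------------

# Default rate constants, chosen so that at the default environment
# concentrations a fixed 200 nm compartment reaches a non-trivial steady
# state on an hours-to-days timescale.  Units: (mol/m^3)^(1-order) per hour.
# The catalysts of the leaner two-cycle network decay faster than those of
# the three-cycle network, which leaves the former operating in the
# decay-dominated (permeability-sensitive) regime and the latter partly
# buffered by growth dilution.
DEFAULT_PM1_RATES: Mapping[str, float] = MappingProxyType(
    {"k1": 0.01, "k2": 1.0e-3, "d1": 0.25, "d2": 0.25}
)
DEFAULT_PM2_RATES: Mapping[str, float] = MappingProxyType(
    {"k1": 0.01, "k2": 5.0e-3, "k3": 0.01, "d1": 0.03, "d2": 0.03, "d3": 0.03}
)

DEFAULT_NUTRIENT_ENV = 10.0  # mol/m^3, each of A, B, C, D (and P when added)
DEFAULT_NUTRIENT_PERMEABILITY = 2.0e-12  # m/s at the pure-l membrane (chi = 0)
DEFAULT_W_PERMEABILITY = 1.0e-11  # m/s, composition-independent


def _require(params: Mapping[str, float], key: str, reaction: str) -> float:
    k = params.get(key)
    if k is None:
        raise ConfigurationError(
            f"missing rate constant {key!r} for reaction {reaction!r}"
        )
    if not k > 0.0:
        raise ConfigurationError(f"rate constant {key!r} for reaction {reaction!r} must be > 0")
    return float(k)


def _core_species(
    extra: tuple[str, ...] = (),
    env_conc: float = DEFAULT_NUTRIENT_ENV,
    nutrient_permeability: float = DEFAULT_NUTRIENT_PERMEABILITY,
    w_permeability: float = DEFAULT_W_PERMEABILITY,
) -> list[SpeciesSpec]:
    nutrients = [
        SpeciesSpec(
            name=n,
            role="nutrient",
            permeability_class="composition_dependent",
            base_permeability=nutrient_permeability,
            env_concentration=env_conc,
        )
        for n in "ABCD"
    ]
    metabolites = [
        SpeciesSpec(name=m, role="metabolite") for m in ("AB",) + extra + ("ACD",)
    ]
    wastes = [
        SpeciesSpec(
            name="w",
            role="waste",
            permeability_class="constant",
            base_permeability=w_permeability,
            env_concentration=0.0,
        ),
        SpeciesSpec(name="acd", role="waste"),  # totally impermeable end-product
    ]
    return nutrients + metabolites + wastes


def build_pm1(params: Optional[Mapping[str, float]] = None, **species_kwargs) -> NetworkModel:
    """Two mutually promoting catalytic cycles driven by AB and ACD.

    Reactions (irreversible mass-action, catalyst in parentheses):

    - R1: A + B -> AB + w      (ACD)
    - R2: A + C + D -> ACD + 2w (AB)
    - D1: AB -> 2w
    - D2: ACD -> acd
    """
    p = dict(DEFAULT_PM1_RATES)
    if params is not None:
        p.update(params)
    reactions = [
        ReactionSpec("R1", {"A": 1, "B": 1}, {"AB": 1, "w": 1}, _require(p, "k1", "R1"), "ACD"),
        ReactionSpec(
            "R2", {"A": 1, "C": 1, "D": 1}, {"ACD": 1, "w": 2}, _require(p, "k2", "R2"), "AB"
        ),
        ReactionSpec("D1", {"AB": 1}, {"w": 2}, _require(p, "d1", "D1")),
        ReactionSpec("D2", {"ACD": 1}, {"acd": 1}, _require(p, "d2", "D2")),
    ]
    return NetworkModel("pm1", _core_species(**species_kwargs), reactions)


def build_pm2(params: Optional[Mapping[str, float]] = None, **species_kwargs) -> NetworkModel:
    """PM1 plus one extra reinforcing cycle through the AC intermediate.

    - R1: A + B -> AB + w   (ACD)
    - R2: A + C -> AC + w   (ACD)
    - R3: AC + D -> ACD + w (AB)
    - D1: AB -> 2w
    - D2: ACD -> acd
    - D3: AC -> 2w
    """
    p = dict(DEFAULT_PM2_RATES)
    if params is not None:
        p.update(params)
    reactions = [
        ReactionSpec("R1", {"A": 1, "B": 1}, {"AB": 1, "w": 1}, _require(p, "k1", "R1"), "ACD"),
        ReactionSpec("R2", {"A": 1, "C": 1}, {"AC": 1, "w": 1}, _require(p, "k2", "R2"), "ACD"),
        ReactionSpec("R3", {"AC": 1, "D": 1}, {"ACD": 1, "w": 1}, _require(p, "k3", "R3"), "AB"),
        ReactionSpec("D1", {"AB": 1}, {"w": 2}, _require(p, "d1", "D1")),
        ReactionSpec("D2", {"ACD": 1}, {"acd": 1}, _require(p, "d2", "D2")),
        ReactionSpec("D3", {"AC": 1}, {"w": 2}, _require(p, "d3", "D3")),
    ]
    return NetworkModel("pm2", _core_species(extra=("AC",), **species_kwargs), reactions)


DEFAULT_LIPID_HEAD_AREA_L = 0.2  # nm^2, primitive lipid l
DEFAULT_LIPID_HEAD_AREA_SYN = 0.6  # nm^2, synthesized lipid L


def add_lipid_synthesis(
    model: NetworkModel,
    k_syn: float,
    k_d: float = 0.0,
    precursor_env: float = DEFAULT_NUTRIENT_ENV,
    precursor_permeability: float = DEFAULT_NUTRIENT_PERMEABILITY,
    alpha_l: float = DEFAULT_LIPID_HEAD_AREA_L,
    alpha_L: float = DEFAULT_LIPID_HEAD_AREA_SYN,
) -> NetworkModel:
    """Extend ``model`` with endogenous lipid synthesis P -> L (catalysed by AB).

    Adds the diffusible precursor P, the aqueous lipid L, and the two
    membrane lipid species (l_mem, L_mem).  The displacement constant ``k_d``
    is registered with the membrane-exchange machinery and is *not* a bulk
    reaction, so varying it leaves the synthesis rate law untouched.
    Returns a new model; the input is not mutated.
    """
    if "AB" not in {s.name for s in model.species}:
        raise StructuralError(f"model {model.name!r} lacks the AB catalyst")
    if not k_syn > 0.0:
        raise ConfigurationError("k_syn must be > 0")
    if k_d < 0.0:
        raise ConfigurationError("k_d must be >= 0")
    new_species = list(model.species) + [
        SpeciesSpec(
            name="P",
            role="lipid_precursor",
            permeability_class="composition_dependent",
            base_permeability=precursor_permeability,
            env_concentration=precursor_env,
        ),
        SpeciesSpec(name="L", role="aqueous_lipid"),
        SpeciesSpec(
            name="l_mem",
            role="membrane_lipid",
            osmotically_active=False,
            head_area=alpha_l,
        ),
        SpeciesSpec(
            name="L_mem",
            role="membrane_lipid",
            osmotically_active=False,
            head_area=alpha_L,
        ),
    ]
    new_reactions = list(model.reactions) + [
        ReactionSpec("RS", {"P": 1}, {"L": 1}, k_syn, "AB")
    ]
    membrane_params = dict(model.membrane_params)
    membrane_params["k_d"] = float(k_d)
    return NetworkModel(model.name + "+lipid", new_species, new_reactions, membrane_params)


# ---------------------------------------------------------------------------
# Moiety bookkeeping
# ---------------------------------------------------------------------------

_PRIMITIVE_MOIETIES = ("a", "b", "c", "d")

# Moiety content per species: the condensation by-product w carries none of
# the primitive moieties (they stay in the condensate); decayed ACD keeps its
# full moiety load in the trapped acd end-product.
_MOIETY_TABLE: Mapping[str, Mapping[str, int]] = {
    "A": {"a": 1},
    "B": {"b": 1},
    "C": {"c": 1},
    "D": {"d": 1},
    "AB": {"a": 1, "b": 1},
    "AC": {"a": 1, "c": 1},
    "ACD": {"a": 1, "c": 1, "d": 1},
    "acd": {"a": 1, "c": 1, "d": 1},
    "ab_decay": {"a": 1, "b": 1},
    "ac_decay": {"a": 1, "c": 1},
}


def moiety_content(species_name: str) -> Mapping[str, int]:
    """Primitive moiety (a, b, c, d) content of a species; unknown species carry none."""
    return dict(_MOIETY_TABLE.get(species_name, {}))


def reaction_moiety_delta(rxn: ReactionSpec) -> dict[str, int]:
    """Net change of each primitive moiety across ``rxn`` (0 everywhere if conserving)."""
    delta = {m: 0 for m in _PRIMITIVE_MOIETIES}
    for sp, nu in rxn.products.items():
        for m, n in moiety_content(sp).items():
            delta[m] += nu * n
    for sp, nu in rxn.reactants.items():
        for m, n in moiety_content(sp).items():
            delta[m] -= nu * n
    return delta


def closed_variant(model: NetworkModel) -> NetworkModel:
    """Moiety-conserving variant for conservation tests.

    Catalyst decays to the structureless by-product w (AB -> 2w, AC -> 2w)
    drop primitive moieties by design; this variant reroutes them to inert,
    impermeable, moiety-carrying sinks so every reaction conserves all four
    primitive moieties exactly.  Transport is a property of the engines, not
    of the network, so a closed trajectory follows from running any engine
    with permeabilities zeroed.
    """
    sinks_needed = set()
    new_reactions = []
    for rxn in model.reactions:
        if any(v != 0 for v in reaction_moiety_delta(rxn).values()):
            if set(rxn.reactants) == {"AB"}:
                sink = "ab_decay"
            elif set(rxn.reactants) == {"AC"}:
                sink = "ac_decay"
            else:
                raise StructuralError(
                    f"no moiety-conserving reroute known for reaction {rxn.name!r}"
                )
            sinks_needed.add(sink)
            new_reactions.append(
                ReactionSpec(rxn.name, rxn.reactants, {sink: 1}, rxn.rate_constant, rxn.catalyst)
            )
        else:
            new_reactions.append(rxn)
    new_species = list(model.species) + [
        SpeciesSpec(name=s, role="waste") for s in sorted(sinks_needed)
    ]
    return NetworkModel(model.name + "+closed", new_species, new_reactions, dict(model.membrane_params))
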