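"""In-memory representation of a well-mixed biochemical reaction network.

A network is a list of species, a single compartment of volume ``Omega``
(litres) and a list of irreversible reactions, each carrying a *mesoscopic
propensity*: a symbolic expression in the molecule-count symbols of the
species (one symbol per species id) and the effective system size symbol
:data:`ssekit.constants.SYSTEM_SIZE`.  The propensity of reaction ``j`` times
``dt`` is the probability that the reaction fires in ``[t, t+dt)``.

Rate constants are inlined numerically into the propensities at construction
time; the ``parameters`` mapping is retained as metadata.  Concentrations are
molar throughout; molecule counts relate to concentrations through the
effective system size ``Omega_eff = volume * N_A`` (or ``volume`` for
item-based substance units).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .constants import AVOGADRO, SYSTEM_SIZE

__all__ = [
    "ValueKind",
    "SpeciesDef",
    "ReactionDef",
    "ReactionNetwork",
    "NetworkBuilder",
    "count_symbol",
    "conc_symbol",
]


def count_symbol(species_id: str) -> sp.Symbol:
    """Molecule-count symbol for a species (used in propensities)."""
    return sp.Symbol(f"n_{species_id}", nonnegative=True)


def conc_symbol(species_id: str) -> sp.Symbol:
    """Concentration symbol for a species (used in macroscopic rates)."""
    return sp.Symbol(f"phi_{species_id}", nonnegative=True)


class ValueKind(enum.Enum):
    AMOUNT = "amount"
    CONCENTRATION = "concentration"


@dataclass
class SpeciesDef:
    id: str
    name: str = ""
    compartment_id: str = "cell"
    initial_value: float = 0.0
    value_kind: ValueKind = ValueKind.CONCENTRATION
    unit: str = "mole"  # substance unit: "mole" (molar frame) or "item"

    def __post_init__(self):
        if self.initial_value < 0:
            raise ValueError(f"species {self.id!r}: negative initial value")
        if not self.name:
            self.name = self.id


@dataclass
class ReactionDef:
    """One irreversible reaction channel.

    ``propensity`` is symbolic in the count symbols and ``SYSTEM_SIZE``;
    evaluating it at integer counts with the numeric system size substituted
    gives the stochastic rate in events per model time unit.
    """

    id: str
    reactant_stoich: dict  # species id -> non-negative int (s_ij)
    product_stoich: dict  # species id -> non-negative int (r_ij)
    propensity: sp.Expr
    is_elementary: bool = True
    rate_constant: float | None = None  # metadata, concentration frame

    def __post_init__(self):
        for st in (self.reactant_stoich, self.product_stoich):
            for sid, v in st.items():
                if int(v) != v or v < 0:
                    raise ValueError(
                        f"reaction {self.id!r}: stoichiometry of {sid!r} "
                        "must be a non-negative integer"
                    )


class ReactionNetwork:
    """Species, reactions and compartment of a single-volume network."""

    def __init__(
        self,
        species: list[SpeciesDef],
        reactions: list[ReactionDef],
        volume_liters: float,
        parameters: dict | None = None,
        time_unit: str = "second",
        name: str = "network",
    ):
        if volume_liters <= 0:
            raise ValueError("compartment volume must be positive")
        if not species:
            raise ValueError("network needs at least one species")
        if not reactions:
            raise ValueError("network needs at least one reaction")
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique")
        self.species = list(species)
        self.reactions = list(reactions)
        self.volume_liters = float(volume_liters)
        self.parameters = dict(parameters or {})
        self.time_unit = time_unit
        self.name = name
        self.avogadro = AVOGADRO
        self._index = {sid: i for i, sid in enumerate(ids)}
        self._check_symbols()

    # -- basic structure ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    @property
    def substance_is_item(self) -> bool:
        return all(s.unit == "item" for s in self.species)

    @property
    def system_size(self) -> float:
        """Molecule count per unit concentration: Omega*N_A (molar) or Omega."""
        if self.substance_is_item:
            return self.volume_liters
        return self.volume_liters * self.avogadro

    def _matrix(self, which: str) -> np.ndarray:
        m = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            st = rxn.reactant_stoich if which == "s" else rxn.product_stoich
            for sid, v in st.items():
                m[self._index[sid], j] = int(v)
        return m

    @property
    def reactant_matrix(self) -> np.ndarray:
        return self._matrix("s")

    @property
    def product_matrix(self) -> np.ndarray:
        return self._matrix("r")

    @property
    def stoich_matrix(self) -> np.ndarray:
        """Net stoichiometry S = r - s, shape (N, R)."""
        return self.product_matrix - self.reactant_matrix

    # -- state frames -------------------------------------------------------

    def initial_concentrations(self) -> np.ndarray:
        """Initial state as molar concentrations (or counts/volume for item)."""
        out = np.empty(self.n_species)
        for i, s in enumerate(self.species):
            if s.value_kind is ValueKind.CONCENTRATION:
                out[i] = s.initial_value
            else:
                out[i] = s.initial_value / self.system_size
        return out

    def initial_counts(self, rounded: bool = True) -> np.ndarray:
        """Initial state as molecule counts (rounded to nearest for the SSA)."""
        out = np.empty(self.n_species)
        for i, s in enumerate(self.species):
            if s.value_kind is ValueKind.AMOUNT:
                out[i] = s.initial_value
            else:
                out[i] = s.initial_value * self.system_size
        if rounded:
            out = np.rint(out)
        return out

    # -- propensity plumbing ------------------------------------------------

    def count_symbols(self) -> list[sp.Symbol]:
        return [count_symbol(s.id) for s in self.species]

    def conc_symbols(self) -> list[sp.Symbol]:
        return [conc_symbol(s.id) for s in self.species]

    def _check_symbols(self):
        allowed = set(self.count_symbols()) | {SYSTEM_SIZE}
        for rxn in self.reactions:
            extra = rxn.propensity.free_symbols - allowed
            if extra:
                raise ValueError(
                    f"reaction {rxn.id!r}: propensity references undeclared "
                    f"symbols {sorted(map(str, extra))}"
                )

    def propensity_function(self):
        """Compile propensities to a vectorised callable a(counts) -> (R,)."""
        syms = self.count_symbols()
        exprs = [
            rxn.propensity.subs(SYSTEM_SIZE, self.system_size)
            for rxn in self.reactions
        ]
        fns = [sp.lambdify(syms, e, modules="numpy") for e in exprs]

        def props(n: np.ndarray) -> np.ndarray:
            return np.array([f(*n) for f in fns], dtype=float)

        return props

    def __repr__(self):
        return (
            f"<ReactionNetwork {self.name!r}: N={self.n_species} species, "
            f"R={self.n_reactions} reactions, Omega={self.volume_liters:g} l>"
        )


def _falling_factorial(x: sp.Symbol, k: int) -> sp.Expr:
    out = sp.Integer(1)
    for i in range(k):
        out *= x - i
    return out


class NetworkBuilder:
    """Convenience builder for programmatic model construction.

    Mass-action reactions take a rate constant in the concentration frame
    (units ``M**(1-order)/time``); the mesoscopic propensity is built as
    ``k * Omega_eff**(1-order) * prod_i falling(n_i, s_ij)``, the falling
    factorial combinatorics of discrete molecules.
    """

    def __init__(self, name: str, volume_liters: float, time_unit: str = "second"):
        self.name = name
        self.volume_liters = volume_liters
        self.time_unit = time_unit
        self._species: list[SpeciesDef] = []
        self._reactions: list[ReactionDef] = []
        self._params: dict = {}

    def add_species(
        self,
        sid: str,
        initial: float = 0.0,
        kind: str = "concentration",
        name: str = "",
        unit: str = "mole",
    ) -> "NetworkBuilder":
        self._species.append(
            SpeciesDef(
                id=sid,
                name=name or sid,
                initial_value=initial,
                value_kind=ValueKind(kind),
                unit=unit,
            )
        )
        return self

    def add_parameter(self, name: str, value: float) -> "NetworkBuilder":
        self._params[name] = value
        return self

    def add_mass_action(
        self,
        rid: str,
        reactants: dict,
        products: dict,
        k: float,
        param_name: str | None = None,
    ) -> "NetworkBuilder":
        order = sum(reactants.values())
        prop = sp.Float(k) * SYSTEM_SIZE ** (1 - order)
        for sid, s in reactants.items():
            prop *= _falling_factorial(count_symbol(sid), int(s))
        self._reactions.append(
            ReactionDef(
                id=rid,
                reactant_stoich=dict(reactants),
                product_stoich=dict(products),
                propensity=sp.expand(prop),
                is_elementary=order <= 2,
                rate_constant=k,
            )
        )
        if param_name:
            self._params[param_name] = k
        return self

    def add_custom(
        self,
        rid: str,
        reactants: dict,
        products: dict,
        propensity: sp.Expr,
        is_elementary: bool = False,
    ) -> "NetworkBuilder":
        """Add a reaction with an arbitrary (possibly non-elementary) propensity."""
        self._reactions.append(
            ReactionDef(
                id=rid,
                reactant_stoich=dict(reactants),
                product_stoich=dict(products),
                propensity=propensity,
                is_elementary=is_elementary,
            )
        )
        return self

    def build(self) -> ReactionNetwork:
        return ReactionNetwork(
            species=self._species,
            reactions=self._reactions,
            volume_liters=self.volume_liters,
            parameters=self._params,
            time_unit=self.time_unit,
            name=self.name,
        )


def to_number_units(net: ReactionNetwork) -> ReactionNetwork:
    """Return an equivalent network with all species in molecule counts.

    Concentration-typed species are converted with ``n = c * Omega_eff``;
    the conversion is exactly invertible up to floating rounding.  Counts are
    *not* rounded here (rounding happens only at SSA initialisation).
    """
    species = []
    for s in net.species:
        if s.value_kind is ValueKind.AMOUNT:
            species.append(s)
        else:
            species.append(
                SpeciesDef(
                    id=s.id,
                    name=s.name,
                    compartment_id=s.compartment_id,
                    initial_value=s.initial_value * net.system_size,
                    value_kind=ValueKind.AMOUNT,
                    unit=s.unit,
                )
            )
    return ReactionNetwork(
        species=species,
        reactions=net.reactions,
        volume_liters=net.volume_liters,
        parameters=net.parameters,
        time_unit=net.time_unit,
        name=net.name,
    )
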