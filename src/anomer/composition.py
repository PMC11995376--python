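"""Species registry and composition bookkeeping for aqueous sugar solutions.

Everything downstream (activity models, solubility solvers, the dissolution
simulator) evaluates thermodynamics on mole fractions.  This module owns the
species metadata (molar masses, roles) and the conversions between the three
concentration bases used in practice:

* ``mole_fraction`` -- the internal canonical basis,
* ``mass_fraction_solution`` -- grams of species per gram of solution,
* ``g_per_g_water`` -- grams of species per gram of solvent water (the basis
  in which suspension densities and solubilities are usually quoted).

The two lactose anomers have identical molar masses, so their mole ratio
equals their mass ratio -- a fact several identities downstream rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .exceptions import CompositionError

__all__ = [
    "Species",
    "SpeciesRegistry",
    "SolutionComposition",
    "composition_from_loading",
    "composition_from_mass_fractions",
    "mass_fractions",
    "convert_concentration",
    "WATER",
    "ALPHA_LACTOSE",
    "BETA_LACTOSE",
    "ALPHA_LACTOSE_MONOHYDRATE",
    "ISOMER_GROUP",
    "BASES",
]

WATER = "water"
ALPHA_LACTOSE = "alpha-lactose"
BETA_LACTOSE = "beta-lactose"
ALPHA_LACTOSE_MONOHYDRATE = "alpha-lactose-monohydrate"
#: Pseudospecies name accepted by :func:`convert_concentration` for the
#: combined mutarotating pair.
ISOMER_GROUP = "isomer-group"

ROLES = ("solvent", "isomer", "foreign_sugar", "crystal_hydrate")
BASES = ("mole_fraction", "mass_fraction_solution", "g_per_g_water")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Species:
    """A chemical species: name, molar mass in g/mol, and its role."""

    name: str
    molar_mass: float
    role: str

    def __post_init__(self) -> None:
        if not (self.molar_mass > 0):
            raise CompositionError(
                f"molar mass of {self.name!r} must be positive, got {self.molar_mass}"
            )
        if self.role not in ROLES:
            raise CompositionError(
                f"unknown role {self.role!r} for species {self.name!r}; expected one of {ROLES}"
            )
        object.__setattr__(self, "name", self.name.strip().lower())


# 4-significant-figure molar masses (g/mol).
_DEFAULT_SPECIES = (
    Species(WATER, 18.015, "solvent"),
    Species(ALPHA_LACTOSE, 342.30, "isomer"),
    Species(BETA_LACTOSE, 342.30, "isomer"),
    Species(ALPHA_LACTOSE_MONOHYDRATE, 360.31, "crystal_hydrate"),
    Species("glucose", 180.16, "foreign_sugar"),
    Species("galactose", 180.16, "foreign_sugar"),
    Species("sucrose", 342.30, "foreign_sugar"),
)


class SpeciesRegistry:
    """Case-insensitive registry of :class:`Species`.

    Exactly one species must carry the ``solvent`` role.  Unknown foreign
    sugars may be added (e.g. from a config file) as long as a molar mass is
    supplied.
    """

    def __init__(self, species: Iterable[Species]):
        self._species: dict[str, Species] = {}
        for sp in species:
            self._species[sp.name] = sp
        solvents = [sp for sp in self._species.values() if sp.role == "solvent"]
        if len(solvents) != 1:
            raise CompositionError(
                f"a registry needs exactly one solvent species, found {len(solvents)}"
            )
        self._solvent = solvents[0]

    @classmethod
    def default(cls) -> "SpeciesRegistry":
        return cls(_DEFAULT_SPECIES)

    def with_species(self, *extra: Species) -> "SpeciesRegistry":
        """Return a new registry with *extra* species added or replaced."""
        merged = dict(self._species)
        for sp in extra:
            merged[sp.name] = sp
        return SpeciesRegistry(merged.values())

    def __getitem__(self, name: str) -> Species:
        key = name.strip().lower()
        try:
            return self._species[key]
        except KeyError:
            raise CompositionError(f"unknown species {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._species

    def __iter__(self):
        return iter(self._species.values())

    def molar_mass(self, name: str) -> float:
        if name.strip().lower() == ISOMER_GROUP:
            m_a = self[ALPHA_LACTOSE].molar_mass
            m_b = self[BETA_LACTOSE].molar_mass
            if abs(m_a - m_b) > 1e-9:
                raise CompositionError(
                    "isomer-group molar mass is only defined when both anomers "
                    "have equal molar masses"
                )
            return m_a
        return self[name].molar_mass

    @property
    def solvent(self) -> Species:
        return self._solvent

    def names_with_role(self, role: str) -> list[str]:
        return [sp.name for sp in self._species.values() if sp.role == role]


class SolutionComposition:
    """Mole fractions of all dissolved species plus the solvent.

    Fractions are validated to lie in [0, 1] and to sum to one (inputs within
    1e-9 of one are renormalised so the stored invariant holds to machine
    precision).  All other concentration bases are derived views.
    """

    def __init__(
        self,
        mole_fractions: Mapping[str, float],
        registry: SpeciesRegistry | None = None,
    ):
        self.registry = registry if registry is not None else SpeciesRegistry.default()
        fr = {name.strip().lower(): float(x) for name, x in mole_fractions.items()}
        for name, x in fr.items():
            if name not in self.registry:
                raise CompositionError(f"species {name!r} not in registry")
            if not (0.0 <= x <= 1.0 + 1e-12):
                raise CompositionError(f"mole fraction of {name!r} out of [0, 1]: {x}")
        total = sum(fr.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(f"mole fractions must sum to 1, got {total!r}")
        self._x = {name: x / total for name, x in fr.items()}

    def __getitem__(self, name: str) -> float:
        return self._x.get(name.strip().lower(), 0.0)

    def as_dict(self) -> dict[str, float]:
        return dict(self._x)

    @property
    def x_w(self) -> float:
        return self[self.registry.solvent.name]

    @property
    def x_alpha(self) -> float:
        return self[ALPHA_LACTOSE]

    @property
    def x_beta(self) -> float:
        return self[BETA_LACTOSE]

    @property
    def x_iso(self) -> float:
        return self.x_alpha + self.x_beta

    @property
    def x_foreign(self) -> float:
        return sum(
            self[name] for name in self.registry.names_with_role("foreign_sugar")
        )

    def mean_molar_mass(self) -> float:
        """Mixture molar mass, sum(x_i * M_i) in g/mol."""
        return sum(x * self.registry.molar_mass(n) for n, x in self._x.items())

    def mass_fractions(self) -> dict[str, float]:
        m_mean = self.mean_molar_mass()
        return {
            n: x * self.registry.molar_mass(n) / m_mean for n, x in self._x.items()
        }


def composition_from_loading(
    lactose_g_per_g_water: float,
    beta_to_alpha_mass_ratio: float = 0.0,
    foreign_loadings: Mapping[str, float] | None = None,
    registry: SpeciesRegistry | None = None,
) -> SolutionComposition:
    """Build a composition from solute loadings in grams per gram of water.

    ``beta_to_alpha_mass_ratio`` partitions the total lactose loading between
    the anomers; because their molar masses are equal the mole ratio equals
    the mass ratio.
    """
    reg = registry if registry is not None else SpeciesRegistry.default()
    if lactose_g_per_g_water < 0:
        raise CompositionError("lactose loading must be non-negative")
    if beta_to_alpha_mass_ratio < 0:
        raise CompositionError("beta:alpha ratio must be non-negative")
    foreign = dict(foreign_loadings or {})

    moles: dict[str, float] = {reg.solvent.name: 1.0 / reg.solvent.molar_mass}
    r = beta_to_alpha_mass_ratio
    m_alpha = lactose_g_per_g_water / (1.0 + r)
    m_beta = lactose_g_per_g_water - m_alpha
    moles[ALPHA_LACTOSE] = m_alpha / reg.molar_mass(ALPHA_LACTOSE)
    moles[BETA_LACTOSE] = m_beta / reg.molar_mass(BETA_LACTOSE)
    for name, load in foreign.items():
        if load < 0:
            raise CompositionError(f"loading of {name!r} must be non-negative")
        key = name.strip().lower()
        moles[key] = moles.get(key, 0.0) + load / reg.molar_mass(name)
    total = sum(moles.values())
    return SolutionComposition({n: v / total for n, v in moles.items()}, reg)


def composition_from_mass_fractions(
    fractions: Mapping[str, float], registry: SpeciesRegistry | None = None
) -> SolutionComposition:
    """Inverse of :meth:`SolutionComposition.mass_fractions`."""
    reg = registry if registry is not None else SpeciesRegistry.default()
    moles = {n: w / reg.molar_mass(n) for n, w in fractions.items()}
    total = sum(moles.values())
    if total <= 0:
        raise CompositionError("mass fractions must have a positive sum")
    return SolutionComposition({n: v / total for n, v in moles.items()}, reg)


def mass_fractions(comp: SolutionComposition) -> dict[str, float]:
    """Functional alias for :meth:`SolutionComposition.mass_fractions`."""
    return comp.mass_fractions()


def basis_factor(
    basis: str, comp: SolutionComposition, species: str = ISOMER_GROUP
) -> float:
    """Local (frozen-context) factor J such that value_in_basis = J * x_species.

    The mixture mean molar mass and the water content are evaluated at the
    context composition *comp*, which makes the three basis maps linear in
    the converted value and therefore exactly commutative.
    """
    reg = comp.registry
    if basis == "mole_fraction":
        return 1.0
    m_s = reg.molar_mass(species)
    if basis == "mass_fraction_solution":
        return m_s / comp.mean_molar_mass()
    if basis == "g_per_g_water":
        if comp.x_w <= 0:
            raise CompositionError("g_per_g_water basis needs a water-bearing context")
        return m_s / (comp.x_w * reg.solvent.molar_mass)
    raise CompositionError(f"unknown basis {basis!r}; expected one of {BASES}")


def convert_concentration(
    value: float,
    from_basis: str,
    to_basis: str,
    comp: SolutionComposition,
    species: str = ISOMER_GROUP,
) -> float:
    """Convert a solute concentration between bases at the context *comp*.

    By default the value refers to the isomer group (total lactose); pass a
    species name to convert e.g. a foreign-sugar concentration.
    """
    j_from = basis_factor(from_basis, comp, species)
    j_to = basis_factor(to_basis, comp, species)
    return value * j_to / j_from
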