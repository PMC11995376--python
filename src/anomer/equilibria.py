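"""Solid-liquid equilibria of alpha-lactose monohydrate.

The solid dissolves according to

    alpha-lactose . H2O (s)  ->  alpha-lactose (aq) + H2O (l)

so at saturation (solid activity taken as unity) the product of the water
activity and the alpha-lactose activity is constant at fixed temperature:

    K_sp = a_w * gamma*_alpha * x_alpha,sat .

Because gamma*_alpha carries a factor (1 + K_x) and the equilibrium
partition x_alpha = (1 - x_w) / (1 + K_x) carries its inverse, the product
is algebraically independent of the K_x(x_w) model -- only K* enters.  The
solvers here exploit nothing but the general forms, so that invariance is
an emergent (and tested) property, not a hard-coded shortcut.

This module provides:

* :func:`chi_stoichiometry` -- the anhydrous mass fraction chi of the
  monohydrate (0.95 for lactose), computed from molar masses;
* :func:`ksp_from_equilibrium_point` -- K_sp from a measured saturation
  composition;
* :class:`SolubilityModel` -- K_sp plus the Margules and mutarotation
  models, with the saturation solvers, the F solubility-depression
  parameter, foreign-sugar depression predictions, and the Type I/II/III
  regime classifier hanging off it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .composition import (
    ALPHA_LACTOSE,
    ALPHA_LACTOSE_MONOHYDRATE,
    BETA_LACTOSE,
    ISOMER_GROUP,
    SolutionComposition,
    SpeciesRegistry,
    basis_factor,
)
from .exceptions import ModelValidityError, NoSolutionError
from .thermo import MargulesModel, MutarotationModel, VALIDITY_WINDOW

__all__ = [
    "Regime",
    "EquilibriumPoint",
    "SolubilityModel",
    "chi_stoichiometry",
    "ksp_from_equilibrium_point",
    "convert_F_basis",
]

_BRACKET = (VALIDITY_WINDOW[0] + 1e-12, 1.0 - 1e-9)
_RESIDUAL_TOL = 1e-12


class Regime(enum.Enum):
    """Response regimes of a powder-in-water dissolution experiment.

    TYPE_I: loading below the alpha saturation concentration -- the powder
    dissolves within seconds and the clear solution relaxes to mutarotation
    equilibrium.  TYPE_II: loading between the alpha and the total
    saturation concentrations -- a saturated suspension forms, then
    mutarotation undersaturates it and the solid eventually vanishes.
    TYPE_III: loading above the total saturation concentration -- solids
    persist while mutarotation equilibrium is reached.
    """

    TYPE_I = "I"
    TYPE_II = "II"
    TYPE_III = "III"


@dataclass(frozen=True)
class EquilibriumPoint:
    """Simultaneous solid-liquid and mutarotation equilibrium state."""

    x_w: float
    x_alpha: float
    x_beta: float

    @property
    def x_iso(self) -> float:
        return self.x_alpha + self.x_beta


def chi_stoichiometry(registry: SpeciesRegistry | None = None) -> float:
    """Mass of anhydrous alpha-lactose released per unit mass of monohydrate
    dissolved, chi = M_alpha / M_hydrate (0.95 to 2 d.p. for lactose)."""
    reg = registry if registry is not None else SpeciesRegistry.default()
    return reg.molar_mass(ALPHA_LACTOSE) / reg.molar_mass(ALPHA_LACTOSE_MONOHYDRATE)


def ksp_from_equilibrium_point(
    x_w_eq: float,
    margules: MargulesModel,
    mutarotation: MutarotationModel,
) -> float:
    """Solubility product from a measured equilibrium water mole fraction.

    K_sp = a_w * gamma*_alpha * x_alpha with the equilibrium partition
    x_alpha = (1 - x_w) / (1 + K_x); independent of the K_x slope.
    """
    a_w = margules.water_activity(x_w_eq)
    g_alpha = np.exp(
        margules.ln_gamma_star_group(x_w_eq)
        + np.log((1.0 + mutarotation.K_x(x_w_eq)) / (1.0 + mutarotation.K_star))
    )
    x_alpha = (1.0 - x_w_eq) / (1.0 + mutarotation.K_x(x_w_eq))
    return float(a_w * g_alpha * x_alpha)


@dataclass
class SolubilityModel:
    """Solubility product plus the activity models; all SLE solvers live here.

    Defaults are the lactose-water parameter set at 25 C.
    """

    K_sp: float = 0.00494
    margules: MargulesModel = field(default_factory=MargulesModel)
    mutarotation: MutarotationModel = field(default_factory=MutarotationModel)
    registry: SpeciesRegistry = field(default_factory=SpeciesRegistry.default)

    def __post_init__(self) -> None:
        if not (self.K_sp > 0):
            raise ModelValidityError(f"K_sp must be positive, got {self.K_sp}")

    @classmethod
    def from_equilibrium_point(
        cls,
        x_w_eq: float,
        margules: MargulesModel,
        mutarotation: MutarotationModel,
        registry: SpeciesRegistry | None = None,
    ) -> "SolubilityModel":
        return cls(
            K_sp=ksp_from_equilibrium_point(x_w_eq, margules, mutarotation),
            margules=margules,
            mutarotation=mutarotation,
            registry=registry if registry is not None else SpeciesRegistry.default(),
        )

    @property
    def chi(self) -> float:
        return chi_stoichiometry(self.registry)

    def gamma_star_alpha_eq(self, x_w):
        """gamma*_alpha evaluated on the mutarotation-equilibrium locus."""
        return np.exp(
            self.margules.ln_gamma_star_group(x_w)
            + np.log((1.0 + self.mutarotation.K_x(x_w)) / (1.0 + self.mutarotation.K_star))
        )

    def x_alpha_sat(self, x_w):
        """Saturation mole fraction of alpha-lactose at the given water
        content: K_sp / (a_w * gamma*_alpha)."""
        return self.K_sp / (
            self.margules.water_activity(x_w) * self.gamma_star_alpha_eq(x_w)
        )

    # -- binary (lactose-water) equilibrium --------------------------------

    def _equilibrium_residual(self, x_w: float) -> float:
        return self.x_alpha_sat(x_w) * (1.0 + self.mutarotation.K_x(x_w)) - (
            1.0 - x_w
        )

    def solve_equilibrium_solubility(self) -> EquilibriumPoint:
        """Water mole fraction at simultaneous solid-liquid and mutarotation
        equilibrium, by bracketed root finding on the validity window."""
        lo, hi = _BRACKET
        f_lo, f_hi = self._equilibrium_residual(lo), self._equilibrium_residual(hi)
        if f_lo * f_hi > 0:
            raise NoSolutionError(
                "no saturation point inside the validity window "
                f"(residuals {f_lo:.3g}, {f_hi:.3g})"
            )
        x_w = brentq(self._equilibrium_residual, lo, hi, xtol=1e-15, rtol=8.9e-16)
        if abs(self._equilibrium_residual(x_w)) > _RESIDUAL_TOL:
            raise NoSolutionError("saturation residual above tolerance")
        kx = self.mutarotation.K_x(x_w)
        x_alpha = (1.0 - x_w) / (1.0 + kx)
        return EquilibriumPoint(x_w=x_w, x_alpha=x_alpha, x_beta=kx * x_alpha)

    def equilibrium_composition(self) -> SolutionComposition:
        eq = self.solve_equilibrium_solubility()
        return SolutionComposition(
            {
                self.registry.solvent.name: eq.x_w,
                ALPHA_LACTOSE: eq.x_alpha,
                BETA_LACTOSE: eq.x_beta,
            },
            self.registry,
        )

    def solubility_g_per_g_water(self) -> float:
        """Total lactose solubility on the grams-per-gram-of-water basis."""
        eq = self.solve_equilibrium_solubility()
        m_lac = self.registry.molar_mass(ISOMER_GROUP)
        m_w = self.registry.solvent.molar_mass
        return eq.x_iso * m_lac / (eq.x_w * m_w)

    def saturation_g_per_g_water(self) -> tuple[float, float]:
        """(c_alpha_sat_eq, c_tot_sat_eq) in g per g water."""
        eq = self.solve_equilibrium_solubility()
        m_lac = self.registry.molar_mass(ISOMER_GROUP)
        m_w = self.registry.solvent.molar_mass
        scale = m_lac / (eq.x_w * m_w)
        return eq.x_alpha * scale, eq.x_iso * scale

    # -- solubility-depression parameter F ----------------------------------

    def F_parameter(self, include_kx_slope: bool = False) -> float:
        """First-order (Taylor) estimate of the solubility-depression
        parameter F = -d x_alpha,sat / d x_beta on the mole-fraction basis.

        Expanding x_alpha,sat(x_w) around the mutarotation-equilibrium
        saturation point and using the closure
        x_w - x_w,eq = -(x_beta - x_beta,eq) - (x_alpha,sat - x_alpha,sat,eq)
        gives F = S / (1 + S) with S = d x_alpha,sat / d x_w evaluated at
        equilibrium.  By default K_x is held constant at its saturation
        value (its composition dependence is a second-order effect there);
        ``include_kx_slope=True`` adds the dK_x/dx_w contribution to
        d ln gamma*_alpha for sensitivity analysis.
        """
        eq = self.solve_equilibrium_solubility()
        x_w = eq.x_w
        dln_aw = self.margules.dln_aw_dxw(x_w)
        dln_gamma = 2.0 * self.margules.A * x_w
        if include_kx_slope:
            dln_gamma += self.mutarotation.slope / (1.0 + self.mutarotation.K_x(x_w))
        S = -eq.x_alpha * (dln_aw + dln_gamma)
        return S / (1.0 + S)

    # -- foreign sugars ------------------------------------------------------

    def solubility_with_foreign_sugar(
        self, foreign_loading: float, foreign_species: str = "sucrose"
    ) -> float:
        """Total lactose solubility (g per g water) in the presence of a
        dissolved foreign sugar at *foreign_loading* grams per gram of water.

        The foreign sugar is assumed not to interact with the lactose
        activity model except through the reduction of the water mole
        fraction: the same K_sp, Margules constant and K_x(x_w) calibrated
        on the binary system are used with
        x_w = 1 - x_iso - x_foreign.
        """
        if foreign_loading < 0:
            raise ModelValidityError("foreign loading must be non-negative")
        m_w = self.registry.solvent.molar_mass
        m_f = self.registry.molar_mass(foreign_species)
        r = foreign_loading * m_w / m_f  # moles foreign per mole water

        def residual(x_w: float) -> float:
            x_iso = 1.0 - x_w * (1.0 + r)
            x_alpha = x_iso / (1.0 + self.mutarotation.K_x(x_w))
            return (
                self.margules.water_activity(x_w)
                * self.gamma_star_alpha_eq(x_w)
                * x_alpha
                - self.K_sp
            )

        lo = _BRACKET[0]
        hi = min(_BRACKET[1], 1.0 / (1.0 + r) - 1e-12)
        if residual(lo) < 0:
            raise ModelValidityError(
                "foreign loading pushes the saturation point below the "
                f"validity window x_w >= {VALIDITY_WINDOW[0]}"
            )
        x_w = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16)
        x_iso = 1.0 - x_w * (1.0 + r)
        m_lac = self.registry.molar_mass(ISOMER_GROUP)
        return x_iso * m_lac / (x_w * m_w)

    def depression_curve(
        self, loadings, foreign_species: str = "sucrose"
    ) -> np.ndarray:
        return np.array(
            [
                self.solubility_with_foreign_sugar(load, foreign_species)
                for load in np.asarray(loadings, dtype=float)
            ]
        )

    # -- regime classification ----------------------------------------------

    def classify_regime(self, loading: float) -> Regime:
        """Classify the response to an initial powder loading (g of
        monohydrate powder per g of water, the initial suspension density).

        The suspension density is compared with the saturation
        concentrations c_alpha,sat,eq and c_tot,sat,eq on the same
        g-per-g-water basis.  Near the II/III boundary the diagram is
        approximate: the water released by the hydrate (1 - chi per gram
        dissolved) shifts the exact full-dissolution boundary slightly
        upward.
        """
        if loading < 0:
            raise ModelValidityError("loading must be non-negative")
        c_alpha, c_tot = self.saturation_g_per_g_water()
        if loading < c_alpha:
            return Regime.TYPE_I
        if loading > c_tot:
            return Regime.TYPE_III
        return Regime.TYPE_II


def convert_F_basis(
    F: float,
    from_basis: str,
    to_basis: str,
    context: SolutionComposition,
    alpha_species: str = ALPHA_LACTOSE,
    depressant_species: str = BETA_LACTOSE,
) -> float:
    """Convert the depression ratio F between concentration bases.

    F relates a change in the alpha saturation concentration to a change in
    the depressant concentration; in basis b it rescales by the ratio of the
    local (frozen-context) basis Jacobians of the two species,
    F_b = F_x * J_alpha(b) / J_dep(b).  For two species of equal molar mass
    every basis gives the same F.
    """
    def ratio(basis: str) -> float:
        return basis_factor(basis, context, alpha_species) / basis_factor(
            basis, context, depressant_species
        )

    return F * ratio(to_basis) / ratio(from_basis)
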