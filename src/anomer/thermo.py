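"""Thermodynamic core: activity coefficients for two isomers in chemical
equilibrium in a solvent.

Model
-----
The solvent (water) activity coefficient follows the one-parameter
(2-suffix) Margules expression on the mole-fraction scale,

    ln gamma_w = A (1 - x_w)^2,          a_w = x_w exp(A (1 - x_w)^2),

with A an empirical, temperature-specific constant (lactose-water at 25 C:
A = -5.8).  Because the two anomers interconvert (mutarotation) the pair can
be treated as a single pseudospecies, the *isomer group*, and the mixture as
a pseudobinary.  Gibbs-Duhem integration of the Margules form from infinite
dilution gives the isomer-group activity coefficient in the solute standard
state (normalised to 1 at infinite dilution, marked with a star):

    ln gamma*_iso = A (x_w^2 - 1).

Resolving the group into its members requires the equilibrium mole-fraction
ratio K_x = x_beta / x_alpha and its infinite-dilution limit K*, the
thermodynamic isomerisation constant.  Integrating the per-isomer
Gibbs-Duhem relation from infinite dilution (where a_beta = K* a_alpha)
yields closed forms valid for any functional K_x(x_w):

    ln gamma*_alpha = A (x_w^2 - 1) + ln[(1 + K_x) / (1 + K*)]
    ln gamma*_beta  = A (x_w^2 - 1) + ln[(1 + 1/K_x) / (1 + 1/K*)]

Two identities pin these expressions down and are exposed as residual
functions for testing: the ratio identity
ln gamma*_alpha - ln gamma*_beta = ln(K_x / K*) (mutual thermodynamic
consistency), and the group identity stating that gamma*_iso is a corrected
geometric average of the per-isomer coefficients.  A numerical Gibbs-Duhem
integrator is provided as an independent oracle for both closed forms.

K_x(x_w) is modelled as linear, K_x = K* - slope * (1 - x_w), matching the
linear extrapolation used to estimate K* from measurements; the default
slope is 0 (composition-independent ratio).

All composition-dependent evaluations are restricted to a declared validity
window x_w in [0.9, 1], the range over which the Margules fit is calibrated;
outside it a :class:`~anomer.exceptions.ModelValidityError` is raised rather
than extrapolating silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CompositionError, ConvergenceError, ModelValidityError

__all__ = [
    "MargulesModel",
    "MutarotationModel",
    "ln_gamma_water",
    "water_activity",
    "gamma_star_group",
    "K_x_of_xw",
    "gamma_star_isomers_eq",
    "isomer_ratio_consistency_residual",
    "group_average_consistency_residual",
    "gamma_star_isomers_numeric",
    "VALIDITY_WINDOW",
]

#: Water mole-fraction window over which the composition-dependent models
#: (K_x and everything built on it) are considered calibrated.
VALIDITY_WINDOW = (0.9, 1.0)


def _check_xw_positive(x_w) -> None:
    x = np.asarray(x_w, dtype=float)
    if np.any(x <= 0.0) or np.any(x > 1.0):
        raise CompositionError(f"water mole fraction must lie in (0, 1], got {x_w}")


def _check_window(x_w) -> None:
    lo, hi = VALIDITY_WINDOW
    x = np.asarray(x_w, dtype=float)
    if np.any(x < lo) or np.any(x > hi):
        raise ModelValidityError(
            f"water mole fraction {x_w} outside the model validity window "
            f"[{lo}, {hi}]"
        )


@dataclass(frozen=True)
class MargulesModel:
    """2-suffix Margules model for the solvent; ``A`` is dimensionless."""

    A: float = -5.8

    def __post_init__(self) -> None:
        if not np.isfinite(self.A):
            raise ModelValidityError(f"Margules constant must be finite, got {self.A}")

    def ln_gamma_water(self, x_w):
        _check_xw_positive(x_w)
        one_minus = 1.0 - np.asarray(x_w, dtype=float)
        return self.A * one_minus**2

    def water_activity(self, x_w):
        return np.asarray(x_w, dtype=float) * np.exp(self.ln_gamma_water(x_w))

    def ln_gamma_star_group(self, x_w):
        _check_xw_positive(x_w)
        x = np.asarray(x_w, dtype=float)
        return self.A * (x**2 - 1.0)

    def gamma_star_group(self, x_w):
        return np.exp(self.ln_gamma_star_group(x_w))

    def dln_aw_dxw(self, x_w):
        """d ln a_w / d x_w for the Margules solvent."""
        _check_xw_positive(x_w)
        x = np.asarray(x_w, dtype=float)
        return 1.0 / x - 2.0 * self.A * (1.0 - x)


@dataclass(frozen=True)
class MutarotationModel:
    """Equilibrium ratio K_x(x_w) = K* - slope (1 - x_w), plus the forward
    mutarotation rate constant.

    Parameters
    ----------
    K_star : thermodynamic (infinite-dilution) beta:alpha mole ratio, > 0.
    slope : d K_x / d x_w, >= 0 reproduces the observed mild decrease of
        K_x with solute content; default 0 (constant ratio).
    k_alpha : forward mutarotation rate constant in 1/h (lactose at 25 C:
        0.64).
    """

    K_star: float = 1.60
    slope: float = 0.0
    k_alpha: float = 0.64

    def __post_init__(self) -> None:
        if not (self.K_star > 0):
            raise ModelValidityError(f"K_star must be positive, got {self.K_star}")
        if self.k_alpha < 0:
            raise ModelValidityError(f"k_alpha must be non-negative, got {self.k_alpha}")
        lo, _ = VALIDITY_WINDOW
        if self.K_star - self.slope * (1.0 - lo) <= 0:
            raise ModelValidityError(
                "K_x(x_w) must stay positive over the validity window; "
                f"K_star={self.K_star}, slope={self.slope}"
            )

    def K_x(self, x_w):
        _check_window(x_w)
        x = np.asarray(x_w, dtype=float)
        val = self.K_star - self.slope * (1.0 - x)
        if np.any(val <= 0):
            raise ModelValidityError(f"K_x(x_w={x_w}) is non-positive")
        return val


# -- functional mirrors -----------------------------------------------------


def ln_gamma_water(x_w, margules: MargulesModel):
    return margules.ln_gamma_water(x_w)


def water_activity(x_w, margules: MargulesModel):
    return margules.water_activity(x_w)


def gamma_star_group(x_w, margules: MargulesModel):
    return margules.gamma_star_group(x_w)


def K_x_of_xw(x_w, mutarotation: MutarotationModel):
    return mutarotation.K_x(x_w)


def ln_gamma_star_isomers_eq(
    x_w, margules: MargulesModel, mutarotation: MutarotationModel
):
    """(ln gamma*_alpha, ln gamma*_beta) at mutarotation equilibrium."""
    _check_window(x_w)
    kx = mutarotation.K_x(x_w)
    ks = mutarotation.K_star
    base = margules.ln_gamma_star_group(x_w)
    ln_ga = base + np.log((1.0 + kx) / (1.0 + ks))
    ln_gb = base + np.log((1.0 + 1.0 / kx) / (1.0 + 1.0 / ks))
    return ln_ga, ln_gb


def gamma_star_isomers_eq(x_w, margules: MargulesModel, mutarotation: MutarotationModel):
    """(gamma*_alpha, gamma*_beta) at mutarotation equilibrium; both -> 1 as
    x_w -> 1."""
    ln_ga, ln_gb = ln_gamma_star_isomers_eq(x_w, margules, mutarotation)
    return np.exp(ln_ga), np.exp(ln_gb)


def isomer_ratio_consistency_residual(
    x_w, margules: MargulesModel, mutarotation: MutarotationModel
):
    """ln gamma*_alpha - ln gamma*_beta - ln(K_x / K*).

    Vanishes identically for thermodynamically consistent per-isomer
    expressions (the chemical-equilibrium condition a_beta = K* a_alpha).
    """
    ln_ga, ln_gb = ln_gamma_star_isomers_eq(x_w, margules, mutarotation)
    kx = mutarotation.K_x(x_w)
    return ln_ga - ln_gb - np.log(kx / mutarotation.K_star)


def group_average_consistency_residual(
    x_w, margules: MargulesModel, mutarotation: MutarotationModel
):
    """Residual of the corrected-geometric-average identity for the group.

    The mole-fraction-weighted average of the per-isomer log coefficients
    exceeds ln gamma*_iso by a mixing term; this function returns the
    weighted average minus that mixing term minus ln gamma*_iso, which is
    identically zero.
    """
    ln_ga, ln_gb = ln_gamma_star_isomers_eq(x_w, margules, mutarotation)
    kx = mutarotation.K_x(x_w)
    ks = mutarotation.K_star
    w_alpha = 1.0 / (1.0 + kx)  # x_alpha / x_iso
    w_beta = kx / (1.0 + kx)  # x_beta / x_iso
    weighted = w_alpha * ln_ga + w_beta * ln_gb
    mixing = np.log((1.0 + kx) / (1.0 + ks)) + w_beta * np.log(ks / kx)
    return weighted - mixing - margules.ln_gamma_star_group(x_w)


def _gibbs_duhem_integrands(xs, margules, mutarotation):
    """Integrands d ln gamma*_i / d x_w assembled from the Gibbs-Duhem
    balance, *not* from the closed forms.

    For each isomer, chemical equilibrium makes d ln a_i equal for both, so
    the binary Gibbs-Duhem relation gives
    d ln a_i = -(x_w / x_iso) d ln a_w, and
    d ln gamma*_i = d ln a_i - d ln x_i with x_i the equilibrium partition
    of x_iso = 1 - x_w through K_x(x_w).  The individually singular terms at
    x_w -> 1 cancel; the exact limit is substituted at grid points within
    1e-12 of pure water.
    """
    A = margules.A
    ks = mutarotation.K_star
    slope = mutarotation.slope
    one_minus = 1.0 - xs
    kx = ks - slope * one_minus

    with np.errstate(divide="ignore", invalid="ignore"):
        dln_aw = 1.0 / xs - 2.0 * A * one_minus
        common = -(xs / one_minus) * dln_aw
        dln_xa = -1.0 / one_minus - slope / (1.0 + kx)
        dln_xb = -1.0 / one_minus + slope / kx - slope / (1.0 + kx)
        g_alpha = common - dln_xa
        g_beta = common - dln_xb

    at_unity = one_minus < 1e-12
    if np.any(at_unity):
        g_alpha[at_unity] = 2.0 * A + slope / (1.0 + ks)
        g_beta[at_unity] = 2.0 * A - slope / (ks * (1.0 + ks))
    return g_alpha, g_beta


def gamma_star_isomers_numeric(
    x_w,
    margules: MargulesModel,
    mutarotation: MutarotationModel,
    steps: int = 10_000,
    tol: float = 1e-8,
):
    """Per-isomer activity coefficients by numerical Gibbs-Duhem integration.

    Trapezoidal integration of the per-isomer Gibbs-Duhem integrand from
    x_w = 1 down to the target, serving as an independent oracle for
    :func:`gamma_star_isomers_eq`.  Convergence is verified by doubling the
    step count; a relative change above *tol* raises
    :class:`~anomer.exceptions.ConvergenceError`.
    """
    if steps < 100:
        raise ValueError("steps must be >= 100")
    _check_window(x_w)
    x_target = float(x_w)
    if x_target == 1.0:
        return 1.0, 1.0

    def integrate(n: int) -> tuple[float, float]:
        xs = np.linspace(1.0, x_target, n + 1)
        g_alpha, g_beta = _gibbs_duhem_integrands(xs, margules, mutarotation)
        return np.trapezoid(g_alpha, xs), np.trapezoid(g_beta, xs)

    coarse = integrate(steps)
    fine = integrate(2 * steps)
    for c, f in zip(coarse, fine):
        if abs(f - c) > tol * max(1.0, abs(f)):
            raise ConvergenceError(
                f"Gibbs-Duhem integration not converged: {c} vs {f} at "
                f"{steps} -> {2 * steps} steps"
            )
    return float(np.exp(fine[0])), float(np.exp(fine[1]))
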