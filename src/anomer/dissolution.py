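"""Coupled dissolution-mutarotation dynamics of alpha-lactose monohydrate.

Model
-----
A batch suspension of monohydrate crystals in water.  Four balances:

* three mass balances for the dissolved species (alpha-lactose,
  beta-lactose, water); dissolving one gram of monohydrate releases
  chi = M_alpha / M_hydrate grams of alpha-lactose and (1 - chi) grams of
  water;
* a population balance for the crystal-size distribution n(L), number
  weighted per unit mass of suspension, solved by the method of
  characteristics.

Mutarotation in the liquid is a first-order reversible reaction referenced
to the solution mass, r = k_alpha c_alpha - (k_alpha / K_x) c_beta (mass
fractions; the mole and mass ratios coincide for the equal-mass anomers),
thermodynamically consistent through the equilibrium ratio K_x.  The
dissolution rate is a linear driving force on the alpha mole fraction,
D = k_D (x_alpha,sat - x_alpha), independent of crystal size, with the
saturation value from the solubility product,
x_alpha,sat = K_sp / (a_w gamma*_alpha).

Because D is size independent, every characteristic shrinks at the same
rate: the population is evolved through a single cumulative size decrement
ell(t) = integral D dt with L_i(t) = max(L_i(0) - ell, 0).  This is the
method of characteristics in its exact form for this model -- no numerical
diffusion, weights constant in time -- and vanished characteristics simply
stop contributing to the moments.  The stiff two-time-scale structure
(dissolution relaxes in seconds, mutarotation in hours) is resolved by an
adaptive LSODA integration in two phases separated by the
complete-dissolution event.

Internally SI units (kg, m, s); the user-facing parameters and outputs use
hours and micrometres as customary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .composition import ISOMER_GROUP, SpeciesRegistry
from .equilibria import Regime, SolubilityModel
from .exceptions import ModelValidityError
from .thermo import VALIDITY_WINDOW

__all__ = [
    "SimulationParams",
    "CrystalPopulation",
    "SimResult",
    "crystal_mass",
    "mutarotation_rate",
    "dissolution_rate",
    "simulate",
    "quasi_equilibrium_profile",
]

_H = 3600.0  # seconds per hour


@dataclass(frozen=True)
class CrystalPopulation:
    """Discretised crystal-size distribution (characteristics).

    ``sizes`` in metres; ``weights`` are number densities per kilogram of
    suspension, constant in time under pure dissolution.
    """

    sizes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if sizes.shape != weights.shape:
            raise ValueError("sizes and weights must have equal shapes")
        if np.any(sizes < 0) or np.any(weights < 0):
            raise ValueError("sizes and weights must be non-negative")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "weights", weights)

    def moment(self, order: int) -> float:
        """Raw moment sum(w_i L_i^k), per kg suspension."""
        return float(np.sum(self.weights * self.sizes**order))

    def scaled_to_mass(
        self, crystal_mass_kg: float, suspension_mass_kg: float, rho_c: float, k_v: float
    ) -> "CrystalPopulation":
        """Rescale weights so the population carries the given crystal mass."""
        m3 = self.moment(3)
        if m3 <= 0 and crystal_mass_kg > 0:
            raise ValueError("cannot scale a massless population to a finite mass")
        scale = (
            crystal_mass_kg / (rho_c * k_v * m3 * suspension_mass_kg)
            if crystal_mass_kg > 0
            else 0.0
        )
        return CrystalPopulation(self.sizes, self.weights * scale)


def crystal_mass(
    pop: CrystalPopulation, rho_c: float, k_v: float, suspension_mass_kg: float
) -> float:
    """Total crystal mass in kg: rho_c k_v m3 per kg suspension, times the
    suspension mass (third-moment relation)."""
    return rho_c * k_v * pop.moment(3) * suspension_mass_kg


def mutarotation_rate(
    c_alpha: float, c_beta: float, K_x: float, k_alpha: float
) -> float:
    """Net alpha -> beta rate in mass fraction per hour.

    First-order reversible kinetics, r = k_alpha c_alpha - (k_alpha/K_x)
    c_beta; zero exactly at the equilibrium ratio c_beta = K_x c_alpha.
    """
    if K_x <= 0:
        raise ModelValidityError(f"K_x must be positive, got {K_x}")
    return k_alpha * c_alpha - (k_alpha / K_x) * c_beta


def dissolution_rate(x_alpha_sat: float, x_alpha: float, k_D: float) -> float:
    """Linear-driving-force dissolution rate in m/s (size independent)."""
    return k_D * (x_alpha_sat - x_alpha)


@dataclass(frozen=True)
class SimulationParams:
    """Inputs of a dissolution run; defaults are the 25 C lactose set.

    loading is the initial suspension density (g monohydrate powder per g
    water); the seed population is Gaussian in size (metres).
    """

    solubility: SolubilityModel = field(default_factory=SolubilityModel)
    rho_c: float = 1545.0  # kg/m^3
    k_v: float = math.pi / 6.0
    k_D: float = 1e-3  # m/s
    loading: float = 0.25  # g powder / g water
    water_mass_g: float = 50.0
    seed_mean: float = 10e-6  # m
    seed_sd: float = 1e-6  # m
    n_characteristics: int = 200
    horizon_h: float = 24.0
    rtol: float = 1e-10
    atol: float = 1e-15

    def __post_init__(self) -> None:
        for name in ("rho_c", "k_v", "k_D", "water_mass_g", "horizon_h"):
            if getattr(self, name) <= 0:
                raise ModelValidityError(f"{name} must be positive")
        if self.loading < 0:
            raise ModelValidityError("loading must be non-negative")
        chi = self.solubility.chi
        if not (0.0 < chi <= 1.0):
            raise ModelValidityError(f"chi must lie in (0, 1], got {chi}")

    @property
    def registry(self) -> SpeciesRegistry:
        return self.solubility.registry

    @property
    def chi(self) -> float:
        return self.solubility.chi

    @property
    def k_alpha(self) -> float:
        return self.solubility.mutarotation.k_alpha


class SimResult:
    """Time series plus events of a dissolution run.

    ``frame`` columns: t_h, c_alpha, c_beta, c_tot (mass fractions of
    solution), c_alpha_gg, c_beta_gg, c_tot_gg (g per g water), x_w, a_w,
    gamma_alpha, x_alpha_sat, m_cry_g.  ``dissolution_complete_h`` is the
    complete-dissolution event time (None if solids persist or none were
    charged), ``regime`` the a-priori phase-diagram label.
    """

    COLUMNS = (
        "t_h",
        "c_alpha",
        "c_beta",
        "c_tot",
        "c_alpha_gg",
        "c_beta_gg",
        "c_tot_gg",
        "x_w",
        "a_w",
        "gamma_alpha",
        "x_alpha_sat",
        "m_cry_g",
    )

    def __init__(
        self,
        params: SimulationParams,
        frame: pd.DataFrame,
        regime: Regime,
        dissolution_complete_h: float | None,
        sampler,
        seed_sizes: np.ndarray,
        solver_stats: dict,
    ):
        self.params = params
        self.frame = frame
        self.regime = regime
        self.dissolution_complete_h = dissolution_complete_h
        self._sampler = sampler
        self.seed_sizes = seed_sizes
        self.solver_stats = solver_stats

    def sample(self, times_h) -> pd.DataFrame:
        """Evaluate the dense solution at arbitrary times (hours)."""
        return self._sampler(np.asarray(times_h, dtype=float))

    def population_at(self, t_h: float) -> CrystalPopulation:
        """Reconstructed characteristic sizes at a given time."""
        ell = float(self._sampler(np.array([t_h]), raw=True)[0][0])
        return CrystalPopulation(
            np.maximum(self.seed_sizes - ell, 0.0), self._seed_weights
        )

    @property
    def final_state(self) -> pd.Series:
        return self.frame.iloc[-1]


def _unit_gaussian_population(mean: float, sd: float, n: int) -> CrystalPopulation:
    # local import: fixtures depends on this module for CrystalPopulation
    from .fixtures import gen_seed_psd

    return gen_seed_psd(mean, sd, n)


def _masses_to_fractions(m_a, m_b, m_w, registry: SpeciesRegistry):
    m_lac = registry.molar_mass(ISOMER_GROUP) * 1e-3  # kg/mol
    m_wat = registry.solvent.molar_mass * 1e-3
    n_a = m_a / m_lac
    n_b = m_b / m_lac
    n_w = m_w / m_wat
    n_tot = n_a + n_b + n_w
    return n_a / n_tot, n_b / n_tot, n_w / n_tot


def simulate(params: SimulationParams) -> SimResult:
    """Integrate the coupled dissolution-mutarotation model.

    Phase 1 integrates [ell, m_alpha, m_beta, m_w] with the solids present
    and terminates at the complete-dissolution event (the cumulative
    decrement ell reaching the largest seed size); phase 2 continues the
    solids-free mutarotation relaxation to the horizon.  Conservation of
    lactose (m_alpha + m_beta + chi m_cry), water (m_w + (1 - chi) m_cry)
    and total suspension mass holds to the integrator tolerance.
    """
    sol_model = params.solubility
    reg = params.registry
    chi = params.chi
    k_alpha_s = params.k_alpha / _H

    m_w0 = params.water_mass_g * 1e-3
    m_powder = params.loading * m_w0
    m_susp = m_w0 + m_powder

    if m_powder > 0:
        unit_pop = _unit_gaussian_population(
            params.seed_mean, params.seed_sd, params.n_characteristics
        )
        pop0 = unit_pop.scaled_to_mass(m_powder, m_susp, params.rho_c, params.k_v)
    else:
        pop0 = CrystalPopulation(np.array([]), np.array([]))
    sizes0 = pop0.sizes
    weights = pop0.weights
    l_max = float(sizes0.max()) if sizes0.size else 0.0

    def solids_state(ell: float) -> tuple[float, float]:
        """(m_cry, second moment of surviving characteristics)."""
        if sizes0.size == 0:
            return 0.0, 0.0
        rem = np.maximum(sizes0 - ell, 0.0)
        m_cry = params.rho_c * params.k_v * float(np.sum(weights * rem**3)) * m_susp
        m2 = float(np.sum(weights * rem**2))
        return m_cry, m2

    def thermo_state(m_a: float, m_b: float, m_w: float):
        x_a, x_b, x_w = _masses_to_fractions(m_a, m_b, m_w, reg)
        if x_w < VALIDITY_WINDOW[0]:
            raise ModelValidityError(
                f"solution left the model validity window (x_w = {x_w:.4f})"
            )
        a_w = float(sol_model.margules.water_activity(x_w))
        g_alpha = float(sol_model.gamma_star_alpha_eq(x_w))
        x_sat = sol_model.K_sp / (a_w * g_alpha)
        kx = float(sol_model.mutarotation.K_x(x_w))
        return x_a, x_b, x_w, a_w, g_alpha, x_sat, kx

    def rhs_solids(t, y):
        ell, m_a, m_b, m_w = y
        x_a, _x_b, _x_w, _a_w, _g, x_sat, kx = thermo_state(m_a, m_b, m_w)
        D = params.k_D * max(x_sat - x_a, 0.0)
        _m_cry, m2 = solids_state(ell)
        diss = 3.0 * params.rho_c * params.k_v * D * m2 * m_susp  # kg/s
        m_sol = m_a + m_b + m_w
        c_a, c_b = m_a / m_sol, m_b / m_sol
        r = k_alpha_s * c_a - (k_alpha_s / kx) * c_b
        return [D, chi * diss - r * m_sol, r * m_sol, (1.0 - chi) * diss]

    def rhs_free(t, y):
        m_a, m_b, m_w = y
        _x_a, _x_b, _x_w, _a_w, _g, _x_sat, kx = thermo_state(m_a, m_b, m_w)
        m_sol = m_a + m_b + m_w
        c_a, c_b = m_a / m_sol, m_b / m_sol
        r = k_alpha_s * c_a - (k_alpha_s / kx) * c_b
        return [-r * m_sol, r * m_sol, 0.0]

    t_end = params.horizon_h * _H
    dissolution_complete_h: float | None = None
    stats: dict = {}
    segments = []  # (t0, t1, callable y(t) -> (ell, m_a, m_b, m_w))

    if m_powder > 0:

        def complete(t, y):
            return y[0] - l_max

        complete.terminal = True
        complete.direction = 1.0
        # per-characteristic vanishing events (non-terminal) help the
        # integrator localise the kinks in the moments
        char_events = []
        for L in np.unique(sizes0):

            def cross(t, y, _L=float(L)):
                return y[0] - _L

            cross.terminal = False
            char_events.append(cross)

        sol1 = solve_ivp(
            rhs_solids,
            (0.0, t_end),
            [0.0, 0.0, 0.0, m_w0],
            method="LSODA",
            events=[complete] + char_events,
            dense_output=True,
            rtol=params.rtol,
            atol=params.atol,
        )
        if not sol1.success:
            raise ModelValidityError(f"integration failed: {sol1.message}")
        stats["phase1_nfev"] = int(sol1.nfev)
        t1 = float(sol1.t[-1])
        segments.append((0.0, t1, lambda t, s=sol1: s.sol(t)))
        if sol1.t_events[0].size:
            dissolution_complete_h = float(sol1.t_events[0][0]) / _H
        y_end = sol1.y[:, -1]
    else:
        t1 = 0.0
        y_end = np.array([0.0, 0.0, 0.0, m_w0])
        segments.append(
            (0.0, 0.0, lambda t, y0=y_end: np.tile(y0[:, None], (1, np.size(t))))
        )

    if t1 < t_end:
        ell_end = y_end[0] if m_powder > 0 else 0.0
        sol2 = solve_ivp(
            rhs_free,
            (t1, t_end),
            list(y_end[1:]),
            method="LSODA",
            dense_output=True,
            rtol=params.rtol,
            atol=params.atol,
        )
        if not sol2.success:
            raise ModelValidityError(f"integration failed: {sol2.message}")
        stats["phase2_nfev"] = int(sol2.nfev)

        def seg2(t, s=sol2, ell=ell_end):
            y = np.asarray(s.sol(t), dtype=float).reshape(3, -1)
            return np.vstack([np.full((1, y.shape[1]), ell), y])

        segments.append((t1, t_end, seg2))

    def raw_sample(times_s: np.ndarray) -> np.ndarray:
        out = np.empty((4, times_s.size))
        for i, t in enumerate(times_s):
            for t0, t_seg_end, f in segments:
                if t <= t_seg_end or (t0, t_seg_end, f) == segments[-1]:
                    out[:, i] = np.asarray(f(t)).reshape(4, -1)[:, 0]
                    break
        return out

    def sampler(times_h: np.ndarray, raw: bool = False):
        times_s = times_h * _H
        y = raw_sample(times_s)
        if raw:
            return y
        rows = []
        for t_h, (ell, m_a, m_b, m_w) in zip(times_h, y.T):
            x_a, x_b, x_w, a_w, g_alpha, x_sat, _kx = thermo_state(m_a, m_b, m_w)
            m_cry, _ = solids_state(ell)
            m_sol = m_a + m_b + m_w
            rows.append(
                {
                    "t_h": t_h,
                    "c_alpha": m_a / m_sol,
                    "c_beta": m_b / m_sol,
                    "c_tot": (m_a + m_b) / m_sol,
                    "c_alpha_gg": m_a / m_w,
                    "c_beta_gg": m_b / m_w,
                    "c_tot_gg": (m_a + m_b) / m_w,
                    "x_w": x_w,
                    "a_w": a_w,
                    "gamma_alpha": g_alpha,
                    "x_alpha_sat": x_sat,
                    "m_cry_g": m_cry * 1e3,
                }
            )
        return pd.DataFrame(rows, columns=list(SimResult.COLUMNS))

    # output grid: geometric early (transient), uniform late
    early = np.geomspace(1e-4, min(0.2, params.horizon_h), 120)
    late = np.linspace(0.0, params.horizon_h, 400)
    times_h = np.unique(np.concatenate([[0.0], early, late]))
    if dissolution_complete_h is not None:
        times_h = np.unique(np.append(times_h, dissolution_complete_h))
    frame = sampler(times_h)

    result = SimResult(
        params=params,
        frame=frame,
        regime=sol_model.classify_regime(params.loading),
        dissolution_complete_h=dissolution_complete_h,
        sampler=sampler,
        seed_sizes=sizes0,
        solver_stats=stats,
    )
    result._seed_weights = weights
    return result


def quasi_equilibrium_profile(params: SimulationParams) -> SimResult:
    """Reference 0-D model assuming instantaneous solid-liquid equilibrium.

    While solids remain, the dissolved alpha mole fraction is pinned
    algebraically to its saturation value x_alpha,sat(x_w); only the beta
    mass evolves by mutarotation, and the dissolved amount follows from
    mass conservation (a scalar root solve at every step).  Serves as the
    large-k_D reference for :func:`simulate`; the short initial transient
    is skipped by construction.  Rejects loadings that leave no solids to
    equilibrate (Type I).
    """
    from scipy.optimize import brentq

    sol_model = params.solubility
    reg = params.registry
    chi = params.chi
    k_alpha_s = params.k_alpha / _H
    if sol_model.classify_regime(params.loading) is Regime.TYPE_I:
        raise ModelValidityError(
            "quasi-equilibrium reference requires solids (Type II/III loading)"
        )

    m_w0 = params.water_mass_g * 1e-3
    m_powder = params.loading * m_w0

    def algebraic_state(m_b: float):
        """Dissolved powder mass d such that x_alpha = x_alpha,sat."""

        def g(d: float) -> float:
            m_a = chi * d - m_b
            m_w = m_w0 + (1.0 - chi) * d
            if m_a < 0:
                return -1.0
            x_a, _x_b, x_w = _masses_to_fractions(m_a, m_b, m_w, reg)
            x_sat = sol_model.K_sp / (
                float(sol_model.margules.water_activity(x_w))
                * float(sol_model.gamma_star_alpha_eq(x_w))
            )
            return x_a - x_sat

        margin = g(m_powder)
        if margin < 0:  # saturation unreachable: all powder dissolved
            return m_powder, False, margin
        d = brentq(g, 0.0, m_powder, xtol=1e-18)
        return d, True, margin

    def rhs(t, y):
        (m_b,) = y
        d, _solids, _margin = algebraic_state(m_b)
        m_a = chi * d - m_b
        m_w = m_w0 + (1.0 - chi) * d
        m_sol = m_a + m_b + m_w
        _x_a, _x_b, x_w = _masses_to_fractions(m_a, m_b, m_w, reg)
        kx = float(sol_model.mutarotation.K_x(x_w))
        r = k_alpha_s * (m_a / m_sol) - (k_alpha_s / kx) * (m_b / m_sol)
        return [r * m_sol]

    def complete(t, y):
        # continuous margin: x_alpha - x_alpha,sat if everything dissolved;
        # crosses zero when the last solids vanish
        _d, _solids, margin = algebraic_state(float(y[0]))
        return margin

    complete.terminal = True
    complete.direction = -1.0

    t_end = params.horizon_h * _H
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0],
        method="LSODA",
        events=[complete],
        dense_output=True,
        rtol=params.rtol,
        atol=params.atol,
    )
    if not sol.success:
        raise ModelValidityError(f"integration failed: {sol.message}")
    t1 = float(sol.t[-1])
    dissolution_complete_h = t1 / _H if t1 < t_end - 1e-9 else None

    # if the powder ran out, continue solids-free
    sol2 = None
    if t1 < t_end:
        m_b1 = float(sol.sol(t1)[0])
        m_a1 = chi * m_powder - m_b1
        m_w1 = m_w0 + (1.0 - chi) * m_powder

        def rhs_free(t, y):
            m_a, m_b = y
            m_sol = m_a + m_b + m_w1
            _x_a, _x_b, x_w = _masses_to_fractions(m_a, m_b, m_w1, reg)
            kx = float(sol_model.mutarotation.K_x(x_w))
            r = k_alpha_s * (m_a / m_sol) - (k_alpha_s / kx) * (m_b / m_sol)
            return [-r * m_sol, r * m_sol]

        sol2 = solve_ivp(
            rhs_free,
            (t1, t_end),
            [m_a1, m_b1],
            method="LSODA",
            dense_output=True,
            rtol=params.rtol,
            atol=params.atol,
        )

    def sampler(times_h: np.ndarray, raw: bool = False):
        times_s = times_h * _H
        ys = np.empty((4, times_s.size))
        for i, t in enumerate(times_s):
            if t <= t1 or sol2 is None:
                m_b = float(sol.sol(min(t, t1))[0])
                d, _solids, _margin = algebraic_state(m_b)
                m_a = chi * d - m_b
                m_w = m_w0 + (1.0 - chi) * d
                ell = 0.0
            else:
                m_a, m_b = (float(v) for v in sol2.sol(t))
                m_w = m_w0 + (1.0 - chi) * m_powder
                d = m_powder
                ell = 0.0
            ys[:, i] = [d, m_a, m_b, m_w]
        if raw:
            return ys
        rows = []
        for t_h, (d, m_a, m_b, m_w) in zip(times_h, ys.T):
            x_a, x_b, x_w = _masses_to_fractions(m_a, m_b, m_w, reg)
            a_w = float(sol_model.margules.water_activity(x_w))
            g_alpha = float(sol_model.gamma_star_alpha_eq(x_w))
            m_sol = m_a + m_b + m_w
            rows.append(
                {
                    "t_h": t_h,
                    "c_alpha": m_a / m_sol,
                    "c_beta": m_b / m_sol,
                    "c_tot": (m_a + m_b) / m_sol,
                    "c_alpha_gg": m_a / m_w,
                    "c_beta_gg": m_b / m_w,
                    "c_tot_gg": (m_a + m_b) / m_w,
                    "x_w": x_w,
                    "a_w": a_w,
                    "gamma_alpha": g_alpha,
                    "x_alpha_sat": sol_model.K_sp / (a_w * g_alpha),
                    "m_cry_g": (m_powder - d) * 1e3,
                }
            )
        return pd.DataFrame(rows, columns=list(SimResult.COLUMNS))

    times_h = np.unique(
        np.concatenate(
            [[0.0], np.geomspace(1e-3, params.horizon_h, 60), np.linspace(0.0, params.horizon_h, 200)]
        )
    )
    frame = sampler(times_h)
    result = SimResult(
        params=params,
        frame=frame,
        regime=sol_model.classify_regime(params.loading),
        dissolution_complete_h=dissolution_complete_h,
        sampler=sampler,
        seed_sizes=np.array([]),
        solver_stats={"phase1_nfev": int(sol.nfev)},
    )
    result._seed_weights = np.array([])
    return result
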