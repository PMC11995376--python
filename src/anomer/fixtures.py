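"""Synthetic measurement tables and seed crystal populations.

The calibration module assumes water-activity and isomer-ratio tables with
a particular statistical structure (a Margules-shaped a_w(x_w) curve and a
line K_x(x_w), each with additive homoscedastic Gaussian noise emulating
symmetric replicate error bars); this module generates such tables
reproducibly so the whole pipeline is testable without measured data.  It
also builds the Gaussian seed crystal-size distribution used by the
dissolution simulator, discretised into equal-probability characteristics
at quantile midpoints (stratified rather than sampled, keeping the
simulator deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dissolution import CrystalPopulation
from .exceptions import ModelValidityError
from .thermo import MargulesModel

__all__ = ["FixtureSpec", "gen_water_activity_data", "gen_kx_data", "gen_seed_psd"]


def _default_activity_grid() -> np.ndarray:
    return np.linspace(0.96, 0.999, 20)


def _default_ratio_grid() -> np.ndarray:
    return np.linspace(0.96, 0.999, 15)


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth parameters and noise levels of the synthetic tables.

    Defaults mirror the lactose-water study conditions: A = -5.8,
    K* = 1.60 with a mild composition slope, water activities measured to
    +/- 5e-4 and isomer ratios to +/- 0.01 (1 sd), on ~15-20 compositions
    spanning the dilute-to-supersaturated range.
    """

    A_true: float = -5.8
    K_star_true: float = 1.60
    slope_true: float = 1.5
    activity_grid: np.ndarray = field(default_factory=_default_activity_grid)
    ratio_grid: np.ndarray = field(default_factory=_default_ratio_grid)
    sd_aw: float = 5e-4
    sd_kx: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name, grid in (("activity_grid", self.activity_grid),
                           ("ratio_grid", self.ratio_grid)):
            g = np.asarray(grid, dtype=float)
            if np.any(g <= 0.9) or np.any(g > 1.0):
                raise ModelValidityError(f"{name} must lie within (0.9, 1]")
            object.__setattr__(self, name, g)
        if self.sd_aw < 0 or self.sd_kx < 0:
            raise ModelValidityError("noise standard deviations must be >= 0")


def gen_water_activity_data(spec: FixtureSpec) -> pd.DataFrame:
    """Water-activity table: a_w = x_w exp(A (1 - x_w)^2) + noise."""
    rng = np.random.default_rng(spec.seed)
    x_w = spec.activity_grid
    a_w = np.asarray(MargulesModel(spec.A_true).water_activity(x_w))
    a_w = a_w + rng.normal(0.0, spec.sd_aw, size=x_w.shape)
    return pd.DataFrame(
        {"x_w": x_w, "a_w": a_w, "sd": np.full(x_w.shape, spec.sd_aw)}
    )


def gen_kx_data(spec: FixtureSpec) -> pd.DataFrame:
    """Isomer-ratio table: K_x = K* - slope (1 - x_w) + noise."""
    rng = np.random.default_rng(spec.seed + 1)
    x_w = spec.ratio_grid
    k_x = spec.K_star_true - spec.slope_true * (1.0 - x_w)
    k_x = k_x + rng.normal(0.0, spec.sd_kx, size=x_w.shape)
    if np.any(k_x <= 0):
        raise ModelValidityError(
            "generated K_x values are non-positive; reduce the noise level "
            "or choose another seed"
        )
    return pd.DataFrame(
        {"x_w": x_w, "K_x": k_x, "sd": np.full(x_w.shape, spec.sd_kx)}
    )


def gen_seed_psd(mean: float, sd: float, n_characteristics: int) -> CrystalPopulation:
    """Gaussian seed size distribution as equal-weight characteristics.

    Characteristics sit at the quantile midpoints Phi^-1((i - 1/2)/n) of a
    Normal(mean, sd) in metres, truncated to strictly positive sizes; each
    carries weight 1/n (unit-normalised number density).  ``sd = 0``
    degenerates to a single characteristic at the mean.  A warning is
    issued if >= 1% of the probability mass is truncated (mean > 3 sd
    recommended).
    """
    if mean <= 0:
        raise ModelValidityError("mean size must be positive")
    if sd < 0:
        raise ModelValidityError("size standard deviation must be >= 0")
    if sd == 0 or n_characteristics == 1:
        return CrystalPopulation(np.array([mean]), np.array([1.0]))
    if n_characteristics < 10:
        raise ModelValidityError("need at least 10 characteristics (or exactly 1)")
    truncated = norm.cdf(0.0, loc=mean, scale=sd)
    if truncated >= 0.01:
        warnings.warn(
            f"{truncated:.1%} of the seed distribution lies at L <= 0 and is "
            "truncated; third-moment accuracy degrades",
            stacklevel=2,
        )
    q = (np.arange(n_characteristics) + 0.5) / n_characteristics
    sizes = norm.ppf(q, loc=mean, scale=sd)
    keep = sizes > 0
    sizes = sizes[keep]
    weights = np.full(sizes.shape, 1.0 / n_characteristics)
    return CrystalPopulation(sizes, weights)
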