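"""Calibration of the thermodynamic parameters from measurement tables.

Two regressions, exposed statsmodels-style (a Model built from a DataFrame
whose ``fit()`` returns a Results object):

* :class:`WaterActivityModel` -- estimates the Margules constant A from
  (x_w, a_w) pairs.  The Margules form forces ln(a_w / x_w) = A (1 - x_w)^2
  with a zero intercept, so the fit is least squares *through the origin*
  of y = ln(a_w / x_w) on z = (1 - x_w)^2; the reported uncertainty is the
  regression standard error of the slope.
* :class:`IsomerRatioModel` -- estimates the thermodynamic mutarotation
  constant K* and the composition slope from (x_w, K_x) pairs by ordinary
  least squares of K_x on (1 - x_w); K* is the intercept (the linear
  extrapolation to infinite dilution, x_w -> 1) and the slope coefficient
  enters the model as dK_x/dx_w = -coefficient.

Replicate standard deviations, when a ``sd`` column is present, enable an
optional inverse-variance weighted fit (off by default).

Input tables are UTF-8 delimited text with a header row; see
:func:`read_activity_table` and :func:`read_ratio_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CompositionError
from .thermo import MargulesModel, MutarotationModel

__all__ = [
    "read_activity_table",
    "read_ratio_table",
    "WaterActivityModel",
    "WaterActivityResults",
    "IsomerRatioModel",
    "IsomerRatioResults",
    "fit_margules_A",
    "fit_mutarotation",
]

_AW_MAX = 1.05  # small super-unity tolerated as measurement noise


def _validate_activity(data: pd.DataFrame) -> pd.DataFrame:
    if not {"x_w", "a_w"}.issubset(data.columns):
        raise CompositionError("activity table needs columns x_w, a_w")
    if ((data["x_w"] <= 0) | (data["x_w"] > 1)).any():
        raise CompositionError("x_w must lie in (0, 1]")
    if ((data["a_w"] <= 0) | (data["a_w"] > _AW_MAX)).any():
        raise CompositionError(f"a_w must lie in (0, {_AW_MAX}]")
    return data.reset_index(drop=True)


def _validate_ratio(data: pd.DataFrame) -> pd.DataFrame:
    if not {"x_w", "K_x"}.issubset(data.columns):
        raise CompositionError("ratio table needs columns x_w, K_x")
    if (data["K_x"] <= 0).any():
        raise CompositionError("K_x must be positive")
    return data.reset_index(drop=True)


def read_activity_table(path) -> pd.DataFrame:
    """Read a delimited water-activity table (columns x_w, a_w[, sd])."""
    return _validate_activity(pd.read_csv(path))


def read_ratio_table(path) -> pd.DataFrame:
    """Read a delimited isomer-ratio table (columns x_w, K_x[, sd])."""
    return _validate_ratio(pd.read_csv(path))


class WaterActivityResults:
    """Margules-constant fit results: estimate, standard error, diagnostics."""

    def __init__(self, sm_results, data: pd.DataFrame):
        self._res = sm_results
        self.data = data
        self.A = float(sm_results.params[0])
        self.se_A = float(sm_results.bse[0])
        self.nobs = int(sm_results.nobs)

    @property
    def params(self):
        return self._res.params

    @property
    def bse(self):
        return self._res.bse

    @property
    def resid(self):
        return self._res.resid

    def margules_model(self) -> MargulesModel:
        return MargulesModel(A=self.A)

    def conf_int(self, alpha: float = 0.05):
        return self._res.conf_int(alpha)

    def summary(self):
        return self._res.summary(
            yname="ln(a_w/x_w)", xname=["A"], title="Margules constant fit"
        )


class WaterActivityModel:
    """Regression model for the Margules constant A.

    Parameters
    ----------
    data : DataFrame with columns ``x_w`` and ``a_w`` and optionally ``sd``
        (replicate standard deviation of a_w, used only when
        ``fit(weighted=True)``).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = _validate_activity(data)
        xw = self.data["x_w"].to_numpy()
        if len(np.unique(xw[xw < 1.0])) < 2:
            raise CompositionError(
                "degenerate design: need >= 2 records with distinct x_w < 1"
            )
        z = (1.0 - xw) ** 2
        self._y = np.log(self.data["a_w"].to_numpy() / self.data["x_w"].to_numpy())
        self._z = z

    @classmethod
    def from_csv(cls, path) -> "WaterActivityModel":
        return cls(read_activity_table(path))

    def fit(self, weighted: bool = False) -> WaterActivityResults:
        if weighted:
            if "sd" not in self.data.columns:
                raise CompositionError("weighted fit requires an sd column")
            # var of y = ln(a_w/x_w) propagated from var of a_w
            w = (self.data["a_w"] / self.data["sd"]) ** 2
            res = sm.WLS(self._y, self._z, weights=w).fit()
        else:
            res = sm.OLS(self._y, self._z).fit()
        return WaterActivityResults(res, self.data)


class IsomerRatioResults:
    """Mutarotation-constant fit results (K*, slope, standard errors)."""

    def __init__(self, sm_results, data: pd.DataFrame):
        self._res = sm_results
        self.data = data
        self.K_star = float(sm_results.params[0])
        self.se_K_star = float(sm_results.bse[0])
        # K_x = K* + b (1 - x_w)  =>  dK_x/dx_w = -b
        self.slope = -float(sm_results.params[1])
        self.se_slope = float(sm_results.bse[1])
        self.nobs = int(sm_results.nobs)

    @property
    def params(self):
        return self._res.params

    @property
    def bse(self):
        return self._res.bse

    def mutarotation_model(self, k_alpha: float = 0.64) -> MutarotationModel:
        return MutarotationModel(K_star=self.K_star, slope=self.slope, k_alpha=k_alpha)

    def summary(self):
        return self._res.summary(
            yname="K_x", xname=["K_star", "1-x_w"], title="Mutarotation constant fit"
        )


class IsomerRatioModel:
    """OLS model K_x ~ K* + b (1 - x_w); the reported slope is -b."""

    def __init__(self, data: pd.DataFrame):
        self.data = _validate_ratio(data)
        if len(np.unique(self.data["x_w"])) < 2:
            raise CompositionError(
                "degenerate design: need >= 2 records with distinct x_w"
            )

    @classmethod
    def from_csv(cls, path) -> "IsomerRatioModel":
        return cls(read_ratio_table(path))

    def fit(self, weighted: bool = False) -> IsomerRatioResults:
        y = self.data["K_x"].to_numpy()
        X = np.column_stack(
            [np.ones(len(y)), 1.0 - self.data["x_w"].to_numpy()]
        )
        if weighted:
            if "sd" not in self.data.columns:
                raise CompositionError("weighted fit requires an sd column")
            res = sm.WLS(y, X, weights=1.0 / self.data["sd"] ** 2).fit()
        else:
            res = sm.OLS(y, X).fit()
        return IsomerRatioResults(res, self.data)


def fit_margules_A(data: pd.DataFrame) -> tuple[float, float]:
    """Convenience wrapper returning (A_hat, se_A)."""
    res = WaterActivityModel(data).fit()
    return res.A, res.se_A


def fit_mutarotation(data: pd.DataFrame) -> tuple[float, float, float]:
    """Convenience wrapper returning (K_star_hat, slope_hat, se_K_star)."""
    res = IsomerRatioModel(data).fit()
    return res.K_star, res.slope, res.se_K_star
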