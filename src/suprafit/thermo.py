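"""Van't Hoff extraction of dimerization enthalpy and entropy.

ln K is linear in 1/T when the reaction enthalpy is temperature independent:

    ln K = -dH/(R T) + dS/R

so a straight-line fit of ln K against 1/T yields dH = -R * slope (J/mol)
and dS = R * intercept (J/(K mol)), with R = 8.314 J/(K mol). Temperatures
are accepted in degrees Celsius and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["R_GAS", "VanHoffDataset", "ThermoFitResult", "fit_vant_hoff"]

R_GAS = 8.314  # J/(K mol)
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class VanHoffDataset:
    """Equilibrium constants measured at several temperatures."""

    temperatures_c: np.ndarray  # degrees Celsius
    k_values: np.ndarray  # L/mol
    k_sd: np.ndarray | None = None  # optional 1-sigma on K

    def __post_init__(self):
        t = np.asarray(self.temperatures_c, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        if t.ndim != 1 or k.shape != t.shape:
            raise InvalidInputError("temperatures and K values must be 1-D, equal length")
        if np.unique(t).size < 2:
            raise InvalidInputError("need at least 2 distinct temperatures")
        if np.any(k <= 0):
            raise InvalidInputError("equilibrium constants must be positive")
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "k_values", k)
        if self.k_sd is not None:
            sd = np.asarray(self.k_sd, dtype=float)
            if sd.shape != t.shape or np.any(sd <= 0):
                raise InvalidInputError("k_sd must match shape and be positive")
            object.__setattr__(self, "k_sd", sd)


@dataclass(frozen=True)
class ThermoFitResult:
    delta_h: float  # kJ/mol
    delta_h_stderr: float
    delta_s: float  # J/(K mol)
    delta_s_stderr: float
    slope: float  # of ln K vs 1/T, in K
    intercept: float
    r_squared: float


def fit_vant_hoff(data: VanHoffDataset, weighted: bool = False) -> ThermoFitResult:
    """Linear regression of ln K on 1/T_K.

    ``weighted=True`` uses 1/sigma_lnK^2 weights with sigma_lnK = sigma_K/K
    (first-order propagation); the default is unweighted, matching the
    common practice of fitting the plotted points directly. Standard errors
    come from the regression covariance.
    """
    t_k = data.temperatures_c + CELSIUS_OFFSET
    x = 1.0 / t_k
    y = np.log(data.k_values)

    if weighted:
        if data.k_sd is None:
            raise InvalidInputError("weighted fit requires k_sd")
        w = (data.k_values / data.k_sd) ** 2  # 1/sigma_lnK^2
    else:
        w = np.ones_like(y)

    # weighted straight line via lstsq on scaled design matrix
    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)]) * sw[:, None]
    coef, _, _, _ = np.linalg.lstsq(design, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])

    resid = y - (slope * x + intercept)
    dof = x.size - 2
    if dof > 0:
        s2 = float(np.sum(w * resid ** 2) / dof)
        cov = s2 * np.linalg.inv(design.T @ design)
        slope_err = float(np.sqrt(cov[0, 0]))
        intercept_err = float(np.sqrt(cov[1, 1]))
    else:
        slope_err = intercept_err = 0.0

    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - float(np.sum(w * resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    return ThermoFitResult(
        delta_h=-R_GAS * slope / 1000.0,  # kJ/mol
        delta_h_stderr=R_GAS * slope_err / 1000.0,
        delta_s=R_GAS * intercept,  # J/(K mol)
        delta_s_stderr=R_GAS * intercept_err,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )
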