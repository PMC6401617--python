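"""Dimerization isotherm: average lifetime versus total concentration.

For a host that self-associates as 2M <=> D and whose fluorescence quantum
yield is unchanged by dimerization (phi_dimer ~ phi_monomer, with the dimer
carrying two chromophores), the intensity-weighted average lifetime of a
solution at total concentration C_t interpolates linearly between the
monomer and dimer lifetimes with the molecule-basis dimer fraction as
weight:

    <tau>(C_t) = tau_0 + (tau_inf - tau_0) * x_molecule(C_t, K_D)

where x_molecule = 2[D]/C_t from exact mass-action speciation, tau_0 is the
monomer lifetime (infinite-dilution limit) and tau_inf the dimer lifetime
(infinite-concentration limit). Fitting <tau> measured over a concentration
series yields K_D, tau_0 and tau_inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .equilibria import dimer_speciation
from .errors import FitFailureError, InvalidInputError

__all__ = [
    "IsothermDataset",
    "IsothermFitResult",
    "IdentifiabilityWarning",
    "isotherm_model",
    "fit_isotherm",
]


class IdentifiabilityWarning(UserWarning):
    """Emitted when a dataset cannot constrain all isotherm parameters."""


@dataclass(frozen=True)
class IsothermDataset:
    """Average lifetime versus total concentration at one temperature."""

    concentrations: np.ndarray  # mol/L, monomer-unit basis
    average_lifetimes: np.ndarray  # ns
    lifetime_sd: np.ndarray | None = None  # ns, optional 1-sigma
    temperature_c: float | None = None  # degrees Celsius

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        tau = np.asarray(self.average_lifetimes, dtype=float)
        if c.ndim != 1 or tau.shape != c.shape:
            raise InvalidInputError("concentrations and lifetimes must be 1-D, equal length")
        if np.unique(c).size < 3:
            raise InvalidInputError("need at least 3 distinct concentrations")
        if np.any(c <= 0):
            raise InvalidInputError("concentrations must be strictly positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "average_lifetimes", tau)
        if self.lifetime_sd is not None:
            sd = np.asarray(self.lifetime_sd, dtype=float)
            if sd.shape != c.shape or np.any(sd <= 0):
                raise InvalidInputError("lifetime_sd must match shape and be positive")
            object.__setattr__(self, "lifetime_sd", sd)


@dataclass(frozen=True)
class IsothermFitResult:
    k_dimer: float  # L/mol
    k_dimer_stderr: float
    tau_monomer: float  # ns (tau_0)
    tau_monomer_stderr: float
    tau_dimer: float  # ns (tau_inf)
    tau_dimer_stderr: float
    residual_norm: float
    converged: bool
    k_unreliable: bool = False


def isotherm_model(c_total, k_dimer: float, tau_monomer: float,
                   tau_dimer: float) -> np.ndarray | float:
    """Predicted <tau> at total concentration(s) ``c_total``."""
    scalar = np.isscalar(c_total)
    c = np.atleast_1d(np.asarray(c_total, dtype=float))
    x = np.array([dimer_speciation(ci, k_dimer).x_molecule for ci in c])
    tau = tau_monomer + (tau_dimer - tau_monomer) * x
    return float(tau[0]) if scalar else tau


def _initial_guess(data: IsothermDataset) -> tuple[float, float, float]:
    """Deterministic start: endpoints for the lifetimes, half-rise for K_D.

    x_molecule = 1/2 at C_t = 1/K_D for the exact quadratic, so the
    concentration where the lifetime crosses halfway between its extremes
    estimates 1/K_D.
    """
    order = np.argsort(data.concentrations)
    c = data.concentrations[order]
    tau = data.average_lifetimes[order]
    tau0, tau_inf = tau[0], tau[-1]
    half = 0.5 * (tau0 + tau_inf)
    rising = tau_inf >= tau0
    crossed = np.nonzero(tau >= half if rising else tau <= half)[0]
    c_half = c[crossed[0]] if crossed.size else np.sqrt(c[0] * c[-1])
    k0 = 1.0 / c_half
    return k0, float(tau0), float(tau_inf)


def fit_isotherm(data: IsothermDataset,
                 init: tuple[float, float, float] | None = None
                 ) -> IsothermFitResult:
    """Fit (K_D, tau_0, tau_inf) to a lifetime-concentration series.

    Nonlinear least squares over (log10 K_D, tau_0, tau_inf); the log
    parameterization enforces K_D > 0 and conditions the problem across the
    many decades K_D can span. Weights are 1/sigma when per-point lifetime
    uncertainties are supplied, uniform otherwise. Standard errors come from
    the covariance at the optimum (the K_D error is propagated from the
    log-scale error). Deterministic given data and ``init``.

    A flat lifetime trend (spread below ~2% of the mean) triggers an
    :class:`IdentifiabilityWarning` and marks K_D unreliable.
    """
    c = data.concentrations
    tau_obs = data.average_lifetimes
    spread = tau_obs.max() - tau_obs.min()
    flat = spread < 0.02 * max(abs(tau_obs.mean()), 1e-12)
    if flat:
        warnings.warn(
            "lifetime data show no concentration trend; K_D is not identifiable",
            IdentifiabilityWarning, stacklevel=2)

    k0, tau0_0, tauinf_0 = init if init is not None else _initial_guess(data)
    w = 1.0 / data.lifetime_sd if data.lifetime_sd is not None else np.ones_like(tau_obs)

    params = lmfit.Parameters()
    params.add("log10_kd", value=np.log10(max(k0, 1e-12)), min=-6, max=12)
    params.add("tau0", value=max(tau0_0, 1e-6), min=1e-6)
    params.add("tau_inf", value=max(tauinf_0, 1e-6), min=1e-6)

    def residual(p):
        model = isotherm_model(c, 10.0 ** p["log10_kd"].value,
                               p["tau0"].value, p["tau_inf"].value)
        return (model - tau_obs) * w

    res = lmfit.minimize(residual, params, method="least_squares", max_nfev=5000)
    if not res.success:
        raise FitFailureError("isotherm fit did not converge", best_result=res)

    p = res.params
    kd = 10.0 ** p["log10_kd"].value
    log_err = p["log10_kd"].stderr
    kd_err = kd * np.log(10.0) * log_err if log_err is not None else np.nan

    def _err(name):
        e = p[name].stderr
        return float(e) if e is not None else np.nan

    return IsothermFitResult(
        k_dimer=float(kd),
        k_dimer_stderr=float(kd_err),
        tau_monomer=float(p["tau0"].value),
        tau_monomer_stderr=_err("tau0"),
        tau_dimer=float(p["tau_inf"].value),
        tau_dimer_stderr=_err("tau_inf"),
        residual_norm=float(np.sqrt(np.sum(np.asarray(res.residual) ** 2))),
        converged=True,
        k_unreliable=bool(flat),
    )
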