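"""Stern-Volmer analysis of dynamic lifetime quenching.

For a dynamically quenched emitter, tau_0 / tau = 1 + K_SV [Q], where
tau_0 is the unquenched (average) lifetime, [Q] the quencher concentration
and K_SV the Stern-Volmer constant. The bimolecular quenching rate constant
follows as k_q = K_SV / tau_0 (with tau_0 converted from ns to s, so k_q
comes out in L mol^-1 s^-1). For mixtures of emitters the plot is linear
only at low [Q]; the intercept is therefore fitted rather than fixed at 1
and flagged when it strays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = ["QuenchSeries", "QuenchFitResult", "fit_stern_volmer",
           "bimolecular_rate"]

NS_TO_S = 1e-9


@dataclass(frozen=True)
class QuenchSeries:
    """Average lifetimes measured over a quencher concentration series."""

    quencher_concentrations: np.ndarray  # mol/L, must include 0
    average_lifetimes: np.ndarray  # ns

    def __post_init__(self):
        q = np.asarray(self.quencher_concentrations, dtype=float)
        tau = np.asarray(self.average_lifetimes, dtype=float)
        if q.ndim != 1 or tau.shape != q.shape:
            raise InvalidInputError("concentrations and lifetimes must be 1-D, equal length")
        if not np.any(q == 0):
            raise InvalidInputError("the zero-quencher point is required")
        if np.any(q < 0) or np.any(tau <= 0):
            raise InvalidInputError("concentrations must be >= 0 and lifetimes > 0")
        object.__setattr__(self, "quencher_concentrations", q)
        object.__setattr__(self, "average_lifetimes", tau)

    @property
    def tau_unquenched(self) -> float:
        """Lifetime at [Q] = 0 (ns)."""
        idx = int(np.nonzero(self.quencher_concentrations == 0)[0][0])
        return float(self.average_lifetimes[idx])


@dataclass(frozen=True)
class QuenchFitResult:
    k_sv: float  # L/mol
    k_sv_stderr: float
    tau_unquenched: float  # ns
    k_q: float  # L/(mol s)
    k_q_stderr: float
    intercept: float
    r_squared: float
    intercept_deviates: bool  # |intercept - 1| > 5%


def bimolecular_rate(k_sv: float, tau_unquenched_ns: float) -> float:
    """k_q = K_SV / tau_0 with the ns -> s conversion, in L/(mol s)."""
    if tau_unquenched_ns <= 0:
        raise InvalidInputError("unquenched lifetime must be positive")
    return k_sv / (tau_unquenched_ns * NS_TO_S)


def fit_stern_volmer(series: QuenchSeries, max_q: float | None = None
                     ) -> QuenchFitResult:
    """Ordinary least squares of tau_0/tau against [Q].

    The slope is K_SV; the intercept is free and flagged when it deviates
    from 1 by more than 5%. ``max_q`` restricts the fit to the low-quencher
    region where the plot is linear for mixed monomer/dimer emission.
    A negative slope (lifetimes increasing with quencher) produces a
    warning rather than an error.
    """
    q = series.quencher_concentrations
    tau = series.average_lifetimes
    if max_q is not None:
        keep = q <= max_q
        q, tau = q[keep], tau[keep]
    if q.size < 3:
        raise InvalidInputError("need at least 3 points for a Stern-Volmer fit")
    tau0 = series.tau_unquenched
    y = tau0 / tau

    if np.ptp(y) == 0.0:
        slope, intercept, r2, slope_err = 0.0, 1.0, 1.0, 0.0
    else:
        reg = stats.linregress(q, y)
        slope, intercept = float(reg.slope), float(reg.intercept)
        r2, slope_err = float(reg.rvalue ** 2), float(reg.stderr)

    if slope < 0:
        warnings.warn("negative Stern-Volmer slope: no quenching detected",
                      UserWarning, stacklevel=2)

    k_q = bimolecular_rate(slope, tau0)
    k_q_err = bimolecular_rate(slope_err, tau0)
    return QuenchFitResult(
        k_sv=slope,
        k_sv_stderr=slope_err,
        tau_unquenched=tau0,
        k_q=k_q,
        k_q_stderr=k_q_err,
        intercept=intercept,
        r_squared=r2,
        intercept_deviates=bool(abs(intercept - 1.0) > 0.05),
    )
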