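"""NMR chemical-shift titrations against 1:1 host-guest binding models.

Under fast exchange the observed shift of a host resonance is the
population-weighted average of its free and bound values:

    delta_obs = delta_free + ddelta_max * [HG] / H_t

with [HG] from the exact 1:1 mass-action quadratic (no dilute-guest
approximation). A self-dimerizing host whose dimer binds the guest intact
("dimer-as-host" mode) is treated as a 1:1 host at the effective dimer
concentration C_t * x_molecule / 2 (or C_t/2 when dimerization is
saturated at the working concentration). Several resonances can be fitted
jointly with a shared association constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .equilibria import coupled_speciation, dimer_speciation, hg_1to1_speciation
from .errors import FitFailureError, InvalidInputError

__all__ = [
    "TitrationDataset",
    "TitrationFitResult",
    "WeakSaturationWarning",
    "titration_model",
    "fit_titration",
    "effective_host_concentration",
]


class WeakSaturationWarning(UserWarning):
    """Emitted when the final titration point is below 50% complexation."""


@dataclass(frozen=True)
class TitrationDataset:
    """Observed shifts of tracked host resonances versus total guest."""

    host_total: float  # mol/L, constant across points
    guest_totals: np.ndarray  # mol/L, non-decreasing
    shifts: np.ndarray  # ppm, shape (n_points, n_resonances)
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        g = np.asarray(self.guest_totals, dtype=float)
        s = np.asarray(self.shifts, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        if g.ndim != 1 or s.shape[0] != g.size:
            raise InvalidInputError("guest_totals and shifts must align on points")
        if self.host_total <= 0:
            raise InvalidInputError("host_total must be positive")
        if np.any(np.diff(g) < 0):
            raise InvalidInputError("guest_totals must be non-decreasing")
        labels = tuple(self.labels) if self.labels else tuple(
            f"res{i + 1}" for i in range(s.shape[1]))
        if len(labels) != s.shape[1]:
            raise InvalidInputError("one label per tracked resonance required")
        object.__setattr__(self, "guest_totals", g)
        object.__setattr__(self, "shifts", s)
        object.__setattr__(self, "labels", labels)

    @property
    def n_points(self) -> int:
        return int(self.guest_totals.size)

    @property
    def n_resonances(self) -> int:
        return int(self.shifts.shape[1])


@dataclass(frozen=True)
class TitrationFitResult:
    k_assoc: float  # L/mol
    k_assoc_stderr: float
    delta_max: np.ndarray  # ppm, per resonance (complexation-induced shift)
    delta_max_stderr: np.ndarray
    delta_free: np.ndarray  # ppm, per resonance
    residuals: np.ndarray  # ppm, shape (n_points, n_resonances)
    effective_host: float  # mol/L actually used as the 1:1 host
    saturation_final: float  # [HG]/H_eff at the last point
    weak_saturation: bool
    converged: bool


def effective_host_concentration(host_total: float, stoichiometry: str,
                                 k_dimer: float | None = None) -> float:
    """Host concentration entering the 1:1 model.

    ``"monomer"`` uses the total as-is. ``"dimer"`` treats the dimer as the
    host: with a dimerization constant the dimer concentration at the
    working total is C_t * x_molecule / 2; without one, dimerization is
    assumed saturated and C_t / 2 is used.
    """
    if stoichiometry == "monomer":
        return float(host_total)
    if stoichiometry == "dimer":
        if k_dimer is None:
            return float(host_total) / 2.0
        sp = dimer_speciation(host_total, k_dimer)
        return sp.dimer_conc
    raise InvalidInputError(f"unknown stoichiometry {stoichiometry!r}")


def titration_model(h_total: float, g_total, k_assoc: float,
                    delta_free: float, delta_max: float) -> np.ndarray | float:
    """Predicted observed shift (ppm) at the given total guest amount(s)."""
    scalar = np.isscalar(g_total)
    g = np.atleast_1d(np.asarray(g_total, dtype=float))
    bound = np.array([
        hg_1to1_speciation(h_total, gi, k_assoc).complex_conc for gi in g])
    delta = delta_free + delta_max * bound / h_total
    return float(delta[0]) if scalar else delta


def titration_model_coupled(c_total: float, g_total, k_dimer: float,
                            k_assoc_dimer: float, delta_free: float,
                            delta_max: float) -> np.ndarray | float:
    """Shift model with dimerization and guest binding solved simultaneously.

    The complexed fraction of host units is 2[DG]/C_t from the coupled
    2M <=> D, D + G <=> DG system; useful when guest binding competes with
    dimer disassembly instead of leaving the dimer intact.
    """
    scalar = np.isscalar(g_total)
    g = np.atleast_1d(np.asarray(g_total, dtype=float))
    frac = np.array([
        2.0 * coupled_speciation(c_total, gi, k_dimer, k_assoc_dimer).complex_conc
        / c_total for gi in g])
    delta = delta_free + delta_max * frac
    return float(delta[0]) if scalar else delta


def fit_titration(data: TitrationDataset, stoichiometry: str = "monomer",
                  k_dimer: float | None = None, shared_k: bool = True,
                  init_k: float | None = None) -> TitrationFitResult:
    """Least-squares fit of K_a and limiting shifts to a titration.

    Parameters are log10(K_a) (shared across resonances unless
    ``shared_k=False``, in which case resonances are fitted independently
    and the amplitude-weighted mean K_a is reported), plus a free-host
    shift and a limiting complexation-induced shift per resonance. The
    exact 1:1 quadratic is evaluated at the effective host concentration
    determined by ``stoichiometry`` (see
    :func:`effective_host_concentration`).

    Emits :class:`WeakSaturationWarning` when the fitted curve puts the
    final point below 50% complexation.
    """
    if data.n_points < 6:
        raise InvalidInputError("need at least 6 titration points")
    h_eff = effective_host_concentration(data.host_total, stoichiometry, k_dimer)
    g = data.guest_totals
    obs = data.shifts
    n_res = data.n_resonances

    if not shared_k and n_res > 1:
        subresults = [
            fit_titration(
                TitrationDataset(data.host_total, g, obs[:, j],
                                 (data.labels[j],)),
                stoichiometry, k_dimer, shared_k=True, init_k=init_k)
            for j in range(n_res)]
        weightsum = sum(abs(r.delta_max[0]) for r in subresults)
        k_mean = sum(r.k_assoc * abs(r.delta_max[0]) for r in subresults) / weightsum
        return TitrationFitResult(
            k_assoc=float(k_mean),
            k_assoc_stderr=float(np.sqrt(sum(
                (r.k_assoc_stderr * abs(r.delta_max[0]) / weightsum) ** 2
                for r in subresults))),
            delta_max=np.array([r.delta_max[0] for r in subresults]),
            delta_max_stderr=np.array([r.delta_max_stderr[0] for r in subresults]),
            delta_free=np.array([r.delta_free[0] for r in subresults]),
            residuals=np.column_stack([r.residuals[:, 0] for r in subresults]),
            effective_host=h_eff,
            saturation_final=float(np.mean([r.saturation_final for r in subresults])),
            weak_saturation=any(r.weak_saturation for r in subresults),
            converged=all(r.converged for r in subresults),
        )

    # deterministic initialization: K from the guest amount at half the
    # observed shift change; delta_free / delta_max from the endpoints
    if init_k is None:
        span = obs[-1] - obs[0]
        j_ref = int(np.argmax(np.abs(span)))
        half_level = obs[0, j_ref] + 0.5 * span[j_ref]
        rising = span[j_ref] >= 0
        y = obs[:, j_ref]
        crossed = np.nonzero(y >= half_level if rising else y <= half_level)[0]
        g_half = g[crossed[0]] if crossed.size and g[crossed[0]] > 0 else \
            max(np.median(g), 1e-12)
        init_k = 1.0 / g_half

    params = lmfit.Parameters()
    params.add("log10_ka", value=np.log10(max(init_k, 1e-12)), min=-3, max=10)
    for j in range(n_res):
        params.add(f"dfree{j}", value=float(obs[0, j]))
        params.add(f"dmax{j}", value=float(obs[-1, j] - obs[0, j]))

    def residual(p):
        ka = 10.0 ** p["log10_ka"].value
        bound = np.array([
            hg_1to1_speciation(h_eff, gi, ka).complex_conc for gi in g])
        frac = bound / h_eff
        out = np.empty_like(obs)
        for j in range(n_res):
            pred = p[f"dfree{j}"].value + p[f"dmax{j}"].value * frac
            out[:, j] = pred - obs[:, j]
        return out.ravel()

    res = lmfit.minimize(residual, params, method="least_squares", max_nfev=5000)
    if not res.success:
        raise FitFailureError("titration fit did not converge", best_result=res)

    p = res.params
    ka = 10.0 ** p["log10_ka"].value
    log_err = p["log10_ka"].stderr
    ka_err = ka * np.log(10.0) * log_err if log_err is not None else np.nan

    def _err(name):
        e = p[name].stderr
        return float(e) if e is not None else np.nan

    sat = hg_1to1_speciation(h_eff, g[-1], ka).complex_conc / h_eff
    weak = bool(sat < 0.5)
    if weak:
        warnings.warn(
            f"final titration point reaches only {sat:.0%} complexation; "
            "K_a is weakly identified", WeakSaturationWarning, stacklevel=2)

    return TitrationFitResult(
        k_assoc=float(ka),
        k_assoc_stderr=float(ka_err),
        delta_max=np.array([p[f"dmax{j}"].value for j in range(n_res)]),
        delta_max_stderr=np.array([_err(f"dmax{j}") for j in range(n_res)]),
        delta_free=np.array([p[f"dfree{j}"].value for j in range(n_res)]),
        residuals=np.asarray(res.residual).reshape(obs.shape),
        effective_host=float(h_eff),
        saturation_final=float(sat),
        weak_saturation=weak,
        converged=True,
    )
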