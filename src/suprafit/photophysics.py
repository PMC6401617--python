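"""Core fluorescence quantities for time-resolved and steady-state data.

Covers the standard observables of a TCSPC (time-correlated single photon
counting) experiment on a multi-exponentially decaying chromophore:

* inner-filter correction of steady-state intensities,
  I_corr = I_obs * 10^((A_ex + A_em)/2);
* the multi-exponential decay law I(t) = sum_i A_i exp(-t / tau_i);
* the amplitude-weighted average lifetime
  <tau> = sum A_i tau_i^2 / sum A_i tau_i;
* fractional steady-state intensity contributions
  f_i = A_i tau_i / sum_j A_j tau_j;
* iterative-reconvolution fitting of decay histograms against a measured
  instrument response function (IRF) with Poisson (Neyman) weighting;
* steady-state anisotropy with the instrumental G factor.

Counts histograms are plain channel-time/counts pairs on a uniform grid;
the convolution of model with IRF is discrete, linear (zero-padded, causal)
and performed on the full channel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import FitFailureError, InvalidInputError, InvalidModelError

__all__ = [
    "IntensityRecord",
    "DecayHistogram",
    "MultiExpModel",
    "MultiExpFitResult",
    "AnisotropySet",
    "correct_inner_filter",
    "decay_model",
    "average_lifetime",
    "fractional_contributions",
    "two_state_average",
    "reconvolve",
    "fit_decay",
    "anisotropy",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityRecord:
    """A steady-state intensity with the absorbances needed to correct it."""

    observed_intensity: float  # arbitrary units, > 0
    absorbance_excitation: float  # dimensionless, >= 0
    absorbance_emission: float  # dimensionless, >= 0


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon counts versus time (a decay curve or an IRF)."""

    channel_times: np.ndarray  # ns, strictly increasing, uniform spacing
    counts: np.ndarray  # non-negative integers per channel

    def __post_init__(self):
        t = np.asarray(self.channel_times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise InvalidInputError("channel_times and counts must be 1-D and equal length")
        if t.size < 2:
            raise InvalidInputError("a histogram needs at least two channels")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidInputError("channel_times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise InvalidInputError("channel spacing must be uniform")
        if np.any(c < 0):
            raise InvalidInputError("counts must be non-negative")
        object.__setattr__(self, "channel_times", t)
        object.__setattr__(self, "counts", c)

    @property
    def channel_width(self) -> float:
        """Channel width in ns."""
        return float(self.channel_times[1] - self.channel_times[0])

    @property
    def window_length(self) -> float:
        """Length of the acquisition window in ns."""
        return float(self.channel_times[-1] - self.channel_times[0]) + self.channel_width

    @property
    def peak_counts(self) -> int:
        return int(self.counts.max())

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))

    def __len__(self) -> int:
        return self.channel_times.size


@dataclass(frozen=True)
class MultiExpModel:
    """Sum-of-exponentials decay model, lifetimes kept in ascending order.

    ``scatter_fraction`` is the fraction of detected photons contributed by
    an IRF-shaped scatter term (stray excitation light); it is carried for
    reconvolution but excluded from all lifetime-derived quantities.
    """

    amplitudes: np.ndarray  # arbitrary units, each >= 0, not all zero
    lifetimes: np.ndarray  # ns, each > 0
    scatter_fraction: float = 0.0

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        tau = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        if a.size != tau.size or a.size == 0:
            raise InvalidModelError("amplitudes and lifetimes must be equal, non-zero length")
        if np.any(tau <= 0):
            raise InvalidModelError("all lifetimes must be positive")
        if np.any(a < 0):
            raise InvalidModelError("amplitudes must be non-negative")
        if not 0.0 <= self.scatter_fraction < 1.0:
            raise InvalidModelError("scatter_fraction must lie in [0, 1)")
        order = np.argsort(tau)
        object.__setattr__(self, "amplitudes", a[order])
        object.__setattr__(self, "lifetimes", tau[order])

    @property
    def n_components(self) -> int:
        return int(self.lifetimes.size)


@dataclass(frozen=True)
class MultiExpFitResult:
    """Outcome of an iterative-reconvolution decay fit."""

    model: MultiExpModel
    average_lifetime: float  # ns, amplitude-weighted
    fractional_contributions: np.ndarray  # sum to 1, scatter excluded
    reduced_chi_square: float
    residuals: np.ndarray = field(repr=False)  # weighted, over the fit window
    fit_window: tuple[int, int] = (0, 0)  # [lo, hi) channel indices
    overparameterized: bool = False
    lifetime_stderr: np.ndarray | None = None  # ns, per component (may be None)


@dataclass(frozen=True)
class AnisotropySet:
    """The four polarized intensities of an L-format anisotropy measurement."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------

def correct_inner_filter(record: IntensityRecord) -> float:
    """Correct a steady-state intensity for the inner-filter effect.

    Returns I_obs * 10^((A_ex + A_em) / 2), the usual first-order
    absorbance-based correction for attenuation of both the excitation
    beam and the emitted light.
    """
    if record.observed_intensity <= 0:
        raise InvalidInputError("observed intensity must be positive")
    if record.absorbance_excitation < 0 or record.absorbance_emission < 0:
        raise InvalidInputError("absorbances must be non-negative")
    exponent = 0.5 * (record.absorbance_excitation + record.absorbance_emission)
    return record.observed_intensity * 10.0 ** exponent


def decay_model(model: MultiExpModel, times) -> np.ndarray:
    """Evaluate I(t) = sum_i A_i exp(-t / tau_i) on a time grid (ns)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    return (model.amplitudes[:, None]
            * np.exp(-t[None, :] / model.lifetimes[:, None])).sum(axis=0)


def average_lifetime(model: MultiExpModel) -> float:
    """Amplitude-weighted average lifetime sum A_i tau_i^2 / sum A_i tau_i."""
    a, tau = model.amplitudes, model.lifetimes
    denom = float(np.sum(a * tau))
    if denom == 0:
        raise InvalidModelError("all amplitudes are zero")
    return float(np.sum(a * tau * tau) / denom)


def fractional_contributions(model: MultiExpModel) -> np.ndarray:
    """Fractional steady-state intensity f_i = A_i tau_i / sum_j A_j tau_j."""
    a, tau = model.amplitudes, model.lifetimes
    w = a * tau
    denom = float(w.sum())
    if denom == 0:
        raise InvalidModelError("all amplitudes are zero")
    return w / denom


def two_state_average(f1: float, tau1: float, f2: float, tau2: float,
                      tol: float = 1e-6) -> float:
    """Intensity-weighted average lifetime of two non-interacting emitters.

    <tau> = f1 tau1 + f2 tau2 with f1 + f2 = 1 (checked to ``tol``).
    """
    if abs(f1 + f2 - 1.0) > tol:
        raise InvalidInputError(f"fractions must sum to 1, got {f1 + f2}")
    return f1 * tau1 + f2 * tau2


def anisotropy(polset: AnisotropySet) -> float:
    """Steady-state anisotropy r = (I_VV - G I_VH)/(I_VV + 2 G I_VH).

    The G factor I_HV/I_HH corrects for polarization bias of the detection
    path.
    """
    if min(polset.i_vv, polset.i_vh, polset.i_hv, polset.i_hh) <= 0:
        raise InvalidInputError("all four polarized intensities must be positive")
    g = polset.i_hv / polset.i_hh
    denom = polset.i_vv + 2.0 * g * polset.i_vh
    if denom == 0:
        raise InvalidInputError("zero denominator in anisotropy")
    return (polset.i_vv - g * polset.i_vh) / denom


# --------------------------------------------------------------------------
# reconvolution
# --------------------------------------------------------------------------

def reconvolve(irf: DecayHistogram, model: MultiExpModel) -> np.ndarray:
    """Convolve a decay model with a measured IRF on the IRF's channel grid.

    The IRF counts are normalized to unit sum; the model is evaluated on
    times relative to the first channel and convolved linearly (zero-padded,
    causal), so a delta-function IRF reproduces the bare decay shifted to
    the delta's channel. A non-zero ``scatter_fraction`` s replaces the
    result with (1 - s) * conv + s * sum(conv) * irf_shape, i.e. a fraction
    s of the total detected intensity follows the IRF itself.
    """
    total = irf.counts.sum()
    if total <= 0:
        raise InvalidInputError("IRF has no counts")
    irf_shape = irf.counts / total
    t_rel = irf.channel_times - irf.channel_times[0]
    pure = decay_model(
        MultiExpModel(model.amplitudes, model.lifetimes), t_rel)
    conv = np.convolve(irf_shape, pure)[: len(irf)]
    s = model.scatter_fraction
    if s > 0:
        conv = (1.0 - s) * conv + s * conv.sum() * irf_shape
    return conv


def _check_same_grid(a: DecayHistogram, b: DecayHistogram) -> None:
    if len(a) != len(b) or not np.allclose(
            a.channel_times, b.channel_times, rtol=1e-9, atol=1e-12):
        raise InvalidInputError("decay and IRF must share the same channel grid")


def _resolve_fit_window(decay: DecayHistogram, fit_range,
                        tail_min_counts: int) -> tuple[int, int]:
    """Translate a fit-range policy into a [lo, hi) channel window.

    ``fit_range`` may be an explicit (lo, hi) channel pair, ``"full"``, or
    ``"tail"`` (the default policy): from the decay's peak channel to the
    last channel holding at least ``tail_min_counts`` counts, which keeps
    Neyman (1/counts) weights in the regime where they are unbiased.
    """
    n = len(decay)
    if fit_range == "full":
        lo, hi = 0, n
    elif fit_range == "tail" or fit_range is None:
        lo = decay.peak_channel
        above = np.nonzero(decay.counts >= tail_min_counts)[0]
        hi = int(above[-1]) + 1 if above.size else lo
    else:
        lo, hi = int(fit_range[0]), int(fit_range[1])
        if lo < 0 or hi > n:
            raise InvalidInputError(f"fit range {fit_range} outside [0, {n})")
    if hi - lo < 2:
        raise InvalidInputError("fit window is empty or too short")
    return lo, hi


def fit_decay(decay: DecayHistogram, irf: DecayHistogram, n_components: int = 3,
              fit_range="tail", fit_scatter: bool = False,
              tail_min_counts: int = 10) -> MultiExpFitResult:
    """Fit a decay histogram by iterative reconvolution.

    Weighted least squares of the IRF-reconvolved multi-exponential model
    against the measured counts, with Neyman weights 1/max(counts, 1)
    appropriate for Poisson statistics. Initialization is deterministic:
    lifetimes log-spaced between one channel width and half the window,
    amplitudes split evenly at the scale of the peak counts.

    Parameters
    ----------
    n_components : number of exponential components, 1-3.
    fit_range : "tail" (peak channel to the last channel with at least
        ``tail_min_counts`` counts; default), "full", or an explicit
        (lo, hi) channel-index pair.
    fit_scatter : add a free IRF-shaped scatter fraction (stray light).

    Returns
    -------
    MultiExpFitResult with lifetimes in ascending order, the
    amplitude-weighted average lifetime, fractional contributions, reduced
    chi-square, weighted residuals over the fit window and an
    over-parameterization flag (raised if any component's fractional
    contribution falls below 1%).
    """
    from scipy.optimize import nnls

    if n_components not in (1, 2, 3):
        raise InvalidInputError("n_components must be 1, 2 or 3")
    _check_same_grid(decay, irf)
    lo, hi = _resolve_fit_window(decay, fit_range, tail_min_counts)

    counts = decay.counts
    weights = 1.0 / np.sqrt(np.maximum(counts[lo:hi], 1.0))
    y = counts[lo:hi] * weights
    dt = decay.channel_width
    window = decay.window_length
    irf_total = irf.counts.sum()
    if irf_total <= 0:
        raise InvalidInputError("IRF has no counts")
    irf_shape = irf.counts / irf_total
    t_rel = irf.channel_times - irf.channel_times[0]
    tau_init = np.geomspace(dt, window / 2.0, n_components) \
        if n_components > 1 else np.array([window / 20.0])

    # Variable projection: for trial lifetimes, the amplitudes (and scatter
    # weight) solve a non-negative linear least-squares problem, so only the
    # log-lifetimes are optimized nonlinearly. This removes the amplitude/
    # lifetime scale disparity that defeats a joint search.
    def design(tau):
        cols = [np.convolve(irf_shape, np.exp(-t_rel / ti))[: len(irf)][lo:hi]
                for ti in tau]
        if fit_scatter:
            cols.append(irf_shape[lo:hi] * irf_total)
        return np.column_stack(cols) * weights[:, None]

    def solve_linear(tau):
        basis = design(tau)
        coef, _ = nnls(basis, y)
        return coef, basis @ coef - y

    params = lmfit.Parameters()
    for i in range(n_components):
        params.add(f"log_tau{i}", value=np.log(tau_init[i]),
                   min=np.log(dt / 100.0), max=np.log(window * 5.0))

    def residual(p):
        tau = np.exp([p[f"log_tau{i}"].value for i in range(n_components)])
        return solve_linear(tau)[1]

    minres = lmfit.minimize(residual, params, method="least_squares",
                            max_nfev=500 * (n_components + 1))
    if not minres.success:
        raise FitFailureError("decay fit did not converge", best_result=minres)

    p = minres.params
    tau = np.exp([p[f"log_tau{i}"].value for i in range(n_components)])
    tau_err = np.array([
        tau[i] * p[f"log_tau{i}"].stderr
        if p[f"log_tau{i}"].stderr is not None else np.nan
        for i in range(n_components)])
    coef, _ = solve_linear(tau)
    a = coef[:n_components]
    if fit_scatter:
        # convert the scatter column weight into a fraction of total counts
        model_counts = design(tau) @ coef / weights
        scatter_counts = coef[-1] * irf_shape[lo:hi] * irf_total
        total = float(model_counts.sum())
        s = float(scatter_counts.sum() / total) if total > 0 else 0.0
        s = min(max(s, 0.0), 1.0 - 1e-12)
    else:
        s = 0.0
    order = np.argsort(tau)
    a, tau, tau_err = a[order], tau[order], tau_err[order]
    if np.all(a == 0):
        raise FitFailureError("fit collapsed to zero amplitude", best_result=minres)

    model = MultiExpModel(a, tau, scatter_fraction=s)
    frac = fractional_contributions(model)
    resid = np.asarray(minres.residual)
    nfree = max(resid.size - len(minres.var_names), 1)
    red_chi2 = float(np.sum(resid ** 2) / nfree)
    overpar = bool(np.any(frac < 0.01))
    return MultiExpFitResult(
        model=model,
        average_lifetime=average_lifetime(model),
        fractional_contributions=frac,
        reduced_chi_square=red_chi2,
        residuals=resid,
        fit_window=(lo, hi),
        overparameterized=overpar,
        lifetime_stderr=tau_err,
    )
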