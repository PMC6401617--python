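"""Seeded generators for every input kind the analysis chain consumes.

Each generator draws from its own RNG stream derived from
``(seed, dataset-kind)``, so datasets of different kinds produced from the
same seed are statistically independent and each generator is
bit-reproducible in isolation.

Defaults mirror the study conditions the analyses are designed for: a
200 ns TCSPC window with 10,000 counts at the intensity maximum, host
concentrations up to ~0.3 mM, temperatures 5-45 degC in 10-degree steps,
quencher 0-8 mM, and ~15-point NMR titrations run to high saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .equilibria import hg_1to1_speciation
from .errors import InvalidInputError
from .isotherm import IsothermDataset, isotherm_model
from .nmr_titration import TitrationDataset, titration_model
from .photophysics import DecayHistogram, MultiExpModel, reconvolve
from .quenching import QuenchSeries
from .thermo import CELSIUS_OFFSET, R_GAS, VanHoffDataset

__all__ = [
    "SimulationConfig",
    "simulate_decay",
    "simulate_isotherm",
    "simulate_titration",
    "simulate_vant_hoff",
    "simulate_quench",
    "saturation_guest_design",
]

# fixed stream tags so each dataset kind has an independent RNG stream
_STREAMS = {"decay": 1, "isotherm": 2, "titration": 3, "vanthoff": 4,
            "quench": 5}


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[kind]])


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and acquisition settings for all generators.

    Lifetime/equilibrium defaults correspond to a strongly dimerizing
    aromatic-clipped cyclodextrin at 25 degC (K_D = 4.1e5 L/mol,
    tau_monomer = 2.3 ns, tau_dimer = 11.6 ns).
    """

    seed: int = 0

    # TCSPC acquisition
    window_ns: float = 200.0
    n_channels: int = 2000
    peak_counts: int = 10_000
    irf_center_ns: float = 10.0
    irf_sigma_ns: float = 0.5
    poisson: bool = True
    background_counts: float = 0.0

    # decay truth
    amplitudes: tuple[float, ...] = (1.0, 1.0)
    lifetimes: tuple[float, ...] = (2.3, 11.6)

    # self-dimerization truth
    k_dimer: float = 4.1e5  # L/mol
    tau_monomer: float = 2.3  # ns
    tau_dimer: float = 11.6  # ns

    # host-guest truth (dimer-as-host convention by default)
    k_assoc: float = 1.3e4  # L/mol
    host_total: float = 2.5e-4  # mol/L (effective 1:1 host)
    delta_free_ppm: float = 3.90
    delta_max_ppm: float = 0.05

    # thermodynamics truth
    delta_h_kj: float = -2.5  # kJ/mol
    delta_s_j: float = 102.7  # J/(K mol)

    # quenching truth
    k_sv: float = 15.0  # L/mol
    tau_unquenched: float = 10.5  # ns

    # noise levels
    lifetime_sigma_ns: float = 0.2
    shift_sigma_ppm: float = 0.002
    k_rel_sigma: float = 0.10  # lognormal sigma on equilibrium constants

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# default measurement designs ------------------------------------------------

DEFAULT_ISOTHERM_CONCENTRATIONS = np.geomspace(1e-6, 3e-4, 12)
DEFAULT_TEMPERATURES_C = np.arange(5.0, 46.0, 10.0)  # 5..45 degC
DEFAULT_QUENCHER_CONCENTRATIONS = np.linspace(0.0, 8e-3, 9)  # 0..8 mM


def saturation_guest_design(h_eff: float, k_assoc: float, n_points: int = 15,
                            max_saturation: float = 0.95) -> np.ndarray:
    """Guest totals driving a 1:1 host from 0 to ``max_saturation`` bound.

    Inverts the exact quadratic: for a target bound fraction s,
    G_t = s H + s / (K (1 - s)). The first point is guest-free so the
    titration anchors the free-host shift.
    """
    if not 0 < max_saturation < 1:
        raise InvalidInputError("max_saturation must lie in (0, 1)")
    s = np.linspace(0.0, max_saturation, n_points)
    return s * h_eff + s / (k_assoc * (1.0 - s + 1e-300))


# generators -----------------------------------------------------------------

def simulate_decay(config: SimulationConfig
                   ) -> tuple[DecayHistogram, DecayHistogram]:
    """Simulate a TCSPC decay histogram and its matching IRF.

    The IRF is a noise-free Gaussian pulse on the channel grid; the decay is
    the IRF-reconvolved multi-exponential truth scaled so the maximum
    expected count equals ``peak_counts``, plus an optional flat background,
    Poisson-sampled per channel when ``poisson`` is on.

    Returns ``(decay, irf)`` sharing one channel grid.
    """
    if config.n_channels < 2:
        raise InvalidInputError("need at least 2 channels")
    rng = _rng(config.seed, "decay")
    dt = config.window_ns / config.n_channels
    times = (np.arange(config.n_channels) + 0.5) * dt

    irf_shape = np.exp(-0.5 * ((times - config.irf_center_ns)
                               / config.irf_sigma_ns) ** 2)
    irf_counts = irf_shape / irf_shape.max() * config.peak_counts
    irf = DecayHistogram(times, irf_counts)

    model = MultiExpModel(np.asarray(config.amplitudes),
                          np.asarray(config.lifetimes))
    expected = reconvolve(irf, model)
    expected = expected / expected.max() * config.peak_counts
    expected = expected + config.background_counts
    if config.poisson:
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DecayHistogram(times, counts), irf


def simulate_isotherm(config: SimulationConfig,
                      concentrations=None) -> IsothermDataset:
    """Simulate an average-lifetime-vs-concentration dimerization isotherm."""
    rng = _rng(config.seed, "isotherm")
    c = np.asarray(DEFAULT_ISOTHERM_CONCENTRATIONS if concentrations is None
                   else concentrations, dtype=float)
    tau = isotherm_model(c, config.k_dimer, config.tau_monomer,
                         config.tau_dimer)
    tau = tau + rng.normal(0.0, config.lifetime_sigma_ns, size=c.size) \
        if config.lifetime_sigma_ns > 0 else tau
    return IsothermDataset(c, tau, temperature_c=25.0)


def simulate_titration(config: SimulationConfig,
                       guest_totals=None) -> TitrationDataset:
    """Simulate a single-resonance NMR titration of a 1:1 host."""
    rng = _rng(config.seed, "titration")
    if guest_totals is None:
        guest_totals = saturation_guest_design(config.host_total,
                                               config.k_assoc)
    g = np.asarray(guest_totals, dtype=float)
    shifts = titration_model(config.host_total, g, config.k_assoc,
                             config.delta_free_ppm, config.delta_max_ppm)
    if config.shift_sigma_ppm > 0:
        shifts = shifts + rng.normal(0.0, config.shift_sigma_ppm, size=g.size)
    return TitrationDataset(config.host_total, g, shifts, ("H3",))


def simulate_vant_hoff(config: SimulationConfig,
                       temperatures_c=None) -> VanHoffDataset:
    """Simulate K(T) with multiplicative lognormal noise."""
    rng = _rng(config.seed, "vanthoff")
    t_c = np.asarray(DEFAULT_TEMPERATURES_C if temperatures_c is None
                     else temperatures_c, dtype=float)
    t_k = t_c + CELSIUS_OFFSET
    k = np.exp(-config.delta_h_kj * 1000.0 / (R_GAS * t_k)
               + config.delta_s_j / R_GAS)
    if config.k_rel_sigma > 0:
        k = k * np.exp(rng.normal(0.0, config.k_rel_sigma, size=t_k.size))
    return VanHoffDataset(t_c, k)


def simulate_quench(config: SimulationConfig,
                    quencher_concentrations=None) -> QuenchSeries:
    """Simulate a lifetime-quenching series obeying Stern-Volmer kinetics."""
    rng = _rng(config.seed, "quench")
    q = np.asarray(DEFAULT_QUENCHER_CONCENTRATIONS
                   if quencher_concentrations is None
                   else quencher_concentrations, dtype=float)
    tau = config.tau_unquenched / (1.0 + config.k_sv * q)
    if config.lifetime_sigma_ns > 0:
        tau = tau + rng.normal(0.0, config.lifetime_sigma_ns, size=q.size)
        tau = np.maximum(tau, 1e-3)
    return QuenchSeries(q, tau)
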