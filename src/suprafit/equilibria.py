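"""Mass-action speciation for self-dimerizing hosts and host-guest binding.

All concentrations are mol/L. The self-association equilibrium is

    2 M <=> D,        K_D = [D] / [M]^2   (L/mol)

with the total concentration C_t counted on a monomer-unit basis,
C_t = [M] + 2[D]. Two dimer-fraction conventions circulate in the
literature and both are exposed:

* ``x_molecule`` = 2[D]/C_t — the fraction of *molecules* (monomer units)
  residing in dimers; this is the natural weight for any per-chromophore
  observable (fluorescence intensity, lifetime fractions).
* ``x_species``  = [D]/([M]+[D]) — the fraction of independent *species*
  that are dimers.

For K_D > 0 and C_t > 0, x_species < x_molecule always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NumericalError

__all__ = [
    "DimerSpeciation",
    "BindingSpeciation",
    "CoupledSpeciation",
    "dimer_speciation",
    "hg_1to1_speciation",
    "coupled_speciation",
]


@dataclass(frozen=True)
class DimerSpeciation:
    """Equilibrium composition of a 2M <=> D system."""

    total_concentration: float  # C_t, mol/L (monomer-unit basis)
    k_dimer: float  # K_D, L/mol
    monomer_conc: float  # [M], mol/L
    dimer_conc: float  # [D], mol/L
    x_molecule: float  # 2[D]/C_t
    x_species: float  # [D]/([M]+[D])


@dataclass(frozen=True)
class BindingSpeciation:
    """Equilibrium composition of a 1:1 H + G <=> HG system."""

    total_host: float
    total_guest: float
    k_assoc: float
    complex_conc: float
    free_host: float
    free_guest: float


@dataclass(frozen=True)
class CoupledSpeciation:
    """Composition of the coupled 2M <=> D, D + G <=> DG system."""

    total_concentration: float  # C_t (monomer-unit basis)
    total_guest: float
    k_dimer: float
    k_assoc_dimer: float
    monomer_conc: float
    dimer_conc: float
    free_guest: float
    complex_conc: float  # [DG]


def dimer_speciation(c_total: float, k_dimer: float) -> DimerSpeciation:
    """Solve the monomer-dimer equilibrium exactly.

    The mass balance [M] + 2 K_D [M]^2 = C_t is a quadratic in [M]; its
    physical (positive) root is

        [M] = (-1 + sqrt(1 + 8 K_D C_t)) / (4 K_D)

    evaluated here in a cancellation-safe form. ``k_dimer == 0`` returns the
    no-association limit [M] = C_t.

    Parameters
    ----------
    c_total : total concentration in mol/L, counted per monomer unit.
    k_dimer : association constant of 2M <=> D, L/mol.
    """
    if c_total < 0 or k_dimer < 0:
        raise InvalidInputError(
            f"c_total and k_dimer must be non-negative, got {c_total}, {k_dimer}"
        )
    if k_dimer == 0 or c_total == 0:
        m = float(c_total)
    else:
        # (-1 + sqrt(1+8KC))/(4K) rewritten as 2C/(1+sqrt(1+8KC)) to avoid
        # subtractive cancellation at small K*C.
        m = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * k_dimer * c_total))
    d = k_dimer * m * m
    x_mol = 2.0 * d / c_total if c_total > 0 else 0.0
    x_sp = d / (m + d) if (m + d) > 0 else 0.0
    return DimerSpeciation(
        total_concentration=float(c_total),
        k_dimer=float(k_dimer),
        monomer_conc=float(m),
        dimer_conc=float(d),
        x_molecule=float(x_mol),
        x_species=float(x_sp),
    )


def hg_1to1_speciation(
    h_total: float, g_total: float, k_assoc: float
) -> BindingSpeciation:
    """Solve 1:1 host-guest binding exactly.

    [HG] is the physical root of K (H_t - x)(G_t - x) = x:

        x = ((H_t + G_t + 1/K) - sqrt((H_t + G_t + 1/K)^2 - 4 H_t G_t)) / 2

    again computed in a cancellation-safe form. K = 0 gives [HG] = 0.
    """
    if h_total < 0 or g_total < 0 or k_assoc < 0:
        raise InvalidInputError(
            "h_total, g_total and k_assoc must all be non-negative"
        )
    if k_assoc == 0 or h_total == 0 or g_total == 0:
        x = 0.0
    else:
        b = h_total + g_total + 1.0 / k_assoc
        disc = b * b - 4.0 * h_total * g_total
        # disc >= (H-G)^2 + 2(H+G)/K + 1/K^2 > 0 always
        sq = np.sqrt(disc)
        # smaller quadratic root via the numerically stable product form
        x = 2.0 * h_total * g_total / (b + sq)
    return BindingSpeciation(
        total_host=float(h_total),
        total_guest=float(g_total),
        k_assoc=float(k_assoc),
        complex_conc=float(x),
        free_host=float(h_total - x),
        free_guest=float(g_total - x),
    )


def coupled_speciation(
    c_total: float,
    g_total: float,
    k_dimer: float,
    k_assoc_dimer: float,
    rtol: float = 1e-12,
) -> CoupledSpeciation:
    """Solve the coupled dimerization + dimer-guest binding system.

    Equilibria and balances:

        [D]  = K_D [M]^2
        [DG] = K_a [D][G]
        [M] + 2[D] + 2[DG] = C_t      (host units)
        [G] + [DG]         = G_t      (guest)

    For a trial [M], [D] follows directly and the guest balance gives
    [G] = G_t / (1 + K_a [D]); the host balance residual is then monotone
    in [M], so a bracketed Brent search on [M] in [0, C_t] is globally
    convergent. ``k_assoc_dimer == 0`` reduces exactly to
    :func:`dimer_speciation`.
    """
    from scipy.optimize import brentq

    if min(c_total, g_total, k_dimer, k_assoc_dimer) < 0:
        raise InvalidInputError("all inputs must be non-negative")

    if k_assoc_dimer == 0 or g_total == 0 or k_dimer == 0:
        ds = dimer_speciation(c_total, k_dimer)
        hg = 0.0
        if k_dimer == 0 and k_assoc_dimer > 0:
            # no dimer ever forms, hence no DG either
            pass
        g_free = float(g_total)
        return CoupledSpeciation(
            total_concentration=float(c_total),
            total_guest=float(g_total),
            k_dimer=float(k_dimer),
            k_assoc_dimer=float(k_assoc_dimer),
            monomer_conc=ds.monomer_conc,
            dimer_conc=ds.dimer_conc,
            free_guest=g_free,
            complex_conc=hg,
        )

    if c_total == 0:
        return CoupledSpeciation(
            float(c_total), float(g_total), float(k_dimer),
            float(k_assoc_dimer), 0.0, 0.0, float(g_total), 0.0,
        )

    def host_residual(m: float) -> float:
        d = k_dimer * m * m
        g = g_total / (1.0 + k_assoc_dimer * d)
        dg = k_assoc_dimer * d * g
        return m + 2.0 * d + 2.0 * dg - c_total

    # residual(0) = -C_t < 0, residual(C_t) >= 0: bracket is [0, C_t]
    try:
        m = brentq(host_residual, 0.0, c_total, xtol=1e-300, rtol=8.9e-16,
                   maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover
        raise NumericalError(
            f"coupled speciation failed for C_t={c_total}, G_t={g_total}, "
            f"K_D={k_dimer}, K_a={k_assoc_dimer}: {exc}"
        ) from exc

    d = k_dimer * m * m
    g = g_total / (1.0 + k_assoc_dimer * d)
    dg = k_assoc_dimer * d * g

    resid = abs(m + 2 * d + 2 * dg - c_total) / c_total
    if resid > rtol * 100:
        raise NumericalError(
            f"mass-balance residual {resid:.3e} exceeds tolerance"
        )
    return CoupledSpeciation(
        total_concentration=float(c_total),
        total_guest=float(g_total),
        k_dimer=float(k_dimer),
        k_assoc_dimer=float(k_assoc_dimer),
        monomer_conc=float(m),
        dimer_conc=float(d),
        free_guest=float(g),
        complex_conc=float(dg),
    )
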