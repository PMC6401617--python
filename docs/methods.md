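# Methods

This note records the models the package implements, the assumptions they
rest on, and the numerical and design choices made where more than one
reasonable option existed.

## Speciation

The self-association 2M ⇌ D with K_D = [D]/[M]² (L/mol) and total
concentration Cₜ = [M] + 2[D] (monomer-unit basis) reduces to the quadratic
2K_D[M]² + [M] − Cₜ = 0, solved in the cancellation-safe form
[M] = 2Cₜ / (1 + √(1 + 8K_DCₜ)). Two dimer-fraction conventions are
first-class outputs because both circulate in the literature and they
differ substantially at intermediate association: x_molecule = 2[D]/Cₜ
(fraction of molecules dimerized; the natural weight for per-chromophore
observables) and x_species = [D]/([M]+[D]) (fraction of independent
species). x_species < x_molecule whenever both are defined; quenching-table
dimer fractions in the literature typically follow the species basis while
"percent dimerized" statements follow the molecule basis. At K_D = 4.1·10⁵
L/mol and Cₜ = 0.02 mM the two bases give 0.64 and 0.78 respectively;
a published value of 0.69 for those conditions matches neither exactly and
is left undecided rather than forced.

1:1 host–guest binding uses the analogous stable quadratic root
[HG] = 2HG/(b + √(b² − 4HG)) with b = H + G + 1/K. The coupled system
(2M ⇌ D, D + G ⇌ DG) is monotone in [M] after eliminating [D] and [G]
through the equilibrium and guest-balance relations, so Brent's method on
[M] ∈ [0, Cₜ] is globally convergent; mass-balance residuals are checked to
10⁻¹⁰ relative.

## TCSPC decay fitting

The decay model is I(t) = Σᵢ Aᵢ e^(−t/τᵢ) (1–3 components), convolved with
the measured IRF by discrete linear convolution (IRF normalized to unit
sum, zero-padded, causal — a delta IRF reproduces the bare decay). Counts
are Poisson, so residuals carry Neyman weights 1/√max(N,1).

Fitting uses **variable projection**: for trial lifetimes the amplitudes
(and the optional IRF-shaped scatter term) solve a non-negative linear
least-squares problem, and only the log-lifetimes are optimized nonlinearly
(trust-region reflective via lmfit). A joint search over amplitudes
(~10⁴ counts) and lifetimes (~ns) is badly scaled and reliably stalls in an
equal-lifetimes saddle on two-component data; projection removes the linear
subspace and converges in milliseconds from the deterministic
initialization (lifetimes log-spaced between one channel width and half the
window). Non-negativity of the projected amplitudes doubles as the
physically motivated bound. Lifetime standard errors come from the
covariance of the projected problem and therefore neglect
amplitude–lifetime correlation; they are indicative, not exact.

The default fit window runs from the decay's peak channel to the last
channel holding ≥ 10 counts. Tail-only fitting is the conventional default;
the count floor exists because Neyman weights are biased for near-empty
channels and would otherwise drag the reduced χ² well below 1 in the long
empty tail of a 200 ns window. Both an explicit channel window and
full-range fitting are available. Sub-nanosecond scatter (stray excitation
light) can be fitted as an IRF-shaped fraction; it is excluded from ⟨τ⟩ and
the fractional contributions, mirroring the practice of discarding the
scatter component when reporting lifetimes. Component count is
user-specified; a fit in which any component contributes < 1 % of the
steady-state intensity is flagged over-parameterized rather than silently
reduced.

## Dimerization isotherm

If the fluorescence quantum yield is unchanged by dimerization and the
dimer carries two chromophores (ε_D ≈ 2ε_M), the intensity fraction
emitted by dimers equals the molecule-basis dimer fraction, and the
two-species intensity-weighted average lifetime becomes

    ⟨τ⟩(Cₜ) = τ₀ + (τ∞ − τ₀) · x_molecule(Cₜ, K_D)

with τ₀ the monomer and τ∞ the dimer lifetime. The molecule basis (rather
than the species basis) is the choice consistent with that
equal-quantum-yield assumption, and it reproduces the ~90 % dimer figure
quoted for a strong dimerizer at 0.15 mM with K_D = 4.1·10⁵ L/mol.

The fit runs over (log₁₀K_D, τ₀, τ∞) — the log keeps K_D positive and
conditions a parameter spanning many decades — with uniform weights by
default (1/σ² when per-point uncertainties are supplied). Initialization is
deterministic: endpoint lifetimes, and K_D from the concentration where the
lifetime crosses halfway (x_molecule = ½ exactly at Cₜ = 1/K_D). K_D
standard errors are propagated from the log-scale covariance. A lifetime
spread below 2 % of the mean triggers an identifiability warning and marks
K_D unreliable. At the reference design (12 log-spaced concentrations over
10⁻⁶–3·10⁻⁴ M, σ_τ = 0.2 ns), the fitted log₁₀K_D spread matches the
Cramér–Rao bound (~0.19 decades), i.e. the estimator is efficient and the
remaining scatter is information-limited, not algorithmic.

## Stern–Volmer quenching

τ₀/⟨τ⟩ vs [Q] by ordinary least squares with a *free* intercept: for mixed
monomer/dimer emission the plot is linear only at low [Q], so a fitted
intercept deviating from 1 by more than 5 % raises a flag, and `max_q`
restricts the window (0–8 mM is a typical linear range for diacetyl
quenching). k_q = K_SV/τ₀ with the ns→s conversion; a negative slope warns
rather than errors.

## Van't Hoff

ln K against 1/T_K (T in °C converted internally, R = 8.314 J K⁻¹ mol⁻¹):
ΔH = −R·slope, ΔS = R·intercept, errors from the regression covariance.
Unweighted by default — K values read from a table rarely carry usable
uncertainties — with optional 1/σ²_lnK weighting (σ_lnK = σ_K/K). No
ΔCp ≠ 0 curvature is modeled.

## NMR titrations

Fast-exchange observed shifts: δ = δ_free + Δδ_max·[HG]/Hₜ with [HG] from
the exact quadratic at every point (no dilute-guest shortcut — at
Hₜ·K_a ≳ 0.1 host depletion is visible and the approximation biases K_a).
δ_free and Δδ_max are fitted per resonance; K_a is shared across resonances
by default (a per-resonance mode reports an amplitude-weighted mean K_a
instead). A host that dimerizes and binds the guest as an intact dimer is
handled by fitting at the effective dimer concentration Cₜ·x_molecule/2
(or Cₜ/2 when dimerization is saturated at the working concentration); a
fully coupled model (dimerization and binding solved simultaneously) is
provided for guests that disassemble the dimer, but only the
dimer-as-inert-host convention is validated by the recovery studies. A
final point below 50 % complexation triggers a weak-identifiability
warning.

## ICD sign rule

Inside the host cavity: positive band for a transition moment parallel to
the host axis, negative perpendicular; both reversed outside; node at the
magic angle 54.7°. A ±3° default tolerance band returns "near-zero" around
the node, expressing bands observed as "almost zero"; the band is
configurable. No rotational-strength magnitudes or exciton-coupling
intensities are computed — the rule is qualitative by nature.

## Synthetic data

Every generator draws from `default_rng([seed, kind])`, one fixed stream
tag per dataset kind, so outputs are bit-reproducible per seed and
different kinds are independent. Defaults emulate the reference study
conditions: 200 ns window, 2000 channels, 10,000 counts at the maximum,
Gaussian IRF (σ = 0.5 ns, centered at 10 ns); isotherms over 10⁻⁶–3·10⁻⁴ M
(12 log-spaced points, Gaussian σ_τ); titrations with 15 guest additions
spaced uniformly in bound fraction up to 95 % by inverting the binding
quadratic (Gaussian σ_δ = 0.002 ppm); temperatures 5–45 °C in 10° steps
with lognormal noise on K; quencher 0–8 mM. The TCSPC generator models
Poisson counting plus an optional flat background only — no after-pulsing,
dead-time or timing-jitter effects — and the IRF is noise-free; real
instruments violate all of these mildly, so passing recovery tests
demonstrate estimator correctness under the assumed noise model, not
robustness to instrument artifacts. Likewise the table generators use
i.i.d. Gaussian noise, whereas real ⟨τ⟩ values inherit correlated errors
from the upstream decay fits.

## Recovery studies and problem sizes

The acceptance script and end-to-end tests use 50 replicates per study,
with child seeds spawned from one master seed via `SeedSequence`; medians
over replicates are reported. Fifty replicates keep the whole script at a
few seconds while placing the median's sampling error well inside the
uncertainty bands being tested against; decays use 2000 channels
(0.1 ns/channel), the native resolution of the emulated acquisition.

## Known limitations

* Lifetime errors from variable projection ignore amplitude coupling.
* The coupled titration model is provided but not validated against
  reference constants (the underlying study fitted the inert-dimer model).
* No isodesmic or higher-aggregate association models; no global
  multi-temperature fits (van't Hoff runs on per-temperature K values).
* The monomer+guest/dimer+guest competition system is limited to the
  documented coupled D+G ⇌ DG form.
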