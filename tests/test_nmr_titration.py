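import numpy as np
import pytest

from suprafit import (
    InvalidInputError, SimulationConfig, TitrationDataset,
    WeakSaturationWarning, dimer_speciation, effective_host_concentration,
    fit_titration, hg_1to1_speciation, saturation_guest_design,
    simulate_titration, titration_model, titration_model_coupled,
)


class TestTitrationModel:
    def test_no_guest_returns_free_shift(self):
        assert titration_model(5e-4, 0.0, 1e4, 3.9, 0.05) == pytest.approx(3.9)

    def test_saturation_returns_free_plus_limiting_shift(self):
        val = titration_model(5e-4, 1.0, 1e9, 3.9, 0.05)
        assert val == pytest.approx(3.95, rel=1e-6)

    def test_half_saturation_point_from_exact_quadratic(self):
        # G chosen so [HG] = H/2: shift is exactly halfway to delta_max
        h, k = 5e-4, 1e4
        g_half = 0.5 * h + 0.5 / (k * 0.5)
        assert titration_model(h, g_half, k, 0.0, 0.08) == pytest.approx(
            0.04, rel=1e-9)

    def test_monotone_in_guest(self):
        g = np.linspace(0, 5e-3, 50)
        shifts = titration_model(5e-4, g, 1e4, 3.9, 0.05)
        assert np.all(np.diff(shifts) > 0)

    def test_exact_quadratic_differs_from_dilute_approximation(self):
        # at H_t K_a >> 0.1 host depletion matters: the exact isotherm lags
        h, k, g = 5e-3, 1e4, 2e-3
        exact = titration_model(h, g, k, 0.0, 1.0)
        dilute = k * g / (1 + k * g)
        assert exact < dilute

    def test_coupled_model_reduces_to_flat_when_no_binding(self):
        vals = titration_model_coupled(5e-4, np.linspace(0, 1e-3, 5),
                                       4.1e5, 0.0, 3.9, 0.05)
        np.testing.assert_allclose(vals, 3.9, rtol=1e-12)


class TestSaturationDesign:
    def test_design_inverts_the_binding_quadratic(self):
        h, k = 2.5e-4, 1.3e4
        g = saturation_guest_design(h, k, n_points=15, max_saturation=0.95)
        frac = np.array([hg_1to1_speciation(h, gi, k).complex_conc / h
                         for gi in g])
        np.testing.assert_allclose(frac, np.linspace(0, 0.95, 15), atol=1e-9)


class TestFitTitration:
    def test_noiseless_dimer_host_round_trip(self):
        cfg = SimulationConfig(seed=0, k_assoc=1.3e4, host_total=2.5e-4,
                               shift_sigma_ppm=0.0)
        res = fit_titration(simulate_titration(cfg), stoichiometry="monomer")
        assert res.k_assoc == pytest.approx(1.3e4, rel=1e-4)
        assert res.delta_max[0] == pytest.approx(0.05, rel=1e-4)

    def test_noiseless_monomer_host_round_trip(self):
        cfg = SimulationConfig(seed=0, k_assoc=1.1e3, host_total=5e-4,
                               shift_sigma_ppm=0.0)
        res = fit_titration(simulate_titration(cfg))
        assert res.k_assoc == pytest.approx(1.1e3, rel=1e-4)

    def test_fitted_curve_passes_through_free_shift(self):
        cfg = SimulationConfig(seed=3, k_assoc=1.3e4, host_total=2.5e-4)
        res = fit_titration(simulate_titration(cfg))
        pred0 = titration_model(res.effective_host, 0.0, res.k_assoc,
                                res.delta_free[0], res.delta_max[0])
        assert pred0 == pytest.approx(res.delta_free[0])

    def test_effective_host_conventions(self):
        assert effective_host_concentration(5e-4, "monomer") == 5e-4
        assert effective_host_concentration(5e-4, "dimer") == 2.5e-4
        with_kd = effective_host_concentration(5e-4, "dimer", k_dimer=4.1e5)
        assert with_kd == pytest.approx(dimer_speciation(5e-4, 4.1e5).dimer_conc)
        with pytest.raises(InvalidInputError):
            effective_host_concentration(5e-4, "trimer")

    def test_dimer_mode_fits_at_half_host_concentration(self):
        cfg = SimulationConfig(seed=1, k_assoc=1.3e4, host_total=2.5e-4,
                               shift_sigma_ppm=0.0)
        data = simulate_titration(cfg)
        doubled = TitrationDataset(2 * data.host_total, data.guest_totals,
                                   data.shifts, data.labels)
        res = fit_titration(doubled, stoichiometry="dimer")
        assert res.effective_host == pytest.approx(2.5e-4)
        assert res.k_assoc == pytest.approx(1.3e4, rel=1e-4)

    def test_multi_resonance_shared_k(self):
        cfg = SimulationConfig(seed=5, k_assoc=1.3e4, host_total=2.5e-4,
                               shift_sigma_ppm=0.0)
        base = simulate_titration(cfg)
        shifts = np.column_stack([base.shifts[:, 0],
                                  7.2 - 2.0 * (base.shifts[:, 0] - 3.9)])
        data = TitrationDataset(base.host_total, base.guest_totals, shifts,
                                ("H3", "H5"))
        res = fit_titration(data)
        assert res.k_assoc == pytest.approx(1.3e4, rel=1e-4)
        assert res.delta_max[1] == pytest.approx(-0.10, rel=1e-3)

    def test_per_resonance_mode_agrees_on_clean_data(self):
        cfg = SimulationConfig(seed=5, k_assoc=1.3e4, host_total=2.5e-4,
                               shift_sigma_ppm=0.0)
        base = simulate_titration(cfg)
        shifts = np.column_stack([base.shifts[:, 0], base.shifts[:, 0] + 1.0])
        data = TitrationDataset(base.host_total, base.guest_totals, shifts,
                                ("a", "b"))
        res = fit_titration(data, shared_k=False)
        assert res.k_assoc == pytest.approx(1.3e4, rel=1e-3)

    def test_weak_saturation_warns(self):
        h, k = 5e-4, 1.1e3
        g = saturation_guest_design(h, k, max_saturation=0.95)
        cfg = SimulationConfig(seed=2, k_assoc=k, host_total=h,
                               shift_sigma_ppm=0.0)
        data = simulate_titration(cfg, guest_totals=g[:8])  # stops at ~48%
        with pytest.warns(WeakSaturationWarning):
            res = fit_titration(data)
        assert res.weak_saturation

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_titration(TitrationDataset(
                5e-4, np.linspace(0, 1e-3, 5), np.linspace(0, 0.05, 5)))

    def test_decreasing_guest_rejected(self):
        with pytest.raises(InvalidInputError):
            TitrationDataset(5e-4, np.array([0.0, 2e-4, 1e-4]),
                             np.zeros(3))
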