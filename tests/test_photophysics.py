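import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from suprafit import (
    AnisotropySet, DecayHistogram, IntensityRecord, MultiExpModel,
    InvalidInputError, InvalidModelError,
    anisotropy, average_lifetime, correct_inner_filter, decay_model,
    fit_decay, fractional_contributions, reconvolve, two_state_average,
    simulate_decay, SimulationConfig,
)

positive_amp = st.floats(1e-3, 1e4, allow_nan=False)
positive_tau = st.floats(1e-2, 1e3, allow_nan=False)


@st.composite
def multiexp_models(draw, max_components=3):
    n = draw(st.integers(1, max_components))
    amps = draw(st.lists(positive_amp, min_size=n, max_size=n))
    taus = draw(st.lists(positive_tau, min_size=n, max_size=n, unique=True))
    return MultiExpModel(np.array(amps), np.array(taus))


class TestInnerFilter:
    @pytest.mark.parametrize("intensity,a_ex,a_em,expected", [
        (5.0, 0.0, 0.0, 5.0),
        (1.0, 1.0, 1.0, 10.0),
        (2.0, 0.1, 0.1, 2.0 * 10 ** 0.1),  # = 2.51785...
    ])
    def test_correction_factor(self, intensity, a_ex, a_em, expected):
        rec = IntensityRecord(intensity, a_ex, a_em)
        assert correct_inner_filter(rec) == pytest.approx(expected, rel=1e-12)

    def test_corrected_never_below_observed(self):
        rec = IntensityRecord(3.0, 0.2, 0.05)
        assert correct_inner_filter(rec) >= rec.observed_intensity

    @pytest.mark.parametrize("intensity,a_ex,a_em", [
        (-1.0, 0.1, 0.1), (0.0, 0.1, 0.1), (1.0, -0.1, 0.1), (1.0, 0.1, -0.1),
    ])
    def test_invalid_inputs_rejected(self, intensity, a_ex, a_em):
        with pytest.raises(InvalidInputError):
            correct_inner_filter(IntensityRecord(intensity, a_ex, a_em))


class TestDecayModel:
    @pytest.mark.parametrize("amps,taus,t,expected", [
        ([1.0], [10.0], 0.0, 1.0),
        ([1.0], [10.0], 10.0, np.exp(-1.0)),
        ([1.0, 1.0], [2.0, 4.0], 4.0, np.exp(-2.0) + np.exp(-1.0)),
    ])
    def test_pointwise_values(self, amps, taus, t, expected):
        model = MultiExpModel(np.array(amps), np.array(taus))
        assert decay_model(model, [t])[0] == pytest.approx(expected, rel=1e-12)

    def test_t0_returns_amplitude_sum(self):
        model = MultiExpModel(np.array([2.0, 3.0]), np.array([1.0, 5.0]))
        assert decay_model(model, [0.0])[0] == pytest.approx(5.0)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(InvalidModelError):
            MultiExpModel(np.array([1.0]), np.array([-2.0]))

    def test_negative_time_rejected(self):
        model = MultiExpModel(np.array([1.0]), np.array([1.0]))
        with pytest.raises(InvalidInputError):
            decay_model(model, [-1.0])


class TestAverageLifetimeAndFractions:
    def test_single_component_returns_its_lifetime(self):
        assert average_lifetime(
            MultiExpModel(np.array([3.0]), np.array([5.0]))) == pytest.approx(5.0)

    def test_two_component_value(self):
        model = MultiExpModel(np.array([1.0, 1.0]), np.array([2.0, 4.0]))
        assert average_lifetime(model) == pytest.approx(20.0 / 6.0, rel=1e-12)
        np.testing.assert_allclose(
            fractional_contributions(model), [1.0 / 3.0, 2.0 / 3.0], rtol=1e-12)

    def test_vanishing_component_limit(self):
        model = MultiExpModel(np.array([1.0, 1e-12]), np.array([2.0, 4.0]))
        assert average_lifetime(model) == pytest.approx(2.0, abs=1e-9)

    def test_all_zero_amplitudes_rejected(self):
        model = MultiExpModel(np.array([0.0, 0.0]), np.array([2.0, 4.0]))
        with pytest.raises(InvalidModelError):
            average_lifetime(model)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(model=multiexp_models())
    def test_fractions_normalize_and_lifetime_bounded(self, model):
        f = fractional_contributions(model)
        assert abs(f.sum() - 1.0) < 1e-9
        avg = average_lifetime(model)
        assert model.lifetimes.min() - 1e-12 <= avg <= model.lifetimes.max() + 1e-12


class TestTwoStateAverage:
    @pytest.mark.parametrize("f1,t1,f2,t2,expected", [
        (0.5, 2.0, 0.5, 12.0, 7.0),
        (1.0, 2.3, 0.0, 11.6, 2.3),
        (0.9, 2.3, 0.1, 11.6, 3.23),
    ])
    def test_weighted_mean(self, f1, t1, f2, t2, expected):
        assert two_state_average(f1, t1, f2, t2) == pytest.approx(expected)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            two_state_average(0.5, 2.0, 0.4, 12.0)


class TestAnisotropy:
    def test_fully_depolarized_is_zero(self):
        assert anisotropy(AnisotropySet(2.0, 2.0, 1.5, 1.5)) == pytest.approx(0.0)

    def test_direct_value_with_unit_g(self):
        assert anisotropy(AnisotropySet(2.0, 1.0, 1.0, 1.0)) == pytest.approx(0.25)

    def test_fully_polarized_limit(self):
        assert anisotropy(AnisotropySet(2.0, 1e-12, 1.0, 1.0)) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            anisotropy(AnisotropySet(1.0, 0.0, 1.0, 1.0))


class TestReconvolve:
    def test_delta_irf_reproduces_bare_decay(self):
        times = np.arange(16, dtype=float)
        irf = DecayHistogram(times, np.r_[100.0, np.zeros(15)])
        model = MultiExpModel(np.array([1.0]), np.array([5.0]))
        np.testing.assert_allclose(
            reconvolve(irf, model), decay_model(model, times), rtol=1e-12)

    def test_delta_irf_at_later_channel_shifts_decay(self):
        times = np.arange(16, dtype=float)
        counts = np.zeros(16)
        counts[3] = 50.0
        irf = DecayHistogram(times, counts)
        model = MultiExpModel(np.array([1.0]), np.array([5.0]))
        out = reconvolve(irf, model)
        np.testing.assert_allclose(out[:3], 0.0, atol=1e-15)
        np.testing.assert_allclose(out[3:], decay_model(model, times[:13]), rtol=1e-12)

    def test_two_channel_irf_matches_hand_convolution(self):
        # IRF (1,1,0,0)/2 convolved with exp(-t/2) on a 4-channel grid
        times = np.array([0.0, 1.0, 2.0, 3.0])
        irf = DecayHistogram(times, np.array([1.0, 1.0, 0.0, 0.0]))
        model = MultiExpModel(np.array([1.0]), np.array([2.0]))
        expected = [0.5, 0.8032653299, 0.4872050504, 0.2955048007]
        np.testing.assert_allclose(reconvolve(irf, model), expected, rtol=1e-9)

    def test_zero_scatter_identical_to_scatter_free(self):
        times = np.arange(32, dtype=float)
        irf = DecayHistogram(times, np.exp(-0.5 * (times - 4.0) ** 2))
        base = MultiExpModel(np.array([1.0]), np.array([5.0]))
        with_zero = MultiExpModel(np.array([1.0]), np.array([5.0]),
                                  scatter_fraction=0.0)
        np.testing.assert_array_equal(reconvolve(irf, base),
                                      reconvolve(irf, with_zero))

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(8, dtype=float)
        t2 = np.arange(8, dtype=float) * 2.0
        decay = DecayHistogram(t1, np.ones(8))
        irf = DecayHistogram(t2, np.ones(8))
        with pytest.raises(InvalidInputError):
            fit_decay(decay, irf, n_components=1)


class TestFitDecay:
    def test_noiseless_single_exponential_recovered_exactly(self):
        cfg = SimulationConfig(seed=0, poisson=False, amplitudes=(1.0,),
                               lifetimes=(10.0,))
        decay, irf = simulate_decay(cfg)
        res = fit_decay(decay, irf, n_components=1)
        assert res.model.lifetimes[0] == pytest.approx(10.0, rel=1e-4)

    def test_noiseless_two_component_recovered(self):
        cfg = SimulationConfig(seed=0, poisson=False)
        decay, irf = simulate_decay(cfg)
        res = fit_decay(decay, irf, n_components=2)
        np.testing.assert_allclose(res.model.lifetimes, [2.3, 11.6], rtol=1e-4)

    def test_poisson_two_component_recovered_within_5pct(self):
        cfg = SimulationConfig(seed=7)
        decay, irf = simulate_decay(cfg)
        res = fit_decay(decay, irf, n_components=2)
        np.testing.assert_allclose(res.model.lifetimes, [2.3, 11.6], rtol=0.05)
        assert 0.8 < res.reduced_chi_square < 1.3
        assert np.all(np.diff(res.model.lifetimes) > 0)
        assert abs(res.fractional_contributions.sum() - 1.0) < 1e-9

    def test_overparameterized_fit_is_flagged(self):
        cfg = SimulationConfig(seed=11, amplitudes=(1.0,), lifetimes=(10.0,))
        decay, irf = simulate_decay(cfg)
        res = fit_decay(decay, irf, n_components=2)
        assert res.overparameterized
        # the genuine component still dominates
        assert np.max(res.fractional_contributions) > 0.98

    def test_empty_fit_range_rejected(self):
        cfg = SimulationConfig(seed=0)
        decay, irf = simulate_decay(cfg)
        with pytest.raises(InvalidInputError):
            fit_decay(decay, irf, n_components=1, fit_range=(5, 6))

    def test_invalid_component_count_rejected(self):
        cfg = SimulationConfig(seed=0)
        decay, irf = simulate_decay(cfg)
        with pytest.raises(InvalidInputError):
            fit_decay(decay, irf, n_components=4)
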