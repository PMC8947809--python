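"""Rate schedules, scenarios, balance line, temperature map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiketempering.background import (
    AlphaScenario,
    BackgroundConfig,
    BalanceLine,
    RateSchedule,
    balance_inh,
    balanced_inh_rate,
    rate_at,
    scenario_rates,
    temperature_from_rates,
    temperature_model_sqrt_alpha,
    temperature_weighted,
)


class TestRateSchedule:
    def test_sinusoid_midpoint_and_peak(self):
        s = RateSchedule(kind="sinusoid", nu_min=0.5, nu_max=22.0, f_osc=2.0)
        assert rate_at(s, 0.0) == pytest.approx((22.0 + 0.5) / 2)
        quarter = 1e3 / (4 * 2.0)  # ms
        assert rate_at(s, quarter) == pytest.approx(22.0)
        assert rate_at(s, 3 * quarter) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t=st.floats(0, 1e4),
        f=st.floats(0.1, 50.0),
        lo=st.floats(0, 5),
        span=st.floats(0.1, 20),
    )
    def test_periodicity(self, t, f, lo, span):
        s = RateSchedule(kind="sinusoid", nu_min=lo, nu_max=lo + span, f_osc=f)
        period = 1e3 / f
        assert s(t) == pytest.approx(s(t + period), rel=1e-9, abs=1e-9)

    def test_phase_zero_at_minimum(self):
        s = RateSchedule(kind="sinusoid", nu_min=1.0, nu_max=3.0, f_osc=10.0)
        t = np.linspace(0, 100.0, 2001)
        ph = s.phase(t)
        vals = np.asarray(s(t))
        assert abs(ph[np.argmin(vals)]) % (2 * np.pi) < 0.05 or (
            2 * np.pi - ph[np.argmin(vals)] % (2 * np.pi)
        ) < 0.05
        assert abs(ph[np.argmax(vals)] - np.pi) < 0.05

    def test_negative_time_rejected(self):
        s = RateSchedule(kind="constant", value=1.0)
        with pytest.raises(ValueError):
            s(-1.0)


class TestBalanceLine:
    def test_identity_line(self):
        line = BalanceLine(nu_0=0.0, m=1.0)
        for nu in (0.1, 2.0, 17.3):
            assert balance_inh(line, nu) == pytest.approx(nu)

    def test_reference_line_reproduces_oscillation_endpoints(self):
        # the balanced oscillation pairs 0.25 -> ~0.13 and 10 -> ~10.27 kHz
        line = BalanceLine(nu_0=-0.13, m=1.04, nu_exc_range=(0.1, 30))
        assert balance_inh(line, 0.25) == pytest.approx(0.13, abs=0.005)
        assert balance_inh(line, 10.0) == pytest.approx(10.27, abs=0.005)

    def test_negative_extrapolation_clips_to_zero(self):
        line = BalanceLine(nu_0=-1.0, m=1.0, nu_exc_range=(0.0, 30))
        assert balance_inh(line, 0.5) == 0.0


class TestScenarios:
    def test_mu_unbalanced_alpha_one(self):
        scen = AlphaScenario.from_preset("mu_unbalanced")
        assert scenario_rates(scen, 1.0) == (5.0, 5.0)

    def test_low_excitation_alpha_two(self):
        scen = AlphaScenario.from_preset("low_excitation")
        assert scenario_rates(scen, 2.0) == (2.0, 10.0)

    def test_zero_alpha_zero_offsets(self):
        scen = AlphaScenario(
            name="x", nu_exc_1=3.0, nu_exc_0=0.0, nu_inh_1=2.0, nu_inh_0=0.0,
            w_exc=0.5, w_inh=0.5, w_stim_max=30.0, alpha_range=(0.0, 5.0),
        )
        assert scenario_rates(scen, 0.0) == (0.0, 0.0)

    def test_mean_balanced_scenario_requires_alpha_at_least_one(self):
        scen = AlphaScenario.from_preset("mu_balanced_55")
        with pytest.raises(ValueError, match="alpha"):
            scenario_rates(scen, 0.5)
        # inside the declared range but below the balance-validity bound
        scen_wide = AlphaScenario(
            name="b", nu_exc_1=scen.nu_exc_1, nu_exc_0=scen.nu_exc_0,
            nu_inh_1=scen.nu_inh_1, nu_inh_0=scen.nu_inh_0,
            w_exc=scen.w_exc, w_inh=scen.w_inh, w_stim_max=scen.w_stim_max,
            alpha_range=(0.5, 5.0), balance_u_hat=-55.0,
        )
        with pytest.raises(ValueError, match="alpha >= 1"):
            scenario_rates(scen_wide, 0.5)

    def test_mean_balance_coefficients_follow_conductance_balance(self, coba_params):
        # nu_inh(alpha) from the conductance-balance relation at -55 mV
        # matches the shipped linear coefficients
        scen = AlphaScenario.from_preset("mu_balanced_55")
        p = coba_params
        for alpha in (1.0, 2.5, 5.0):
            nu_exc = 5.0 * alpha
            expected = balanced_inh_rate(
                nu_exc, -55.0, g_l=p.g_l, E_l=p.E_l, E_exc=p.E_exc, E_inh=p.E_inh,
                tau_exc=p.tau_exc, tau_inh=p.tau_inh, w_exc=scen.w_exc,
                w_inh=scen.w_inh,
            )
            assert scenario_rates(scen, alpha)[1] == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_alpha_rejected(self):
        scen = AlphaScenario.from_preset("mu_unbalanced")
        with pytest.raises(ValueError, match="alpha"):
            scenario_rates(scen, 7.0)


class TestTemperature:
    def test_reference_rates_give_unit_temperature(self):
        assert temperature_from_rates(2.0, 2.0, (2.0, 2.0)) == 1.0

    def test_quadrupled_rates_double_temperature(self):
        assert temperature_from_rates(8.0, 8.0, (2.0, 2.0)) == pytest.approx(2.0)

    def test_oscillation_gives_square_root_of_sine_course(self):
        sched = RateSchedule(kind="sinusoid", nu_min=0.25, nu_max=10.0, f_osc=1.0)
        line = BalanceLine(nu_0=-0.13, m=1.04, nu_exc_range=(0.1, 30))
        t = np.linspace(0, 1000.0, 101)
        nu_e = np.asarray(sched(t))
        nu_i = np.asarray(balance_inh(line, nu_e))
        T = temperature_from_rates(nu_e, nu_i, (2.0, 2.0))
        np.testing.assert_allclose(T, np.sqrt((nu_e + nu_i) / 4.0), rtol=1e-12)
        assert np.all(np.diff(T[:25]) > 0)  # rising quarter-cycle

    def test_rescaling_rates_and_weights_preserves_temperature(self):
        # nu -> s*nu with w -> w/sqrt(s) leaves T unchanged
        T0 = temperature_weighted(4.0, 4.0, 0.5, 0.5, (2.0, 2.0), (0.5, 0.5))
        for s in (0.5, 2.0, 4.0):
            T = temperature_weighted(
                4.0 * s, 4.0, 0.5 / np.sqrt(s), 0.5, (2.0, 2.0), (0.5, 0.5)
            )
            assert T == pytest.approx(T0, rel=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            temperature_from_rates(-1.0, 2.0, (2.0, 2.0))


class TestSqrtAlphaFit:
    def test_exact_square_root_points_recovered(self):
        a = np.array([0.5, 1, 2, 3, 5])
        c, resid = temperature_model_sqrt_alpha(a, np.sqrt(a))
        assert c == pytest.approx(1.0, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_robust_fit_resists_outlier(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        T = np.sqrt(a)
        T[2] += 3.0  # gross outlier
        # brute-force reference: minimize squared error on clean points only
        c_clean = float(
            np.dot(np.sqrt(np.delete(a, 2)), np.delete(T, 2))
            / np.dot(np.sqrt(np.delete(a, 2)), np.sqrt(np.delete(a, 2)))
        )
        c_plain, _ = temperature_model_sqrt_alpha(a, T)
        c_robust, _ = temperature_model_sqrt_alpha(a, T, robust=True)
        assert abs(c_robust - c_clean) < abs(c_plain - c_clean)
        assert c_robust == pytest.approx(1.0, abs=0.12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            temperature_model_sqrt_alpha([1.0], [1.0])


def test_scenario_background_rate_arrays_follow_alpha_schedule():
    scen = AlphaScenario.from_preset("mu_unbalanced")
    sched = RateSchedule(kind="sinusoid", nu_min=0.5, nu_max=5.0, f_osc=10.0)
    bg = BackgroundConfig.from_scenario(scen, sched)
    nu_e, nu_i = bg.rate_arrays(n_steps=2000, dt=0.05)
    alpha = sched.sample(2000, 0.05)
    np.testing.assert_allclose(nu_e, 5.0 * alpha, rtol=1e-12)
    np.testing.assert_allclose(nu_i, 5.0 * alpha, rtol=1e-12)
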