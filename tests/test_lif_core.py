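"""Simulator correctness: closed-form limits, moment analytics, contracts."""

import dataclasses

import numpy as np
import pytest

from spiketempering.background import BackgroundConfig
from spiketempering.lif_core import (
    Network,
    NeuronParams,
    SpikeRaster,
    Synapse,
    free_membrane_moments_coba,
    free_membrane_moments_cuba,
    simulate,
)


def _single_neuron(params, background, **kw):
    return Network(params=params, n_neurons=1, background=background, **kw)


def quiet_bg(kind):
    if kind == "current":
        return BackgroundConfig.constant(0.0, 0.0, 0.5, -0.5)
    return BackgroundConfig.constant(0.0, 0.0, 0.5, 0.5)


class TestDeterministicLimits:
    def test_quiescent_neuron_stays_at_leak_potential(self, cuba_params):
        net = _single_neuron(cuba_params, quiet_bg("current"))
        run = simulate(net, duration=500.0, seed=0, record_u=True)
        assert run.raster.times.size == 0
        np.testing.assert_allclose(run.u[:, 0], cuba_params.E_l, atol=1e-9)

    def test_suprathreshold_isi_matches_rc_charging_time(self, cuba_params):
        # ISI = tau_ref + tau_m * ln((u_inf - v_reset)/(u_inf - v_th))
        I_in = 6.0  # nA
        p = cuba_params
        u_inf = p.E_l + I_in * 1000.0 / p.g_l
        t_charge = p.tau_m * np.log((u_inf - p.v_reset) / (u_inf - p.v_th))
        expected_isi = p.tau_ref + t_charge
        net = _single_neuron(p, quiet_bg("current"), I_in=I_in)
        run = simulate(net, duration=2_000.0, dt=0.1, seed=0)
        isis = np.diff(run.raster.times)
        assert isis.size > 10
        assert np.all(np.abs(isis - expected_isi) <= 0.1 + 1e-9)

    def test_activation_in_deterministic_limit_is_ref_over_isi(self, cuba_params):
        p = cuba_params
        I_in = 4.0
        u_inf = p.E_l + I_in * 1000.0 / p.g_l
        isi = p.tau_ref + p.tau_m * np.log((u_inf - p.v_reset) / (u_inf - p.v_th))
        net = _single_neuron(p, quiet_bg("current"), I_in=I_in)
        run = simulate(net, duration=20_000.0, seed=3)
        p_on = run.raster.counts()[0] * p.tau_ref / 20_000.0
        assert p_on == pytest.approx(p.tau_ref / isi, rel=0.02)


class TestContracts:
    def test_identical_seed_gives_identical_raster(self, cuba_params, ref_background):
        net = _single_neuron(cuba_params, ref_background, I_in=1.0)
        a = simulate(net, duration=2_000.0, seed=42).raster
        b = simulate(net, duration=2_000.0, seed=42).raster
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.ids, b.ids)
        c = simulate(net, duration=2_000.0, seed=43).raster
        assert c.times.size != a.times.size or not np.array_equal(c.times, a.times)

    def test_refractory_period_is_respected(self, cuba_params, ref_background):
        net = _single_neuron(cuba_params, ref_background, I_in=2.0)
        run = simulate(net, duration=10_000.0, seed=7)
        run.raster.validate(tau_ref=cuba_params.tau_ref)

    def test_non_multiple_delay_is_rejected(self, coba_params):
        net = Network(
            params=coba_params,
            n_neurons=2,
            background=quiet_bg("conductance"),
            synapses=[Synapse(pre=0, post=1, weight=1.0, delay=0.13)],
        )
        with pytest.raises(ValueError, match="multiple of dt"):
            simulate(net, duration=10.0, dt=0.05, seed=0)

    def test_coarse_dt_warns(self, cuba_params, ref_background):
        net = _single_neuron(cuba_params, ref_background)
        with pytest.warns(UserWarning, match="coarse"):
            simulate(net, duration=12.0, dt=3.0, seed=0)

    def test_raster_tsv_roundtrip(self, tmp_path, cuba_params, ref_background):
        net = _single_neuron(cuba_params, ref_background, I_in=1.5)
        raster = simulate(net, duration=1_000.0, seed=1).raster
        path = tmp_path / "raster.tsv"
        raster.to_tsv(path)
        back = SpikeRaster.from_tsv(path)
        np.testing.assert_allclose(back.times, raster.times, atol=1e-6)
        np.testing.assert_array_equal(back.ids, raster.ids)
        assert back.n_neurons == raster.n_neurons

    def test_halving_dt_leaves_firing_rate_within_sampling_error(
        self, cuba_params, ref_background
    ):
        net = _single_neuron(cuba_params, ref_background, I_in=0.0)
        rates = []
        for dt in (0.1, 0.05):
            run = simulate(net, duration=60_000.0, dt=dt, seed=9)
            rates.append(run.raster.counts()[0] / 60.0)  # Hz
        assert abs(rates[0] - rates[1]) / rates[0] < 0.05


class TestCubaMoments:
    def test_no_input_gives_leak_potential_and_zero_variance(self, cuba_params):
        mu, s2 = free_membrane_moments_cuba(cuba_params, quiet_bg("current"), 0.0)
        assert mu == cuba_params.E_l
        assert s2 == 0.0

    def test_closed_form_matches_threshold_free_simulation(
        self, cuba_params, ref_background
    ):
        mu, s2 = free_membrane_moments_cuba(cuba_params, ref_background, 0.0)
        free = dataclasses.replace(cuba_params, v_th=1e6)
        net = _single_neuron(free, ref_background)
        run = simulate(net, duration=200_000.0, seed=3, record_u=True)
        u = run.u[10_000:, 0]  # drop transient
        assert u.mean() == pytest.approx(mu, abs=0.05)
        assert u.var() == pytest.approx(s2, rel=0.02)

    def test_balanced_input_cancels_in_mean_but_adds_to_variance(self, cuba_params):
        rates = [1.0, 2.0, 4.0, 8.0]
        mus, s2s = zip(
            *(
                free_membrane_moments_cuba(
                    cuba_params, BackgroundConfig.constant(nu, nu, 0.5, -0.5), 0.0
                )
                for nu in rates
            )
        )
        assert np.ptp(mus) < 1e-12
        assert np.all(np.diff(s2s) > 0)

    def test_conductance_params_rejected(self, coba_params):
        with pytest.raises(ValueError, match="current-based"):
            free_membrane_moments_cuba(coba_params, quiet_bg("conductance"), 0.0)


class TestCobaMoments:
    def test_leak_only_limit(self, coba_params):
        mu, s2, tau = free_membrane_moments_coba(coba_params, quiet_bg("conductance"))
        assert mu == coba_params.E_l
        assert s2 == 0.0
        assert tau == pytest.approx(coba_params.tau_m)

    def test_closed_form_matches_threshold_free_simulation(self, coba_params):
        bg = BackgroundConfig.constant(5.0, 5.0, 0.5, 0.5)
        mu, s2, _ = free_membrane_moments_coba(coba_params, bg)
        free = dataclasses.replace(coba_params, v_th=1e6)
        net = _single_neuron(free, bg)
        run = simulate(net, duration=150_000.0, dt=0.05, seed=5, record_u=True)
        u = run.u[20_000:, 0]
        assert u.mean() == pytest.approx(mu, abs=0.15)
        assert u.var() == pytest.approx(s2, rel=0.05)

    def test_high_rate_variance_falls_off_with_total_rate(self, coba_params):
        # high-conductance limit: variance proportional to 1/(sum nu tau)
        rates = np.array([50.0, 100.0, 200.0, 400.0])
        s2 = np.array(
            [
                free_membrane_moments_coba(
                    coba_params, BackgroundConfig.constant(nu, nu, 0.5, 0.5)
                )[1]
                for nu in rates
            ]
        )
        assert np.all(np.diff(s2) < 0)
        # ratio approaches the 1/nu scaling
        assert s2[-2] / s2[-1] == pytest.approx(2.0, rel=0.15)

    def test_variance_monotonic_for_cuba_but_not_coba(self, cuba_params, coba_params):
        rates = np.linspace(0.5, 30.0, 40)
        s2_cuba = np.array(
            [
                free_membrane_moments_cuba(
                    cuba_params, BackgroundConfig.constant(nu, nu, 0.5, -0.5), 0.0
                )[1]
                for nu in rates
            ]
        )
        s2_coba = np.array(
            [
                free_membrane_moments_coba(
                    coba_params, BackgroundConfig.constant(nu, nu, 2.5, 2.5)
                )[1]
                for nu in rates
            ]
        )
        assert np.all(np.diff(s2_cuba) > 0)
        d = np.diff(s2_coba)
        assert np.any(d > 0) and np.any(d < 0)  # rises then falls

    def test_negative_rates_rejected(self, coba_params):
        with pytest.raises(ValueError):
            free_membrane_moments_coba(
                coba_params, BackgroundConfig.constant(5.0, 5.0, -0.5, 0.5)
            )
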