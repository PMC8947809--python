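"""State readout and sampling metrics."""

import numpy as np
import pytest

from spiketempering.boltzmann import DiscreteDistribution
from spiketempering.cli_io import make_binary_fixture
from spiketempering.lif_core import SpikeRaster
from spiketempering.readout_metrics import (
    AssemblyActivity,
    autocorrelation,
    detect_mixed_states,
    detect_solutions,
    empirical_distribution,
    isl,
    mode_durations,
    states_from_raster,
)


def _raster(times, ids, duration=500.0, n=4):
    return SpikeRaster(times=np.asarray(times, float), ids=np.asarray(ids),
                       duration=duration, dt=0.1, n_neurons=n)


class TestStatesFromRaster:
    def test_refractory_readout_covers_exactly_tau_ref(self):
        tr = states_from_raster(_raster([100.0], [0]), kind="refractory",
                                tau_ref=10.0, grid_dt=1.0)
        on = np.nonzero(tr.states[:, 0])[0]
        np.testing.assert_array_equal(on, np.arange(100, 110))

    def test_empty_raster_gives_all_zero_trace(self):
        tr = states_from_raster(_raster([], []), kind="window", window_ms=10.0)
        assert tr.states.sum() == 0

    def test_window_readout_includes_spike_time_and_window(self):
        tr = states_from_raster(_raster([100.0], [2]), kind="window",
                                window_ms=10.0, grid_dt=1.0)
        on = np.nonzero(tr.states[:, 2])[0]
        assert on.min() == 100 and on.max() == 110

    def test_spike_times_recoverable_from_rising_edges(self):
        times = [50.0, 80.0, 200.0]
        tr = states_from_raster(_raster(times, [1, 1, 1]), kind="refractory",
                                tau_ref=10.0, grid_dt=1.0)
        z = tr.states[:, 1].astype(int)
        edges = np.nonzero(np.diff(z) == 1)[0] + 1
        np.testing.assert_allclose(tr.times[edges], times)

    def test_integer_encoding_uses_neuron_zero_as_lsb(self):
        tr = states_from_raster(_raster([100.0, 100.0], [0, 2]),
                                kind="window", window_ms=5.0, grid_dt=1.0)
        assert tr.as_ints()[101] == 1 + 4


class TestEmpiricalDistribution:
    def test_constant_state_gives_point_mass(self):
        tr = states_from_raster(_raster([], [], duration=50.0, n=2),
                                kind="window", window_ms=10.0)
        d = empirical_distribution(tr)
        np.testing.assert_allclose(d.p, [1, 0, 0, 0])

    def test_restriction_to_mode_states(self):
        tr = states_from_raster(
            _raster([10.0, 100.0, 100.0], [0, 0, 1], duration=200.0, n=2),
            kind="window", window_ms=10.0,
        )
        d = empirical_distribution(tr, restrict_to=np.array([1, 2]))
        assert d.p.sum() == pytest.approx(1.0)
        assert d.p[0] > 0  # only-neuron-0 states observed

    def test_empty_restriction_rejected(self):
        tr = states_from_raster(_raster([], [], n=2), kind="window",
                                window_ms=10.0)
        with pytest.raises(ValueError, match="no usable"):
            empirical_distribution(tr, restrict_to=np.array([3]))


class TestModeDurations:
    def test_alternating_labels_have_unit_durations(self):
        out = mode_durations(list("ABABABAB"), readout_dt=1.0)
        np.testing.assert_allclose(out["durations"], 1.0)

    def test_constant_labels_flagged_as_censored(self):
        out = mode_durations(["A"] * 10)
        assert out["censored_only"] and np.isnan(out["mean"])

    def test_final_censored_interval_excluded(self):
        out = mode_durations(list("AAABBBCCCC"), readout_dt=2.0)
        np.testing.assert_allclose(out["durations"], [6.0, 6.0])


class TestIsl:
    def test_identical_single_sample(self):
        x = np.array([[1, 0, 1, 1, 0, 0, 1, 0]])
        assert isl(x, x, gamma=0.95) == pytest.approx(8 * np.log(0.95))

    def test_complement_single_sample(self):
        x = np.array([[1, 0, 1, 1, 0, 0, 1, 0]])
        assert isl(x, 1 - x, gamma=0.95) == pytest.approx(8 * np.log(0.05))

    def test_log_space_matches_direct_product_evaluation(self, rng):
        gamma = 0.95
        G = rng.integers(0, 2, size=(12, 10))
        Y = rng.integers(0, 2, size=(7, 10))
        direct = []
        for y in Y:
            terms = [
                np.prod([gamma if y[j] == x[j] else 1 - gamma
                         for j in range(10)])
                for x in G
            ]
            direct.append(np.log(np.mean(terms)))
        assert isl(G, Y, gamma) == pytest.approx(np.mean(direct), abs=1e-10)

    def test_diverse_samples_beat_single_mode_repetition(self):
        protos, train, test = make_binary_fixture(
            n_modes=4, d=8, flip_p=0.05, n_samples=60, seed=3
        )
        single = np.tile(train[:1], (60, 1))
        assert isl(train, test) > isl(single, test)

    def test_gamma_domain_checked(self):
        x = np.zeros((2, 4))
        with pytest.raises(ValueError, match="gamma"):
            isl(x, x, gamma=0.3)


class TestAutocorrelation:
    def test_lag_zero_is_one_and_white_noise_decorrelates(self, rng):
        x = rng.normal(size=20_000)
        out = autocorrelation(x, max_lag=50)
        assert out["r"][0] == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(out["r"][1:])) < 0.05

    def test_slow_signal_has_larger_area_than_fast(self, rng):
        t = np.arange(4000)
        slow = np.sin(2 * np.pi * t / 800) + 0.1 * rng.normal(size=t.size)
        fast = np.sin(2 * np.pi * t / 40) + 0.1 * rng.normal(size=t.size)
        a_slow = autocorrelation(slow, 100)["auc"]
        a_fast = autocorrelation(fast, 100)["auc"]
        assert a_slow > a_fast


def _activity(fractions):
    fr = np.asarray(fractions, dtype=float)
    members = tuple(np.array([i]) for i in range(fr.shape[1]))
    return AssemblyActivity(times=np.arange(fr.shape[0], dtype=float),
                            fractions=fr, members=members)


class TestDetectors:
    linkage = [[0, 3], [1, 4], [2, 5]]

    def test_silence_yields_no_solution(self):
        act = _activity(np.zeros((5, 6)))
        assert np.all(detect_solutions(act, self.linkage) == -1)

    def test_exclusive_linked_pair_detected(self):
        fr = np.zeros((3, 6))
        fr[1, [1, 4]] = 1.0
        labels = detect_solutions(_activity(fr), self.linkage)
        assert labels[1] == 1 and labels[0] == -1

    def test_exact_threshold_tie_counts_as_no_solution(self):
        fr = np.zeros((1, 6))
        fr[0, [0, 3]] = 0.5  # exactly at threshold, strict > required
        assert detect_solutions(_activity(fr), self.linkage)[0] == -1

    def test_extra_active_assembly_invalidates_solution(self):
        fr = np.zeros((1, 6))
        fr[0, [0, 3, 1]] = 1.0
        assert detect_solutions(_activity(fr), self.linkage)[0] == -1

    def test_mixed_state_definition(self):
        act = _activity([[1.0, 0.0], [0.25, 0.25], [0.2, 0.25]])
        out = detect_mixed_states(act, threshold=0.2)
        np.testing.assert_array_equal(out["mixed"], [False, True, False])

    def test_mixed_state_phase_halves(self):
        fr = np.tile([[0.3, 0.3]], (100, 1))
        fr[50:] = 0.0  # mixed only in first half
        phases = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        out = detect_mixed_states(_activity(fr), phases=phases)
        assert out["p_first_half"] == 1.0
        assert out["p_second_half"] == 0.0

    def test_overlapping_assemblies_rejected(self):
        raster = _raster([10.0], [0], n=4)
        with pytest.raises(ValueError, match="overlap"):
            AssemblyActivity.from_raster(raster, [np.array([0, 1]),
                                                  np.array([1, 2])])
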