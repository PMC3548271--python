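"""Firing-rate clamp: control law, schedulers, correlations, closed loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroloop.clamp import (ClampParams, compute_pairwise_correlations,
                             compute_tuning_factors, estimate_population_rate,
                             feedback_time_constant, generate_poisson_protocol,
                             run_clamp, schedule_stimuli, update_voltage)
from neuroloop.core import SpikeEvent


class TestUpdateVoltage:
    P = ClampParams(alpha=0.002, f_star=3.0, v_max=2.0)

    def test_fixed_point_at_setpoint(self):
        assert update_voltage(1.0, 3.0, self.P) == pytest.approx(1.0)

    def test_above_setpoint_decreases(self):
        # f_avg twice the setpoint: v <- v - alpha * v * 1
        assert update_voltage(1.0, 6.0, self.P) == pytest.approx(0.998)

    def test_silent_network_increases(self):
        assert update_voltage(1.0, 0.0, self.P) == pytest.approx(1.002)

    def test_clipped_at_v_max(self):
        p = ClampParams(alpha=0.5, f_star=3.0, v_max=1.0)
        assert update_voltage(0.9999, 0.0, p) <= 1.0

    @given(st.floats(1e-6, 1.0), st.floats(0.0, 50.0), st.floats(0.1, 20.0),
           st.floats(1e-4, 0.5))
    @settings(max_examples=200, derandomize=True)
    def test_sign_property(self, v, f_avg, f_star, alpha):
        """v strictly decreases when the network fires above the setpoint and
        strictly increases below it (before clipping)."""
        p = ClampParams(alpha=alpha, f_star=f_star, v_max=np.inf)
        out = update_voltage(v, f_avg, p)
        if f_avg > f_star:
            assert out < v
        elif f_avg < f_star:
            assert out > v
        else:
            assert out == pytest.approx(v)


class TestFeedbackTimeConstant:
    def test_reference_settings_give_five_seconds(self):
        assert feedback_time_constant(0.010, 0.002) == 5.0

    def test_unit_gain_identity(self):
        assert feedback_time_constant(0.123, 1.0) == 0.123

    def test_direct_evaluation(self):
        assert feedback_time_constant(0.150, 0.05) == pytest.approx(3.0)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            feedback_time_constant(0.01, 0.0)


class TestPopulationRate:
    def test_arithmetic(self):
        fs = 25_000.0
        spikes = [SpikeEvent(time=int(t * fs), channel=0)
                  for t in (0.1, 0.5, 0.9, 1.2, 1.5, 1.9)]
        rate = estimate_population_rate(spikes, now=int(2.0 * fs), window=2.0,
                                        n_units=2, sample_rate=fs)
        assert rate == pytest.approx(1.5)

    def test_empty_list(self):
        assert estimate_population_rate([], now=1000, window=2.0, n_units=3) == 0.0

    def test_poisson_unbiased(self):
        rng = np.random.default_rng(0)
        fs, r, n_units, window = 25_000.0, 4.0, 5, 2.0
        est = []
        for _ in range(300):
            n = rng.poisson(r * n_units * window)
            times = np.sort(rng.integers(0, int(window * fs), size=n)) + 1
            est.append(estimate_population_rate(times, now=int(window * fs),
                                                window=window, n_units=n_units,
                                                sample_rate=fs))
        se = r / np.sqrt(n_units * window * r * 300)
        assert abs(np.mean(est) - r) < 2 * se


class TestTuningFactors:
    def test_equal_counts_give_unity(self):
        np.testing.assert_allclose(compute_tuning_factors(np.full(10, 7)), 1.0)

    def test_stated_example(self):
        # counts [1, 3] -> 1/(1+c) = [1/2, 1/4] -> mean-normalized [4/3, 2/3]
        np.testing.assert_allclose(compute_tuning_factors(np.array([1, 3])),
                                   [4 / 3, 2 / 3])

    def test_all_zero_counts_degenerate(self):
        np.testing.assert_allclose(compute_tuning_factors(np.zeros(5)), 1.0)

    def test_scale_invariance_of_normalization(self):
        c = np.array([0, 2, 5, 9])
        f = compute_tuning_factors(c)
        assert f.mean() == pytest.approx(1.0)


class TestScheduler:
    def test_aggregate_rate_and_counts(self):
        cmds = schedule_stimuli(list(range(10)), 1.0, 100.0, rng_seed=0)
        assert len(cmds) == 1000
        dt = np.diff([c.time for c in cmds]) / 25_000.0
        np.testing.assert_allclose(dt, 0.1)
        counts = np.bincount([c.channel for c in cmds], minlength=10)
        np.testing.assert_array_equal(counts, 100)

    def test_each_block_is_same_permutation(self):
        cmds = schedule_stimuli(list(range(5)), 2.0, 10.0, rng_seed=1)
        blocks = np.array([c.channel for c in cmds]).reshape(-1, 5)
        assert np.all(blocks == blocks[0])
        assert sorted(blocks[0]) == list(range(5))

    def test_deterministic_under_seed(self):
        a = schedule_stimuli(list(range(10)), 1.0, 50.0, rng_seed=42)
        b = schedule_stimuli(list(range(10)), 1.0, 50.0, rng_seed=42)
        assert a == b


class TestPoissonProtocol:
    def test_repeated_trials_identical(self):
        trials = generate_poisson_protocol(10.0, 1.0, 100, mode="repeated",
                                           rng_seed=0)
        assert len(trials) == 100
        first = [(c.time, c.channel) for c in trials[0]]
        assert all([(c.time, c.channel) for c in t] == first for t in trials)

    def test_fresh_mean_count(self):
        trials = generate_poisson_protocol(10.0, 1.0, 1000, mode="fresh",
                                           rng_seed=1)
        counts = [len(t) for t in trials]
        se = np.sqrt(10.0 / 1000)
        assert abs(np.mean(counts) - 10.0) < 2 * se

    def test_intervals_exponential_ks(self):
        from scipy import stats
        trials = generate_poisson_protocol(10.0, 10.0, 50, mode="fresh",
                                           rng_seed=2)
        gaps = np.concatenate([
            np.diff([c.time for c in t]) / 25_000.0 for t in trials if len(t) > 1])
        _, p = stats.kstest(gaps, "expon", args=(0, 0.1))
        assert p > 0.01


class TestPairwiseCorrelations:
    def test_identical_trains_peak_one_at_zero(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 60, 400))
        lags, corr = compute_pairwise_correlations([t, t.copy()], bin=0.010,
                                                   max_lag=0.1)
        assert corr[lags == 0][0] == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(20):
            a = np.sort(rng.uniform(0, 120, 600))
            b = np.sort(rng.uniform(0, 120, 600))
            lags, corr = compute_pairwise_correlations([a, b], bin=0.010,
                                                       max_lag=0.05,
                                                       duration=120.0)
            vals.append(corr[lags == 0][0])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_shifted_train_peaks_at_lag(self):
        t = np.sort(np.random.default_rng(2).uniform(0, 60, 500))
        shifted = t + 0.020  # +2 bins at 10 ms
        lags, corr = compute_pairwise_correlations([t, shifted], bin=0.010,
                                                   max_lag=0.1, duration=60.2)
        assert lags[np.argmax(corr)] == pytest.approx(0.020)


class _DeterministicPlant:
    """Linear dose-response plant: per-unit rate = gain * pulse amplitude."""

    def __init__(self, n_units=30, gain_per_pulse=0.5, fs=25_000.0):
        self.n_units = n_units
        self.sample_rate = fs
        self.stim_electrodes = list(range(10))
        self.gain = gain_per_pulse
        self._acc = 0.0
        self.t = 0.0

    def step(self, commands, dt):
        spikes = []
        for c in commands:
            self._acc += self.gain * c.amplitude * self.n_units
            k = int(self._acc)
            self._acc -= k
            for i in range(k):
                spikes.append(SpikeEvent(time=c.time + 1 + i, channel=0,
                                         unit=i % self.n_units))
        self.t += dt
        return spikes


class TestRunClamp:
    def test_converges_on_deterministic_plant(self):
        """With a linear plant the loop settles at f* within ~3 tau_FB and
        holds within 5%."""
        p = ClampParams()
        tau = feedback_time_constant(p.dT, p.alpha)
        traj = run_clamp(_DeterministicPlant(), p, duration=8 * tau, seed=0)
        settle = traj.t > 3 * tau + p.rate_window
        assert np.all(np.abs(traj.f_avg[settle] - p.f_star) / p.f_star < 0.05)

    def test_deviation_decays_with_tau_fb(self):
        """Linearized loop: deviations decay with time constant ~ dT/alpha."""
        p = ClampParams()
        tau = feedback_time_constant(p.dT, p.alpha)
        traj = run_clamp(_DeterministicPlant(), p, duration=6 * tau, seed=0)
        dev = np.abs(traj.f_avg - p.f_star)
        # fit exponential between 1 tau and 3 tau after the rate window fills
        t0, t1 = p.rate_window + tau, p.rate_window + 3 * tau
        i0, i1 = np.searchsorted(traj.t, [t0, t1])
        fitted_tau = (t1 - t0) / np.log(dev[i0] / dev[i1])
        assert fitted_tau == pytest.approx(tau, rel=0.2)

    def test_zero_gain_keeps_voltage_constant(self):
        traj = run_clamp(_DeterministicPlant(),
                         ClampParams(alpha=0.0, v_init=0.4),
                         duration=5.0, seed=0)
        np.testing.assert_allclose(traj.mean_v, 0.4)

    def test_null_controller_gives_spontaneous_rate(self):
        from neuroloop.plant import CultureParams, make_culture
        plant = make_culture(CultureParams(baseline_rate=2.0, burst_rate=0.0,
                                           drift_sigma=0.0), seed=3)
        p = ClampParams(v_init=0.0)
        traj = run_clamp(plant, p, duration=60.0, open_loop_after=0.0, seed=3)
        assert len(traj.commands) > 0
        assert all(c.amplitude == 0.0 for c in traj.commands)
        mean_rate = traj.f_avg[traj.t > 2.0].mean()
        assert mean_rate == pytest.approx(2.0, rel=0.1)

    def test_plant_fault_returns_partial_trajectory(self):
        class FaultyPlant(_DeterministicPlant):
            def step(self, commands, dt):
                if self.t > 1.0:
                    raise RuntimeError("electrode dropout")
                return super().step(commands, dt)

        traj = run_clamp(FaultyPlant(), ClampParams(), duration=10.0, seed=0)
        assert traj.aborted
        assert "electrode dropout" in traj.diagnostic
        assert 0 < len(traj.t) < 1000
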