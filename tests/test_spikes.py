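import numpy as np
import pytest

from poretrace.geometry import PoreTrajectory
from poretrace.spikes import (
    Spike,
    baseline_subtract,
    classify_decay,
    pore_features,
    spike_features,
)


def make_spike(currents, dt=1e-4, sd=0.0):
    t = np.arange(len(currents)) * dt
    return Spike(t, np.asarray(currents, dtype=float), baseline_sd=sd)


class TestBaselineSubtract:
    def test_constant_trace_goes_to_zero(self):
        t = np.arange(100) * 1e-4
        sp = baseline_subtract(t, np.full(100, 3e-12), (0.0, 2e-3))
        assert np.allclose(sp.currents, 0.0)
        assert sp.baseline_sd == pytest.approx(0.0, abs=1e-20)

    def test_additive_offset_removed_exactly(self):
        t = np.arange(200) * 1e-4
        shape = np.exp(-((t - 1e-2) / 2e-3) ** 2) * 1e-10
        sp = baseline_subtract(t, shape + 5e-12, (0.0, 2e-3))
        # window mean of the pure spike shape is ~0 out there
        assert np.allclose(sp.currents, shape, atol=1e-15)

    def test_noise_sd_estimated(self):
        rng = np.random.default_rng(5)
        t = np.arange(2000) * 1e-4
        noise = rng.normal(0.0, 1e-13, t.size)
        sp = baseline_subtract(t, noise, (0.0, 0.1))
        assert sp.baseline_sd == pytest.approx(1e-13, rel=0.2)

    def test_empty_window_rejected(self):
        t = np.arange(10) * 1e-4
        with pytest.raises(ValueError):
            baseline_subtract(t, np.zeros(10), (5.0, 6.0))


class TestSpikeShape:
    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 1e-4, 3e-4])
        with pytest.raises(ValueError, match="uniform"):
            Spike(t, np.zeros(3))

    def test_linear_ramp_rise_time(self):
        # ramp 0 -> I_max over 1 ms then instant drop: t_rise = 0.9 ms
        ramp = np.concatenate([np.linspace(0.0, 1e-10, 11), [0.0]])
        sp = make_spike(ramp)
        f = spike_features(sp)
        assert f.t_rise == pytest.approx(0.9e-3, rel=1e-9)
        assert f.i_max == pytest.approx(1e-10)

    def test_triangle_peak_position_and_charge(self):
        tri = np.concatenate([np.linspace(0, 1e-10, 11),
                              np.linspace(1e-10, 0, 11)[1:]])
        sp = make_spike(tri)
        f = spike_features(sp)
        assert f.t_max == pytest.approx(10 * 1e-4)
        assert f.q == pytest.approx(np.trapezoid(tri, sp.times))

    def test_rise_time_invariant_to_rescaling(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 6e-3, 1e-4)
        y = 1e-10 / (1 + np.exp(-(t - 2e-3) / 3e-4))
        a = spike_features(make_spike(y)).t_rise
        b = spike_features(make_spike(1e3 * y)).t_rise
        assert a == pytest.approx(b, rel=1e-12)


class TestClassifyDecay:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 8e-3, 1e-4)
        y = 1e-10 * np.exp(-t / 1e-3)
        tau, r2, nd = classify_decay(make_spike(y))
        assert tau == pytest.approx(1e-3, rel=1e-2)
        assert r2 >= 0.999
        assert nd is True

    def test_double_exponential_flagged(self):
        t = np.arange(0, 10e-3, 1e-4)
        y = 0.5e-10 * np.exp(-t / 0.3e-3) + 0.5e-10 * np.exp(-t / 3e-3)
        tau, r2, nd = classify_decay(make_spike(y), r2_threshold=0.98)
        single = classify_decay(make_spike(1e-10 * np.exp(-t / 1e-3)),
                                r2_threshold=0.98)
        assert r2 < single[1]
        assert nd is False

    def test_noisy_exponential_still_single(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 8e-3, 1e-4)
        y = 1e-10 * np.exp(-t / 1e-3)
        y = y + rng.normal(0, 0.01 * y.max(), y.size)
        y[y < 1e-14] = 1e-14
        tau, r2, nd = classify_decay(make_spike(y), r2_threshold=0.95)
        assert nd is True

    def test_short_falling_portion_rejected(self):
        y = np.array([0.0, 1e-10, 0.0])
        with pytest.raises(ValueError):
            classify_decay(make_spike(y))


class TestRiseTimeTracksExpansion:
    def test_t_rise_approximates_t_expa_at_low_depletion(
            self, geometry_150, transport, c0_150):
        # with little content released during the expansion phase the
        # current rise mirrors the pore expansion (within 30 %)
        from poretrace.quasi_steady import quasi_steady_current
        from poretrace.synthetic import logistic_trajectory
        traj = logistic_trajectory(10e-9, 1e-3, 3e-4, 6e-3)
        tr = quasi_steady_current(geometry_150, transport, c0_150, traj, 6e-3)
        f = spike_features(Spike(tr.times, tr.currents))
        _, te = pore_features(traj)
        assert f.t_rise == pytest.approx(te, rel=0.30)


class TestPoreFeatures:
    def test_linear_ramp_then_plateau(self):
        # 0 -> 20 nm over 2 ms then constant: t_expa = 1.8 ms
        t = np.concatenate([np.linspace(0, 2e-3, 21),
                            np.linspace(2.1e-3, 4e-3, 20)])
        r = np.concatenate([np.linspace(0, 20e-9, 21), np.full(20, 20e-9)])
        rpm, te = pore_features(PoreTrajectory(t, r))
        assert rpm == pytest.approx(20e-9)
        assert te == pytest.approx(1.8e-3, rel=1e-9)

    def test_constant_trajectory_zero_expansion(self):
        traj = PoreTrajectory(np.array([0.0, 1e-3]), np.array([1e-8, 1e-8]))
        rpm, te = pore_features(traj)
        assert te == 0.0

    def test_logistic_closed_form(self):
        # t_expa = 2 s ln 19 for a logistic with steepness s
        s = 3e-4
        t = np.arange(0, 8e-3, 1e-5)
        r = 30e-9 / (1 + np.exp(-(t - 2e-3) / s))
        rpm, te = pore_features(PoreTrajectory(t, r))
        assert te == pytest.approx(2 * s * np.log(19.0), rel=1e-3)

    def test_scaling_invariance(self):
        t = np.arange(0, 6e-3, 1e-4)
        r = 30e-9 / (1 + np.exp(-(t - 2e-3) / 3e-4))
        _, a = pore_features(PoreTrajectory(t, r))
        _, b = pore_features(PoreTrajectory(t, 5 * r))
        assert a == pytest.approx(b, rel=1e-12)
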