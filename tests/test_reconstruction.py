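"""Closed-loop tests of the sequential pore-radius inverse.

Ground truth is always known by construction: spikes are generated by a
forward model from a prescribed trajectory, then inverted.
"""

import numpy as np
import pytest

from poretrace import (
    PoreTrajectory,
    TransportParams,
    VesicleGeometry,
    initial_concentration,
)
from poretrace.quasi_steady import QuasiSteadyStepper, quasi_steady_current
from poretrace.reconstruction import (
    FLAG_CLIPPED,
    FLAG_UNIDENTIFIABLE,
    ReconstructionConfig,
    fit_step,
    quasi_steady_reconstruct,
    reconstruct_pore_trajectory,
)
from poretrace.spikes import Spike, pore_features
from poretrace.synthetic import SynthSpec, synth_spike


def qs_spike(geometry, transport, q, traj, t_end):
    c0 = initial_concentration(q, geometry.vesicle_radius, transport)
    trace = quasi_steady_current(geometry, transport, c0, traj, t_end)
    return Spike(trace.times, trace.currents)


def logistic(r_max, t50=1e-3, s=3e-4, t_end=6e-3, dt=1e-4):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return PoreTrajectory(t, r_max / (1.0 + np.exp(-(t - t50) / s)))


class TestFitStep:
    def setup_method(self):
        self.geo = VesicleGeometry(vesicle_radius=150e-9)
        self.tp = TransportParams()
        c0 = initial_concentration(1e-12, 150e-9, self.tp)
        self.backend = QuasiSteadyStepper(self.geo, self.tp, c0)

    def test_fixed_point_returns_previous_radius(self):
        state = self.backend.initial_state()
        r_prev = 1e-8
        s = state.copy()
        target = self.backend.advance(s, r_prev, r_prev, 1e-4, 10)
        r, flag, res = fit_step(self.backend, state, r_prev, target,
                                (1e-11, 1.2e-7), 1e-11, 1e-4, 10)
        assert flag == "ok"
        assert r == pytest.approx(r_prev, abs=5e-11)

    def test_single_step_inversion(self):
        state = self.backend.initial_state()
        r_true = 2.3e-8
        s = state.copy()
        target = self.backend.advance(s, 1e-8, r_true, 1e-4, 10)
        r, flag, _ = fit_step(self.backend, state, 1e-8, target,
                              (1e-11, 1.2e-7), 1e-11, 1e-4, 10)
        assert flag == "ok"
        assert r == pytest.approx(r_true, rel=0.02)

    def test_unreachable_target_clipped(self):
        state = self.backend.initial_state()
        s = state.copy()
        i_ub = self.backend.advance(s, 1e-8, 1.2e-7, 1e-4, 10)
        r, flag, _ = fit_step(self.backend, state, 1e-8, 2 * i_ub,
                              (1e-11, 1.2e-7), 1e-11, 1e-4, 10)
        assert flag == FLAG_CLIPPED
        assert r == 1.2e-7

    def test_subnoise_target_flagged_unidentifiable(self):
        state = self.backend.initial_state()
        r, flag, _ = fit_step(self.backend, state, 1e-8, 1e-14,
                              (1e-11, 1.2e-7), 1e-11, 1e-4, 10,
                              noise_floor=1e-13)
        assert flag == FLAG_UNIDENTIFIABLE
        assert r == 1e-8


class TestClosedLoopRecovery:
    @pytest.mark.parametrize("r_ves,ratio", [
        (75e-9, 0.05), (75e-9, 0.3),
        (150e-9, 0.1), (150e-9, 0.3),
        (300e-9, 0.05), (300e-9, 0.1),
    ])
    def test_noiseless_recovery_within_5_percent(self, r_ves, ratio):
        geo = VesicleGeometry(vesicle_radius=r_ves)
        tp = TransportParams()
        truth = logistic(ratio * r_ves)
        q = 1e-12 * (r_ves / 150e-9) ** 3  # fixed lumen concentration
        spike = qs_spike(geo, tp, q, truth, 6e-3)
        res = reconstruct_pore_trajectory(spike, r_ves, q)
        # identifiable window: released fraction still below 90 %
        nF = tp.nF
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (spike.currents[1:] + spike.currents[:-1])
            * np.diff(spike.times))])
        window = (cum / nF) < 0.9 * (q / nF)
        rec, tru = res.trajectory.radii, truth.radii
        rel = np.abs(rec[1:] - tru[1:]) / tru[1:]
        assert np.max(rel[window[1:]]) <= 0.05

    def test_noisy_recovery_of_features(self):
        spec = SynthSpec(seed=3, noise_sd_frac=0.02)
        spike, truth, _ = synth_spike(spec)
        res = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        rpm_t, te_t = pore_features(truth)
        assert res.r_p_max == pytest.approx(rpm_t, rel=0.10)
        assert res.t_expa == pytest.approx(te_t, rel=0.20)

    def test_zero_spike_unidentifiable(self):
        t = np.arange(0.0, 2e-3, 1e-4)
        spike = Spike(t, np.zeros(t.size))
        res = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        assert all(f == FLAG_UNIDENTIFIABLE for f in res.flags[1:])
        # the pore stays at the (effectively closed) seed radius
        assert np.all(res.trajectory.radii <= 1e-10 + 1e-15)

    def test_sequential_causality_on_truncation(self):
        geo = VesicleGeometry(vesicle_radius=150e-9)
        tp = TransportParams()
        spike = qs_spike(geo, tp, 1e-12, logistic(30e-9), 6e-3)
        full = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        half = Spike(spike.times[:31], spike.currents[:31])
        part = reconstruct_pore_trajectory(half, 150e-9, 1e-12)
        assert np.array_equal(part.trajectory.radii,
                              full.trajectory.radii[:31])

    def test_determinism(self):
        spec = SynthSpec(seed=9, noise_sd_frac=0.02)
        spike, _, _ = synth_spike(spec)
        a = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        b = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        assert np.array_equal(a.trajectory.radii, b.trajectory.radii)

    def test_residuals_within_noise(self):
        spec = SynthSpec(seed=4, noise_sd_frac=0.02)
        spike, _, clean = synth_spike(spec)
        res = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        ok = np.array([f == "ok" for f in res.flags])
        bound = np.maximum(3 * spike.baseline_sd,
                           0.01 * np.abs(spike.currents) + 1e-14)
        assert np.all(res.residuals[ok] <= bound[ok])


class TestQuasiSteadyReconstruct:
    def test_static_pore_self_inversion(self):
        geo = VesicleGeometry(vesicle_radius=150e-9)
        tp = TransportParams()
        traj = PoreTrajectory(np.array([0.0, 6e-3]), np.array([1e-8, 1e-8]))
        spike = qs_spike(geo, tp, 1e-12, traj, 6e-3)
        rec = quasi_steady_reconstruct(spike, 150e-9, 1e-12)
        # pre-depletion: while < 90 % of the content has left
        from poretrace.quasi_steady import diffusive_resistance
        tau = geo.lumen_volume() * diffusive_resistance(1e-8, 5e-9, tp)
        m = (1 - np.exp(-spike.times / tau)) < 0.9
        rel = np.abs(rec.radii[m] - 1e-8) / 1e-8
        assert rel.max() <= 0.01

    def test_zero_sample_flagged(self):
        geo = VesicleGeometry(vesicle_radius=150e-9)
        t = np.arange(0.0, 1e-3, 1e-4)
        i = np.full(t.size, 1e-11)
        i[3] = 0.0
        spike = Spike(t, i)
        traj, flags = quasi_steady_reconstruct(spike, 150e-9, 1e-12,
                                               with_flags=True)
        assert flags[3] == "low"
        assert traj.radii[3] == 0.0

    def test_fesa_agrees_with_closed_form_oracle(self):
        # two independent inversion routes on the same synthetic spike:
        # sequential Nelder-Mead vs per-sample bisection
        geo = VesicleGeometry(vesicle_radius=150e-9)
        tp = TransportParams()
        truth = logistic(30e-9)
        spike = qs_spike(geo, tp, 1e-12, truth, 6e-3)
        fesa = reconstruct_pore_trajectory(spike, 150e-9, 1e-12)
        oracle = quasi_steady_reconstruct(spike, 150e-9, 1e-12)
        a = fesa.trajectory.radii / np.mean(fesa.trajectory.radii[-10:])
        b = oracle.radii / np.mean(oracle.radii[-10:])
        t = spike.times
        expansion = (t > 0) & (t <= 2.2e-3)  # 5-95 % rise of the truth
        rms = np.sqrt(np.mean((a[expansion] - b[expansion]) ** 2))
        assert rms <= 0.10
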