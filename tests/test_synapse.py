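"""Tsodyks–Markram dynamics, steady states, the control synapse and fitting."""

import numpy as np
import pytest

import hd2speed as h
from hd2speed._kernels import tm_ode_rk4
from hd2speed.synapse import FITTED_TAU_D, FITTED_TAU_F, FITTED_U


@pytest.fixture
def params():
    return h.TMParams()


def periodic_train(n, isi, t0=10.0):
    return h.SpikeTrain(times=t0 + np.arange(n) * isi, refractory=0.0)


class TestRelaxAndSpike:
    def test_zero_dt_identity(self, params):
        s = h.TMState(x=0.5, u=0.3, g=0.2)
        out = h.tm_relax(s, 0.0, params)
        assert (out.x, out.u, out.g) == (s.x, s.u, s.g)

    def test_long_relaxation_fixed_point(self, params):
        s = h.TMState(x=0.1, u=0.9, g=5.0)
        out = h.tm_relax(s, 1e7, params)
        assert out.x == pytest.approx(1.0)
        assert out.u == pytest.approx(0.0, abs=1e-12)
        assert out.g == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_closed_form(self, params):
        s = h.TMState(x=0.72, u=0.0, g=0.0)
        out = h.tm_relax(s, 100.0, params)
        assert out.x == pytest.approx(1 - 0.28 * np.exp(-100 / 270), rel=1e-12)
        assert out.x == pytest.approx(0.8067, abs=2e-4)

    def test_spike_from_rest(self, params):
        s, release = h.tm_spike(h.TMState(), params)
        assert release == pytest.approx(params.U)
        assert s.u == pytest.approx(params.U)
        assert s.x == pytest.approx(1 - params.U)
        assert s.g == pytest.approx(params.weight * params.U)

    def test_depression_only_limit(self):
        # facilitation off: u decays instantly, so u+ = U on every spike
        p = h.TMParams(tau_f=1e-9)
        rel = h.tm_releases(np.arange(10) * 100.0, p)
        st = h.TMState()
        for k in range(10):
            st = h.tm_relax(st, 100.0, p)
            st, r = h.tm_spike(st, p)
            assert st.u == pytest.approx(p.U)

    def test_second_pulse_ratio_10hz(self, params):
        rel = h.tm_releases(np.array([0.0, 100.0]), params)
        assert rel[1] / rel[0] == pytest.approx(0.854, abs=1e-3)

    def test_negative_dt_rejected(self, params):
        with pytest.raises(ValueError):
            h.tm_relax(h.TMState(), -1.0, params)


class TestEventDrivenVsODE:
    def test_matches_rk4_oracle(self, params, rng):
        # event-driven exact updates vs brute-force fixed-step integration
        for _ in range(5):
            times = np.round(np.sort(rng.uniform(5, 400, 12)) / 0.01) * 0.01
            times = times[np.concatenate(([True], np.diff(times) >= 4.0))]
            xs, us, gs = tm_ode_rk4(times, 420.0, 0.01, params.tau_d, params.tau_f,
                                    params.tau_g, params.U, params.weight)
            st = h.TMState()
            tcur, isp = 0.0, 0
            for ci in range(0, 42000, 997):
                tt = ci * 0.01
                while isp < len(times) and times[isp] <= tt + 1e-12:
                    st = h.tm_relax(st, times[isp] - tcur, params)
                    tcur = times[isp]
                    st, _ = h.tm_spike(st, params)
                    isp += 1
                probe = h.tm_relax(st, tt - tcur, params)
                assert abs(probe.x - xs[ci]) < 1e-6
                assert abs(probe.u - us[ci]) < 1e-6
                assert abs(probe.g - gs[ci]) < 1e-6

    def test_state_bounds_on_random_trains(self, params, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0, 1000, rng.integers(1, 60)))
            st = h.TMState()
            tcur = 0.0
            for t in times:
                st = h.tm_relax(st, t - tcur, params)
                tcur = t
                st, rel = h.tm_spike(st, params)
                assert 0.0 <= st.x <= 1.0
                assert params.U <= st.u <= 1.0  # u+ >= U always
                assert rel >= 0.0


class TestConductanceTrain:
    def test_empty_train(self, params):
        g, amps = h.conductance_train(h.SpikeTrain(times=np.empty(0)), params, dt=1.0,
                                      duration=100.0)
        assert np.allclose(g, 0.0)
        assert len(amps.amps) == 0

    def test_single_spike(self, params):
        g, amps = h.conductance_train(h.SpikeTrain(times=np.array([10.0])), params, dt=1.0)
        peak = params.weight * params.U
        assert g.max() == pytest.approx(peak, rel=1e-9)
        k = np.argmax(g)
        assert g[k + 10] == pytest.approx(peak * np.exp(-10 / params.tau_g), rel=1e-9)

    def test_10hz_train_monotone_depression(self, params):
        _, amps = h.conductance_train(periodic_train(10, 100.0), params, dt=1.0)
        norm = amps.normalized
        assert norm[0] == 1.0
        assert np.all(np.diff(norm) < 0)
        # approaches the periodic steady state from above
        _, _, rel_ss = h.tm_steady_state(10.0, params)
        assert norm[-1] > rel_ss / params.U * 0.999

    def test_depression_dominant_regime_sweep(self):
        # tau_f <= tau_d/5 keeps 10 Hz responses monotone nonincreasing
        for tau_d in (100.0, 300.0, 600.0):
            p = h.TMParams(tau_d=tau_d, tau_f=tau_d / 5, U=0.3)
            _, amps = h.conductance_train(periodic_train(10, 100.0), p, dt=1.0)
            assert np.all(np.diff(amps.normalized) <= 1e-12)


class TestSteadyState:
    def test_low_rate_limit(self, params):
        x, u, rel = h.tm_steady_state(1e-4, params)
        assert x == pytest.approx(1.0)
        assert rel == pytest.approx(params.U)

    def test_release_decreases_with_rate(self, params):
        rates = np.array([1.0, 5.0, 10.0, 20.0, 40.0])
        rels = [h.tm_steady_state(r, params)[2] for r in rates]
        assert np.all(np.diff(rels) < 0)

    def test_40hz_depresses_more_than_10hz(self, params):
        # steady-state normalized response ordering matches stimulation frequency
        rel10 = h.tm_steady_state(10.0, params)[2]
        rel40 = h.tm_steady_state(40.0, params)[2]
        assert rel40 < rel10

    def test_consistent_with_long_simulation(self, params):
        _, amps = h.conductance_train(periodic_train(100, 100.0), params, dt=1.0)
        _, _, rel_ss = h.tm_steady_state(10.0, params)
        assert amps.amps[-1] / params.weight == pytest.approx(rel_ss, abs=1e-9)

    def test_invalid_rate(self, params):
        with pytest.raises(ValueError):
            h.tm_steady_state(0.0, params)


class TestExpSynapse:
    def test_history_independent_jumps(self):
        st = h.SpikeTrain(times=np.array([10.0, 15.0, 100.0]), refractory=0.0)
        g = h.exp_synapse(st, weight=2.0, tau_g=10.0, dt=0.5)
        # jump size at each spike equals the weight regardless of ISI
        for t_sp in st.times:
            k = int(round(t_sp / 0.5))
            assert g[k] - (g[k - 1] * np.exp(-0.5 / 10.0)) == pytest.approx(2.0, rel=1e-6)

    def test_empty(self):
        g = h.exp_synapse(h.SpikeTrain(times=np.empty(0)), 1.0, 10.0, 1.0, duration=50.0)
        assert np.allclose(g, 0.0)

    def test_tm_limit_equivalence(self):
        # with instant recovery and no facilitation, TM == exponential synapse
        p = h.TMParams(tau_d=1e-6, tau_f=1e-6, tau_g=10.0, U=0.3, weight=2.0)
        st = periodic_train(5, 30.0)
        g_tm, _ = h.conductance_train(st, p, dt=1.0, duration=300.0)
        g_exp = h.exp_synapse(st, weight=2.0 * 0.3, tau_g=10.0, dt=1.0, duration=300.0)
        assert np.allclose(g_tm, g_exp, atol=1e-9)


class TestFitTM:
    def test_recovers_grid_point_parameters(self):
        truth = h.TMParams(tau_d=270.0, tau_f=40.0, U=0.28, weight=1.0)
        rel = h.tm_releases(np.arange(10) * 100.0, truth)
        best, loss = h.fit_tm(h.PulseAmplitudes(amps=rel, isi=100.0))
        assert (best.tau_d, best.tau_f, best.U) == (270.0, 40.0, 0.28)
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_flat_train_no_depression(self):
        best, _ = h.fit_tm(h.PulseAmplitudes(amps=np.ones(10), isi=100.0))
        rel = h.tm_releases(np.arange(10) * 100.0, best)
        depression_index = 1 - rel[-1] / rel[0]
        assert depression_index < 0.05

    def test_weight_recovered_from_first_amplitude(self):
        truth = h.TMParams(tau_d=270.0, tau_f=40.0, U=0.28, weight=3.5)
        rel = truth.weight * h.tm_releases(np.arange(8) * 100.0, truth)
        best, _ = h.fit_tm(h.PulseAmplitudes(amps=rel, isi=100.0))
        assert best.weight == pytest.approx(3.5, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            h.fit_tm(h.PulseAmplitudes(amps=np.array([1.0]), isi=100.0))
        with pytest.raises(ValueError):
            h.fit_tm(h.PulseAmplitudes(amps=np.ones(5), isi=100.0),
                     tau_d_grid=np.array([]))


class TestParamValidation:
    def test_bad_params(self):
        with pytest.raises(ValueError):
            h.TMParams(U=0.0)
        with pytest.raises(ValueError):
            h.TMParams(tau_d=-1.0)
        with pytest.raises(ValueError):
            h.TMState(x=1.5)
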