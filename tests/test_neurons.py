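"""Unit and property tests for the LIF/SFA discrete-time dynamics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnl2l import (AdaptationParams, NetworkState, NeuronParams, WeightSet,
                    network_step, simulate)
from snnl2l.neurons import (membrane_step, spike_and_refractory,
                            spikes_to_events, synaptic_current, threshold_step)

from conftest import make_toy_network


def _silent_weights(n, n_in):
    return WeightSet(w_in=np.zeros((n, n_in)), w_rec=np.zeros((n, n)),
                     w_out=np.zeros((1, n)), w0=1.0)


class TestMembrane:
    def test_resting_fixed_point(self):
        p = NeuronParams()
        v = membrane_step(np.zeros((1, 3)), np.zeros((1, 3)), p, np.zeros((1, 3)))
        assert np.all(v == 0.0)

    @pytest.mark.parametrize("v0,z,expected", [
        (20.0, 0.0, 20.0 * np.exp(-1 / 20)),          # pure decay
        (31.0, 1.0, 31.0 * np.exp(-1 / 20) - 30.0),   # subtractive reset
    ])
    def test_decay_and_reset(self, v0, z, expected):
        p = NeuronParams(tau_m=20.0, v_th=30.0)
        v = membrane_step(np.array([[v0]]), np.zeros((1, 1)), p, np.array([[z]]))
        assert v[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_membrane_aborts(self):
        p = NeuronParams()
        with pytest.raises(FloatingPointError):
            membrane_step(np.array([[np.inf]]), np.zeros((1, 1)), p,
                          np.zeros((1, 1)))

    def test_exponential_decay_oracle_thousand_trajectories(self):
        """Zero input, no spikes: V(t) = V(0) * alpha^t to 1e-12."""
        n, T = 1000, 60
        g = np.random.default_rng(0)
        v0 = g.uniform(-20.0, 25.0, (1, n))
        p = NeuronParams(tau_m=20.0, v_th=30.0)
        w = _silent_weights(n, 1)
        state = NetworkState.zeros(1, n, 1)
        state.v[:] = v0
        rec = simulate(w, p, AdaptationParams(), np.zeros((T, 1, 1)), state=state)
        expected = v0[None] * p.alpha ** np.arange(T)[:, None, None]
        assert rec.z.sum() == 0
        np.testing.assert_allclose(rec.v, expected, atol=1e-12, rtol=1e-12)


class TestThresholdAdaptation:
    def test_resting(self):
        a, A = threshold_step(np.zeros(1), np.zeros(1), AdaptationParams(beta=1.6), 30.0)
        assert a[0] == 0.0 and A[0] == 30.0

    def test_geometric_decay(self):
        ad = AdaptationParams(beta=1.6, tau_a=100.0)
        a, _ = threshold_step(np.ones(1), np.zeros(1), ad, 30.0)
        assert a[0] == pytest.approx(np.exp(-1 / 100), rel=1e-12)

    def test_spike_increment(self):
        ad = AdaptationParams(beta=1.6, tau_a=1000.0)
        a, _ = threshold_step(np.zeros(1), np.ones(1), ad, 30.0)
        assert a[0] == pytest.approx(1 - np.exp(-1e-3), rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.booleans(), min_size=1, max_size=80),
           st.floats(min_value=5.0, max_value=2000.0))
    def test_closed_form_spike_sum(self, spikes, tau_a):
        """a(T) equals sum over spike times of (1-rho) rho^(T-1-s)."""
        ad = AdaptationParams(beta=1.0, tau_a=tau_a)
        a = np.zeros(1)
        for z in spikes:
            a, _ = threshold_step(a, np.array([float(z)]), ad, 30.0)
        rho = ad.rho
        T = len(spikes)
        expected = sum((1 - rho) * rho ** (T - 1 - s)
                       for s, z in enumerate(spikes) if z)
        assert a[0] == pytest.approx(expected, abs=1e-12)


class TestSpikeRefractory:
    def test_threshold_is_strict(self):
        p = NeuronParams(tau_ref=5.0)
        z, _ = spike_and_refractory(np.array([30.0]), np.array([30.0]),
                                    np.array([0]), p)
        assert z[0] == 0.0

    def test_spike_sets_countdown(self):
        p = NeuronParams(tau_ref=5.0)
        z, r = spike_and_refractory(np.array([31.0]), np.array([30.0]),
                                    np.array([0]), p)
        assert z[0] == 1.0 and r[0] == 5

    def test_refractory_gates_spike(self):
        p = NeuronParams(tau_ref=5.0)
        z, r = spike_and_refractory(np.array([40.0]), np.array([30.0]),
                                    np.array([2]), p)
        assert z[0] == 0.0 and r[0] == 1

    def test_spacing_on_generated_rasters(self):
        """No two spikes of a neuron closer than tau_ref/delta_t steps."""
        w, neuron, adapt = make_toy_network(seed=7, n=8, n_in=4, delays=False)
        g = np.random.default_rng(1)
        x = (g.random((400, 2, 4)) < 0.6).astype(float)
        rec = simulate(w, neuron, adapt, x)
        assert rec.z.sum() > 10  # the check must exercise actual spikes
        for b in range(2):
            for j in range(8):
                t_spk = np.flatnonzero(rec.z[:, b, j])
                if len(t_spk) > 1:
                    assert np.diff(t_spk).min() >= neuron.n_ref_steps


class TestSynapticCurrent:
    def test_empty_buffers_give_zero(self):
        w = WeightSet(w_in=np.ones((3, 2)), w_rec=np.ones((3, 3)),
                      w_out=np.zeros((1, 3)), w0=1.0)
        state = NetworkState.zeros(1, 3, 2)
        assert np.all(synaptic_current(state, w) == 0.0)

    def test_single_delayed_spike(self):
        w = WeightSet(w_in=np.array([[2.5, 0.0]]), w_rec=np.zeros((1, 1)),
                      w_out=np.zeros((1, 1)), w0=1.0, d_in=np.array([[2, 1]]))
        state = NetworkState.zeros(1, 1, 2, max_delay_in=2)
        state.x_buf[1, 0, 0] = 1.0  # input spike two steps ago
        assert synaptic_current(state, w)[0, 0] == 2.5

    def test_two_delays_sum(self):
        w = WeightSet(w_in=np.array([[0.7, 1.3]]), w_rec=np.zeros((1, 1)),
                      w_out=np.zeros((1, 1)), w0=1.0, d_in=np.array([[1, 3]]))
        state = NetworkState.zeros(1, 1, 2, max_delay_in=3)
        state.x_buf[0, 0, 0] = 1.0
        state.x_buf[2, 0, 1] = 1.0
        assert synaptic_current(state, w)[0, 0] == pytest.approx(2.0)

    def test_delay_beyond_buffer_is_config_error(self):
        w = WeightSet(w_in=np.ones((1, 1)), w_rec=np.zeros((1, 1)),
                      w_out=np.zeros((1, 1)), w0=1.0, d_in=np.array([[4]]))
        state = NetworkState.zeros(1, 1, 1, max_delay_in=2)
        with pytest.raises(ValueError):
            synaptic_current(state, w)


class TestNetworkStep:
    def test_silent_network_stays_silent(self):
        w = _silent_weights(1, 1)
        state = NetworkState.zeros(1, 1, 1)
        p, ad = NeuronParams(), AdaptationParams()
        for _ in range(50):
            state, z = network_step(state, np.zeros((1, 1)), w, p, ad)
            assert z[0, 0] == 0.0 and state.v[0, 0] == 0.0

    def test_input_width_mismatch(self):
        w = _silent_weights(2, 3)
        state = NetworkState.zeros(1, 2, 3)
        with pytest.raises(ValueError):
            network_step(state, np.zeros((1, 2)), w, NeuronParams(),
                         AdaptationParams())

    def test_matches_simulate_bit_exactly(self):
        """Step-by-step and full-history paths implement the same recursion."""
        w, neuron, adapt = make_toy_network(seed=3)
        g = np.random.default_rng(5)
        x = (g.random((60, 2, 2)) < 0.5).astype(float)
        rec = simulate(w, neuron, adapt, x)
        d_in, d_rec = w.delay_arrays()
        state = NetworkState.zeros(2, 3, 2, int(d_in.max()), int(d_rec.max()))
        for t in range(60):
            state, z = network_step(state, x[t], w, neuron, adapt)
            np.testing.assert_array_equal(z, rec.z[t])
        np.testing.assert_allclose(state.v, rec.final_state.v, rtol=1e-12)
        np.testing.assert_allclose(state.a, rec.final_state.a, rtol=1e-12)

    def test_constant_drive_periodic_spiking(self):
        """Suprathreshold constant current: ISIs settle to the period of an
        independent scalar reference of the same affine recursion."""
        p = NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0)
        w = _silent_weights(1, 1)
        drive = 45.0
        T = 600
        rec = simulate(w, p, AdaptationParams(),
                       np.zeros((T, 1, 1)),
                       extra_drive=np.full((T, 1, 1), drive))
        isis = np.diff(np.flatnonzero(rec.z[:, 0, 0]))
        assert len(isis) > 3 and len(set(isis[1:])) == 1

        alpha = float(p.alpha)
        v = 0.0
        refrac = 0
        ref_spikes = []
        for t in range(T):
            z = 1.0 if (refrac == 0 and v > 30.0) else 0.0
            if z:
                ref_spikes.append(t)
                refrac = 5
            else:
                refrac = max(refrac - 1, 0)
            v = alpha * v + (1 - alpha) * drive - 30.0 * z
        np.testing.assert_array_equal(np.flatnonzero(rec.z[:, 0, 0]),
                                      np.array(ref_spikes))

    def test_sfa_lengthens_interspike_intervals(self):
        p = NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0)
        w = _silent_weights(1, 1)
        ad = AdaptationParams(beta=10.0, tau_a=600.0)
        T = 2000
        rec = simulate(w, p, ad, np.zeros((T, 1, 1)),
                       extra_drive=np.full((T, 1, 1), 50.0))
        isis = np.diff(np.flatnonzero(rec.z[:, 0, 0]))
        assert len(isis) >= 5
        # intervals lengthen toward a limit (integer dithering aside)
        assert isis[0] == isis.min()
        assert np.all(np.diff(isis[:4]) >= 0)
        assert isis[:3].mean() < isis[-3:].mean()

    def test_beta_zero_reduces_to_plain_lif(self):
        w, neuron, _ = make_toy_network(seed=11, delays=False)
        g = np.random.default_rng(2)
        x = (g.random((200, 1, 2)) < 0.5).astype(float)
        sfa_off = AdaptationParams(beta=np.zeros(3), tau_a=np.array([5., 50., 500.]))
        plain = AdaptationParams(beta=0.0, tau_a=1000.0)
        z1 = simulate(w, neuron, sfa_off, x).z
        z2 = simulate(w, neuron, plain, x).z
        np.testing.assert_array_equal(z1, z2)

    def test_time_rescaling_subthreshold(self):
        """Halving delta_t reproduces the coarse-grid membrane trajectory on
        a piecewise-constant subthreshold drive (exponential integrator)."""
        w = _silent_weights(1, 1)
        g = np.random.default_rng(3)
        blocks = g.uniform(-5.0, 5.0, 50)
        coarse_p = NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0, delta_t=1.0)
        fine_p = NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0, delta_t=0.5)
        coarse = simulate(w, coarse_p, AdaptationParams(),
                          np.zeros((50, 1, 1)),
                          extra_drive=blocks[:, None, None])
        fine = simulate(w, fine_p, AdaptationParams(delta_t=0.5),
                        np.zeros((100, 1, 1)),
                        extra_drive=np.repeat(blocks, 2)[:, None, None])
        np.testing.assert_allclose(fine.v[::2, 0, 0], coarse.v[:, 0, 0],
                                   atol=1e-10)


def test_event_list_export():
    z = np.zeros((5, 3))
    z[1, 2] = z[4, 0] = 1
    ev = spikes_to_events(z)
    np.testing.assert_array_equal(ev, [[1.0, 2.0], [4.0, 0.0]])


def test_param_invariants_enforced():
    with pytest.raises(ValueError):
        NeuronParams(tau_m=-1.0)
    with pytest.raises(ValueError):
        AdaptationParams(beta=-0.1)
    with pytest.raises(ValueError):
        AdaptationParams(tau_a=0.0)
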