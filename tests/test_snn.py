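"""Neuron/synapse dynamics, mismatch sampling, calibration, DPI characterisation."""

import numpy as np
import pandas as pd
import pytest

from hfosnn.adm import SpikeTrain
from hfosnn.snn import (
    CalibrationError,
    NeuronParams,
    SNNConfig,
    SNNState,
    SynapseParams,
    calibrate_threshold,
    dpi_bandpass_response,
    dpi_frequency_response,
    regular_train_counts,
    run_network,
    sample_network,
    simulate_neuron,
    step,
)

DT = 1e-4


def make_train(times, polarity=1, duration=1.0):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(times, np.full(times.size, polarity, dtype=np.int8),
                      duration_s=duration)


class TestSampleNetwork:
    def test_no_mismatch_degenerate_ranges_identical_neurons(self, nominal_synapse):
        neuron = NeuronParams(v_thresh=5.0)
        cfg = SNNConfig(n_neurons=16, mismatch_cv=0.0,
                        tau_exc_range=(4e-3, 4e-3), tau_inh_range=(5e-4, 5e-4))
        table = sample_network(cfg, nominal_synapse, neuron)
        assert (table.nunique() == 1).all()

    def test_mean_tau_mem_close_to_nominal(self, nominal_synapse):
        neuron = NeuronParams(v_thresh=5.0)
        cfg = SNNConfig(n_neurons=256, mismatch_cv=0.2, seed=4)
        table = sample_network(cfg, nominal_synapse, neuron)
        se = 0.2 * 15.2e-3 / np.sqrt(256)
        assert abs(table["tau_mem"].mean() - 15.2e-3) < 3 * se

    def test_mismatch_respects_truncation(self, nominal_synapse):
        neuron = NeuronParams(v_thresh=5.0)
        cfg = SNNConfig(n_neurons=256, mismatch_cv=0.2, seed=1)
        table = sample_network(cfg, nominal_synapse, neuron)
        factors = table["tau_mem"] / 15.2e-3
        assert factors.min() >= 1 - 3 * 0.2 - 1e-12
        assert factors.max() <= 1 + 3 * 0.2 + 1e-12

    def test_determinism(self, nominal_synapse):
        neuron = NeuronParams(v_thresh=5.0)
        cfg = SNNConfig(n_neurons=32, seed=9)
        a = sample_network(cfg, nominal_synapse, neuron)
        b = sample_network(cfg, nominal_synapse, neuron)
        pd.testing.assert_frame_equal(a, b)

    def test_requires_calibrated_threshold(self, nominal_synapse, nominal_neuron):
        with pytest.raises(ValueError, match="calibrate"):
            sample_network(SNNConfig(n_neurons=4), nominal_synapse, nominal_neuron)


class TestDynamics:
    def test_membrane_leak_matches_closed_form(self):
        neuron = NeuronParams(v_thresh=1e9)
        table = pd.DataFrame({
            "tau_mem": [neuron.tau_mem], "tau_ahp": [neuron.tau_ahp],
            "w_ahp": [0.0], "v_thresh": [1e9], "v_reset": [0.0],
            "tau_exc": [4.5e-3], "tau_inh": [1e-3], "w_exc": [1.0], "w_inh": [1.0],
        })
        state = SNNState.zeros(1)
        v0 = 3.0
        state.v_mem[:] = v0
        n = int(round(neuron.tau_mem / DT))
        for _ in range(n):
            step(state, table, 0, 0, DT)
        assert state.v_mem[0] == pytest.approx(v0 / np.e, rel=0.01)

    def test_single_spike_jump_and_decay(self, nominal_neuron, nominal_synapse):
        tau, w = nominal_synapse.tau_exc, nominal_synapse.w_exc
        n = int(round(tau / DT))
        exc = np.zeros(10 * n, dtype=np.int64)
        exc[0] = 1
        out = simulate_neuron(exc, np.zeros_like(exc), nominal_neuron, nominal_synapse,
                              DT, v_thresh=np.inf)
        # traces record end-of-step state: index n-1 sits exactly tau after the jump
        assert out["i_exc"][n - 1] == pytest.approx(w / np.e, rel=0.01)
        # end-of-step trace: the jump to w is sampled after one decay factor
        assert out["i_exc"].max() == pytest.approx(w * np.exp(-DT / tau), rel=1e-9)

    def test_steady_state_mean_current(self, nominal_neuron, nominal_synapse):
        rate = 500.0
        exc = regular_train_counts(1000, rate, DT, tail_s=0.0)
        out = simulate_neuron(exc, np.zeros_like(exc), nominal_neuron, nominal_synapse,
                              DT, v_thresh=np.inf)
        mean_tail = out["i_exc"][exc.size // 2 :].mean()
        expected = nominal_synapse.w_exc * rate * nominal_synapse.tau_exc
        assert mean_tail == pytest.approx(expected, rel=0.02)

    def test_state_positivity_under_strong_inhibition(self, rng):
        table = pd.DataFrame({
            "tau_mem": [15.2e-3] * 4, "tau_ahp": [35.7e-3] * 4, "w_ahp": [1.0] * 4,
            "v_thresh": [2.0] * 4, "v_reset": [0.0] * 4, "tau_exc": [4.5e-3] * 4,
            "tau_inh": [5e-4] * 4, "w_exc": [2.0] * 4, "w_inh": [5.0] * 4,
        })
        state = SNNState.zeros(4)
        for i in range(2000):
            step(state, table, int(rng.poisson(0.3)), int(rng.poisson(0.6)), DT)
            for arr in (state.i_exc, state.i_inh, state.v_ahp, state.v_mem):
                assert np.all(arr >= 0.0)

    def test_synaptic_linearity(self, nominal_neuron, nominal_synapse, rng):
        a = rng.poisson(0.1, 3000).astype(np.int64)
        b = rng.poisson(0.2, 3000).astype(np.int64)
        zeros = np.zeros_like(a)
        ia = simulate_neuron(a, zeros, nominal_neuron, nominal_synapse, DT, np.inf)["i_exc"]
        ib = simulate_neuron(b, zeros, nominal_neuron, nominal_synapse, DT, np.inf)["i_exc"]
        iab = simulate_neuron(a + b, zeros, nominal_neuron, nominal_synapse, DT, np.inf)["i_exc"]
        np.testing.assert_allclose(iab, ia + ib, atol=1e-9 * max(1.0, iab.max()))

    def test_kernel_matches_numpy_step(self, rng):
        n_neurons, n_steps = 6, 800
        table = pd.DataFrame({
            "tau_mem": rng.uniform(10e-3, 20e-3, n_neurons),
            "tau_ahp": rng.uniform(20e-3, 50e-3, n_neurons),
            "w_ahp": rng.uniform(0.5, 2.0, n_neurons),
            "v_thresh": rng.uniform(2.0, 6.0, n_neurons),
            "v_reset": np.zeros(n_neurons),
            "tau_exc": rng.uniform(3e-3, 6e-3, n_neurons),
            "tau_inh": rng.uniform(1e-4, 1e-3, n_neurons),
            "w_exc": rng.uniform(1.0, 3.0, n_neurons),
            "w_inh": rng.uniform(1.0, 3.0, n_neurons),
        })
        exc = rng.poisson(0.4, n_steps).astype(np.int64)
        inh = rng.poisson(0.2, n_steps).astype(np.int64)
        up = np.repeat(np.flatnonzero(exc) * DT, exc[exc > 0])
        dn = np.repeat(np.flatnonzero(inh) * DT, inh[inh > 0])
        raster = run_network(
            [make_train(up, 1, n_steps * DT), make_train(dn, -1, n_steps * DT)],
            table, dt=DT, duration_s=n_steps * DT,
        )
        state = SNNState.zeros(n_neurons)
        ref_spikes = [[] for _ in range(n_neurons)]
        for i in range(n_steps):
            fired = step(state, table, exc[i], inh[i], DT)
            for j in np.flatnonzero(fired):
                ref_spikes[j].append(i * DT)
        for j in range(n_neurons):
            np.testing.assert_allclose(raster.spike_times[j], ref_spikes[j], atol=1e-12)

    def test_dt_refinement_agreement(self, nominal_neuron, nominal_synapse):
        # subthreshold membrane trajectory: dt = 0.1 ms vs 0.01 ms within 2%
        duration = 0.2
        rate = 800.0
        out = {}
        for dt in (1e-4, 1e-5):
            n = int(round(duration / dt))
            exc = np.zeros(n, dtype=np.int64)
            idx = np.minimum((np.arange(int(duration * rate)) / rate / dt).astype(int), n - 1)
            np.add.at(exc, idx, 1)
            res = simulate_neuron(exc, np.zeros_like(exc), nominal_neuron,
                                  nominal_synapse, dt, v_thresh=np.inf)
            out[dt] = res["v_mem"][:: int(round(1e-4 / dt))]
        m = min(len(out[1e-4]), len(out[1e-5]))
        scale = np.abs(out[1e-5][:m]).max()
        assert np.abs(out[1e-4][:m] - out[1e-5][:m]).max() <= 0.02 * scale

    def test_spike_frequency_adaptation(self, nominal_synapse, calibrated_threshold):
        neuron = NeuronParams(v_thresh=calibrated_threshold)
        exc = regular_train_counts(3000, 3000.0, DT, tail_s=0.0)
        out = simulate_neuron(exc, np.zeros_like(exc), neuron, nominal_synapse, DT)
        isis = np.diff(out["spike_steps"]) * DT
        assert len(isis) >= 3
        # drop the cold-start interval (synaptic current still ramping up)
        steady = isis[1:]
        assert np.all(np.diff(steady) >= -DT)  # non-decreasing up to one-step jitter
        assert steady[-1] > steady[0]


class TestCalibration:
    def test_fourteen_spikes_at_3khz_fire_thirteen_do_not(
        self, nominal_neuron, nominal_synapse, calibrated_threshold
    ):
        for n, expect in ((14, True), (13, False)):
            exc = regular_train_counts(n, 3000.0, DT)
            out = simulate_neuron(exc, np.zeros_like(exc), nominal_neuron,
                                  nominal_synapse, DT, v_thresh=calibrated_threshold)
            assert (out["spike_steps"].size >= 1) == expect

    def test_fourteen_spikes_at_slow_rate_leak_away(
        self, nominal_neuron, nominal_synapse, calibrated_threshold
    ):
        exc = regular_train_counts(14, 300.0, DT)
        out = simulate_neuron(exc, np.zeros_like(exc), nominal_neuron,
                              nominal_synapse, DT, v_thresh=calibrated_threshold)
        assert out["spike_steps"].size == 0

    def test_unreachable_anchor_raises(self, nominal_neuron, nominal_synapse):
        with pytest.raises((CalibrationError, ValueError)):
            calibrate_threshold(nominal_neuron, nominal_synapse, n_spikes=1)


@pytest.fixture(scope="module")
def small_table(nominal_synapse):
    neuron = NeuronParams(v_thresh=calibrate_threshold(NeuronParams(), nominal_synapse))
    cfg = SNNConfig(n_neurons=24, seed=2)
    return sample_network(cfg, nominal_synapse, neuron)


class TestRunNetwork:
    def test_empty_inputs_empty_raster(self, small_table):
        raster = run_network([make_train([], duration=0.5)], small_table, duration_s=0.5)
        assert raster.total_spikes == 0
        assert raster.n_neurons == 24

    def test_inhibition_never_increases_counts(self, small_table):
        up = np.arange(0, 0.2, 1 / 2500.0)
        raster_exc = run_network([make_train(up, 1, 0.3)], small_table, duration_s=0.3)
        raster_both = run_network(
            [make_train(up, 1, 0.3), make_train(up + 2e-4, -1, 0.3)],
            small_table, duration_s=0.3,
        )
        assert np.all(raster_both.counts() <= raster_exc.counts())
        assert raster_exc.total_spikes > 0

    def test_determinism(self, small_table):
        up = np.arange(0, 0.1, 1 / 3000.0)
        a = run_network([make_train(up, 1, 0.2)], small_table, duration_s=0.2)
        b = run_network([make_train(up, 1, 0.2)], small_table, duration_s=0.2)
        for ta, tb in zip(a.spike_times, b.spike_times):
            np.testing.assert_array_equal(ta, tb)

    def test_unsorted_inputs_rejected(self, small_table):
        bad = SpikeTrain.__new__(SpikeTrain)
        bad.times = np.array([0.2, 0.1])
        bad.polarities = np.array([1, 1], dtype=np.int8)
        bad.source = ""
        bad.duration_s = 0.5
        with pytest.raises(ValueError):
            run_network([bad], small_table, duration_s=0.5)


DPI_FREQS = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 265.0])


@pytest.fixture(scope="module")
def gains():
    return dpi_frequency_response(6e-3, DPI_FREQS, n_cycles=20)


class TestDPIResponse:
    FREQS = DPI_FREQS

    def test_dc_gain_is_one(self, gains):
        assert gains[0] == pytest.approx(1.0, rel=0.05)

    def test_matches_first_order_low_pass(self, gains):
        analytic = 1.0 / np.sqrt(1.0 + (2 * np.pi * self.FREQS * 6e-3) ** 2)
        np.testing.assert_allclose(gains, analytic, rtol=0.30)

    def test_rolloff_at_ten_corner_frequencies(self, gains):
        # f = 10/(2 pi tau) -> |H| = 1/sqrt(101)
        assert gains[-1] == pytest.approx(1 / np.sqrt(101), rel=0.30)

    def test_monotone_non_increasing(self, gains):
        assert np.all(np.diff(gains) <= 0.02)

    @pytest.mark.parametrize("tau_inh", [0.5e-3, 4.5e-3])
    def test_exc_minus_inh_has_interior_maximum(self, tau_inh):
        freqs = np.array([2.0, 8.0, 30.0, 80.0, 200.0, 500.0, 1200.0])
        curve = dpi_bandpass_response(6e-3, tau_inh, freqs, n_cycles=15)
        peak = int(np.argmax(curve))
        assert 0 < peak < len(freqs) - 1
        assert curve[peak] > curve[0] and curve[peak] > curve[-1]
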