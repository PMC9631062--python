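"""Membrane-dynamics simulator: step responses, spike trains, ensembles."""

import numpy as np
import pytest

from spadvi import neuron


class TestStepResponse:
    def test_ohms_law_steady_state(self):
        # 100 pA into 100 MOhm settles at +10 mV when steps last >= 10 tau
        cell = neuron.CellMembraneModel(resistance_MOhm=100.0,
                                        tau_membrane_ms=10.0)
        proto = neuron.StepProtocol(step_levels=(100.0,), step_duration_s=0.5,
                                    inter_step_s=0.0)
        v = neuron.simulate_step_response(proto, cell, 20_000.0)
        assert v.values[-1] == pytest.approx(cell.resting_mV + 10.0, abs=1e-9)

    def test_default_protocol_duration_without_gaps(self):
        # 100 ms baseline + 5 x 100 ms back-to-back steps = 0.6 s
        proto = neuron.StepProtocol(inter_step_s=0.0)
        assert proto.duration_s == pytest.approx(0.6)
        v = neuron.simulate_step_response(proto, neuron.CellMembraneModel(),
                                          20_000.0)
        assert v.values.size == 12_000

    def test_default_protocol_levels(self):
        assert neuron.StepProtocol.default_current().step_levels == \
            (-200.0, -100.0, 0.0, 100.0, 200.0)
        assert neuron.StepProtocol.default_voltage().step_levels == \
            (-50.0, -30.0, -10.0, 10.0, 30.0)

    def test_exponential_relaxation_63_percent(self):
        tau_ms = 10.0
        cell = neuron.CellMembraneModel(tau_membrane_ms=tau_ms)
        proto = neuron.StepProtocol(step_levels=(200.0,), step_duration_s=0.2,
                                    inter_step_s=0.0)
        rate = 20_000.0
        v = neuron.simulate_step_response(proto, cell, rate)
        t0 = int(proto.baseline_s * rate)
        t1 = t0 + int(tau_ms / 1000 * rate)
        dv_ss = 200.0 * cell.resistance_MOhm * 1e-3
        frac = (v.values[t1] - v.values[t0]) / dv_ss
        assert frac == pytest.approx(1 - np.exp(-1), abs=1e-3)

    def test_voltage_clamp_follows_command(self):
        proto = neuron.StepProtocol.default_voltage()
        v = neuron.simulate_step_response(proto, neuron.CellMembraneModel(),
                                          20_000.0)
        # settled by the end of each 100 ms step (settling constant 1 ms)
        onsets = proto.step_onsets()
        for onset, level in zip(onsets, proto.step_levels):
            idx = int((onset + 0.099) * 20_000)
            assert v.values[idx] == pytest.approx(level, abs=1e-6)

    def test_bad_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            neuron.simulate_step_response(neuron.StepProtocol(),
                                          neuron.CellMembraneModel(), -5.0)


class TestSpikeTrain:
    @pytest.mark.parametrize("freq,isi_ms", [(25.0, 40.0), (100.0, 10.0)])
    def test_pulse_train_spike_times(self, freq, isi_ms):
        proto = neuron.PulseTrainProtocol(frequency_Hz=freq, onset_s=0.0)
        _, train = neuron.simulate_spike_train(proto,
                                               neuron.CellMembraneModel(),
                                               20_000.0)
        assert len(train) == 10
        np.testing.assert_allclose(np.diff(train.times) * 1e3, isi_ms)
        assert train.times[0] == 0.0

    def test_single_pulse_single_spike(self):
        proto = neuron.PulseTrainProtocol(n_pulses=1)
        v, train = neuron.simulate_spike_train(proto,
                                               neuron.CellMembraneModel(),
                                               20_000.0)
        assert len(train) == 1
        # exactly one prominent depolarization in the trace
        above = v.values > v.values.min() + 40.0
        assert above.any()
        edges = np.flatnonzero(np.diff(above.astype(int)) == 1)
        assert edges.size <= 1

    def test_overlapping_waveforms_rejected(self):
        proto = neuron.PulseTrainProtocol(frequency_Hz=150.0,
                                          pulse_width_ms=2.0)
        with pytest.raises(ValueError, match="conflict"):
            neuron.simulate_spike_train(proto, neuron.CellMembraneModel(),
                                        20_000.0)

    def test_waveform_peak_amplitude(self):
        cell = neuron.CellMembraneModel(spike_peak_mV=80.0)
        w, peak_idx = cell.spike_waveform(20_000.0)
        assert w.max() == pytest.approx(80.0)
        assert w[peak_idx] == w.max()


class TestEnsemble:
    def test_zero_jitter_spikes_identical_across_cells(self):
        model = neuron.EnsembleModel(sync_jitter_ms=0.0,
                                     independent_rate_Hz=0.0,
                                     burst_rate_Hz=1.0, seed=3)
        cells = neuron.simulate_ensemble(model)
        np.testing.assert_allclose(cells[0][1].times, cells[1][1].times)

    def test_background_poisson_count(self):
        # 5 Hz for 10 s -> 50 expected spikes; 3 sqrt(50) tolerance
        counts = []
        for seed in range(5):
            model = neuron.EnsembleModel(burst_rate_Hz=0.0,
                                         independent_rate_Hz=5.0, seed=seed)
            cells = neuron.simulate_ensemble(model)
            counts += [len(tr) for _, tr in cells]
        assert abs(np.mean(counts) - 50) < 3 * np.sqrt(50) / np.sqrt(len(counts))

    def test_deterministic_replay(self):
        model = neuron.EnsembleModel(seed=7)
        a = neuron.simulate_ensemble(model)
        b = neuron.simulate_ensemble(model)
        for (va, ta), (vb, tb) in zip(a, b):
            np.testing.assert_array_equal(va.values, vb.values)
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_short_duration_warns(self):
        model = neuron.EnsembleModel(burst_rate_Hz=0.05, duration_s=2.0, seed=0)
        with pytest.warns(UserWarning, match="burst"):
            neuron.simulate_ensemble(model, sample_rate=2000.0)

    def test_synchrony_decreases_with_jitter(self):
        # fraction of cell-2 spikes within +-2 ms of a cell-1 spike is
        # monotonically non-increasing in the jitter SD
        def sync_frac(jitter):
            fracs = []
            for seed in range(4):
                model = neuron.EnsembleModel(sync_jitter_ms=jitter,
                                             independent_rate_Hz=0.0,
                                             burst_rate_Hz=1.0, seed=40 + seed)
                cells = neuron.simulate_ensemble(model)
                t1, t2 = cells[0][1].times, cells[1][1].times
                if t2.size == 0:
                    continue
                near = [np.min(np.abs(t1 - t)) <= 0.002 for t in t2]
                fracs.append(np.mean(near))
            return np.mean(fracs)

        vals = [sync_frac(j) for j in (0.0, 1.0, 5.0, 20.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(1.0)


class TestDomainTypes:
    def test_voltage_trace_requires_uniform_grid(self):
        with pytest.raises(ValueError):
            neuron.VoltageTrace(times=np.array([0.0, 0.1, 0.15]),
                                values=np.zeros(3), sample_rate=10.0)

    def test_spike_train_requires_increasing_times(self):
        with pytest.raises(ValueError):
            neuron.SpikeTrain(times=np.array([0.2, 0.1]), duration_s=1.0)

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            neuron.PulseTrainProtocol(frequency_Hz=100.0, pulse_width_ms=12.0)

    def test_ground_truth_text_round_trip(self, tmp_path):
        train = neuron.SpikeTrain(times=np.array([0.1, 0.25, 0.9]),
                                  duration_s=1.0)
        path = tmp_path / "spikes.txt"
        train.to_text(path)
        back = neuron.SpikeTrain.from_text(path, 1.0)
        np.testing.assert_allclose(back.times, train.times)
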