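"""Field-potential pipeline tests: filters, detection, classification,
ISF, PSTH."""

import numpy as np
import pytest

from finwave.ephys import (
    SpikeTrain,
    bandpass,
    classify_amplitude,
    detect_spikes,
    instantaneous_frequency,
    notch50,
    psth,
)
from finwave.synthetic import EphysTrace, simulate_field_potential

FS = 25_000.0


def _sine(freq, duration=2.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return EphysTrace(samples=np.sin(2 * np.pi * freq * t), fs=fs)


def _steady_amp(trace, margin=0.2):
    n = trace.samples.size
    lo, hi = int(margin * n), int((1 - margin) * n)
    return np.max(np.abs(trace.samples[lo:hi]))


class TestBandpass:
    def test_dc_rejected(self):
        dc = EphysTrace(samples=np.ones(int(FS)), fs=FS)
        out = bandpass(dc)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_passband_tone_preserved(self):
        assert _steady_amp(bandpass(_sine(400.0))) >= 0.85

    def test_mains_tone_rejected(self):
        assert _steady_amp(bandpass(_sine(50.0))) <= 0.1

    def test_above_band_rejected(self):
        assert _steady_amp(bandpass(_sine(1000.0))) <= 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass(EphysTrace(samples=np.zeros(2000), fs=1100.0),
                     high_hz=600.0)


class TestNotch50:
    def test_mains_sine_attenuated_20db(self):
        assert _steady_amp(notch50(_sine(50.0))) <= 0.1

    def test_passband_tone_untouched(self):
        amp = _steady_amp(notch50(_sine(400.0)))
        assert amp >= 10 ** (-1 / 20)  # at most 1 dB loss

    def test_spike_template_peak_preserved(self):
        trace, _ = simulate_field_potential([1.0], [], amp_large=10.0,
                                            amp_small=1.0, hum_amp=0.0,
                                            noise_sd=0.0, duration_s=2.0, seed=0)
        out = notch50(trace)
        assert np.max(np.abs(out.samples)) == pytest.approx(10.0, rel=0.1)

    def test_zero_in_zero_out(self):
        z = EphysTrace(samples=np.zeros(int(FS)), fs=FS)
        assert np.allclose(notch50(z).samples, 0.0)


class TestDetectSpikes:
    def test_snr10_precision_recall_and_timing(self):
        rng = np.random.default_rng(1)
        times = np.linspace(0.05, 4.95, 100) + rng.uniform(-0.012, 0.012, 100)
        trace, _ = simulate_field_potential(times[::2], times[1::2],
                                            amp_large=25.0, amp_small=10.0,
                                            hum_amp=1.0, noise_sd=1.0, seed=1)
        train = detect_spikes(notch50(bandpass(trace)))
        det = train.times_s
        recall = np.mean([np.min(np.abs(det - t0)) <= 5e-4 for t0 in times])
        precision = np.mean([np.min(np.abs(times - d)) <= 5e-4 for d in det])
        assert recall >= 0.95
        assert precision >= 0.95

    def test_pure_noise_false_positive_rate(self):
        # expected false positives < 1 per 5 s of noise-only recording
        counts = []
        for seed in range(100):
            trace, _ = simulate_field_potential([], [], hum_amp=1.0,
                                                noise_sd=1.0, duration_s=1.0,
                                                seed=seed)
            counts.append(len(detect_spikes(notch50(bandpass(trace)))))
        per_5s = np.mean(counts) * 5
        assert per_5s < 1.0

    def test_refractory_merges_close_spikes(self):
        trace, _ = simulate_field_potential([1.0], [1.001], amp_large=10.0,
                                            amp_small=5.0, hum_amp=0.0,
                                            noise_sd=0.0, duration_s=2.0, seed=0)
        train = detect_spikes(notch50(bandpass(trace)))
        assert len(train) == 1

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_spikes(EphysTrace(samples=np.array([]), fs=FS))


class TestClassifyAmplitude:
    def _train(self, amps):
        amps = np.asarray(amps, float)
        return SpikeTrain(times_s=np.arange(amps.size) * 0.01, amplitudes=amps)

    def test_two_cluster_split_by_hand(self):
        ct = classify_amplitude(self._train([1, 1, 1, 3, 3]))
        assert list(ct.classes) == ["small"] * 3 + ["large"] * 2

    def test_equal_amplitudes_single_class_flagged(self):
        ct = classify_amplitude(self._train([2.0, 2.0, 2.0]))
        assert ct.degenerate_classes
        assert len(set(ct.classes)) == 1

    def test_scale_invariance(self):
        a = classify_amplitude(self._train([1, 1, 1, 3, 3, 2.8]))
        b = classify_amplitude(self._train(np.array([1, 1, 1, 3, 3, 2.8]) * 10))
        assert list(a.classes) == list(b.classes)

    def test_needs_two_spikes(self):
        with pytest.raises(ValueError):
            classify_amplitude(self._train([1.0]))


class TestInstantaneousFrequency:
    def test_regular_train_constant_rate(self):
        train = SpikeTrain(times_s=np.arange(20) * 0.1,
                           amplitudes=np.ones(20))
        isf = instantaneous_frequency(train)
        assert np.allclose(isf[:, 1], 10.0)

    def test_single_spike_empty_with_flag(self):
        train = SpikeTrain(times_s=np.array([1.0]), amplitudes=np.array([1.0]))
        with pytest.warns(RuntimeWarning):
            isf = instantaneous_frequency(train)
        assert isf.shape == (0, 2)

    def test_poisson_train_median_rate(self, rng):
        # for a Poisson train the ISI distribution is exponential, so
        # the median instantaneous frequency is lambda / ln 2 (the mean
        # of 1/ISI diverges and is not a usable summary)
        lam = 20.0
        medians = []
        for _ in range(100):
            isi = rng.exponential(1 / lam, 400)
            train = SpikeTrain(times_s=np.cumsum(isi), amplitudes=np.ones(400))
            medians.append(np.median(instantaneous_frequency(train)[:, 1]))
        assert np.mean(medians) == pytest.approx(lam / np.log(2), rel=0.05)


class TestPsth:
    def _train(self, rel_times, stim=1.0):
        t = np.sort(np.asarray(rel_times) + stim)
        return SpikeTrain(times_s=t, amplitudes=np.ones(t.size), stim_time_s=stim)

    def test_no_spikes_all_zero(self):
        h = psth([SpikeTrain(times_s=np.array([]), amplitudes=np.array([]))],
                 window_s=(-0.5, 0.5), bin_width_s=0.1)
        assert np.all(h["mean_counts"] == 0)

    def test_counts_conserved_per_train(self):
        rel = [-0.3, -0.1, 0.02, 0.04, 0.3]
        h = psth([self._train(rel)], window_s=(-0.5, 0.5), bin_width_s=0.1)
        assert h["per_train_counts"].sum() == len(rel)

    def test_stimulus_coupled_spikes_peak_at_zero_bin(self, rng):
        trains = []
        for _ in range(8):
            coupled = rng.uniform(0.0, 0.04, 6)      # tight post-stimulus burst
            background = rng.uniform(-1.0, 1.0, 4)
            trains.append(self._train(np.concatenate([coupled, background])))
        h = psth(trains, window_s=(-1.0, 1.0), bin_width_s=0.05)
        assert int(np.argmax(h["mean_counts"])) == h["zero_bin"]

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            psth([], window_s=(0.5, 0.5), bin_width_s=0.1)


class TestPipelineRecovery:
    def test_large_spike_recovery_and_class_accuracy(self):
        rng = np.random.default_rng(3)
        times = np.linspace(0.1, 4.9, 60) + rng.uniform(-0.015, 0.015, 60)
        large_t, small_t = times[::2], times[1::2]
        trace, _ = simulate_field_potential(large_t, small_t, amp_large=16.0,
                                            amp_small=6.0, hum_amp=1.0,
                                            noise_sd=1.0, seed=3)
        train = classify_amplitude(detect_spikes(notch50(bandpass(trace))))
        large = train.select("large").times_s
        hits = np.mean([np.min(np.abs(large - t0)) <= 1e-3 for t0 in large_t])
        assert hits >= 0.95
        correct = tot = 0
        for d, c in zip(train.times_s, train.classes):
            if np.min(np.abs(large_t - d)) <= 1e-3:
                tot += 1
                correct += c == "large"
            elif np.min(np.abs(small_t - d)) <= 1e-3:
                tot += 1
                correct += c == "small"
        assert correct / tot >= 0.95
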