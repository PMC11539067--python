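"""Wave-model tests: generation, reconstruction, decomposition."""

import numpy as np
import pytest

from finwave.propulsion import PRESETS
from finwave.wave_model import (
    BendingField,
    InsufficientDataError,
    Midline,
    UndefinedPeakError,
    WaveParams,
    decompose_standing_travelling,
    fit_single_frequency,
    generate_bending_field,
    midlines_from_bending,
    pectoral_peak_position,
)


class TestGenerateBendingField:
    def test_zero_amplitudes_give_zero_field(self):
        p = WaveParams(standing_amp_rad=0.0, travelling_amp_rad=0.0)
        field = generate_bending_field(p, duration_s=1.0, fps=100.0)
        assert np.all(field.theta == 0.0)

    def test_full_flexibility_is_exact_identity(self):
        p = WaveParams(stiffness_gamma=1.0)
        a = generate_bending_field(p, duration_s=1.0, fps=100.0)
        b = generate_bending_field(p.with_(), duration_s=1.0, fps=100.0)
        assert np.array_equal(a.theta, b.theta)

    def test_travelling_phase_slope_matches_closed_form(self):
        # pure travelling wave: per-segment temporal phase of the
        # generating cosine is -2*pi*s/lambda, so the fitted phase must
        # decrease along s with slope 2*pi/lambda
        p = WaveParams(standing_amp_rad=0.0, wavelength_bl=0.8,
                       caudal_growth_exp=0.0)
        field = generate_bending_field(p, duration_s=4.0, fps=100.0)
        fit = fit_single_frequency(field)
        phase = np.unwrap(fit.phase)
        slope = np.polyfit(field.s_frac, phase, 1)[0]
        assert slope == pytest.approx(-2 * np.pi / 0.8, rel=1e-3)

    def test_invalid_parameter_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            WaveParams(freq_hz=np.nan)
        with pytest.raises(ValueError):
            WaveParams(stiffness_gamma=1.5)

    def test_sub_nyquist_fps_warns(self):
        p = WaveParams(freq_hz=10.0)
        with pytest.warns(RuntimeWarning, match="alias"):
            generate_bending_field(p, duration_s=1.0, fps=15.0)


class TestMidlinesFromBending:
    def test_zero_bending_gives_straight_body(self):
        p = WaveParams(standing_amp_rad=0.0, travelling_amp_rad=0.0)
        field = generate_bending_field(p, duration_s=0.5, fps=50.0)
        seq = midlines_from_bending(field, p)
        m = seq.midlines[0]
        assert np.allclose(m.points[:, 1], 0.0)
        assert m.arc_length == pytest.approx(p.body_length_mm, rel=1e-9)
        chord = np.linalg.norm(m.tail - m.head)
        assert chord == pytest.approx(p.body_length_mm, rel=1e-9)

    def test_arc_length_is_body_length_for_any_frame(self, flexible_params,
                                                     flexible_field):
        seq = midlines_from_bending(flexible_field, flexible_params)
        for m in seq.midlines[::100]:
            assert m.arc_length == pytest.approx(
                flexible_params.body_length_mm, rel=1e-9)

    def test_constant_bending_traces_circular_arc(self):
        # per-segment bending Theta/n bends the body onto a circle of
        # radius R = L/Theta; the chord must equal 2 R sin(Theta/2)
        p = WaveParams(standing_amp_rad=0.0, travelling_amp_rad=0.0)
        total = 1.2
        theta = np.full((1, p.n_segments), total / p.n_segments)
        field = BendingField(theta=theta, times_s=np.array([0.0]),
                             s_frac=(np.arange(p.n_segments) + 0.5) / p.n_segments)
        seq = midlines_from_bending(field, p)
        m = seq.midlines[0]
        chord = np.linalg.norm(m.tail - m.head)
        R = p.body_length_mm / total
        # discrete polygon vs continuous arc: agreement to O(1/n^2)
        assert chord == pytest.approx(2 * R * np.sin(total / 2), rel=1e-3)

    def test_roundtrip_recovers_bending_field(self, flexible_params,
                                              flexible_field):
        from finwave.features import bending_series

        seq = midlines_from_bending(flexible_field, flexible_params)
        rec = bending_series(seq)
        assert np.max(np.abs(rec.theta - flexible_field.theta)) < 1e-6


class TestFitSingleFrequency:
    def test_recovers_generator_frequency(self, flexible_field):
        fit = fit_single_frequency(flexible_field)
        df = 1.0 / (flexible_field.times_s[-1] - flexible_field.times_s[0])
        assert abs(fit.freq_hz - 2.5) <= df

    def test_pure_cosine_amplitude_exact(self):
        t = np.arange(400) / 100.0
        s = np.linspace(0.01, 0.99, 20)
        a = 0.37
        theta = a * np.cos(2 * np.pi * 2.0 * t)[:, None] * np.ones_like(s)[None, :]
        field = BendingField(theta=theta, times_s=t, s_frac=s)
        fit = fit_single_frequency(field)
        assert np.allclose(fit.amplitude, a, atol=1e-6)

    def test_noise_only_field_flags_low_power(self, rng):
        t = np.arange(600) / 100.0
        s = np.linspace(0.01, 0.99, 20)
        theta = rng.normal(0, 0.01, (t.size, s.size))
        field = BendingField(theta=theta, times_s=t, s_frac=s)
        with pytest.warns(RuntimeWarning, match="low-power"):
            fit = fit_single_frequency(field)
        assert fit.low_power
        # fitted amplitude stays near the noise floor, far below a
        # signal-bearing field's amplitude
        assert np.max(fit.amplitude) < 0.01

    def test_short_record_raises(self):
        t = np.arange(20) / 100.0  # 0.2 s: less than one 2.5 Hz period
        s = np.linspace(0.01, 0.99, 20)
        theta = np.cos(2 * np.pi * 2.5 * t)[:, None] * np.ones_like(s)[None, :]
        with pytest.raises(InsufficientDataError):
            fit_single_frequency(BendingField(theta=theta, times_s=t, s_frac=s))


class TestDecomposition:
    s = np.linspace(0.01, 0.99, 50)

    def test_pure_standing_low_travelling_index(self):
        z = np.exp(-0.5 * ((self.s - 0.3) / 0.1) ** 2) + 0j  # spatially in phase
        d = decompose_standing_travelling(z, self.s)
        assert np.mean(d.travelling_index) <= 0.1

    def test_pure_travelling_high_travelling_index(self):
        z = np.exp(-2j * np.pi * self.s / 0.5)
        d = decompose_standing_travelling(z, self.s)
        assert np.mean(d.travelling_index) >= 0.9

    def test_fifty_fifty_mixture(self):
        # travelling wave plus equal-amplitude standing wave: the
        # standing and travelling amplitudes match, so the index is 0.5
        k = 2 * np.pi / 0.5
        z = np.exp(-1j * k * self.s) + np.cos(k * self.s)
        d = decompose_standing_travelling(z, self.s)
        assert np.mean(d.travelling_index) == pytest.approx(0.5, abs=0.1)

    def test_zero_profile_gives_zeros_without_error(self):
        d = decompose_standing_travelling(np.zeros(50, dtype=complex), self.s)
        assert np.all(d.standing == 0)
        assert np.all(d.travelling == 0)
        assert np.all(d.travelling_index == 0)

    def test_travelling_index_decreases_with_stiffness(self):
        # damping the caudal travelling wave reduces the caudal
        # travelling content: monotone up to the estimator's resolution.
        # The index is a ratio, so once the residual standing reading
        # (spectral leakage of the amplitude envelope) is all that is
        # left, further gamma reduction saturates; the decrease is
        # required to hold within that ~0.01 floor and to be large at
        # the strongly stiffened end.
        means = []
        for gamma in [0.2, 0.4, 0.6, 0.8, 1.0]:
            p = WaveParams(stiffness_gamma=gamma)
            field = generate_bending_field(p, duration_s=4.0, fps=100.0)
            fit = fit_single_frequency(field)
            d = decompose_standing_travelling(fit)
            caudal = (d.s_frac > p.stiffness_onset) & (d.s_frac < 0.7)
            means.append(np.mean(d.travelling_index[caudal]))
        assert np.all(np.diff(means) >= -0.01)
        assert means[0] < means[-1] - 0.05


class TestPectoralPeakPosition:
    def test_gaussian_envelope_peak_recovered(self):
        s = np.linspace(0, 1, 51)
        env = np.exp(-0.5 * ((s - 0.25) / 0.08) ** 2)
        assert pectoral_peak_position(env, s) == pytest.approx(0.25, abs=0.01)

    def test_flat_envelope_breaks_ties_rostrally(self):
        s = np.linspace(0, 1, 51)
        assert pectoral_peak_position(np.ones(51), s) == 0.0

    def test_compensated_preset_peaks_caudal_to_wildtype(self):
        peaks = {}
        for name in ("flexible", "compensated"):
            field = generate_bending_field(PRESETS[name], duration_s=4.0, fps=200.0)
            fit = fit_single_frequency(field)
            peaks[name] = pectoral_peak_position(fit.amplitude, fit.s_frac)
        assert peaks["compensated"] > peaks["flexible"]

    def test_generator_peak_recovered_from_clean_field(self, flexible_params,
                                                       flexible_field):
        fit = fit_single_frequency(flexible_field)
        p = pectoral_peak_position(fit.amplitude, fit.s_frac)
        assert p == pytest.approx(flexible_params.standing_peak_pos, abs=0.02)

    def test_zero_envelope_raises(self):
        s = np.linspace(0, 1, 51)
        with pytest.raises(UndefinedPeakError):
            pectoral_peak_position(np.zeros(51), s)


class TestMidlineType:
    def test_resample_is_equidistant(self):
        pts = np.column_stack([np.linspace(0, 10, 7) ** 1.3,
                               np.sin(np.linspace(0, 2, 7))])
        m = Midline(pts).resample(21)
        seg = m.segment_lengths
        assert np.all(np.abs(seg - seg.mean()) <= 1e-6 * seg.mean())

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            Midline(np.array([[0, 0], [0, 0], [1, 1]]))
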