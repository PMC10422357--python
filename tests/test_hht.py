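"""Hilbert layer: analytic pairs, instantaneous descriptors, spectra."""

import numpy as np
import pytest

from swinghht.hht import (
    analytic_signal,
    analyze_mode,
    build_spectrum,
    default_freq_edges,
    instantaneous_amplitude,
    instantaneous_frequency,
)


class TestAnalyticSignal:
    def test_cos_pairs_with_sin(self, t_2s):
        re, im = analytic_signal(np.cos(2 * np.pi * 5 * t_2s))
        np.testing.assert_allclose(
            im[10:-10], np.sin(2 * np.pi * 5 * t_2s)[10:-10], atol=0.02
        )

    def test_real_part_unchanged(self, t_2s):
        x = np.cos(2 * np.pi * 5 * t_2s)
        re, _ = analytic_signal(x)
        np.testing.assert_allclose(re, x, atol=1e-12)

    def test_constant_has_zero_quadrature(self):
        _, im = analytic_signal(np.full(64, 3.0))
        assert np.max(np.abs(im)) < 1e-9

    def test_sin_pairs_with_negative_cos(self, t_2s):
        _, im = analytic_signal(np.sin(2 * np.pi * 5 * t_2s))
        np.testing.assert_allclose(
            im[10:-10], -np.cos(2 * np.pi * 5 * t_2s)[10:-10], atol=0.02
        )

    def test_non_finite_rejected(self):
        x = np.ones(32)
        x[0] = np.inf
        with pytest.raises(ValueError):
            analytic_signal(x)


class TestInstantaneousDescriptors:
    def test_amplitude_of_scaled_tone(self, t_2s):
        re, im = analytic_signal(3.0 * np.cos(2 * np.pi * 5 * t_2s))
        amp = instantaneous_amplitude(re, im)
        interior = amp[12:-12]
        assert np.max(np.abs(interior - 3.0)) / 3.0 <= 0.02

    def test_amplitude_pythagorean(self):
        assert instantaneous_amplitude(np.array([3.0]), np.array([4.0]))[0] == 5.0
        assert instantaneous_amplitude(np.zeros(3), np.zeros(3)).tolist() == [0, 0, 0]

    @pytest.mark.parametrize("f0, tol", [(5.0, 0.2), (20.0, 0.5)])
    def test_tone_frequency_recovered(self, t_2s, fs, f0, tol):
        mode = analyze_mode(np.cos(2 * np.pi * f0 * t_2s), fs)
        interior = mode.frequency[mode.interior()]
        assert np.max(np.abs(interior - f0)) <= tol

    def test_chirp_frequency_tracked(self, fs):
        # 2 -> 10 Hz linear chirp over 2 s: f(t) = 2 + 4t
        t = np.arange(int(2 * fs)) / fs
        phase = 2 * np.pi * (2 * t + 2 * t**2)
        mode = analyze_mode(np.cos(phase), fs)
        sl = mode.interior()
        err = mode.frequency[sl] - (2 + 4 * t[sl])
        assert np.sqrt(np.mean(err**2)) <= 0.5

    def test_zero_amplitude_marks_frequency_missing(self):
        freq = instantaneous_frequency(np.zeros(16), np.zeros(16), 120.0)
        assert np.all(np.isnan(freq))

    def test_energy_identity_for_pure_tone(self, t_2s, fs):
        x = 2.0 * np.cos(2 * np.pi * 8 * t_2s)
        mode = analyze_mode(x, fs)
        sl = mode.interior()
        assert np.mean(mode.amplitude[sl] ** 2) / 2 == pytest.approx(
            np.var(x[sl]), rel=0.05
        )

    def test_amplitude_identity_holds_pointwise(self, t_2s, fs):
        mode = analyze_mode(np.cos(2 * np.pi * 5 * t_2s), fs)
        np.testing.assert_allclose(
            mode.amplitude**2, mode.real_part**2 + mode.imag_part**2, atol=1e-9
        )

    def test_oscillatory_imf_frequency_mostly_nonnegative(self, t_2s, fs):
        # well-separated oscillatory modes stay far from phase reversals:
        # the phase derivative should almost never run backwards
        from swinghht.emd import emd

        x = np.sin(2 * np.pi * 2 * t_2s) + np.sin(2 * np.pi * 20 * t_2s)
        s = emd(x, fs)
        assert s.n >= 2
        for m in s.imfs[:2]:
            mode = analyze_mode(m, fs)
            f = mode.frequency[mode.interior()]
            assert np.mean(f >= 0) >= 0.95

    def test_negative_frequency_excursions_counted_not_clipped(self, swing_clip, fs):
        from swinghht.emd import emd

        clip, _ = swing_clip
        s = emd(clip.euler["Neck"][:, 0], fs)
        for m in s.imfs:
            mode = analyze_mode(m, fs)
            assert mode.n_negative_freq == np.sum(mode.frequency < 0)


class TestBuildSpectrum:
    def test_constant_tone_mass_conservation(self):
        n = 100
        freq = np.full(n, 5.0)
        amp = np.full(n, 2.0)
        spec = build_spectrum([(freq, amp)], time_axis=np.arange(n) / 120.0)
        assert spec.total_mass == pytest.approx(200.0)
        hot = np.nonzero(spec.power.sum(axis=0))[0]
        assert list(hot) == [10]  # the 0.5 Hz bin containing 5 Hz
        assert spec.freq_edges[10] <= 5.0 < spec.freq_edges[11]

    def test_empty_mode_list_is_zero(self):
        spec = build_spectrum([], time_axis=np.arange(8) / 120.0)
        assert spec.total_mass == 0.0

    def test_two_tones_occupy_disjoint_bands(self):
        n = 50
        t = np.arange(n) / 120.0
        spec = build_spectrum(
            [(np.full(n, 3.0), np.ones(n)), (np.full(n, 12.0), np.ones(n))], t
        )
        hot = np.nonzero(spec.power.sum(axis=0))[0]
        assert len(hot) == 2
        assert spec.freq_edges[hot[0]] <= 3.0 < spec.freq_edges[hot[0] + 1]
        assert spec.freq_edges[hot[1]] <= 12.0 < spec.freq_edges[hot[1] + 1]

    def test_undefined_and_out_of_range_samples_counted_not_deposited(self):
        n = 10
        freq = np.array([np.nan, -1.0, 100.0] + [5.0] * 7)
        amp = np.ones(n)
        spec = build_spectrum([(freq, amp)], time_axis=np.arange(n) / 120.0)
        assert spec.n_undefined == 1
        assert spec.n_below_range == 1
        assert spec.n_above_range == 1
        assert spec.total_mass == pytest.approx(7.0)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            build_spectrum(
                [(np.ones(4), np.ones(4))],
                time_axis=np.arange(4.0),
                freq_edges=np.array([0.0, 2.0, 1.0]),
            )

    def test_default_edges_span_movement_band(self):
        edges = default_freq_edges()
        assert edges[0] == 0.0 and edges[-1] == 40.0
        assert np.allclose(np.diff(edges), 0.5)
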