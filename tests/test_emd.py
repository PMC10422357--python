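"""Sifting machinery: extrema, envelopes, SD criterion, IMF checks, EMD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swinghht.emd import (
    EMDConfig,
    SiftState,
    count_zero_crossings,
    emd,
    find_extrema,
    is_imf,
    mean_envelope,
    sd_criterion,
    sift_once,
    spline_envelope,
)
from swinghht.hht import analyze_mode


class TestFindExtrema:
    def test_single_peak_and_trough(self):
        maxima, minima = find_extrema(np.array([0, 1, 0, -1, 0.0]))
        assert list(maxima) == [1] and list(minima) == [3]

    def test_monotone_ramp_has_none(self):
        maxima, minima = find_extrema(np.arange(10.0))
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_contributes_midpoint_floor(self):
        maxima, _ = find_extrema(np.array([0, 1, 1, 0.0]))
        assert list(maxima) == [1]
        maxima, _ = find_extrema(np.array([0, 1, 1, 1, 0.0]))
        assert list(maxima) == [2]

    def test_constant_series_has_none(self):
        maxima, minima = find_extrema(np.zeros(16))
        assert maxima.size == 0 and minima.size == 0

    def test_maxima_and_minima_interleave(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(200)
        maxima, minima = find_extrema(s)
        merged = sorted([(i, "M") for i in maxima] + [(i, "m") for i in minima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestSplineEnvelope:
    def test_pure_tone_upper_envelope_is_unit(self, t_2s):
        s = np.sin(2 * np.pi * 5 * t_2s)
        maxima, _ = find_extrema(s)
        env = spline_envelope(s, maxima)
        assert np.max(np.abs(env[10:-10] - 1.0)) <= 0.02

    def test_two_extrema_degenerate_to_line(self):
        s = np.array([0, 2, 0, -1, 0, 2, 0.0])
        env = spline_envelope(s, np.array([1, 5]), boundary=1)
        # natural spline through two (mirrored) collinear-by-pairs knots stays linear
        assert abs(env[3] - 2.0) < 1e-9

    def test_fewer_than_two_extrema_signals_termination(self):
        assert spline_envelope(np.zeros(8), np.array([], dtype=int)) is None
        assert mean_envelope(np.zeros(8)) is None


class TestSiftOnce:
    def test_symmetric_oscillation_is_near_fixed_point(self, t_2s):
        h = np.sin(2 * np.pi * 5 * t_2s)
        state = sift_once(SiftState(h=h))
        assert np.linalg.norm(state.h - h) / np.linalg.norm(h) < 0.2

    def test_constant_offset_is_removed(self, t_2s):
        c = 3.0
        h = np.sin(2 * np.pi * 5 * t_2s) + c
        state = sift_once(SiftState(h=h))
        assert abs(state.h.mean()) < 0.05 * c

    def test_iteration_count_increments(self, t_2s):
        state = sift_once(SiftState(h=np.sin(2 * np.pi * 5 * t_2s), k=1))
        assert state.k == 2

    def test_envelope_undefined_terminates(self):
        assert sift_once(SiftState(h=np.linspace(0, 1, 32))) is None


class TestSDCriterion:
    def test_identical_iterates_give_zero(self):
        h = np.array([1.0, -2.0, 3.0])
        assert sd_criterion(h, h) == 0.0

    def test_zero_successor_gives_one(self):
        h = np.array([1.0, -2.0, 3.0])
        assert sd_criterion(h, np.zeros(3)) == 1.0

    def test_direct_ratio(self):
        assert sd_criterion(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == 0.5

    def test_zero_energy_predecessor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sd_criterion(np.zeros(4), np.ones(4))


class TestIsIMF:
    def test_pure_tone_passes(self, t_2s):
        ok, _ = is_imf(np.sin(2 * np.pi * 5 * t_2s))
        assert ok

    def test_monotone_ramp_fails(self):
        ok, _ = is_imf(np.linspace(-1, 1, 64))
        assert not ok

    def test_large_offset_fails_by_zero_crossings(self, t_2s):
        s = np.sin(2 * np.pi * 5 * t_2s) + 10.0
        ok, diag = is_imf(s)
        assert not ok and diag["n_zero_crossings"] == 0

    def test_zero_crossing_counting_rules(self):
        assert count_zero_crossings(np.array([1.0, -1.0, 1.0])) == 2
        assert count_zero_crossings(np.array([1.0, 0.0, -1.0])) == 1
        assert count_zero_crossings(np.ones(5)) == 0


class TestEMD:
    def test_constant_signal_is_all_trend(self):
        s = emd(np.full(64, 2.5), 120.0)
        assert s.n == 0
        np.testing.assert_allclose(s.trend, 2.5)

    def test_two_tone_separation(self, t_2s, fs):
        x = np.sin(2 * np.pi * 2 * t_2s) + np.sin(2 * np.pi * 20 * t_2s)
        s = emd(x, fs)
        assert s.n >= 2
        interior = slice(12, -12)
        f1 = np.nanmean(analyze_mode(s.imfs[0], fs).frequency[interior])
        f2 = np.nanmean(analyze_mode(s.imfs[1], fs).frequency[interior])
        assert abs(f1 - 20) / 20 <= 0.10
        assert abs(f2 - 2) / 2 <= 0.10

    def test_tone_plus_ramp_recovers_tone_and_linear_trend(self, t_2s, fs):
        tone = np.sin(2 * np.pi * 5 * t_2s)
        ramp = 3.0 * t_2s
        s = emd(tone + ramp, fs)
        interior = slice(12, -12)
        r = np.corrcoef(s.imfs[0][interior], tone[interior])[0, 1]
        assert r >= 0.99
        # remainder (everything but the fast tone) is close to the ramp
        rest = s.reconstruct() - s.imfs[0]
        assert np.corrcoef(rest[interior], ramp[interior])[0, 1] >= 0.99

    def test_non_finite_input_rejected(self):
        bad = np.ones(32)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            emd(bad, 120.0)

    def test_every_mode_passes_imf_check_and_count_is_bounded(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(256)
        s = emd(x, 1.0)
        assert s.n <= np.log2(x.size) + 2
        for m in s.imfs:
            assert is_imf(m)[0]

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        a, b = emd(x, 1.0), emd(x, 1.0)
        assert a.n == b.n
        for ma, mb in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ma, mb)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(64, 400))
def test_completeness_on_random_signals(seed, n):
    """x = sum(IMFs) + trend to machine precision, for arbitrary inputs."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) + np.linspace(0, rng.uniform(-2, 2), n)
    s = emd(x, 1.0)
    err = np.max(np.abs(s.reconstruct() - x)) / max(np.max(np.abs(x)), 1e-12)
    assert err <= 1e-9
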