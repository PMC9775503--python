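"""Wavelet bank, phase extraction, PLV, pulse normalization, level values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulselock import (
    build_wavelet_bank,
    compute_plv,
    extract_levels,
    normalize_to_pulse,
    wavelet_phase,
)
from pulselock.entrain import METRICAL_LEVELS, PhaseSeries, PLVMatrix


def naive_plv(th1, th2):
    """Direct-sum oracle for the phase-locking statistic."""
    C, K, N = th2.shape
    out = np.empty((C, K))
    for c in range(C):
        for k in range(K):
            acc = 0.0 + 0.0j
            for t in range(N):
                acc += np.exp(1j * (th1[k, t] - th2[c, k, t]))
            out[c, k] = abs(acc / N)
    return out


def make_series(th):
    return PhaseSeries(th, np.ones(th.shape, dtype=bool), 100.0)


class TestWaveletBank:
    def test_default_bank_shape_and_cycle_rule(self):
        bank = build_wavelet_bank(fs=250.0)
        assert len(bank) == 65
        assert np.allclose(bank.center_freqs, 0.25 * 2.0 ** (np.arange(65) / 15))
        # cycles: round(2f) clamped to [3, 8], non-decreasing
        assert bank.cycles.min() == 3 and bank.cycles.max() == 8
        k2 = np.argmin(abs(bank.center_freqs - 2.0))
        assert bank.cycles[k2] == 4
        assert np.all(np.diff(bank.cycles) >= 0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            build_wavelet_bank(fs=8.0)

    def test_kernels_are_zero_mean(self, bank250):
        for w in bank250.kernels:
            assert abs(w.sum()) < 1e-10


class TestWaveletPhase:
    def test_pure_cosine_phase_advance(self, bank250):
        fs = 250.0
        t = np.arange(0, 80, 1 / fs)
        ps = wavelet_phase(np.cos(2 * np.pi * 2.0 * t), bank250)
        k = np.argmin(abs(bank250.center_freqs - 2.0))
        dph = np.diff(np.unwrap(ps.phases[k][ps.valid[k]]))
        assert np.allclose(dph.mean(), 2 * np.pi * 2.0 / fs, rtol=1e-4)

    def test_delayed_copy_phase_offset(self, bank250):
        fs, T = 250.0, 0.1
        t = np.arange(0, 120, 1 / fs)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(t.size)  # flat spectrum
        d = int(T * fs)
        p1 = wavelet_phase(x[:-d], bank250)
        p2 = wavelet_phase(x[d:], bank250)  # advanced copy
        for k in (10, 30, 50):
            f = bank250.center_freqs[k]
            both = p1.valid[k] & p2.valid[k]
            dphi = np.angle(np.exp(1j * (p2.phases[k] - p1.phases[k])))[both]
            expect = np.angle(np.exp(1j * 2 * np.pi * f * T))
            assert abs(np.median(dphi) - expect) < 0.05

    def test_constant_signal_flagged_invalid(self, bank250):
        ps = wavelet_phase(np.full(8000, 3.0), bank250)
        assert not ps.valid.any()

    def test_too_short_signal_rejected(self, bank250):
        with pytest.raises(ValueError, match="shorter than the longest wavelet"):
            wavelet_phase(np.zeros(100), bank250)

    def test_fft_and_direct_convolution_agree(self):
        bank = build_wavelet_bank(fmin=1.0, fmax=4.0, fs=100.0)
        rng = np.random.default_rng(2)
        short = rng.standard_normal(int(2.0 * max(len(k) for k in bank.kernels)))
        long_ = np.concatenate([short] * 12)
        pd_ = wavelet_phase(short, bank)
        pf = wavelet_phase(long_, bank)
        n = short.size
        k = len(bank) // 2
        both = pd_.valid[k] & pf.valid[k][:n]
        assert np.allclose(pd_.phases[k][both], pf.phases[k][:n][both], atol=1e-8)


class TestPLV:
    def test_matches_naive_direct_sum(self, rng):
        for _ in range(20):
            C, K, N = rng.integers(1, 4), rng.integers(1, 8), rng.integers(10, 400)
            th1 = rng.uniform(-np.pi, np.pi, (K, N))
            th2 = rng.uniform(-np.pi, np.pi, (C, K, N))
            got = compute_plv(make_series(th1), make_series(th2)).values
            assert np.allclose(got, naive_plv(th1, th2), atol=1e-12)

    def test_identical_phases_lock_perfectly(self, rng):
        th = rng.uniform(-np.pi, np.pi, (5, 1000))
        plv = compute_plv(make_series(th), make_series(th[None].repeat(3, 0)))
        assert np.allclose(plv.values, 1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(-10.0, 10.0))
    def test_constant_offset_invariance(self, offset):
        rng = np.random.default_rng(7)
        th = rng.uniform(-np.pi, np.pi, (3, 200))
        p0 = compute_plv(make_series(th), make_series(th[None]))
        p1 = compute_plv(make_series(th), make_series(th[None] + offset))
        assert np.allclose(p0.values, p1.values, atol=1e-9)

    def test_symmetric_three_phase_cancellation(self):
        rel = np.tile([0.0, 2 * np.pi / 3, 4 * np.pi / 3], 100)
        th1 = np.zeros((1, rel.size))
        plv = compute_plv(make_series(th1), make_series(-rel[None, None, :]))
        assert plv.values[0, 0] < 1e-12

    def test_chance_level_scaling(self, rng):
        n, reps = 2000, 200
        d = rng.uniform(-np.pi, np.pi, (reps, n))
        vals = np.abs(np.mean(np.exp(1j * d), axis=1))
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert abs(vals.mean() - expect) < 4 * vals.std() / np.sqrt(reps)

    def test_misaligned_series_rejected(self, rng):
        th1 = rng.uniform(-np.pi, np.pi, (3, 100))
        th2 = rng.uniform(-np.pi, np.pi, (2, 3, 101))
        with pytest.raises(ValueError, match="misaligned"):
            compute_plv(make_series(th1), make_series(th2))


def bump_plv(bank, f0, width=0.08, height=0.8, floor=0.05):
    vals = floor + height * np.exp(-0.5 * ((np.log2(bank.center_freqs / f0)) / width) ** 2)
    return PLVMatrix(vals[None, :], np.full((1, len(bank)), 1000), bank.center_freqs)


class TestNormalization:
    def test_peak_at_detected_pulse_moves_to_two(self, bank250):
        plv = bump_plv(bank250, 2.5)
        norm = normalize_to_pulse(plv, bank250, 2.5)
        u_peak = norm.axis[np.nanargmax(norm.values[0])]
        assert u_peak == pytest.approx(2.0, abs=0.01)

    def test_pulse_two_is_identity_on_shared_grid(self, bank250):
        plv = bump_plv(bank250, 2.0)
        norm = normalize_to_pulse(plv, bank250, 2.0)
        shared = np.isin(np.round(np.log2(norm.axis) * 15).astype(int),
                         np.round(np.log2(bank250.center_freqs) * 15).astype(int))
        f_of_u = norm.axis[shared]
        expect = np.interp(np.log2(f_of_u), np.log2(bank250.center_freqs), plv.values[0])
        assert np.allclose(norm.values[0][shared], expect, atol=1e-9)

    def test_round_trip_recovers_curve(self, bank250):
        """Normalizing with pulse f, then re-normalizing the dimensionless
        curve (axis read as Hz) with pulse 4/f, lands every point back at
        its original frequency; shared log-grid points must match the
        original spectrum exactly."""
        from pulselock.entrain import WaveletBank

        f = 1.6
        # a smooth curve: the round trip is exact only up to the linear
        # interpolation of the two off-lattice resamplings
        plv = bump_plv(bank250, f, width=0.35)
        norm1 = normalize_to_pulse(plv, bank250, f)
        ok = np.isfinite(norm1.values[0])
        fake = WaveletBank(norm1.axis[ok], None, bank250.fs, [], None)
        norm2 = normalize_to_pulse(
            PLVMatrix(norm1.values[:, ok], None, fake.center_freqs), fake, 4.0 / f
        )
        # norm2 axis point u corresponds to original frequency u (in Hz)
        shared = np.isfinite(norm2.values[0]) & (norm2.axis >= bank250.center_freqs[0]) \
            & (norm2.axis <= bank250.center_freqs[-1])
        ref = np.interp(np.log2(norm2.axis[shared]),
                        np.log2(bank250.center_freqs), plv.values[0])
        assert np.allclose(norm2.values[0][shared], ref, atol=6e-3)

    def test_out_of_band_points_missing_not_extrapolated(self, bank250):
        norm = normalize_to_pulse(bump_plv(bank250, 2.0), bank250, 2.0)
        # u < 2*fmin/pulse maps below the measured band
        assert np.isnan(norm.values[0][norm.axis < 0.25 * 2 / 2.0 - 1e-9]).all()

    def test_nonpositive_pulse_rejected(self, bank250):
        with pytest.raises(ValueError):
            normalize_to_pulse(bump_plv(bank250, 2.0), bank250, 0.0)


class TestLevels:
    def test_flat_curve_gives_equal_levels(self, bank250):
        vals = np.full((2, len(bank250)), 0.3)
        plv = PLVMatrix(vals, None, bank250.center_freqs)
        lv = extract_levels(normalize_to_pulse(plv, bank250, 2.0))
        present = np.isfinite(lv.values)
        assert np.allclose(lv.values[present], 0.3, atol=1e-9)

    def test_pulse_coupling_dominates_off_pulse(self, bank250):
        lv = extract_levels(normalize_to_pulse(bump_plv(bank250, 2.0), bank250, 2.0))
        assert lv.level(2.0)[0] > 3 * lv.level(3.0)[0]

    def test_levels_outside_measured_band_missing(self, bank250):
        # pulse 2.5 Hz: harmonic level (u=4) maps to 5 Hz > measured 4.81 Hz
        lv = extract_levels(normalize_to_pulse(bump_plv(bank250, 2.5), bank250, 2.5))
        assert np.isnan(lv.level(4.0)[0]) and np.isnan(lv.level(5.0)[0])
        assert np.isfinite(lv.level(2.0)[0])

    def test_level_axis_is_the_metrical_ladder(self, bank250):
        lv = extract_levels(normalize_to_pulse(bump_plv(bank250, 2.0), bank250, 2.0))
        assert tuple(lv.levels) == METRICAL_LEVELS
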