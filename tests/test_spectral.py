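"""Sliding-window spectra, dominant-frequency picking, Quinn refinement."""

import numpy as np
import pytest

from respidepth.core_io import PipelineConfig, RespirationSignal
from respidepth.spectral import (
    dominant_frequency,
    quinn_refine,
    sliding_rate_estimates,
    window_spectrum,
    windowed_fft,
)


def sine(freq, fs=30.0, dur=48.0, amp=1.0, phase=0.3):
    t = np.arange(0, dur, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t + phase)


def dense_fft_peak(x, fs, f_lo=0.1, f_hi=1.5, pad=64):
    """Oracle: argmax of a heavily zero-padded FFT (dense frequency grid)."""
    x = x - x.mean()
    n = len(x) * pad
    spec = np.abs(np.fft.rfft(x, n))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    idx = np.flatnonzero(band)
    return freqs[idx[np.argmax(spec[idx])]], fs / n


def test_bin_spacing_is_reciprocal_window_length():
    freqs, _ = window_spectrum(sine(0.25, dur=48.0), 30.0)
    assert freqs[1] - freqs[0] == pytest.approx(1.0 / 48.0)
    freqs40, _ = window_spectrum(sine(0.25, dur=40.0), 30.0)
    assert freqs40[1] - freqs40[0] == pytest.approx(1.0 / 40.0)


def test_bin_aligned_sine_single_bin():
    freqs, amps = window_spectrum(sine(0.25), 30.0, "rectangular")
    k = int(round(0.25 * 48))
    assert amps[k] == pytest.approx(1.0, abs=1e-9)
    others = np.delete(amps, [0, k])
    assert np.max(others) < 1e-8


def test_hann_spectrum_matches_direct_dft_oracle():
    x = sine(0.26)
    freqs, amps = window_spectrum(x, 30.0, "hann")
    n = len(x)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)  # periodic Hann
    xd = (x - x.mean()) * w
    for k in [10, 12, 13, 14, 20]:  # around 0.26*48 = 12.48
        direct = sum(xd[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
        assert amps[k] == pytest.approx(2 * abs(direct) / w.sum(), rel=1e-9)
    # energy concentrated next to 0.26 Hz
    band = (freqs >= 0.1) & (freqs <= 1.5)
    assert abs(freqs[band][np.argmax(amps[band])] - 0.26) < 1.5 / 48


def test_dominant_frequency_amplitude_and_band():
    x = 2 * sine(0.25) + sine(0.5)
    freqs, amps = window_spectrum(x, 30.0)
    assert dominant_frequency(freqs, amps) == pytest.approx(0.25)
    # out-of-band sine: the in-band argmax of its leakage tail is returned
    y = sine(2.0)
    freqs, amps = window_spectrum(y, 30.0)
    f = dominant_frequency(freqs, amps)
    assert 0.1 <= f <= 1.5
    band = (freqs >= 0.1) & (freqs <= 1.5)
    assert f == freqs[band][np.argmax(amps[band])]
    with pytest.raises(ValueError):
        dominant_frequency(np.array([0.0, 5.0]), np.array([1.0, 1.0]), 0.1, 1.5)


def test_quinn_on_bin_centre_is_exact():
    x = sine(0.25)
    freqs, spec = windowed_fft(x, 30.0)
    k = int(round(0.25 * 48))
    assert quinn_refine(spec, k, 1 / 48.0) == pytest.approx(0.25, abs=1e-6)


def test_quinn_off_bin_accuracy():
    x = sine(0.26)
    freqs, spec = windowed_fft(x, 30.0)
    amps = np.abs(spec)
    band = (freqs >= 0.1) & (freqs <= 1.5)
    k = np.flatnonzero(band)[np.argmax(amps[band])]
    refined = quinn_refine(spec, int(k), 1 / 48.0)
    assert abs(refined - 0.26) < 0.005


def test_quinn_beats_bin_frequency_across_a_sweep():
    """Dense-FFT oracle sweep: refinement error < half a bin everywhere and
    smaller than the raw bin error off-centre."""
    fs, dur = 30.0, 48.0
    bin_spacing = 1 / dur
    rng = np.random.default_rng(3)
    for f_true in np.linspace(0.22, 0.22 + bin_spacing, 17):
        x = sine(f_true, fs, dur, phase=float(rng.uniform(0, 2 * np.pi)))
        freqs, spec = windowed_fft(x, fs)
        amps = np.abs(spec)
        band = (freqs >= 0.1) & (freqs <= 1.5)
        k = int(np.flatnonzero(band)[np.argmax(amps[band])])
        refined = quinn_refine(spec, k, bin_spacing)
        f_dense, dense_step = dense_fft_peak(x, fs)
        assert abs(refined - f_true) < bin_spacing / 2
        assert abs(refined - f_dense) < bin_spacing / 2
        bin_err = abs(k * bin_spacing - f_true)
        if bin_err > 0.1 * bin_spacing:
            assert abs(refined - f_true) < bin_err


def test_quinn_edge_bin_returns_unrefined():
    spec = np.array([1.0 + 0j, 2.0 + 0j, 0.5 + 0j])
    assert quinn_refine(spec, 0, 0.1) == 0.0
    assert quinn_refine(spec, 2, 0.1) == pytest.approx(0.2)


def test_sliding_window_count_formula():
    cfg = PipelineConfig(fft_window_len=48.0, fft_step=4.0)
    sig = RespirationSignal(values=sine(0.25, dur=300.0), sample_rate=30.0)
    ests = sliding_rate_estimates(sig, cfg)
    assert len(ests) == (300 - 48) // 4 + 1  # 64 windows
    assert all(e.dominant_bin_freq == pytest.approx(0.25) for e in ests)
    assert all(abs(e.refined_freq - e.dominant_bin_freq) <= 0.5 / 48 + 1e-12 for e in ests)


def test_sliding_window_detects_frequency_step():
    fs = 30.0
    t1 = np.arange(0, 150, 1 / fs)
    t2 = np.arange(0, 150, 1 / fs)
    x = np.concatenate(
        [np.sin(2 * np.pi * (1 / 6) * t1), np.sin(2 * np.pi * 0.25 * t2)]
    )
    cfg = PipelineConfig(fft_window_len=48.0, fft_step=4.0)
    ests = sliding_rate_estimates(RespirationSignal(values=x, sample_rate=fs), cfg)
    early = [e for e in ests if e.t_end <= 150]
    late = [e for e in ests if e.t_start >= 150]
    assert all(e.dominant_bin_freq == pytest.approx(1 / 6, abs=1e-9) for e in early)
    assert all(e.dominant_bin_freq == pytest.approx(0.25, abs=1e-9) for e in late)
    # transition windows report one of the two components
    mixed = [e for e in ests if e.t_start < 150 < e.t_end]
    for e in mixed:
        assert min(abs(e.dominant_bin_freq - 1 / 6), abs(e.dominant_bin_freq - 0.25)) < 1 / 48


def test_signal_shorter_than_window_raises():
    cfg = PipelineConfig(fft_window_len=48.0)
    sig = RespirationSignal(values=sine(0.25, dur=20.0), sample_rate=30.0)
    with pytest.raises(ValueError):
        sliding_rate_estimates(sig, cfg)
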