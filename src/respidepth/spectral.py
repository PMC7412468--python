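"""Sliding-window dominant-frequency estimation with Quinn refinement.

The breathing rate is the dominant in-band (default 0.1-1.5 Hz) frequency
of the extracted signal, estimated per sliding FFT window.  The FFT bin
frequency is refined with Quinn's second estimator, which interpolates the
true peak position between bins from the complex spectrum values at the
peak and its two neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .core_io import PipelineConfig, RespirationSignal

__all__ = [
    "RateWindowEstimate",
    "window_spectrum",
    "windowed_fft",
    "dominant_frequency",
    "quinn_refine",
    "sliding_rate_estimates",
]


@dataclass(frozen=True)
class RateWindowEstimate:
    """Dominant in-band frequency of one sliding FFT window."""

    t_start: float
    t_end: float
    dominant_bin_freq: float
    refined_freq: float
    peak_amplitude: float

    @property
    def dominant_bin_bpm(self) -> float:
        return self.dominant_bin_freq * 60.0

    @property
    def refined_bpm(self) -> float:
        return self.refined_freq * 60.0


def _taper(n: int, kind: str) -> np.ndarray:
    if kind == "rectangular":
        return np.ones(n)
    if kind == "hann":
        return windows.hann(n, sym=False)
    raise ValueError(f"unknown taper {kind!r}")


def windowed_fft(
    segment: np.ndarray, sample_rate: float, taper: str = "rectangular"
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed, tapered one-sided DFT: returns (frequencies, complex bins)."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or len(seg) < 2:
        raise ValueError("segment must be 1-D with at least 2 samples")
    w = _taper(len(seg), taper)
    spec = np.fft.rfft((seg - seg.mean()) * w)
    freqs = np.fft.rfftfreq(len(seg), d=1.0 / sample_rate)
    return freqs, spec


def window_spectrum(
    segment: np.ndarray, sample_rate: float, taper: str = "rectangular"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a (mean-removed, tapered) segment.

    Amplitudes are normalised so a unit-amplitude bin-aligned sine yields
    an amplitude of 1 at its bin; bin spacing is 1/window_duration.
    """
    freqs, spec = windowed_fft(segment, sample_rate, taper)
    w = _taper(len(np.asarray(segment)), taper)
    amps = 2.0 * np.abs(spec) / w.sum()
    amps[0] /= 2.0
    if len(np.asarray(segment)) % 2 == 0:
        amps[-1] /= 2.0
    return freqs, amps


def dominant_frequency(
    freqs: np.ndarray, amplitudes: np.ndarray, f_lo: float = 0.1, f_hi: float = 1.5
) -> float:
    """Frequency of the largest-amplitude bin inside [f_lo, f_hi].

    Ties resolve to the lowest frequency.
    """
    freqs = np.asarray(freqs)
    amplitudes = np.asarray(amplitudes)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        raise ValueError("no FFT bin falls inside the frequency band")
    idx = np.flatnonzero(band)
    return float(freqs[idx[np.argmax(amplitudes[idx])]])


def _quinn_tau(x: float) -> float:
    s = np.sqrt(6.0) / 24.0
    r = np.sqrt(2.0 / 3.0)
    return 0.25 * np.log(3 * x * x + 6 * x + 1) - s * np.log((x + 1 - r) / (x + 1 + r))


def quinn_refine(
    spectrum: np.ndarray,
    peak_bin: int,
    bin_spacing: float,
    f_lo: float | None = None,
    f_hi: float | None = None,
) -> float:
    """Quinn's second estimator: inter-bin refinement of a spectral peak.

    Uses the complex DFT values at bins (k-1, k, k+1).  The result is kept
    within half a bin of the peak bin and, when a band is given, clamped
    to it.  A peak at the spectrum edge is returned unrefined.
    """
    spec = np.asarray(spectrum)
    k = int(peak_bin)
    bin_freq = k * bin_spacing
    if k - 1 < 0 or k + 1 >= len(spec) or spec[k] == 0:
        refined = bin_freq
    else:
        ap = (spec[k + 1] / spec[k]).real
        am = (spec[k - 1] / spec[k]).real
        dp = -ap / (1.0 - ap) if ap != 1.0 else 0.0
        dm = am / (1.0 - am) if am != 1.0 else 0.0
        delta = 0.5 * (dp + dm) + _quinn_tau(dp * dp) - _quinn_tau(dm * dm)
        if not np.isfinite(delta):
            delta = 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        refined = (k + delta) * bin_spacing
    if f_lo is not None:
        refined = max(refined, f_lo)
    if f_hi is not None:
        refined = min(refined, f_hi)
    return float(refined)


def sliding_rate_estimates(
    signal: RespirationSignal, config: PipelineConfig
) -> list[RateWindowEstimate]:
    """Dominant and refined frequency for every sliding FFT window.

    Windows start at offsets 0, s, 2s, ... while fully inside the signal.
    """
    fs = signal.sample_rate
    n = len(signal)
    lw = int(round(config.fft_window_len * fs))
    step = int(round(config.fft_step * fs))
    if lw < 2 or step < 1:
        raise ValueError("window length and step too small for the sample rate")
    if n < lw:
        raise ValueError("signal shorter than one FFT window")
    estimates = []
    bin_spacing = fs / lw
    for off in range(0, n - lw + 1, step):
        seg = signal.values[off : off + lw]
        freqs, spec = windowed_fft(seg, fs, config.fft_taper)
        w = _taper(lw, config.fft_taper)
        amps = 2.0 * np.abs(spec) / w.sum()
        f_dom = dominant_frequency(freqs, amps, config.f_lo, config.f_hi)
        k = int(round(f_dom / bin_spacing))
        refined = quinn_refine(spec, k, bin_spacing, config.f_lo, config.f_hi)
        estimates.append(
            RateWindowEstimate(
                t_start=signal.t0 + off / fs,
                t_end=signal.t0 + (off + lw) / fs,
                dominant_bin_freq=f_dom,
                refined_freq=refined,
                peak_amplitude=float(amps[k]),
            )
        )
    return estimates
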