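"""Breathing-derived features for activity discrimination.

Seven descriptors of a breathing signal that separate breathing-specific
activities (paced meditation, relaxing, post-exercise recovery, speaking):
moments of the in-band amplitude spectrum (Std-Spec, Skew-Spec,
Kurt-Spec), the in-band SNR, the median inter-peak interval (Med-PP, the
time-domain period estimate), normalised spectral entropy (ESP: near 0 for
regular single-frequency breathing, near 1 for irregular), and the
standard deviation of the signal's first derivative (Std-Deriv).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core_io import PipelineConfig, RespirationSignal
from .evaluation import snr_db
from .spectral import window_spectrum

__all__ = ["FeatureVector", "compute_features", "feature_table"]


@dataclass(frozen=True)
class FeatureVector:
    std_spec: float
    skew_spec: float
    kurt_spec: float
    snr_db: float
    med_pp: float | None  # seconds; None when fewer than 2 peaks were found
    esp: float
    std_deriv: float  # mm/s

    def as_dict(self) -> dict:
        return {
            "std_spec": self.std_spec,
            "skew_spec": self.skew_spec,
            "kurt_spec": self.kurt_spec,
            "snr_db": self.snr_db,
            "med_pp": np.nan if self.med_pp is None else self.med_pp,
            "esp": self.esp,
            "std_deriv": self.std_deriv,
        }


def compute_features(
    signal: RespirationSignal, config: PipelineConfig | None = None
) -> FeatureVector:
    """Compute the seven-feature breathing descriptor of one signal.

    Spectral moments and ESP are computed over the in-band one-sided
    amplitude spectrum of the whole signal; the SNR uses the sliding-window
    measure.  Peaks for Med-PP are local maxima with prominence at least a
    quarter of the signal's standard deviation and minimum separation of
    one upper-cutoff period.
    """
    config = config or PipelineConfig()
    x = signal.values
    fs = signal.sample_rate
    freqs, amps = window_spectrum(x, fs, "rectangular")
    band = (freqs >= config.f_lo) & (freqs <= config.f_hi)
    if not band.any():
        raise ValueError("no in-band FFT bin; signal too short")
    a = amps[band]
    std_spec = float(np.std(a))
    skew_spec = float(stats.skew(a))
    kurt_spec = float(stats.kurtosis(a))

    power = a**2
    p = power / power.sum() if power.sum() > 0 else np.full_like(power, 1 / len(power))
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0))
    esp = float(h / np.log2(len(p))) if len(p) > 1 else 0.0

    min_dist = max(int(round(fs / config.f_hi)), 1)
    prominence = 0.25 * np.std(x)
    if prominence > 0:
        peaks, _ = sps.find_peaks(x, prominence=prominence, distance=min_dist)
    else:
        peaks = np.array([], dtype=int)
    med_pp = float(np.median(np.diff(peaks)) / fs) if len(peaks) >= 2 else None

    std_deriv = float(np.std(np.diff(x)) * fs)
    snr, _ = snr_db(signal, config)
    return FeatureVector(
        std_spec=std_spec,
        skew_spec=skew_spec,
        kurt_spec=kurt_spec,
        snr_db=snr,
        med_pp=med_pp,
        esp=esp,
        std_deriv=std_deriv,
    )


def feature_table(
    labelled_signals: list[tuple[str, RespirationSignal]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One feature row per labelled signal (label column first)."""
    rows = []
    for label, sig in labelled_signals:
        row = {"label": label}
        row.update(compute_features(sig, config).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
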