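"""Breathing-signal extraction from the torso model, baselines, filtering.

The motion-robust extractor takes, per frame, the difference between a
quasi-static reference (the 90th percentile of depth in a small throat
region, i.e. its farthest points, which suppresses a moving collar) and a
strongly breathing-affected region (the mean depth of the chest band).
Whole-body motion moves both regions equally and cancels; chest expansion
moves only the chest term.  The sign convention is inhalation-positive:
the chest moving nearer to the camera increases the signal.

Four baseline extractors (mean/median of the chest region, on raw window
cuts or on the recovered model states) are provided for comparison, plus
zero-phase Butterworth band-pass filtering of the extracted signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .core_io import JointSet, RespirationSignal, TorsoWindow

__all__ = [
    "RegionSpec",
    "make_regions",
    "extract_sample",
    "extract_signal",
    "baseline_sample",
    "baseline_signal",
    "bandpass",
    "BASELINE_METHODS",
]

BASELINE_METHODS = ("mean_raw", "median_raw", "mean_model", "median_model")


@dataclass(frozen=True)
class RegionSpec:
    """Chest and throat rectangles in window-fractional coordinates.

    Each rectangle is (x0, y0, x1, y1) with 0 <= x0 < x1 <= 1 and likewise
    for y, relative to the torso window.  The chest and throat must be
    disjoint.  ``throat_percentile`` selects how far into the far tail of
    the throat depth distribution the reference reaches.
    """

    chest: tuple[float, float, float, float]
    throat: tuple[float, float, float, float]
    throat_percentile: float = 90.0

    def __post_init__(self) -> None:
        for rect in (self.chest, self.throat):
            x0, y0, x1, y1 = rect
            if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
                raise ValueError(f"rectangle {rect} not inside the unit square")
        if not (0 < self.throat_percentile <= 100):
            raise ValueError("throat percentile must lie in (0, 100]")
        cx0, cy0, cx1, cy1 = self.chest
        tx0, ty0, tx1, ty1 = self.throat
        if cx0 < tx1 and tx0 < cx1 and cy0 < ty1 and ty0 < cy1:
            raise ValueError("chest and throat rectangles must be disjoint")

    def chest_slices(self, w: int, h: int) -> tuple[slice, slice]:
        return _rect_slices(self.chest, w, h)

    def throat_slices(self, w: int, h: int) -> tuple[slice, slice]:
        return _rect_slices(self.throat, w, h)


def _rect_slices(rect: tuple[float, float, float, float], w: int, h: int):
    x0, y0, x1, y1 = rect
    c0, c1 = int(np.floor(x0 * w)), max(int(np.ceil(x1 * w)), int(np.floor(x0 * w)) + 1)
    r0, r1 = int(np.floor(y0 * h)), max(int(np.ceil(y1 * h)), int(np.floor(y0 * h)) + 1)
    return slice(r0, min(r1, h)), slice(c0, min(c1, w))


def make_regions(
    window: TorsoWindow,
    joints: JointSet,
    chest_margin: float = 0.2,
    throat_width_frac: float = 0.2,
    throat_height_frac: float = 0.1,
    throat_percentile: float = 90.0,
) -> RegionSpec:
    """Derive the chest and throat rectangles from the window and joints.

    The chest band leaves ``chest_margin`` of the window width free on the
    left and right and spans vertically from the shoulder mid to the spine
    mid joint.  The throat rectangle is a small box centred on the neck
    joint (falling back to the top-centre of the window if the neck is
    invalid); if it would overlap the chest its bottom edge is trimmed.
    """
    if joints.is_valid("neck"):
        nx, ny = joints.get("neck")
        tcx = np.clip((nx - window.x) / window.w, 0.0, 1.0)
        tcy = np.clip((ny - window.y) / window.h, 0.0, 1.0)
    else:
        tcx, tcy = 0.5, 0.0
    if joints.is_valid("spine_shoulder") and joints.is_valid("spine_mid"):
        cy0 = np.clip((joints.get("spine_shoulder")[1] - window.y) / window.h, 0.0, 1.0)
        cy1 = np.clip((joints.get("spine_mid")[1] - window.y) / window.h, 0.0, 1.0)
    else:
        cy0, cy1 = 0.15, 0.55
    if cy1 - cy0 < 0.05:
        cy0, cy1 = 0.15, 0.55  # degenerate joint geometry: default band
    chest = (chest_margin, float(cy0), 1.0 - chest_margin, float(cy1))
    tx0 = float(np.clip(tcx - throat_width_frac / 2, 0.0, 1.0 - throat_width_frac))
    ty0 = float(np.clip(tcy - throat_height_frac / 2, 0.0, 1.0 - throat_height_frac))
    ty1 = ty0 + throat_height_frac
    if ty1 > cy0:  # keep the reference strictly above the chest band
        ty1 = float(cy0)
        ty0 = max(ty1 - throat_height_frac, 0.0)
    throat = (tx0, ty0, tx0 + throat_width_frac, ty1)
    return RegionSpec(chest=chest, throat=throat, throat_percentile=throat_percentile)


def extract_sample(model_state: np.ndarray, regions: RegionSpec) -> float:
    """Difference-based breathing sample (mm) from one model state.

    Returns ``throat_p90 - chest_mean``: inhalation (chest nearer, smaller
    depth) increases the value; common-mode body motion cancels.
    """
    state = np.asarray(model_state, dtype=float)
    h, w = state.shape
    chest = state[regions.chest_slices(w, h)]
    throat = state[regions.throat_slices(w, h)]
    if chest.size == 0 or throat.size == 0:
        raise ValueError("empty chest or throat region")
    return float(
        np.percentile(throat, regions.throat_percentile) - chest.mean()
    )


def extract_signal(
    states: Iterable[np.ndarray], regions: RegionSpec, sample_rate: float
) -> RespirationSignal:
    """Difference-based signal: one sample per model state."""
    values = [extract_sample(s, regions) for s in states]
    if len(values) < 2:
        raise ValueError("need at least two frames")
    return RespirationSignal(values=np.array(values), sample_rate=sample_rate)


def baseline_sample(
    image: np.ndarray,
    regions: RegionSpec,
    method: str,
    previous: float | None = None,
) -> float:
    """One chest-region baseline sample, negated to inhalation-positive.

    Raw variants receive raw window cuts and exclude hole (0) pixels from
    the statistic; if the chest region is entirely invalid the previous
    sample is carried forward.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    chest = img[regions.chest_slices(w, h)]
    if method.endswith("_raw"):
        chest = chest[chest > 0]
        if chest.size == 0:
            if previous is None:
                raise ValueError("chest region entirely invalid in first frame")
            return previous
    stat = np.mean if method.startswith("mean") else np.median
    return float(-stat(chest))


def baseline_signal(
    images: Sequence[np.ndarray],
    regions: RegionSpec,
    method: str,
    sample_rate: float,
) -> RespirationSignal:
    """Per-frame chest mean/median baseline over raw cuts or model states."""
    values: list[float] = []
    prev: float | None = None
    for img in images:
        prev = baseline_sample(img, regions, method, prev)
        values.append(prev)
    if len(values) < 2:
        raise ValueError("need at least two frames")
    return RespirationSignal(values=np.array(values), sample_rate=sample_rate)


def bandpass(
    signal: RespirationSignal,
    f_lo: float = 0.1,
    f_hi: float = 1.5,
    order: int = 5,
) -> RespirationSignal:
    """Zero-phase (forward-backward) Butterworth band-pass filter."""
    if signal.sample_rate <= 2 * f_hi:
        raise ValueError("sample rate must exceed twice the upper cutoff")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=signal.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.values)
    return RespirationSignal(values=filtered, sample_rate=signal.sample_rate, t0=signal.t0)
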