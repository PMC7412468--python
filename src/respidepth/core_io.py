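"""Shared domain types and file I/O for depth sequences, joints, and signals.

Conventions used throughout the package:

* Depth values are millimetres, stored as non-negative integers; a value of
  0 marks an invalid pixel (a "hole" caused by shadowing, reflective
  materials, or defective sensor pixels).
* Pixel coordinates are 0-based with ``x`` the column and ``y`` the row,
  origin at the top-left.  Windows are half-open: ``[x, x+w) x [y, y+h)``.
* A depth sequence on disk is a directory of 16-bit grayscale PNG frames
  plus a JSON ``manifest.json`` listing frame files, frame rate, and
  dimensions.  Joints and signals are plain CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REQUIRED_JOINTS",
    "DepthFrame",
    "JointSet",
    "TorsoWindow",
    "OcclusionMask",
    "RespirationSignal",
    "PipelineConfig",
    "FormatError",
    "read_depth_sequence",
    "write_depth_sequence",
    "read_joints",
    "write_joints",
    "read_signal",
    "write_signal",
    "load_config",
    "save_config",
]

#: The seven joints the torso tracker requires (anchor points for the
#: torso window: shoulders horizontally; neck, shoulder mid, spine mid and
#: hips vertically).
REQUIRED_JOINTS = (
    "neck",
    "shoulder_left",
    "shoulder_right",
    "spine_shoulder",
    "spine_mid",
    "hip_left",
    "hip_right",
)


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass
class DepthFrame:
    """A single depth image in millimetres with invalid-pixel semantics.

    ``pixels`` is a 2-D integer array; 0 means invalid.  ``timestamp`` is in
    seconds since the start of the sequence.
    """

    pixels: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError("depth frame must be a 2-D array")
        if np.any(self.pixels < 0):
            raise FormatError("depth values must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def invalid_mask(self) -> np.ndarray:
        """Boolean grid, True where the depth reading is a hole (0)."""
        return self.pixels == 0


@dataclass
class JointSet:
    """Named 2-D pixel coordinates of body joints with validity flags."""

    coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)

    def is_valid(self, name: str) -> bool:
        return bool(self.valid.get(name, False))

    def get(self, name: str) -> tuple[float, float]:
        if not self.is_valid(name):
            raise KeyError(f"joint {name!r} is not valid in this frame")
        return self.coords[name]

    def all_valid(self, names: Iterable[str] = REQUIRED_JOINTS) -> bool:
        return all(self.is_valid(n) for n in names)


@dataclass(frozen=True)
class TorsoWindow:
    """Fixed-size rectangular region tracking the torso across frames.

    ``x``/``y`` are the top-left corner (column, row); ``w``/``h`` are fixed
    after initialization, as is the aspect ratio ``h/w``.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("window dimensions must be positive")

    @property
    def aspect(self) -> float:
        return self.h / self.w

    def cut(self, pixels: np.ndarray) -> np.ndarray:
        """Extract the window region from a full frame."""
        return pixels[self.y : self.y + self.h, self.x : self.x + self.w]

    def clamped(self, frame_w: int, frame_h: int) -> "TorsoWindow":
        """Return a copy shifted (not resized) to lie inside the frame."""
        x = int(min(max(self.x, 0), frame_w - self.w))
        y = int(min(max(self.y, 0), frame_h - self.h))
        if x < 0 or y < 0:
            raise ValueError("window larger than frame")
        return replace(self, x=x, y=y)

    def moved_to(self, x: int, y: int) -> "TorsoWindow":
        return replace(self, x=int(x), y=int(y))


@dataclass
class OcclusionMask:
    """Binary grid over a torso window; 1/True marks occluded pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("occlusion mask must be 2-D")

    @property
    def any(self) -> bool:
        return bool(self.mask.any())

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RespirationSignal:
    """Uniformly sampled breathing time series in millimetres."""

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sample_rate


@dataclass
class PipelineConfig:
    """All tunable parameters of the processing chain.

    Depth/masking: ``z_threshold`` is the minimum distance (mm) a
    measurement must be in front of the model surface to count as an
    occlusion; ``halo_margin`` dilates the mask to absorb infrared halos on
    occluder edges.  Filtering: ``alpha``/``beta``/``gamma`` are the
    exponential smoothing factors of the state, velocity and acceleration
    recursions, ``damping`` reduces the double-exponential overshoot.
    Spectral: dominant frequencies are searched in ``[f_lo, f_hi]`` Hz with
    sliding FFT windows of ``fft_window_len`` seconds every ``fft_step``
    seconds.
    """

    z_threshold: float = 30.0
    halo_margin: int = 3
    init_avg_frames: int = 30
    alpha: float = 0.5
    beta: float = 0.9
    gamma: float = 0.9
    damping: float = 0.3
    width_factor: float = 1.2
    search_cap: int = 8
    median_fill_size: int = 5
    inpaint_sigma: float = 5.0
    chest_margin: float = 0.2
    throat_width_frac: float = 0.2
    throat_height_frac: float = 0.1
    throat_percentile: float = 90.0
    f_lo: float = 0.1
    f_hi: float = 1.5
    bandpass_order: int = 5
    fft_window_len: float = 48.0
    fft_step: float = 4.0
    fft_taper: str = "rectangular"
    sample_rate: float = 30.0
    snr_signal_halfwidth: int = 1
    snr_max_db: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.fft_window_len <= 0 or self.fft_step <= 0:
            raise ValueError("FFT window length and step must be positive")
        for name in ("alpha", "beta", "gamma", "damping"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"coefficient {name} must lie in [0, 1)")
        if self.fft_taper not in ("rectangular", "hann"):
            raise ValueError("fft_taper must be 'rectangular' or 'hann'")


# ---------------------------------------------------------------------------
# Depth sequences (PNG frames + JSON manifest)
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def write_depth_sequence(frames: Sequence[DepthFrame], path: str | Path) -> None:
    """Write frames as 16-bit grayscale PNGs plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, frame in enumerate(frames):
        name = f"frame_{i:06d}.png"
        arr = np.asarray(frame.pixels)
        if arr.max(initial=0) > np.iinfo(np.uint16).max:
            raise FormatError("depth value exceeds 16-bit range")
        iio.imwrite(path / name, arr.astype(np.uint16))
        entries.append({"file": name, "timestamp": float(frame.timestamp)})
    h, w = frames[0].pixels.shape if frames else (0, 0)
    ts = [e["timestamp"] for e in entries]
    rate = None
    if len(ts) >= 2:
        rate = (len(ts) - 1) / (ts[-1] - ts[0])
    manifest = {"width": int(w), "height": int(h), "frame_rate": rate, "frames": entries}
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))


def read_depth_sequence(path: str | Path) -> list[DepthFrame]:
    """Read a depth sequence directory, returning frames in timestamp order.

    16-bit PNG pixel values are interpreted as millimetres; 0 stays invalid.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise IOError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    frames = []
    expected = (manifest["height"], manifest["width"])
    entries = sorted(manifest["frames"], key=lambda e: e["timestamp"])
    prev_t = -np.inf
    for entry in entries:
        fp = path / entry["file"]
        if not fp.exists():
            raise IOError(f"missing frame file {entry['file']}")
        try:
            arr = iio.imread(fp)
        except Exception as exc:  # corrupt PNG
            raise IOError(f"corrupt frame file {entry['file']}: {exc}") from exc
        if arr.shape != tuple(expected):
            raise FormatError(
                f"frame {entry['file']} has shape {arr.shape}, manifest says {expected}"
            )
        t = float(entry["timestamp"])
        if t <= prev_t:
            raise FormatError("timestamps must be strictly increasing")
        prev_t = t
        frames.append(DepthFrame(pixels=arr.astype(np.uint16), timestamp=t))
    return frames


# ---------------------------------------------------------------------------
# Joints (CSV: frame_index, joint_name, x, y, valid)
# ---------------------------------------------------------------------------

def write_joints(joint_sets: Sequence[JointSet], path: str | Path) -> None:
    rows = []
    for i, js in enumerate(joint_sets):
        for name, (x, y) in js.coords.items():
            rows.append(
                {
                    "frame_index": i,
                    "joint_name": name,
                    "x": x,
                    "y": y,
                    "valid": int(js.is_valid(name)),
                }
            )
    pd.DataFrame(rows, columns=["frame_index", "joint_name", "x", "y", "valid"]).to_csv(
        path, index=False
    )


def read_joints(path: str | Path) -> list[JointSet]:
    """Read per-frame joint sets from CSV.

    Unknown joint names are ignored with a warning.  A required joint absent
    from every frame is a format error.
    """
    df = pd.read_csv(path)
    required_cols = {"frame_index", "joint_name", "x", "y", "valid"}
    if not required_cols.issubset(df.columns):
        raise FormatError(f"joints CSV needs columns {sorted(required_cols)}")
    unknown = set(df["joint_name"].unique()) - set(REQUIRED_JOINTS)
    if unknown:
        warnings.warn(f"ignoring unknown joint names: {sorted(unknown)}")
        df = df[df["joint_name"].isin(REQUIRED_JOINTS)]
    for name in REQUIRED_JOINTS:
        sub = df[df["joint_name"] == name]
        if sub.empty or not sub["valid"].astype(bool).any():
            raise FormatError(f"required joint {name!r} absent (or never valid)")
    n_frames = int(df["frame_index"].max()) + 1
    joint_sets = [JointSet() for _ in range(n_frames)]
    for row in df.itertuples():
        js = joint_sets[int(row.frame_index)]
        js.coords[row.joint_name] = (float(row.x), float(row.y))
        js.valid[row.joint_name] = bool(row.valid)
    return joint_sets


# ---------------------------------------------------------------------------
# Signals (CSV: time_s, value)
# ---------------------------------------------------------------------------

def write_signal(signal: RespirationSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": signal.times(), "value": signal.values}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_signal(path: str | Path, sample_rate: float | None = None) -> RespirationSignal:
    """Read a two-column (time_s, value) CSV.

    Irregular timestamps are linearly resampled to ``sample_rate`` (default:
    the median source rate).  A non-monotone time column is a format error.
    """
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise FormatError("signal CSV needs columns time_s, value")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("signal needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time column must be strictly increasing")
    if sample_rate is None:
        # span-based estimate is less sensitive to per-stamp rounding noise
        sample_rate = (len(t) - 1) / float(t[-1] - t[0])
    uniform = np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) and np.isclose(
        1.0 / dt[0], sample_rate, rtol=1e-6
    )
    if uniform:
        return RespirationSignal(values=v, sample_rate=sample_rate, t0=float(t[0]))
    grid = np.arange(t[0], t[-1] + 0.5 / sample_rate, 1.0 / sample_rate)
    grid = grid[grid <= t[-1] + 1e-12]
    return RespirationSignal(
        values=np.interp(grid, t, v), sample_rate=sample_rate, t0=float(t[0])
    )


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(config)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
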