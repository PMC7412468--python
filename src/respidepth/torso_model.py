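"""The adaptive per-pixel torso model.

The model holds, for every pixel of the torso window, a depth state (mm)
plus its first and second temporal derivatives (mm/frame, mm/frame^2).
Each incoming frame is predicted one step ahead; pixels measured more than
``z_threshold`` millimetres in front of the prediction are flagged as
occluded (occluders are always nearer than the torso they cover), the mask
is dilated by a halo margin, and the occluded region is reconstructed from
the model's memory plus in-painted context (normalized convolution with a
Gaussian kernel).  The state recursion is a damped double-exponential
filter that tracks each pixel with little delay while suppressing sensor
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import DepthFrame, OcclusionMask, TorsoWindow

__all__ = [
    "TorsoModel",
    "initialize",
    "predict",
    "occlusion_mask",
    "normalized_convolution_inpaint",
    "occlusion_recovery",
    "update",
    "step_with_recovery",
]


@dataclass
class TorsoModel:
    """Per-pixel state, velocity, acceleration and filter coefficients."""

    state: np.ndarray  # depth estimate, mm
    vel: np.ndarray  # mm per frame
    acc: np.ndarray  # mm per frame^2
    alpha: float = 0.5
    beta: float = 0.9
    gamma: float = 0.9
    damping: float = 0.3

    def __post_init__(self) -> None:
        if not (self.state.shape == self.vel.shape == self.acc.shape):
            raise ValueError("state, vel, acc grids must share dimensions")
        for name in ("alpha", "beta", "gamma", "damping"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"coefficient {name} must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    def copy(self) -> "TorsoModel":
        return TorsoModel(
            state=self.state.copy(),
            vel=self.vel.copy(),
            acc=self.acc.copy(),
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            damping=self.damping,
        )


def initialize(
    frame: DepthFrame,
    window: TorsoWindow,
    alpha: float = 0.5,
    beta: float = 0.9,
    gamma: float = 0.9,
    damping: float = 0.3,
    median_fill_size: int = 5,
) -> TorsoModel:
    """Initialise the model from the window cut of the first frame.

    Zero-valued holes are replaced by the median of the valid pixels in a
    k x k neighbourhood, repeated until no holes remain.  Derivatives start
    at zero and converge over the first frames.
    """
    cut = window.cut(frame.pixels).astype(float)
    holes = cut == 0
    if holes.all():
        raise ValueError("window contains no valid pixels; cannot initialise")
    state = _median_fill(cut, holes, median_fill_size)
    zeros = np.zeros_like(state)
    return TorsoModel(
        state=state,
        vel=zeros.copy(),
        acc=zeros.copy(),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        damping=damping,
    )


def _median_fill(image: np.ndarray, holes: np.ndarray, size: int) -> np.ndarray:
    out = image.copy()
    holes = holes.copy()
    r = size // 2
    while holes.any():
        progressed = False
        remaining = holes.copy()
        ys, xs = np.nonzero(holes)
        for y, x in zip(ys, xs):
            nb = out[max(y - r, 0) : y + r + 1, max(x - r, 0) : x + r + 1]
            nb_holes = holes[max(y - r, 0) : y + r + 1, max(x - r, 0) : x + r + 1]
            vals = nb[~nb_holes]
            if vals.size:
                out[y, x] = np.median(vals)
                remaining[y, x] = False
                progressed = True
        holes = remaining
        if not progressed:
            raise RuntimeError("median fill made no progress")  # pragma: no cover
    return out


def predict(model: TorsoModel) -> np.ndarray:
    """One-step-ahead prediction: x + x' + 0.5 x'' per pixel, floored at 0."""
    return np.maximum(model.state + model.vel + 0.5 * model.acc, 0.0)


def occlusion_mask(
    window_cut: np.ndarray,
    prediction: np.ndarray,
    z_threshold: float = 30.0,
    halo_margin: int = 3,
) -> OcclusionMask:
    """Flag pixels measured more than ``z_threshold`` mm before the model.

    Occluding entities lie in front of the torso, so their depth readings
    are smaller than the predicted surface; pixels with
    ``prediction - measurement > z_threshold`` are masked.  Invalid (0)
    readings are masked too.  The mask is then dilated by ``halo_margin``
    pixels (square structuring element) to absorb infrared halos on the
    occluder edges.
    """
    cut = np.asarray(window_cut, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if cut.shape != pred.shape:
        raise ValueError("window cut and prediction must share dimensions")
    mask = (pred - cut > z_threshold) | (cut == 0)
    if halo_margin > 0 and mask.any():
        mask = ndimage.maximum_filter(mask, size=2 * halo_margin + 1, mode="constant")
    return OcclusionMask(mask=mask)


def _gaussian_kernel(sigma: float) -> np.ndarray:
    radius = max(int(np.ceil(3.0 * sigma)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _separable_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    tmp = ndimage.convolve1d(image, kernel, axis=0, mode="constant", cval=0.0)
    return ndimage.convolve1d(tmp, kernel, axis=1, mode="constant", cval=0.0)


def normalized_convolution_inpaint(
    image: np.ndarray, validity: np.ndarray, kernel_sigma: float = 5.0
) -> np.ndarray:
    """Fill invalid pixels by normalized convolution with a Gaussian kernel.

    Invalid pixels become ``(G * (image . validity)) / (G * validity)``;
    valid pixels are returned unchanged.  If the kernel support does not
    reach some invalid pixels the procedure is iterated with the filled
    pixels counted as valid and, when necessary, a doubled kernel width,
    until full coverage.
    """
    img = np.asarray(image, dtype=float)
    valid = np.asarray(validity).astype(bool)
    if img.shape != valid.shape:
        raise ValueError("image and validity must share dimensions")
    if not valid.any():
        raise ValueError("normalized convolution requires at least one valid pixel")
    out = img.copy()
    sigma = float(kernel_sigma)
    while not valid.all():
        kernel = _gaussian_kernel(sigma)
        num = _separable_convolve(np.where(valid, out, 0.0), kernel)
        den = _separable_convolve(valid.astype(float), kernel)
        reachable = (~valid) & (den > 1e-12)
        if not reachable.any():
            sigma *= 2.0  # grow support until the hole interior is reached
            continue
        out[reachable] = num[reachable] / den[reachable]
        valid = valid | reachable
    return out


def occlusion_recovery(
    partly_updated: np.ndarray,
    prev_state: np.ndarray,
    mask: OcclusionMask | np.ndarray,
    kernel_sigma: float = 5.0,
) -> np.ndarray:
    """Reconstruct the occluded region from model memory plus context.

    The partly updated state (holes at the masked pixels) is in-painted.
    The previous state is split into the model cut (unmasked) and the model
    patch (masked); the cut is in-painted over the mask with the identical
    method.  The difference between the patch and the in-painted cut
    carries the torso surface detail, and is added onto the in-painted
    update at the masked pixels.  Unmasked pixels pass through unchanged.
    With a fully occluded window the previous state's patch is used
    verbatim.
    """
    m = mask.mask if isinstance(mask, OcclusionMask) else np.asarray(mask, dtype=bool)
    upd = np.asarray(partly_updated, dtype=float)
    prev = np.asarray(prev_state, dtype=float)
    if not (upd.shape == prev.shape == m.shape):
        raise ValueError("partly_updated, prev_state and mask must share dimensions")
    if not m.any():
        return upd.copy()
    if m.all():
        return prev.copy()  # full occlusion: keep the model's memory
    valid = ~m
    inpainted_update = normalized_convolution_inpaint(upd, valid, kernel_sigma)
    inpainted_cut = normalized_convolution_inpaint(prev, valid, kernel_sigma)
    out = upd.copy()
    out[m] = inpainted_update[m] + (prev[m] - inpainted_cut[m])
    return out


def update(model: TorsoModel, measurement: np.ndarray) -> TorsoModel:
    """Apply the damped double-exponential recursion to every pixel.

    state:    x_t  = a (x_{t-1} + x'_{t-1} + 0.5 x''_{t-1}) + (1-a) m_t
    velocity: x'_t = b x'_{t-1} + (1-b) (x_t - x_{t-1})
    accel.:   x''_t = g x''_{t-1} + (1-g) ((x_t - x_{t-1} - x'_{t-1}) - d x'_{t-1})

    The measurement must be hole-free (holes are handled upstream by
    masking and occlusion recovery).  Mutates and returns ``model``.
    """
    meas = np.asarray(measurement, dtype=float)
    if meas.shape != model.shape:
        raise ValueError("measurement dimensions do not match the model")
    new_state = model.alpha * predict(model) + (1.0 - model.alpha) * meas
    _advance(model, np.maximum(new_state, 0.0))
    return model


def _advance(model: TorsoModel, new_state: np.ndarray) -> None:
    """Commit a new state and refresh derivatives through the recursions."""
    dx = new_state - model.state
    new_vel = model.beta * model.vel + (1.0 - model.beta) * dx
    new_acc = model.gamma * model.acc + (1.0 - model.gamma) * (
        (dx - model.vel) - model.damping * model.vel
    )
    model.state = new_state
    model.vel = new_vel
    model.acc = new_acc


def step_with_recovery(
    model: TorsoModel,
    window_cut: np.ndarray,
    mask: OcclusionMask,
    kernel_sigma: float = 5.0,
) -> TorsoModel:
    """One model step for a frame that may contain occluded pixels.

    Unmasked pixels follow the ordinary filter update; masked pixels are
    reconstructed by occlusion recovery and the recovered state is fed
    through the derivative recursions so velocity and acceleration stay
    consistent.
    """
    meas = np.asarray(window_cut, dtype=float)
    if meas.shape != model.shape:
        raise ValueError("window cut dimensions do not match the model")
    partly = model.alpha * predict(model) + (1.0 - model.alpha) * meas
    if mask.any:
        new_state = occlusion_recovery(partly, model.state, mask, kernel_sigma)
    else:
        new_state = partly
    _advance(model, np.maximum(new_state, 0.0))
    return model
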