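"""Torso-window localisation and stabilisation.

The window is anchored on the skeleton joints (shoulders horizontally;
neck, shoulder mid, spine mid and hips vertically) but joint estimates
jitter between neighbouring pixels.  To stabilise the window, every integer
position between the previous window position and the joint-derived one is
considered a candidate, and the candidate whose content best matches the
torso model's prediction (sum of squared differences over non-occluded
pixels) wins.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .core_io import DepthFrame, JointSet, OcclusionMask, TorsoWindow

__all__ = [
    "TrackingError",
    "initial_torso_window",
    "joint_window",
    "candidate_windows",
    "best_fit_window",
]


class TrackingError(RuntimeError):
    pass


def _round(v: float) -> int:
    """Round half up (keeps equal joint shifts giving equal window shifts)."""
    return int(np.floor(v + 0.5))


def _anchor(joints: JointSet) -> tuple[float, float, float, float]:
    """Return (centre_x, top_y, shoulder_span, neck_to_hip_height)."""
    sl = joints.get("shoulder_left")
    sr = joints.get("shoulder_right")
    neck = joints.get("neck")
    hl = joints.get("hip_left")
    hr = joints.get("hip_right")
    span = abs(sr[0] - sl[0])
    cx = 0.5 * (sl[0] + sr[0])
    hip_y = 0.5 * (hl[1] + hr[1])
    return cx, neck[1], span, hip_y - neck[1]


def initial_torso_window(
    joints: JointSet, frame: DepthFrame, width_factor: float = 1.2
) -> TorsoWindow:
    """Initialise the torso window from the joints of the first frame.

    Width is the shoulder span scaled by ``width_factor`` (the shoulder
    joints sit inside the body silhouette); height spans neck to hip mid.
    The aspect ratio is fixed from here on.  The window is clamped inside
    the frame.
    """
    if not joints.all_valid():
        raise TrackingError("required joints invalid; cannot initialise window")
    cx, top_y, span, height = _anchor(joints)
    w = _round(span * width_factor)
    h = _round(height)
    if w <= 0 or h <= 0:
        raise TrackingError("degenerate joint geometry")
    win = TorsoWindow(x=_round(cx - w / 2.0), y=_round(top_y), w=w, h=h)
    return win.clamped(frame.width, frame.height)


def joint_window(joints: JointSet, prev: TorsoWindow) -> TorsoWindow:
    """Re-anchor the previous window at the current joint positions.

    The window keeps its fixed (w, h).  If any required joint is invalid
    the previous window is returned unchanged.
    """
    if not joints.all_valid():
        return prev
    cx, top_y, _, _ = _anchor(joints)
    return prev.moved_to(_round(cx - prev.w / 2.0), _round(top_y))


def candidate_windows(
    prev: TorsoWindow, current: TorsoWindow, search_cap: int = 8
) -> list[TorsoWindow]:
    """All integer window positions between the previous and current window.

    Returns the Cartesian product of x in [min, max] and y in [min, max]
    (inclusive).  To bound the cost when joints jump far, an axis whose
    span exceeds ``search_cap`` falls back to a full +-search_cap sweep
    around the previous position (re-acquisition rather than a one-sided
    chase of a possibly misdetected joint).
    """
    if (prev.w, prev.h) != (current.w, current.h):
        raise ValueError("candidate windows require identical dimensions")

    def axis_range(p: int, c: int) -> tuple[int, int]:
        if abs(c - p) > search_cap:
            return p - search_cap, p + search_cap
        return min(p, c), max(p, c)

    x_lo, x_hi = axis_range(prev.x, current.x)
    y_lo, y_hi = axis_range(prev.y, current.y)
    return [
        prev.moved_to(x, y)
        for y in range(y_lo, y_hi + 1)
        for x in range(x_lo, x_hi + 1)
    ]


def best_fit_window(
    frame: DepthFrame,
    candidates: Sequence[TorsoWindow],
    prediction: np.ndarray,
    mask_fn: Callable[[np.ndarray], OcclusionMask],
    prev: TorsoWindow | None = None,
) -> tuple[TorsoWindow, OcclusionMask]:
    """Select the candidate window best matching the model prediction.

    The energy of a candidate is the sum over its non-occluded pixels of
    the squared difference between the frame content and the prediction;
    occluded pixels (per ``mask_fn``, which computes each candidate's
    occlusion mask) are ignored so that occluders cannot push the window
    away from the torso.  A fully masked candidate gets infinite energy
    unless every candidate is fully masked.  Ties are broken by Euclidean
    distance to the previous position, then row-major order.
    """
    if not candidates:
        raise TrackingError("empty candidate list")
    pred = np.asarray(prediction, dtype=float)
    ref = prev if prev is not None else candidates[0]
    fh, fw = frame.pixels.shape
    energies = np.empty(len(candidates))
    masks: list[OcclusionMask] = []
    oob = np.zeros(len(candidates), dtype=bool)
    for i, cand in enumerate(candidates):
        if cand.x < 0 or cand.y < 0 or cand.x + cand.w > fw or cand.y + cand.h > fh:
            oob[i] = True
            energies[i] = np.inf
            masks.append(OcclusionMask(mask=np.ones((cand.h, cand.w), dtype=bool)))
            continue
        cut = cand.cut(frame.pixels).astype(float)
        mask = mask_fn(cut)
        masks.append(mask)
        valid = ~mask.mask
        if not valid.any():
            energies[i] = np.inf
        else:
            d = cut[valid] - pred[valid]
            energies[i] = float(d @ d)
    if oob.all():
        raise TrackingError("no candidate window fits inside the frame")
    if np.isinf(energies).all():
        # all in-bounds candidates fully masked: tie-break decides
        energies = np.where(oob, np.inf, 0.0)
    # argmin with distance-to-previous then row-major tie-breaking
    dist2 = np.array(
        [(c.x - ref.x) ** 2 + (c.y - ref.y) ** 2 for c in candidates], dtype=float
    )
    order = np.array([(c.y, c.x) for c in candidates])
    keys = np.lexsort((order[:, 1], order[:, 0], dist2, energies))
    best = int(keys[0])
    return candidates[best], masks[best]
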