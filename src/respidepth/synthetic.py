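"""Seeded synthetic depth-scene generator.

Renders a breathing torso as seen by a front-facing depth camera at about
2 m: a smooth convex (half-cylinder) torso surface whose chest/abdomen
pixels oscillate towards the camera by ~10 mm per breath, a flat and
quasi-static throat/head strip used as the motion reference, optional
whole-body sway (common-mode depth offset plus a small lateral drift), an
optional hand-held occluder (a disk a few hundred mm in front of the
torso, following a slow repeated raising gesture), Gaussian depth noise
that grows with the square of the distance, salt-and-pepper holes (zeroed
pixels), and jittering joint estimates.

All randomness flows from a single seed.  Random draws are consumed in a
fixed order independent of which features are enabled, so two sequences
generated with the same seed but, say, the occluder toggled differ only at
the occluder pixels.  The returned ground truth is the noiseless
chest-centre displacement trace in millimetres (inhalation positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DepthFrame, JointSet, RespirationSignal, REQUIRED_JOINTS

__all__ = [
    "SwayConfig",
    "OccluderConfig",
    "SceneConfig",
    "paced_rate",
    "generate_sequence",
    "sitting_preset",
    "standing_preset",
    "drinking_preset",
]


def paced_rate(nominal_hz: float) -> float:
    """Map a nominal paced-breathing rate to its exact frequency.

    The two paced rates used in the studies are 10 and 15 breaths per
    minute, usually quoted rounded as 0.17 Hz and 0.25 Hz.  10 bpm is
    exactly 1/6 Hz; the rounded 0.17 would not be bin-aligned for a 48 s
    FFT window, so the exact value is substituted.
    """
    if abs(nominal_hz - 0.17) < 0.006:
        return 1.0 / 6.0
    return float(nominal_hz)


@dataclass(frozen=True)
class SwayConfig:
    """Whole-body sway: slow sinusoid plus a bounded random walk.

    The depth component is applied to every body pixel (common mode); the
    lateral component drifts the body sideways by a few pixels.
    """

    enabled: bool = False
    amplitude_mm: float = 10.0
    frequency_hz: float = 0.1
    walk_step_mm: float = 0.5
    walk_bound_mm: float = 15.0
    lateral_px: float = 2.0
    lateral_frequency_hz: float = 0.07


@dataclass(frozen=True)
class OccluderConfig:
    """Hand-held occluding disk in front of the torso.

    ``mode='gesture'`` raises the disk from below the torso to the chest
    and back once per ``period_s`` (a slow drinking-like gesture);
    ``mode='static'`` holds it at a fixed centre.  A thin halo ring at
    intermediate depth emulates infrared interference on occluder edges.
    """

    enabled: bool = False
    radius_px: float = 15.0
    offset_mm: float = 400.0
    t_start_s: float = 20.0
    t_end_s: float = np.inf
    period_s: float = 8.0
    mode: str = "gesture"
    center: tuple[float, float] | None = None
    halo_px: float = 1.0
    halo_offset_mm: float | None = None


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of one synthetic recording."""

    distance_mm: float = 2000.0
    frame_width: int = 112
    frame_height: int = 152
    torso_width_px: int = 60
    torso_height_px: int = 92
    shoulder_span_frac: float = 0.73  # shoulder joints sit inside the silhouette
    bulge_mm: float = 80.0
    breathing_amplitude_mm: float = 10.0
    breathing_frequency_hz: float = 0.25
    weight_ramp_frac: float = 0.15  # vertical ramp-in of breathing below shoulders
    weight_lateral_flat_frac: float = 0.6
    sway: SwayConfig = field(default_factory=SwayConfig)
    occluder: OccluderConfig = field(default_factory=OccluderConfig)
    noise_sigma0_mm: float = 1.5  # sigma at 2000 mm; scales with (d/2000)^2
    hole_probability: float = 0.002
    joint_jitter_px: float = 1.5
    duration_s: float = 300.0
    frame_rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breathing_amplitude_mm < 0:
            raise ValueError("breathing amplitude must be >= 0")
        if not (0.0 <= self.hole_probability < 1.0):
            raise ValueError("hole probability must lie in [0, 1)")
        if not (0.0 < self.breathing_frequency_hz < self.frame_rate_hz / 2):
            raise ValueError("breathing frequency must lie in (0, frame_rate/2)")
        if self.occluder.enabled and (
            2 * self.occluder.radius_px > min(self.frame_width, self.frame_height)
        ):
            raise ValueError("occluder larger than frame")

    # -- derived scene layout (all in pixels) -------------------------------
    @property
    def center_x(self) -> float:
        return self.frame_width / 2.0

    @property
    def y_shoulder(self) -> int:
        return max(28, (self.frame_height - self.torso_height_px) // 2)

    @property
    def y_hip(self) -> int:
        return self.y_shoulder + self.torso_height_px

    @property
    def y_neck(self) -> int:
        return self.y_shoulder - 12

    @property
    def shoulder_span_px(self) -> float:
        return self.shoulder_span_frac * self.torso_width_px

    @property
    def noise_sigma_mm(self) -> float:
        return self.noise_sigma0_mm * (self.distance_mm / 2000.0) ** 2

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def _vertical_weights(config: SceneConfig) -> np.ndarray:
    """Breathing weight per torso row: 0 at the shoulder line, ramping to 1."""
    n = config.torso_height_px + 1
    rel = np.arange(n) / max(config.torso_height_px, 1)
    ramp = np.clip(rel / max(config.weight_ramp_frac, 1e-9), 0.0, 1.0)
    return ramp


def _lateral_weights(u_over_r: np.ndarray, flat_frac: float) -> np.ndarray:
    """Breathing weight across the torso: 1 in the middle, cosine taper at the edge."""
    a = np.abs(u_over_r)
    w = np.ones_like(a)
    taper = a > flat_frac
    w[taper] = 0.5 * (1 + np.cos(np.pi * (a[taper] - flat_frac) / (1 - flat_frac)))
    w[a >= 1.0] = 0.0
    return w


def render_clean_frame(
    config: SceneConfig,
    t: float,
    sway_z_mm: float = 0.0,
    sway_x_px: float = 0.0,
    occluder_on: bool = True,
) -> np.ndarray:
    """Render one noiseless, hole-free depth frame (float mm)."""
    H, W = config.frame_height, config.frame_width
    depth = np.full((H, W), config.distance_mm + 1500.0)
    cx = config.center_x + sway_x_px
    cols = np.arange(W, dtype=float)
    R = config.torso_width_px / 2.0
    u = (cols - cx) / R

    # head / throat strip: flat, static (breathing weight 0), slightly nearer;
    # half-width 0.35 R ~ 12 cm at the default scale, a realistic neck width
    head_cols = np.abs(u) <= 0.35
    y_head_top = max(config.y_neck - 16, 0)
    depth[y_head_top : config.y_shoulder + 1, head_cols] = (
        config.distance_mm - 40.0 + sway_z_mm
    )

    # torso: half-cylinder bulge + breathing displacement
    inside = np.abs(u) < 1.0
    bulge = np.zeros(W)
    bulge[inside] = config.bulge_mm * np.sqrt(1.0 - u[inside] ** 2)
    disp = config.breathing_amplitude_mm * np.sin(
        2 * np.pi * config.breathing_frequency_hz * t
    )
    w_lat = _lateral_weights(u, config.weight_lateral_flat_frac)
    w_vert = _vertical_weights(config)
    rows = slice(config.y_shoulder, config.y_hip + 1)
    weight = np.outer(w_vert, w_lat[inside])
    depth[rows, inside] = (
        config.distance_mm
        - bulge[inside][None, :]
        + sway_z_mm
        - disp * weight
    )

    if occluder_on and config.occluder.enabled:
        occ = config.occluder
        if occ.t_start_s <= t < occ.t_end_s:
            if occ.mode == "static" and occ.center is not None:
                ox, oy = occ.center
            else:
                phase = 0.5 * (1 - np.cos(2 * np.pi * (t - occ.t_start_s) / occ.period_s))
                y_base = min(config.y_hip + 12, H - 1)
                y_chest = 0.5 * (config.y_shoulder + config.y_hip) - 6
                ox = cx + 4.0
                oy = y_base - phase * (y_base - y_chest)
            yy, xx = np.ogrid[:H, :W]
            r2 = (xx - ox) ** 2 + (yy - oy) ** 2
            occ_depth = config.distance_mm - occ.offset_mm
            if occ.halo_px > 0:
                halo_depth = (
                    occ.halo_offset_mm
                    if occ.halo_offset_mm is not None
                    else config.distance_mm - occ.offset_mm / 2.0
                )
                halo = r2 <= (occ.radius_px + occ.halo_px) ** 2
                depth[halo] = np.minimum(depth[halo], halo_depth)
            disk = r2 <= occ.radius_px**2
            depth[disk] = occ_depth
    return depth


def _joint_layout(config: SceneConfig, cx: float) -> dict[str, tuple[float, float]]:
    span = config.shoulder_span_px
    y_mid = 0.5 * (config.y_shoulder + config.y_hip)
    return {
        "neck": (cx, float(config.y_neck)),
        "shoulder_left": (cx - span / 2.0, float(config.y_shoulder)),
        "shoulder_right": (cx + span / 2.0, float(config.y_shoulder)),
        "spine_shoulder": (cx, float(config.y_shoulder)),
        "spine_mid": (cx, y_mid),
        "hip_left": (cx - 0.35 * span, float(config.y_hip)),
        "hip_right": (cx + 0.35 * span, float(config.y_hip)),
    }


def generate_sequence(
    config: SceneConfig,
) -> tuple[list[DepthFrame], list[JointSet], RespirationSignal]:
    """Generate one synthetic recording: depth frames, joints, ground truth.

    Deterministic for a given ``config`` (which includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    fps = config.frame_rate_hz
    H, W = config.frame_height, config.frame_width

    # Random-walk sway components are always drawn (kept at zero when sway
    # is disabled) so the rng stream does not depend on the toggle.
    steps_z = rng.normal(0.0, config.sway.walk_step_mm, size=n)
    steps_x = rng.normal(0.0, config.sway.walk_step_mm / 4.0, size=n)
    phase_z = rng.uniform(0, 2 * np.pi)
    phase_x = rng.uniform(0, 2 * np.pi)
    if config.sway.enabled:
        walk_z = np.clip(
            np.cumsum(steps_z), -config.sway.walk_bound_mm, config.sway.walk_bound_mm
        )
        walk_x = np.clip(np.cumsum(steps_x), -3.0, 3.0)
        t_arr = np.arange(n) / fps
        sway_z = (
            config.sway.amplitude_mm
            * np.sin(2 * np.pi * config.sway.frequency_hz * t_arr + phase_z)
            + walk_z
        )
        sway_x = (
            config.sway.lateral_px
            * np.sin(2 * np.pi * config.sway.lateral_frequency_hz * t_arr + phase_x)
            + walk_x
        )
    else:
        sway_z = np.zeros(n)
        sway_x = np.zeros(n)

    sigma = config.noise_sigma_mm
    frames: list[DepthFrame] = []
    joints: list[JointSet] = []
    for i in range(n):
        t = i / fps
        depth = render_clean_frame(config, t, sway_z[i], sway_x[i])
        jitter = config.joint_jitter_px * rng.normal(
            0.0, 1.0, size=(len(REQUIRED_JOINTS), 2)
        )
        noise = rng.normal(0.0, 1.0, size=(H, W))
        holes = rng.random(size=(H, W)) < config.hole_probability
        depth = depth + sigma * noise
        pixels = np.clip(np.rint(depth), 1, np.iinfo(np.uint16).max).astype(np.uint16)
        pixels[holes] = 0
        frames.append(DepthFrame(pixels=pixels, timestamp=t))

        layout = _joint_layout(config, config.center_x + sway_x[i])
        js = JointSet()
        for k, name in enumerate(REQUIRED_JOINTS):
            x, y = layout[name]
            jx = float(np.clip(x + jitter[k, 0], 0, W - 1))
            jy = float(np.clip(y + jitter[k, 1], 0, H - 1))
            js.coords[name] = (jx, jy)
            js.valid[name] = True
        joints.append(js)

    truth = RespirationSignal(
        values=config.breathing_amplitude_mm
        * np.sin(2 * np.pi * config.breathing_frequency_hz * np.arange(n) / fps),
        sample_rate=fps,
    )
    return frames, joints, truth


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

def sitting_preset(rate_hz: float = 0.25, duration_s: float = 300.0, seed: int = 0) -> SceneConfig:
    """Seated user: no sway, no occluder (chair-supported posture)."""
    return SceneConfig(
        breathing_frequency_hz=paced_rate(rate_hz),
        duration_s=duration_s,
        seed=seed,
    )


def standing_preset(rate_hz: float = 0.25, duration_s: float = 300.0, seed: int = 0) -> SceneConfig:
    """Standing user: whole-body sway on, no occluder."""
    return SceneConfig(
        breathing_frequency_hz=paced_rate(rate_hz),
        sway=SwayConfig(enabled=True),
        duration_s=duration_s,
        seed=seed,
    )


def drinking_preset(rate_hz: float = 0.25, duration_s: float = 300.0, seed: int = 0) -> SceneConfig:
    """Standing user holding a cup: sway plus a repeated occluding gesture."""
    return SceneConfig(
        breathing_frequency_hz=paced_rate(rate_hz),
        sway=SwayConfig(enabled=True),
        occluder=OccluderConfig(enabled=True, t_start_s=20.0),
        duration_s=duration_s,
        seed=seed,
    )
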