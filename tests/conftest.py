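import numpy as np
import pytest

from respidepth.core_io import DepthFrame, JointSet, PipelineConfig, TorsoWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PipelineConfig()


def make_joints(
    cx: float = 60.0,
    neck_y: float = 20.0,
    shoulder_y: float = 32.0,
    hip_y: float = 120.0,
    span: float = 44.0,
    valid: bool = True,
) -> JointSet:
    js = JointSet()
    coords = {
        "neck": (cx, neck_y),
        "shoulder_left": (cx - span / 2, shoulder_y),
        "shoulder_right": (cx + span / 2, shoulder_y),
        "spine_shoulder": (cx, shoulder_y),
        "spine_mid": (cx, (shoulder_y + hip_y) / 2),
        "hip_left": (cx - 0.35 * span, hip_y),
        "hip_right": (cx + 0.35 * span, hip_y),
    }
    for name, xy in coords.items():
        js.coords[name] = xy
        js.valid[name] = valid
    return js


def make_frame(h: int = 160, w: int = 120, fill: int = 2000, t: float = 0.0) -> DepthFrame:
    return DepthFrame(pixels=np.full((h, w), fill, dtype=np.uint16), timestamp=t)


@pytest.fixture
def joints():
    return make_joints()


@pytest.fixture
def flat_frame():
    return make_frame()


@pytest.fixture
def small_window():
    return TorsoWindow(x=2, y=3, w=4, h=4)
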