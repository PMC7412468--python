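"""Model initialisation, prediction, masking, in-painting, recovery, update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respidepth.core_io import DepthFrame, OcclusionMask, TorsoWindow
from respidepth.torso_model import (
    TorsoModel,
    initialize,
    normalized_convolution_inpaint,
    occlusion_mask,
    occlusion_recovery,
    predict,
    step_with_recovery,
    update,
)


def make_model(state, alpha=0.5, beta=0.9, gamma=0.9, damping=0.3, vel=None, acc=None):
    state = np.asarray(state, dtype=float)
    return TorsoModel(
        state=state,
        vel=np.zeros_like(state) if vel is None else np.asarray(vel, float),
        acc=np.zeros_like(state) if acc is None else np.asarray(acc, float),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        damping=damping,
    )


# -- initialisation ---------------------------------------------------------

def test_initialize_hole_free_equals_cut():
    px = np.arange(1, 101, dtype=np.uint16).reshape(10, 10) + 1000
    frame = DepthFrame(pixels=px, timestamp=0.0)
    win = TorsoWindow(x=2, y=2, w=5, h=5)
    model = initialize(frame, win)
    np.testing.assert_array_equal(model.state, win.cut(px).astype(float))
    assert np.all(model.vel == 0) and np.all(model.acc == 0)


def test_initialize_median_fills_hole():
    px = np.full((10, 10), 2000, dtype=np.uint16)
    px[5, 5] = 0
    model = initialize(DepthFrame(pixels=px, timestamp=0.0), TorsoWindow(x=3, y=3, w=5, h=5))
    assert model.state[2, 2] == 2000.0
    assert np.all(model.state == 2000.0)


def test_initialize_all_holes_raises():
    px = np.zeros((6, 6), dtype=np.uint16)
    with pytest.raises(ValueError):
        initialize(DepthFrame(pixels=px, timestamp=0.0), TorsoWindow(x=0, y=0, w=4, h=4))


# -- prediction -------------------------------------------------------------

def test_predict_identity_with_zero_derivatives():
    m = make_model(np.full((3, 3), 1234.0))
    np.testing.assert_array_equal(predict(m), m.state)


def test_predict_direct_substitution():
    m = make_model([[1000.0]], vel=[[2.0]], acc=[[1.0]])
    assert predict(m)[0, 0] == 1002.5


# -- update (damped double-exponential recursion) ---------------------------

def test_update_coefficient_zero_reduction():
    m = make_model([[1000.0]], alpha=0.0, beta=0.0, gamma=0.0, damping=0.0,
                   vel=[[3.0]], acc=[[7.0]])
    update(m, np.array([[1010.0]]))
    assert m.state[0, 0] == 1010.0
    assert m.vel[0, 0] == 10.0  # x_t - x_{t-1}
    assert m.acc[0, 0] == 10.0 - 3.0  # delta velocity


def test_update_hand_evaluated_recursion():
    m = make_model([[1000.0]], alpha=0.5, beta=0.5, gamma=0.5, damping=0.0)
    update(m, np.array([[1010.0]]))
    assert m.state[0, 0] == pytest.approx(1005.0)
    assert m.vel[0, 0] == pytest.approx(2.5)
    assert m.acc[0, 0] == pytest.approx(2.5)


@pytest.mark.parametrize(
    "coeffs",
    [(0.5, 0.9, 0.9, 0.3), (0.5, 0.5, 0.5, 0.0), (0.8, 0.8, 0.9, 0.5), (0.0, 0.0, 0.0, 0.0)],
)
def test_constant_measurement_fixed_point(coeffs):
    """A constant stream drives the state to the measurement, derivatives to 0."""
    a, b, g, d = coeffs
    m = make_model([[1500.0]], alpha=a, beta=b, gamma=g, damping=d)
    meas = np.array([[1540.0]])
    for _ in range(600):
        update(m, meas)
    assert m.state[0, 0] == pytest.approx(1540.0, abs=1e-6)
    assert abs(m.vel[0, 0]) < 1e-6 and abs(m.acc[0, 0]) < 1e-6


def test_ramp_tracking_lag():
    """Constant-velocity input: prediction lag vanishes for d=0 and stays
    bounded and small for the damped default."""
    slope = 3.0
    for d, bound in [(0.0, 1e-6), (0.3, 0.95 * slope)]:
        m = make_model([[0.0]], alpha=0.5, beta=0.9, gamma=0.9, damping=d)
        for t in range(1, 600):
            update(m, np.array([[slope * t]]))
        pred = predict(m)[0, 0]
        lag = abs(slope * 600 - pred)
        assert lag <= bound


def test_noise_variance_reduction(rng):
    """On a static scene the filtered state has less variance than the input."""
    sigma = 2.0
    m = make_model(np.full((4, 4), 2000.0))
    states = []
    for _ in range(800):
        update(m, 2000.0 + rng.normal(0, sigma, size=(4, 4)))
        states.append(m.state.copy())
    steady = np.stack(states[200:])
    assert steady.std(axis=0).max() < sigma


# -- occlusion mask ---------------------------------------------------------

def test_mask_sign_convention():
    pred = np.full((5, 5), 2000.0)
    nearer = np.full((5, 5), 2000.0)
    nearer[2, 2] = 1960.0  # 40 mm nearer than predicted -> occluder
    m = occlusion_mask(nearer, pred, z_threshold=30.0, halo_margin=0)
    assert m.mask[2, 2] and m.area == 1
    farther = np.full((5, 5), 2040.0)  # farther points are not occluders
    assert not occlusion_mask(farther, pred, 30.0, 0).any
    assert not occlusion_mask(pred.copy(), pred, 30.0, 0).any


def test_mask_invalid_pixels_and_halo_dilation():
    pred = np.full((9, 9), 2000.0)
    cut = pred.copy()
    cut[4, 4] = 0.0  # hole
    m = occlusion_mask(cut, pred, 30.0, halo_margin=3)
    assert m.area == 49  # 7x7 block from a single masked pixel
    assert m.mask[1:8, 1:8].all()


@given(z1=st.floats(5, 100), z2=st.floats(5, 100))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_mask_monotone_in_threshold(z1, z2):
    rng = np.random.default_rng(7)
    pred = np.full((8, 8), 2000.0)
    cut = pred + rng.normal(0, 40, size=(8, 8))
    lo, hi = sorted((z1, z2))
    m_hi = occlusion_mask(cut, pred, hi, 0).mask
    m_lo = occlusion_mask(cut, pred, lo, 0).mask
    assert not np.any(m_hi & ~m_lo)  # raising the threshold never adds pixels


# -- normalized convolution in-painting -------------------------------------

def test_inpaint_identity_and_constant():
    img = np.full((10, 10), 321.5)
    out = normalized_convolution_inpaint(img, np.ones((10, 10), bool))
    np.testing.assert_array_equal(out, img)
    holes = np.ones((10, 10), bool)
    holes[::3, ::2] = False  # arbitrary hole pattern
    out = normalized_convolution_inpaint(img, ~holes)
    np.testing.assert_allclose(out, 321.5)


def test_inpaint_symmetric_neighbours_average():
    img = np.zeros((1, 11))
    valid = np.zeros((1, 11), bool)
    img[0, 4], valid[0, 4] = 100.0, True
    img[0, 6], valid[0, 6] = 200.0, True
    out = normalized_convolution_inpaint(img, valid, kernel_sigma=2.0)
    assert out[0, 5] == pytest.approx(150.0)


def test_inpaint_matches_direct_summation_oracle(rng):
    """Single-pass fills equal the dense normalized-convolution formula."""
    from respidepth.torso_model import _gaussian_kernel

    for _ in range(20):
        img = rng.uniform(1000, 3000, size=(16, 16))
        valid = rng.random((16, 16)) > 0.2
        valid[0, 0] = True
        out = normalized_convolution_inpaint(img, valid, kernel_sigma=5.0)
        k1 = _gaussian_kernel(5.0)
        kern = np.outer(k1, k1)
        r = len(k1) // 2
        for y, x in zip(*np.nonzero(~valid)):
            num = den = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 16 and 0 <= xx < 16 and valid[yy, xx]:
                        wgt = kern[dy + r, dx + r]
                        num += wgt * img[yy, xx]
                        den += wgt
            assert den > 0  # sigma 5 reaches everywhere on 16x16
            assert out[y, x] == pytest.approx(num / den, rel=1e-9)
        np.testing.assert_array_equal(out[valid], img[valid])


def test_inpaint_grows_support_for_large_holes():
    img = np.zeros((40, 40))
    valid = np.zeros((40, 40), bool)
    valid[0, 0] = True
    img[0, 0] = 777.0
    out = normalized_convolution_inpaint(img, valid, kernel_sigma=1.0)
    np.testing.assert_allclose(out, 777.0)


def test_inpaint_requires_valid_pixel():
    with pytest.raises(ValueError):
        normalized_convolution_inpaint(np.zeros((4, 4)), np.zeros((4, 4), bool))


# -- occlusion recovery ------------------------------------------------------

def _disk_mask(shape, c, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return OcclusionMask(mask=(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2)


def test_recovery_empty_mask_is_identity(rng):
    img = rng.uniform(1000, 2000, size=(8, 8))
    prev = rng.uniform(1000, 2000, size=(8, 8))
    out = occlusion_recovery(img, prev, np.zeros((8, 8), bool))
    np.testing.assert_array_equal(out, img)


def test_recovery_static_scene_restores_patch_exactly(rng):
    prev = rng.uniform(1900, 2100, size=(20, 20))
    mask = _disk_mask((20, 20), (10, 10), 4)
    partly = prev.copy()  # unchanged surroundings
    out = occlusion_recovery(partly, prev, mask)
    np.testing.assert_allclose(out[mask.mask], prev[mask.mask], atol=1e-9)
    np.testing.assert_array_equal(out[~mask.mask], partly[~mask.mask])


def test_recovery_applies_uniform_shift_to_patch(rng):
    prev = rng.uniform(1900, 2100, size=(20, 20))
    mask = _disk_mask((20, 20), (10, 10), 4)
    partly = prev - 5.0  # whole torso moved 5 mm nearer outside the mask
    out = occlusion_recovery(partly, prev, mask)
    np.testing.assert_allclose(out[mask.mask], prev[mask.mask] - 5.0, atol=1e-9)


def test_recovery_full_occlusion_falls_back_to_memory(rng):
    prev = rng.uniform(1900, 2100, size=(6, 6))
    out = occlusion_recovery(np.zeros((6, 6)), prev, np.ones((6, 6), bool))
    np.testing.assert_array_equal(out, prev)


def test_recovery_never_alters_unmasked(rng):
    prev = rng.uniform(1900, 2100, size=(15, 15))
    partly = rng.uniform(1900, 2100, size=(15, 15))
    mask = _disk_mask((15, 15), (7, 7), 3)
    out = occlusion_recovery(partly, prev, mask)
    np.testing.assert_array_equal(out[~mask.mask], partly[~mask.mask])


def test_step_with_recovery_matches_update_when_unoccluded(rng):
    state = rng.uniform(1900, 2100, size=(6, 6))
    m1 = make_model(state.copy())
    m2 = make_model(state.copy())
    meas = state + rng.normal(0, 2, size=(6, 6))
    update(m1, meas)
    step_with_recovery(m2, meas, OcclusionMask(mask=np.zeros((6, 6), bool)))
    np.testing.assert_allclose(m1.state, m2.state)
    np.testing.assert_allclose(m1.vel, m2.vel)
    np.testing.assert_allclose(m1.acc, m2.acc)
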