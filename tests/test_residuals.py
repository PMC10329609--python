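"""2D/3D geometric residuals, weighting, masking and the objective."""

import numpy as np
import pytest

from endovo.camera_geometry import CameraIntrinsics, DepthMap, FlowField, PixelMask
from endovo.exceptions import DegenerateProblemError, InvalidArgumentError
from endovo.residuals import (
    FrameObservation,
    GeometricResidualProblem,
    ResidualField,
    WeightMaps,
    apply_masks,
    combined_residual,
    objective,
    residual_2d,
    residual_3d,
    specularity_mask,
)


def _make_frame(depth_values, flow_uv=None, intr=None, t=1, image=None):
    h, w = depth_values.shape
    intr = intr or CameraIntrinsics(
        fx=float(w), fy=float(h), cx=(w - 1) / 2.0, cy=(h - 1) / 2.0,
        baseline=1.0, width=w, height=h,
    )
    depth = DepthMap(values=depth_values, normalized=True, max_expected_depth=1.0)
    flow = None
    if flow_uv is not None:
        flow = FlowField(flow_uv, role="temporal")
    par = FlowField(np.zeros((h, w, 2)) - 1.0, role="parallax")
    img = image if image is not None else np.full((h, w, 3), 0.5)
    return FrameObservation(
        image=img, depth=depth, flow=flow, parallax=par, intrinsics=intr, t=t
    )


def _static_pair(h=16, w=20, depth=0.5):
    d = np.full((h, w), depth)
    cur = _make_frame(d, np.zeros((h, w, 2)), t=1)
    prev = _make_frame(d, None, t=0)
    return cur, prev


def test_static_scene_zero_residuals():
    cur, prev = _static_pair()
    r2 = residual_2d(np.zeros(6), cur, prev)
    r3 = residual_3d(np.zeros(6), cur, prev)
    assert r2.valid.any()
    assert np.max(r2.values) < 1e-6
    assert np.max(r3.values) < 1e-6


def test_residual_2d_hand_arithmetic():
    """Projection landing 3 px right of the flow target with X=640 gives
    a residual of exactly 3/640."""
    h, w = 512, 640
    d = np.full((h, w), 0.5)
    flow = np.zeros((h, w, 2))
    flow[..., 0] = -3.0  # target = x - 3; projection stays at x
    intr = CameraIntrinsics(fx=500.0, fy=500.0, cx=319.5, cy=255.5, baseline=1.0, width=640, height=512)
    cur = _make_frame(d, flow, intr=intr)
    prev = _make_frame(d, None, intr=intr, t=0)
    r2 = residual_2d(np.zeros(6), cur, prev)
    vals = r2.values[r2.valid]
    assert np.allclose(vals, 3.0 / 640.0, atol=1e-10)


def test_residual_3d_hand_arithmetic_3_4_5():
    """Transformed point (0,0,0.5) vs warped target (0,0.3,0.9): 0.5."""
    h = w = 8
    intr = CameraIntrinsics(fx=9.0, fy=9.0, cx=3.0, cy=3.0, baseline=1.0, width=8, height=8)
    d_cur = np.full((h, w), 0.5)
    d_prev = np.full((h, w), 0.9)
    flow = np.zeros((h, w, 2))
    flow[3, 3] = [0.0, 3.0]  # pixel (3,3) -> target (3,6)
    cur = _make_frame(d_cur, flow, intr=intr)
    prev = _make_frame(d_prev, None, intr=intr, t=0)
    r3 = residual_3d(np.zeros(6), cur, prev)
    assert r3.valid[3, 3]
    assert r3.values[3, 3] == pytest.approx(0.5, abs=1e-9)


def test_zero_residual_at_gt_on_forward_rendered_scene(planar_obs, planar_seq):
    tw = planar_seq.gt_relative_twists()
    prob = GeometricResidualProblem(planar_obs[2], planar_obs[1])
    r2, r3 = prob.residual_fields(tw[1])
    assert r2.values.max() < 1e-6
    assert r3.values.max() < 1e-6
    assert prob.objective(tw[1]) < 1e-10


def test_bumped_scene_residuals_at_gt_within_warp_floor(rigid_obs, rigid_seq):
    """On curved surfaces the bilinear point-cloud warp leaves an
    interpolation floor in the 3D residual; the 2D residual stays exact."""
    tw = rigid_seq.gt_relative_twists()
    prob = GeometricResidualProblem(rigid_obs[2], rigid_obs[1])
    r2, r3 = prob.residual_fields(tw[1])
    assert r2.values.max() < 1e-6
    assert r3.values.max() < 1e-3


def test_combined_residual_rules():
    shape = (4, 5)
    r2 = ResidualField(np.full(shape, 0.2), np.ones(shape, bool))
    r3 = ResidualField(np.full(shape, 0.1), np.ones(shape, bool))
    w = WeightMaps(np.full(shape, 0.5), np.full(shape, 1.0))
    out = combined_residual(r2, r3, w)
    assert np.allclose(out.values, 0.2)
    ones = WeightMaps.ones(shape)
    assert np.allclose(combined_residual(r2, r3, ones).values, 0.3)
    only2d = WeightMaps(np.ones(shape), np.zeros(shape))
    assert np.allclose(combined_residual(r2, r3, only2d).values, 0.2)
    with pytest.raises(InvalidArgumentError):
        WeightMaps(np.full(shape, 1.5), np.ones(shape))


def test_objective_zero_weights_and_degenerate(rng):
    cur, prev = _static_pair()
    zero = WeightMaps(np.zeros(cur.shape), np.zeros(cur.shape))
    for _ in range(3):
        p = rng.normal(scale=0.05, size=6)
        assert objective(p, cur, prev, zero) == pytest.approx(0.0, abs=1e-25)
    # fully masked frame -> degenerate
    cur.instrument_mask = PixelMask(np.zeros(cur.shape, bool))
    with pytest.raises(DegenerateProblemError):
        objective(np.zeros(6), cur, prev)


def test_objective_two_pixel_hand_sum():
    h = w = 8
    intr = CameraIntrinsics(fx=9.0, fy=9.0, cx=3.0, cy=3.0, baseline=1.0, width=8, height=8)
    d_cur = np.full((h, w), 0.5)
    d_prev = np.full((h, w), 0.9)
    flow = np.zeros((h, w, 2))
    flow[3, 3] = [0.0, 3.0]
    cur = _make_frame(d_cur, flow, intr=intr)
    prev = _make_frame(d_prev, None, intr=intr, t=0)
    keep = np.zeros((h, w), bool)
    keep[3, 3] = keep[4, 4] = True
    cur.instrument_mask = PixelMask(keep)
    prob = GeometricResidualProblem(cur, prev)
    assert prob.n_valid == 2
    r2, r3 = prob.residual_fields(np.zeros(6))
    expect = sum(
        (r2.values[y, x] + r3.values[y, x]) ** 2 for (y, x) in [(3, 3), (4, 4)]
    )
    assert prob.objective(np.zeros(6)) == pytest.approx(expect, rel=1e-12)
    # pixel (4,4): static, prev depth 0.9 vs 0.5 -> 3-D offset
    # (0.4/9, 0.4/9, 0.4) whose norm is the expected residual
    expected_r3 = np.sqrt(0.4**2 + 2 * (0.4 / 9.0) ** 2)
    assert r3.values[4, 4] == pytest.approx(expected_r3, abs=1e-9)


def test_objective_invariant_to_masked_pixels(rigid_obs):
    prob = GeometricResidualProblem(rigid_obs[1], rigid_obs[0])
    p = np.full(6, 0.01)
    f_full = prob.objective(p)
    # additionally masking pixels already outside Omega changes nothing
    cur = rigid_obs[1]
    masked_frame = FrameObservation(
        image=cur.image, depth=cur.depth, flow=cur.flow, parallax=cur.parallax,
        intrinsics=cur.intrinsics, t=cur.t,
        instrument_mask=PixelMask(prob.omega),
        specular_mask=cur.specular_mask,
    )
    f_again = GeometricResidualProblem(masked_frame, rigid_obs[0]).objective(p)
    assert f_again == pytest.approx(f_full, rel=1e-12)


def test_disjoint_weight_supports_are_additive(rigid_obs):
    prob = GeometricResidualProblem(rigid_obs[1], rigid_obs[0])
    h, w = prob.shape
    left = np.zeros((h, w))
    left[:, : w // 2] = 1.0
    right = 1.0 - left
    p = np.full(6, 0.005)
    f_left = prob.objective(p, WeightMaps(left, left))
    f_right = prob.objective(p, WeightMaps(right, right))
    f_all = prob.objective(p, WeightMaps.ones((h, w)))
    assert f_left + f_right == pytest.approx(f_all, rel=1e-9)


def test_gradients_match_finite_differences():
    from endovo.synthetic_scene import SceneConfig, render_sequence

    cfg = SceneConfig(scenario="rigid", width=16, height=16, n_frames=3, seed=2,
                      flow_noise_sigma=0.2, specularity_count=0)
    seq = render_sequence(cfg)
    obs = seq.frame_observations()
    rng = np.random.default_rng(3)
    w = WeightMaps(rng.uniform(0.2, 1.0, (16, 16)), rng.uniform(0.2, 1.0, (16, 16)))
    prob = GeometricResidualProblem(obs[2], obs[1])
    p = rng.normal(scale=0.01, size=6)
    f, g, h_mat = prob.objective(p, w, order=2)
    step = 1e-6
    for i in range(6):
        e = np.zeros(6)
        e[i] = step
        fd = (prob.objective(p + e, w) - prob.objective(p - e, w)) / (2 * step)
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)
    g2, g3 = prob.weight_gradient(p, w)
    pix = np.argwhere(prob.omega)[::37][:5]
    for yy, xx in pix:
        for which, dense in ((0, g2), (1, g3)):
            w2p, w3p = w.w2d.copy(), w.w3d.copy()
            (w2p if which == 0 else w3p)[yy, xx] += step
            fp = prob.objective(p, WeightMaps(w2p, w3p))
            (w2p if which == 0 else w3p)[yy, xx] -= 2 * step
            fm = prob.objective(p, WeightMaps(w2p, w3p))
            assert dense[yy, xx] == pytest.approx((fp - fm) / (2 * step), rel=1e-4, abs=1e-10)


def test_residual_fields_nonnegative_and_zero_outside_omega(rigid_obs, rng):
    prob = GeometricResidualProblem(rigid_obs[1], rigid_obs[0])
    r2, r3 = prob.residual_fields(rng.normal(scale=0.01, size=6))
    for fld in (r2, r3):
        assert np.all(fld.values[fld.valid] >= 0)
        assert np.all(fld.values[~fld.valid] == 0)


def test_specularity_mask_rules():
    img = np.zeros((9, 9, 3))
    assert specularity_mask(img).values.all()  # nothing masked
    img[4, 4] = 1.0
    m = specularity_mask(img, threshold=0.98, dilation_radius=1)
    blocked = ~m.values
    ys, xs = np.where(blocked)
    assert blocked[4, 4] and blocked.sum() == 9  # pixel + 8-neighbourhood
    assert set(zip(ys, xs)) == {(y, x) for y in (3, 4, 5) for x in (3, 4, 5)}
    everything = specularity_mask(np.full((5, 5, 3), 0.2), threshold=0.0)
    assert not everything.values.any()


def test_apply_masks():
    shape = (6, 6)
    fld = ResidualField(np.full(shape, 2.0), np.ones(shape, bool))
    same = apply_masks(fld, [PixelMask(np.ones(shape, bool))])
    assert np.array_equal(same.values, fld.values)
    gone = apply_masks(fld, [PixelMask(np.zeros(shape, bool))])
    assert not gone.valid.any() and np.all(gone.values == 0)
    half = np.ones(shape, bool)
    half[:3] = False
    halved = apply_masks(fld, [half])
    assert (halved.values**2).sum() == pytest.approx((fld.values**2).sum() / 2)


def test_shape_mismatch_errors():
    cur, prev = _static_pair(16, 20)
    other, _ = _static_pair(16, 24)
    with pytest.raises(InvalidArgumentError):
        GeometricResidualProblem(cur, other)
    with pytest.raises(InvalidArgumentError):
        residual_2d(np.zeros(6), cur, other)
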