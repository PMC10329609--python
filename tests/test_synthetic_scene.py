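"""The synthetic generator and its internal consistency oracles."""

import numpy as np
import pytest

from endovo.camera_geometry import disparity_to_depth
from endovo.exceptions import InvalidArgumentError
from endovo.lie_se3 import RigidTransform, Trajectory, chain_relative_poses, exp_map
from endovo.synthetic_scene import (
    SceneConfig,
    classify_frames,
    generate_deformation_field,
    generate_surface,
    generate_trajectory,
    render_sequence,
)


def _flow_consistency(seq, k):
    """max |pi2d(exp(p_gt) pi3d(D_t, x)) - (x + F_t(x))| in pixels."""
    obs_cur = seq.frame_observation(k, detect_specular=False)
    tw = seq.gt_relative_twists()[k - 1]
    intr = seq.intrinsics
    h, w = obs_cur.shape
    gy, gx = np.mgrid[0:h, 0:w]
    d = obs_cur.depth.values
    pts = np.stack(
        [d * (gx - intr.cx) / intr.fx, d * (gy - intr.cy) / intr.fy, d]
    ).reshape(3, -1)
    q = exp_map(tw).apply(pts)
    u = intr.fx * q[0] / q[2] + intr.cx
    v = intr.fy * q[1] / q[2] + intr.cy
    tx = (gx + obs_cur.flow.uv[..., 0]).ravel()
    ty = (gy + obs_cur.flow.uv[..., 1]).ravel()
    return np.hypot(u - tx, v - ty).reshape(h, w)


def test_surface_zero_bumps_is_plane_and_determinism():
    cfg = SceneConfig(scenario="rigid", n_bumps=0, seed=1)
    rng = np.random.default_rng(1)
    surf = generate_surface(cfg, rng)
    xs = np.linspace(-20, 20, 7)
    assert np.allclose(surf(xs, xs), cfg.base_depth_frac * cfg.max_expected_depth)

    cfg2 = SceneConfig(scenario="rigid", seed=2)
    a = generate_surface(cfg2, np.random.default_rng(9))
    b = generate_surface(cfg2, np.random.default_rng(9))
    assert np.allclose(a(xs, xs), b(xs, xs))


def test_surface_range_and_gradient_bound():
    for seed in range(5):
        cfg = SceneConfig(scenario="rigid", seed=seed)
        surf = generate_surface(cfg, np.random.default_rng(seed))
        g = np.linspace(-40, 40, 81)
        xx, yy = np.meshgrid(g, g)
        z = surf(xx, yy)
        assert z.min() > 0.2 * cfg.max_expected_depth
        assert z.max() < cfg.max_expected_depth
        # numeric gradient within the analytic bound
        gx = np.gradient(z, g, axis=1)
        gy = np.gradient(z, g, axis=0)
        assert np.hypot(gx, gy).max() <= surf.gradient_bound + 1e-6


def test_trajectory_semantics():
    rng = np.random.default_rng(0)
    breathing = SceneConfig(scenario="breathing", n_frames=10)
    assert np.all(generate_trajectory(breathing, rng) == 0)
    deforming = SceneConfig(scenario="deforming", n_frames=10)
    assert np.all(generate_trajectory(deforming, rng) == 0)
    flat = SceneConfig(scenario="scanning", n_frames=10, camera_amplitude=0.0)
    assert np.all(generate_trajectory(flat, rng) == 0)
    for seed in range(20):
        cfg = SceneConfig(scenario="scanning", n_frames=12, seed=seed)
        tw = generate_trajectory(cfg, np.random.default_rng(seed))
        assert np.max(np.abs(tw)) <= cfg.camera_amplitude + 1e-12


def test_deformation_field_rules():
    none = SceneConfig(scenario="deforming", deform_amplitude=0.0)
    dz, mask = generate_deformation_field(none, 5)
    assert np.all(dz == 0) and not mask.any()

    breathing = SceneConfig(scenario="breathing")
    dz0, _ = generate_deformation_field(breathing, 0.0)
    assert np.allclose(dz0, 0.0)  # sin(0)
    dz_half, _ = generate_deformation_field(breathing, breathing.breathing_period / 4)
    assert np.abs(dz_half).max() > 0

    poke = SceneConfig(scenario="deforming")
    g = np.linspace(-40, 40, 161)
    xx, yy = np.meshgrid(g, g)
    dz, mask = generate_deformation_field(poke, poke.deform_period / 2, xx, yy)
    r = np.hypot(xx, yy)
    assert mask.any()
    assert np.all(r[mask] <= poke.deform_radius + 1e-9)  # inside the 3-sigma disk


@pytest.mark.parametrize("scenario", ["rigid", "scanning", "breathing", "deforming"])
def test_flow_pose_depth_consistency_without_deformation(scenario):
    cfg = SceneConfig(
        scenario=scenario,
        n_frames=4,
        seed=2,
        breathing_amplitude=0.0,
        deform_amplitude=0.0,
        specularity_count=0,
    )
    seq = render_sequence(cfg)
    for k in (1, 3):
        err = _flow_consistency(seq, k)
        assert err.max() < 0.05


def test_deformation_breaks_consistency_inside_mask_only():
    cfg = SceneConfig(scenario="deforming", n_frames=12, seed=3, specularity_count=0)
    seq = render_sequence(cfg)
    hit = False
    for k in range(1, 12):
        err = _flow_consistency(seq, k)
        mask = seq.frames[k].deformation_mask
        if mask.any() and err[mask].max() > 0.5:
            hit = True
        assert err[~mask].max() < 0.05
    assert hit


def test_stereo_consistency():
    cfg = SceneConfig(scenario="rigid", n_frames=2, seed=4)
    seq = render_sequence(cfg)
    fr = seq.frames[1]
    rec = disparity_to_depth(fr.parallax, seq.intrinsics)
    rel = np.abs(rec.values - fr.depth.values) / fr.depth.values
    assert rel[rec.valid].max() < 1e-3


def test_render_determinism_and_seed_variation():
    cfg = SceneConfig(scenario="scanning", n_frames=3, seed=8)
    a = render_sequence(cfg)
    b = render_sequence(cfg)
    assert np.array_equal(a.frames[2].left_image, b.frames[2].left_image)
    assert np.array_equal(a.frames[2].depth.values, b.frames[2].depth.values)
    c = render_sequence(SceneConfig(scenario="scanning", n_frames=3, seed=9))
    assert not np.array_equal(a.frames[2].depth.values, c.frames[2].depth.values)


def test_pair_observation_consistency_over_intervals():
    """Flow across k-frame intervals matches the k-step relative pose."""
    cfg = SceneConfig(scenario="rigid", n_frames=8, seed=5, specularity_count=0)
    seq = render_sequence(cfg)
    for ip, ic in [(0, 3), (2, 7)]:
        cur, prev, tw = seq.pair_observation(ip, ic)
        intr = seq.intrinsics
        h, w = cur.shape
        gy, gx = np.mgrid[0:h, 0:w]
        d = cur.depth.values
        pts = np.stack(
            [d * (gx - intr.cx) / intr.fx, d * (gy - intr.cy) / intr.fy, d]
        ).reshape(3, -1)
        q = exp_map(tw).apply(pts)
        u = intr.fx * q[0] / q[2] + intr.cx
        tx = (gx + cur.flow.uv[..., 0]).ravel()
        assert np.abs(u - tx).max() < 0.05


def test_classify_frames():
    eye = RigidTransform.identity()
    static = Trajectory(np.arange(4.0), [eye] * 4)
    assert classify_frames(static, 1e-6) == ["static"] * 4

    big = np.array([0.3, 0, 0, 0, 0, 0])
    traj = chain_relative_poses([big, np.zeros(6), big, np.zeros(6)])
    labels = classify_frames(traj, 0.01)
    assert labels == ["static", "moving", "static", "moving", "static"]
    assert classify_frames(traj, np.inf) == ["static"] * 5


def test_instrument_mask_and_specularities():
    cfg = SceneConfig(scenario="rigid", n_frames=2, seed=0, instrument=True,
                      specularity_count=4)
    seq = render_sequence(cfg)
    fr = seq.frames[1]
    assert fr.instrument_mask is not None
    assert not fr.instrument_mask.values.all()  # some tool pixels
    assert fr.left_image.max() >= 0.99  # saturated highlights present
    obs = seq.frame_observation(1)
    assert not obs.specular_mask.values.all()


def test_invalid_configs():
    with pytest.raises(InvalidArgumentError):
        SceneConfig(scenario="flying")
    with pytest.raises(InvalidArgumentError):
        SceneConfig(scenario="rigid", width=8, height=8)
    with pytest.raises(InvalidArgumentError):
        SceneConfig(scenario="rigid", camera_amplitude=-0.1)
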