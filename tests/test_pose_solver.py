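"""Pose NLLS model: recovery, ablation modes, invariances, odometry."""

import numpy as np
import pytest

from endovo.camera_geometry import CameraIntrinsics, DepthMap, FlowField, PixelMask
from endovo.exceptions import DegenerateProblemError, InvalidArgumentError
from endovo.pose_solver import PoseModel, SolverConfig, run_odometry, solve_pose
from endovo.residuals import FrameObservation, WeightMaps
from endovo.synthetic_scene import SceneConfig, render_sequence
from endovo.trajectory_metrics import ate_rmse


def _static_pair(h=16, w=20, depth=0.5):
    intr = CameraIntrinsics(float(w), float(h), (w - 1) / 2, (h - 1) / 2, 1.0, w, h)
    d = DepthMap(values=np.full((h, w), depth), normalized=True)
    # mild depth texture so the pose is fully constrained
    vals = d.values + 0.05 * np.sin(np.arange(w) / 3.0)[None, :] + 0.04 * np.cos(np.arange(h) / 2.0)[:, None]
    d = DepthMap(values=vals, normalized=True)
    par = FlowField(np.full((h, w, 2), -1.0), role="parallax")
    img = np.full((h, w, 3), 0.5)
    cur = FrameObservation(img, d, FlowField(np.zeros((h, w, 2))), par, intr, t=1)
    prev = FrameObservation(img, d, None, par, intr, t=0)
    return cur, prev


def test_static_frames_give_zero_pose():
    cur, prev = _static_pair()
    res = solve_pose(cur, prev, config=SolverConfig(mode="unweighted"))
    assert res.converged
    assert np.max(np.abs(res.p_star)) < 1e-8


def test_recovery_on_noiseless_rigid_scene(planar_seq, planar_obs):
    tw = planar_seq.gt_relative_twists()
    for k in (1, 2):
        fit = PoseModel(
            planar_obs[k], planar_obs[k - 1], config=SolverConfig(mode="unweighted")
        ).fit()
        assert np.max(np.abs(fit.params - tw[k - 1])) < 1e-5
        assert fit.final_objective <= fit.initial_objective


def test_recovery_on_curved_scene_within_warp_floor(rigid_seq, rigid_obs):
    tw = rigid_seq.gt_relative_twists()
    fit = PoseModel(rigid_obs[2], rigid_obs[1], config=SolverConfig(mode="unweighted")).fit()
    assert np.max(np.abs(fit.params - tw[1])) < 5e-5


def test_toy_problem_beats_brute_force_search():
    """The fitted twist is at least as good as an extensive brute-force
    sampling of the pose box, and is locally minimal."""
    cur, prev = _static_pair(16, 16)
    shifted = DepthMap(values=prev.depth.values - 0.02, normalized=True)
    prev2 = FrameObservation(prev.image, shifted, None, prev.parallax, prev.intrinsics, t=0)
    model = PoseModel(cur, prev2, config=SolverConfig(mode="3d_only"))
    fit = model.fit()
    f_star = model.objective(fit.params)
    rng = np.random.default_rng(0)
    samples = rng.uniform(-0.05, 0.05, size=(20000, 6))
    best_f = min(model.objective(p) for p in samples)
    assert f_star <= best_f
    # local minimality in random directions
    for _ in range(20):
        d = rng.normal(size=6)
        d /= np.linalg.norm(d)
        assert model.objective(fit.params + 1e-4 * d) >= f_star - 1e-15


def test_unweighted_is_bitwise_weighted_with_ones(rigid_obs):
    shape = rigid_obs[1].shape
    a = PoseModel(rigid_obs[1], rigid_obs[0], config=SolverConfig(mode="unweighted")).fit()
    b = PoseModel(
        rigid_obs[1], rigid_obs[0], WeightMaps.ones(shape), SolverConfig(mode="weighted")
    ).fit()
    assert np.array_equal(a.params, b.params)
    assert a.final_objective == b.final_objective


@pytest.mark.parametrize(
    "mode,w2,w3", [("2d_only", 1.0, 0.0), ("3d_only", 0.0, 1.0)]
)
def test_single_residual_modes_equal_zeroed_maps(rigid_obs, mode, w2, w3):
    shape = rigid_obs[1].shape
    a = PoseModel(rigid_obs[1], rigid_obs[0], config=SolverConfig(mode=mode)).fit()
    maps = WeightMaps(np.full(shape, w2), np.full(shape, w3))
    b = PoseModel(rigid_obs[1], rigid_obs[0], maps, SolverConfig(mode="weighted")).fit()
    assert np.array_equal(a.params, b.params)


def test_weight_scale_invariance(rigid_obs):
    """Scaling both maps by c > 0 scales the objective by c^2 but leaves
    the minimizer unchanged."""
    shape = rigid_obs[1].shape
    rng = np.random.default_rng(0)
    base = rng.uniform(0.1, 0.5, shape)
    a = PoseModel(
        rigid_obs[1], rigid_obs[0], WeightMaps(base, base), SolverConfig(mode="weighted")
    ).fit()
    c = 2.0
    b = PoseModel(
        rigid_obs[1], rigid_obs[0], WeightMaps(c * base, c * base), SolverConfig(mode="weighted")
    ).fit()
    assert np.max(np.abs(a.params - b.params)) < 1e-7
    assert b.final_objective == pytest.approx(c**2 * a.final_objective, rel=1e-6)


def test_objective_monotone_over_accepted_iterates(rigid_obs):
    fit = PoseModel(rigid_obs[1], rigid_obs[0], config=SolverConfig(mode="unweighted")).fit()
    hist = [fit.initial_objective] + fit.objective_history + [fit.final_objective]
    assert all(b <= a * (1 + 1e-9) + 1e-300 for a, b in zip(hist, hist[1:]))


def test_convergence_basin_at_amplitude_0_05():
    """From identity init, twists up to |p|_inf = 0.05 are recovered."""
    for seed in range(3):
        cfg = SceneConfig(
            scenario="rigid", n_frames=3, seed=seed, camera_amplitude=0.05, n_bumps=0
        )
        seq = render_sequence(cfg)
        obs = seq.frame_observations()
        tw = seq.gt_relative_twists()
        assert np.max(np.abs(tw)) <= 0.05 + 1e-12
        fit = PoseModel(obs[2], obs[1], config=SolverConfig(mode="unweighted")).fit()
        assert np.max(np.abs(fit.params - tw[1])) < 1e-5


def test_degenerate_problem_raises():
    cur, prev = _static_pair()
    cur.instrument_mask = PixelMask(np.zeros(cur.shape, bool))
    with pytest.raises(DegenerateProblemError):
        PoseModel(cur, prev, config=SolverConfig(mode="unweighted"))


def test_invalid_config():
    with pytest.raises(InvalidArgumentError):
        SolverConfig(gtol=-1.0)
    with pytest.raises(InvalidArgumentError):
        SolverConfig(mode="nope")
    with pytest.raises(InvalidArgumentError):
        PoseModel(*_static_pair(), config=SolverConfig(mode="weighted"))  # no maps


def test_run_odometry_static_sequence():
    frames = []
    cur, prev = _static_pair()
    frames = [prev] + [
        FrameObservation(cur.image, cur.depth, cur.flow, cur.parallax, cur.intrinsics, t=i)
        for i in range(1, 4)
    ]
    traj, results = run_odometry(frames, config=SolverConfig(mode="unweighted"))
    assert len(traj) == 4 and len(results) == 3
    assert np.max(np.abs(traj.positions())) < 1e-7


def test_run_odometry_recovers_trajectory(planar_seq, planar_obs):
    traj, results = run_odometry(
        planar_obs, config=SolverConfig(mode="unweighted", init_policy="previous")
    )
    tw = planar_seq.gt_relative_twists()
    for k, r in enumerate(results):
        assert np.max(np.abs(r.params - tw[k])) < 1e-5
    est_mm = traj.scaled_translation(planar_seq.config.max_expected_depth)
    ate = ate_rmse(planar_seq.trajectory, est_mm)
    assert ate / planar_seq.config.max_expected_depth < len(results) * 1e-5


def test_results_summary_and_covariance(rigid_obs):
    fit = PoseModel(rigid_obs[1], rigid_obs[0], config=SolverConfig(mode="unweighted")).fit()
    text = fit.summary()
    for token in ("objective", "converged", "tx", "wz"):
        assert token in text
    cov = fit.cov_params()
    assert cov.shape == (6, 6)
    assert np.all(np.linalg.eigvalsh((cov + cov.T) / 2) > -1e-18)
    assert np.allclose(fit.transform.matrix[3], [0, 0, 0, 1])
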