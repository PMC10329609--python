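"""Implicit differentiation of the pose argmin and the training loss."""

import numpy as np
import pytest

from endovo.ddn_layer import (
    implicit_from_derivatives,
    implicit_gradient,
    training_loss,
    training_loss_grad,
    end_to_end_gradient_step,
)
from endovo.exceptions import EmptyBatchError, StationarityError
from endovo.pose_solver import PoseModel, SolverConfig
from endovo.residuals import WeightMaps
from endovo.synthetic_scene import SceneConfig, render_sequence


def test_training_loss_l1():
    p = np.array([0.1, 0, 0, 0, -0.2, 0])
    assert training_loss(p, np.zeros(6)) == pytest.approx(0.3)
    assert training_loss(p, p) == 0.0
    q = np.ones(6)
    assert training_loss(p, q) == training_loss(q, p)  # symmetric
    assert np.all(training_loss_grad(p, p) == 0)  # subgradient at ties is 0
    with pytest.raises(ValueError):
        training_loss(np.full(6, np.nan), np.zeros(6))


def test_implicit_formula_analytic_cases():
    # f(p, w) = w (p - a)^2: p* = a independent of w -> gradient 0
    a, w = 0.7, 1.3
    hess = np.array([[2 * w]])
    mixed = np.array([[2 * (a - a)]])  # df^2/dpdw = 2(p - a) at p* = a
    g, lam = implicit_from_derivatives(hess, mixed, np.array([1.0]))
    assert g[0] == 0.0 and lam == 0.0
    # f(p, w) = (p - w)^2: dp*/dw = 1 -> gradient equals upstream
    hess = np.array([[2.0]])
    mixed = np.array([[-2.0]])
    for upstream in (1.0, -3.5):
        g, _ = implicit_from_derivatives(hess, mixed, np.array([upstream]))
        assert g[0] == pytest.approx(upstream)


def test_implicit_formula_damping_and_linearity():
    hess = np.zeros((2, 2))  # singular: needs damping
    mixed = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    u = np.array([1.0, 2.0])
    g, lam = implicit_from_derivatives(hess, mixed, u)
    assert lam > 0 and np.all(np.isfinite(g))
    g2, _ = implicit_from_derivatives(hess, mixed, 2 * u)
    assert np.allclose(g2, 2 * g)  # linear in the upstream gradient


@pytest.fixture(scope="module")
def small_problem():
    cfg = SceneConfig(
        scenario="rigid", width=16, height=16, n_frames=3, seed=5,
        flow_noise_sigma=0.3, specularity_count=0,
    )
    seq = render_sequence(cfg)
    obs = seq.frame_observations()
    rng = np.random.default_rng(9)
    w = WeightMaps(rng.uniform(0.2, 0.9, (16, 16)), rng.uniform(0.2, 0.9, (16, 16)))
    model = PoseModel(obs[2], obs[1], w, SolverConfig(mode="weighted", gtol=1e-11))
    fit = model.fit()
    assert fit.converged
    return obs, w, model, fit


def test_implicit_gradient_matches_resolve_fd(small_problem):
    obs, w, model, fit = small_problem
    rng = np.random.default_rng(2)
    upstream = rng.normal(size=6)
    dw2, dw3, report = implicit_gradient(model.problem, fit.params, w, upstream)
    assert report.stationarity_norm <= 1e-6
    assert report.hessian_min_eigenvalue > 0
    gscale = max(np.abs(dw2).max(), np.abs(dw3).max())
    pix = np.argwhere(model.problem.omega)
    rng.shuffle(pix)
    h = 1e-3
    for yy, xx in pix[:3]:
        for which, dense in ((0, dw2), (1, dw3)):
            vals = []
            for s in (h, -h):
                w2p, w3p = w.w2d.copy(), w.w3d.copy()
                (w2p if which == 0 else w3p)[yy, xx] += s
                refit = PoseModel(
                    obs[2], obs[1], WeightMaps(w2p, w3p),
                    SolverConfig(mode="weighted", gtol=1e-11),
                ).fit(start=fit.params)
                vals.append(float(upstream @ refit.params))
            fd = (vals[0] - vals[1]) / (2 * h)
            assert abs(fd - dense[yy, xx]) <= 1e-3 * max(abs(fd), 1e-3 * gscale)


def test_implicit_gradient_zero_outside_omega(small_problem):
    obs, w, model, fit = small_problem
    dw2, dw3, _ = implicit_gradient(model.problem, fit.params, w, np.ones(6))
    assert np.all(dw2[~model.problem.omega] == 0)
    assert np.all(dw3[~model.problem.omega] == 0)


def test_implicit_gradient_requires_stationarity(small_problem):
    obs, w, model, fit = small_problem
    with pytest.raises(StationarityError):
        implicit_gradient(model.problem, fit.params + 0.01, w, np.ones(6))


def test_end_to_end_gradient_matches_fd():
    """Chained net -> argmin -> l1 loss gradient vs finite differences
    through the whole pipeline."""
    from endovo.weight_net import make_networks

    cfg = SceneConfig(
        scenario="deforming", width=16, height=16, n_frames=4, seed=1,
        specularity_count=0,
    )
    seq = render_sequence(cfg)
    cur, prev, p_gt = seq.pair_observation(1, 2)
    params = make_networks(seed=3, base_channels=4)
    batch = [(cur, prev, p_gt)]
    scfg = SolverConfig(mode="weighted", gtol=1e-11)
    loss, g2, g3, used = end_to_end_gradient_step(batch, params.net2d, params.net3d, scfg)
    assert used == 1

    def full_loss():
        w = params.predict(cur, prev)
        fit = PoseModel(cur, prev, w, scfg).fit()
        return training_loss(fit.params, p_gt)

    rng = np.random.default_rng(0)
    checked = 0
    for name in ("c1a.w", "out.w"):
        for net, grads in ((params.net2d, g2), (params.net3d, g3)):
            arr = net.params[name]
            idx = rng.integers(arr.size)
            h = 1e-4
            orig = arr.flat[idx]
            arr.flat[idx] = orig + h
            lp = full_loss()
            arr.flat[idx] = orig - h
            lm = full_loss()
            arr.flat[idx] = orig
            fd = (lp - lm) / (2 * h)
            an = grads[name].flat[idx]
            if abs(fd) > 1e-7:
                assert an == pytest.approx(fd, rel=1e-2)
                checked += 1
    assert checked >= 2


def test_end_to_end_empty_batch_raises():
    from endovo.weight_net import make_networks

    cfg = SceneConfig(scenario="rigid", width=16, height=16, n_frames=3, seed=2)
    seq = render_sequence(cfg)
    cur, prev, p_gt = seq.pair_observation(1, 2)
    params = make_networks(seed=0, base_channels=4)
    impossible = SolverConfig(mode="weighted", stationarity_tol=1e-300)
    with pytest.raises(EmptyBatchError):
        end_to_end_gradient_step([(cur, prev, p_gt)], params.net2d, params.net3d, impossible)
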