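"""Implicit differentiation of the pose argmin (declarative layer).

The pose solve is an optimization layer: weight maps go in, the argmin
twist comes out.  Backpropagating the training loss through it does not
unroll solver iterations; instead, at a stationary point ``p*`` of the
objective ``f(p, w)`` the implicit function theorem for unconstrained
declarative nodes gives

    dp*/dw = -H^{-1} B,   H = d^2 f / dp^2,   B = d^2 f / dp dw,

so the loss gradient with respect to every weight-map entry is
``-(H^{-1} u)^T B`` for upstream ``u = dL/dp*``.  Two requirements make
this valid: the objective is twice differentiable (guaranteed by the
smoothed residual norms) and the forward pass actually reached a local
minimum (checked here via the gradient norm; near-singular Hessians are
Levenberg-damped and the damping recorded).

``H`` is the exact 6x6 second derivative from forward-mode AD -- not a
Gauss-Newton approximation -- and ``B`` is assembled from per-pixel
first-order tangents, so memory stays linear in the pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import EmptyBatchError, StationarityError
from .residuals import GeometricResidualProblem, WeightMaps

__all__ = [
    "ImplicitGradientReport",
    "training_loss",
    "training_loss_grad",
    "implicit_from_derivatives",
    "implicit_gradient",
    "end_to_end_gradient_step",
]

#: gradient infinity-norm up to which a forward solution is accepted as
#: stationary (looser than the solver's own tolerance to survive float
#: noise on flat objectives).
STATIONARITY_TOL = 1e-6

#: Levenberg damping schedule; the first value making H positive
#: definite is used.
DAMPING_SCHEDULE = (0.0, 1e-9, 1e-6, 1e-3)


def training_loss(p_star, p_gt) -> float:
    """Supervised twist loss: l1 norm of ``p* - p_gt``."""
    a = np.asarray(getattr(p_star, "data", p_star), dtype=float)
    b = np.asarray(getattr(p_gt, "data", p_gt), dtype=float)
    if a.shape != (6,) or b.shape != (6,):
        raise ValueError("twists must be 6-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite twist")
    return float(np.sum(np.abs(a - b)))


def training_loss_grad(p_star, p_gt) -> np.ndarray:
    """Subgradient of the l1 loss w.r.t. ``p*`` (0 at ties, by convention)."""
    a = np.asarray(getattr(p_star, "data", p_star), dtype=float)
    b = np.asarray(getattr(p_gt, "data", p_gt), dtype=float)
    return np.sign(a - b)


def implicit_from_derivatives(hess, mixed, upstream, damping=DAMPING_SCHEDULE):
    """Core declarative-node formula ``-(H^{-1} u)^T B``.

    ``hess`` is the (k, k) parameter Hessian at the argmin, ``mixed`` the
    (n, k) mixed partials d^2 f / dp dw over n auxiliary variables and
    ``upstream`` the (k,) loss gradient w.r.t. the argmin.  Returns the
    (n,) gradient and the damping value used (first schedule entry
    making H positive definite)."""
    hess = np.atleast_2d(np.asarray(hess, dtype=float))
    mixed = np.atleast_2d(np.asarray(mixed, dtype=float))
    upstream = np.atleast_1d(np.asarray(upstream, dtype=float))
    k = hess.shape[0]
    for lam in damping:
        try:
            cho = linalg.cho_factor(hess + lam * np.eye(k))
        except np.linalg.LinAlgError:
            continue
        y = linalg.cho_solve(cho, upstream)
        return -(mixed @ y), lam
    raise StationarityError("Hessian indefinite even after maximum damping")


@dataclass
class ImplicitGradientReport:
    """Diagnostics of one implicit-gradient evaluation."""

    stationarity_norm: float
    hessian_min_eigenvalue: float
    damping: float


def implicit_gradient(
    problem: GeometricResidualProblem,
    p_star,
    weights: WeightMaps,
    upstream,
    stationarity_tol: float = STATIONARITY_TOL,
):
    """Gradient of ``upstream . p*`` w.r.t. every weight-map entry.

    Returns ``(dw2d, dw3d, report)`` where the first two are dense grids
    matching the weight maps (zero at pixels outside the valid set).
    Raises :class:`StationarityError` if ``p_star`` is not stationary,
    and a :class:`StationarityError` if no damping value renders the
    Hessian positive definite.
    """
    p_star = np.asarray(getattr(p_star, "data", p_star), dtype=float)
    upstream = np.asarray(upstream, dtype=float)
    f, g, h = problem.objective(p_star, weights, order=2)
    gnorm = float(np.max(np.abs(g)))
    if gnorm > stationarity_tol:
        raise StationarityError(
            f"gradient inf-norm {gnorm:.2e} exceeds {stationarity_tol:.0e}; "
            "implicit gradient undefined away from a minimum"
        )
    min_eig = float(np.linalg.eigvalsh(h)[0])
    b2, b3 = problem.mixed_partials(p_star, weights)  # (n_valid, 6)
    grad2, used = implicit_from_derivatives(h, b2, upstream)
    grad3, _ = implicit_from_derivatives(h, b3, upstream, damping=(used,))
    dw2 = problem.scatter(grad2)
    dw3 = problem.scatter(grad3)
    report = ImplicitGradientReport(
        stationarity_norm=gnorm,
        hessian_min_eigenvalue=min_eig,
        damping=used,
    )
    return dw2, dw3, report


def end_to_end_gradient_step(batch, net2d, net3d, solver_config=None, logger=None):
    """Loss and parameter gradients for one batch of frame pairs.

    ``batch`` is a sequence of ``(t_frame, prev_frame, p_gt)`` tuples;
    ``net2d`` / ``net3d`` are weight networks (see
    :mod:`endovo.weight_net`) whose ``forward`` caches activations and
    whose ``backward`` returns parameter gradients.  For each pair the
    nets predict weight maps, the pose is solved, the l1 twist loss is
    evaluated and its gradient is chained through the implicit
    derivative of the argmin into both networks.  Pairs whose solve does
    not reach stationarity are skipped (and counted); if every pair is
    skipped an :class:`EmptyBatchError` is raised.

    Returns ``(mean_loss, grads2d, grads3d, n_used)``.
    """
    from .pose_solver import PoseModel, SolverConfig
    from .weight_net import build_input_stack

    cfg = solver_config or SolverConfig(mode="weighted")
    grads2d = None
    grads3d = None
    total = 0.0
    used = 0
    for t_frame, prev_frame, p_gt in batch:
        stack2d = build_input_stack(t_frame, prev_frame, "2d")
        stack3d = build_input_stack(t_frame, prev_frame, "3d")
        w2d = net2d.forward(stack2d)
        w3d = net3d.forward(stack3d)
        weights = WeightMaps(w2d, w3d)
        model = PoseModel(t_frame, prev_frame, weights, cfg)
        fit = model.fit()
        if not fit.converged:
            if logger is not None:
                logger.warning(
                    "skipping pair t=%d (|g|=%.2e not stationary)",
                    t_frame.t,
                    fit.gradient_norm,
                )
            continue
        total += training_loss(fit.params, p_gt)
        upstream = training_loss_grad(fit.params, p_gt)
        dw2, dw3, _ = implicit_gradient(model.problem, fit.params, weights, upstream)
        g2 = net2d.backward(dw2)
        g3 = net3d.backward(dw3)
        if grads2d is None:
            grads2d = g2
            grads3d = g3
        else:
            for k in grads2d:
                grads2d[k] += g2[k]
            for k in grads3d:
                grads3d[k] += g3[k]
        used += 1
    if used == 0:
        raise EmptyBatchError("no batch element reached a stationary solution")
    for k in grads2d:
        grads2d[k] /= used
    for k in grads3d:
        grads3d[k] /= used
    return total / used, grads2d, grads3d, used
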