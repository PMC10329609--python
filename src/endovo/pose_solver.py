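"""Quasi-Newton pose estimation: the NLLS model and its fitted results.

The relative camera pose between two frames is a mechanistic model --
rigid motion in se(3) -- fitted to dense flow/depth observations by
nonlinear least squares.  Following the Model/Results idiom of
statistical modelling packages, :class:`PoseModel` holds the data and
the objective, ``fit()`` minimizes it with L-BFGS (scipy), and
:class:`PoseResults` carries the estimated twist, its covariance (from
the objective Hessian), convergence diagnostics and a ``summary()``
table.  :func:`run_odometry` chains per-pair fits into a trajectory.

Ablation modes mirror the weighting study of the method:

* ``weighted``   -- use the provided per-pixel weight maps,
* ``unweighted`` -- all-ones weights (identical code path),
* ``2d_only``    -- w3d = 0, w2d = 1,
* ``3d_only``    -- w2d = 0, w3d = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DegenerateProblemError, InvalidArgumentError
from .lie_se3 import RigidTransform, Trajectory, TwistVector, chain_relative_poses, exp_map
from .residuals import FrameObservation, GeometricResidualProblem, WeightMaps

__all__ = ["SolverConfig", "SolverResult", "PoseModel", "PoseResults", "run_odometry", "solve_pose"]

logger = logging.getLogger(__name__)

MODES = ("weighted", "unweighted", "2d_only", "3d_only")


@dataclass(frozen=True)
class SolverConfig:
    """L-BFGS settings for the pose optimization.

    The stopping rule is: gradient infinity-norm <= ``gtol`` or relative
    objective change <= ``ftol``, within ``max_iterations``.  A fit is
    reported converged when the final gradient infinity-norm is below
    ``stationarity_tol`` -- the (looser) stationarity the implicit
    differentiation layer accepts.
    """

    max_iterations: int = 100
    gtol: float = 1e-9
    ftol: float = 1e-12
    history: int = 10
    init_policy: str = "identity"  # "identity" | "previous"
    mode: str = "weighted"
    stationarity_tol: float = 1e-6

    def __post_init__(self):
        if self.gtol <= 0 or self.ftol <= 0 or self.stationarity_tol <= 0:
            raise InvalidArgumentError("tolerances must be positive")
        if self.history < 1:
            raise InvalidArgumentError("history must be >= 1")
        if self.mode not in MODES:
            raise InvalidArgumentError(f"mode must be one of {MODES}")
        if self.init_policy not in ("identity", "previous"):
            raise InvalidArgumentError("init_policy must be 'identity' or 'previous'")


@dataclass
class SolverResult:
    """Minimal record of one pose solve (see :class:`PoseResults`)."""

    p_star: np.ndarray
    final_objective: float
    gradient_norm: float
    iterations: int
    converged: bool


def resolve_weights(
    weights: Optional[WeightMaps], shape, mode: str
) -> WeightMaps:
    """Materialize the effective weight maps for an ablation mode."""
    if mode == "weighted":
        if weights is None:
            raise InvalidArgumentError("mode 'weighted' requires weight maps")
        return weights
    if mode == "unweighted":
        return WeightMaps.ones(shape)
    if mode == "2d_only":
        return WeightMaps(np.ones(shape), np.zeros(shape))
    if mode == "3d_only":
        return WeightMaps(np.zeros(shape), np.ones(shape))
    raise InvalidArgumentError(f"unknown mode {mode!r}")


class PoseModel:
    """The relative-pose NLLS model for one frame pair.

    Parameters
    ----------
    t_frame, prev_frame
        Observations of the current and previous frame (normalized
        depth, temporal flow on ``t_frame``).
    weights
        Per-pixel weight maps; optional for the ablation modes.
    config
        Solver settings; ``config.mode`` selects the ablation.
    """

    def __init__(
        self,
        t_frame: FrameObservation,
        prev_frame: FrameObservation,
        weights: Optional[WeightMaps] = None,
        config: Optional[SolverConfig] = None,
    ):
        self.config = config or SolverConfig()
        self.problem = GeometricResidualProblem(t_frame, prev_frame)
        self.weights = resolve_weights(weights, self.problem.shape, self.config.mode)
        if self.problem.n_valid < 6:
            raise DegenerateProblemError(
                f"only {self.problem.n_valid} valid pixels; pose is unconstrained"
            )

    # ------------------------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.problem.n_valid

    def objective(self, p) -> float:
        return self.problem.objective(p, self.weights)

    def objective_grad(self, p):
        return self.problem.objective(p, self.weights, order=1)

    def hessian(self, p) -> np.ndarray:
        return self.problem.objective(p, self.weights, order=2)[2]

    def _newton_polish(self, p, max_steps: int = 8):
        """Drive the gradient to stationarity with damped Newton steps.

        L-BFGS stops on objective decrease, which near a flat minimum
        can leave the gradient above the stationarity the implicit
        differentiation layer needs; a few exact-Hessian steps (6x6
        solves with Levenberg damping) finish the job.  Steps are only
        accepted when they do not increase the objective and do shrink
        the gradient.
        """
        eye = np.eye(6)
        f, g, h = self.problem.objective(p, self.weights, order=2)
        gn = float(np.max(np.abs(g)))
        for _ in range(max_steps):
            if gn <= self.config.gtol:
                break
            accepted = False
            for lam in (0.0, 1e-12, 1e-9, 1e-6, 1e-3, 1.0):
                try:
                    step = np.linalg.solve(h + lam * eye, -g)
                except np.linalg.LinAlgError:
                    continue
                # generous backtracking: near the smoothing floor the
                # quadratic model only holds for very short steps
                for scale in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                    p_try = p + scale * step
                    f_try, g_try, h_try = self.problem.objective(
                        p_try, self.weights, order=2
                    )
                    gn_try = float(np.max(np.abs(g_try)))
                    if gn_try < gn and f_try <= f * (1 + 1e-12) + 1e-300:
                        p, f, g, h, gn = p_try, f_try, g_try, h_try, gn_try
                        accepted = True
                        break
                if accepted:
                    break
            if not accepted:
                break
        return p, f, gn

    def fit(self, start=None) -> "PoseResults":
        """Minimize the objective with L-BFGS from ``start`` (default 0)."""
        cfg = self.config
        p0 = np.zeros(6) if start is None else np.asarray(
            getattr(start, "data", start), dtype=float
        ).copy()
        f0 = self.objective(p0)

        history: list[float] = []

        def fun(p):
            f, g = self.objective_grad(p)
            return f, g

        def cb(pk):
            history.append(self.objective(pk))

        res = optimize.minimize(
            fun,
            p0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={
                "maxiter": cfg.max_iterations,
                "maxcor": cfg.history,
                "gtol": cfg.gtol,
                "ftol": cfg.ftol,
            },
        )
        p_star, f_star = res.x, float(res.fun)
        # never report an iterate worse than the start
        if f_star > f0:
            p_star, f_star = p0, f0
        p_star, f_star, gnorm = self._newton_polish(p_star)
        return PoseResults(
            model=self,
            params=p_star,
            final_objective=f_star,
            initial_objective=f0,
            gradient_norm=gnorm,
            iterations=int(res.nit),
            converged=bool(gnorm <= cfg.stationarity_tol),
            objective_history=history,
        )


class PoseResults:
    """Fitted relative pose with uncertainties and diagnostics."""

    def __init__(
        self,
        model: PoseModel,
        params: np.ndarray,
        final_objective: float,
        initial_objective: float,
        gradient_norm: float,
        iterations: int,
        converged: bool,
        objective_history: Sequence[float] = (),
    ):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.final_objective = final_objective
        self.initial_objective = initial_objective
        self.gradient_norm = gradient_norm
        self.iterations = iterations
        self.converged = converged
        self.objective_history = list(objective_history)

    param_names = ("tx", "ty", "tz", "wx", "wy", "wz")

    # ------------------------------------------------------------------
    @property
    def twist(self) -> TwistVector:
        return TwistVector(self.params)

    @property
    def transform(self) -> RigidTransform:
        """The SE(3) matrix ``exp(p*)`` mapping frame t into frame t-1."""
        return exp_map(self.params)

    def as_solver_result(self) -> SolverResult:
        return SolverResult(
            p_star=self.params.copy(),
            final_objective=self.final_objective,
            gradient_norm=self.gradient_norm,
            iterations=self.iterations,
            converged=self.converged,
        )

    def scale(self) -> float:
        """Residual scale sigma^2 = f(p*) / (n - 6)."""
        dof = max(self.model.nobs - 6, 1)
        return self.final_objective / dof

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of the twist, sigma^2 * (H/2)^{-1}.

        H/2 plays the role of J^T J in classical NLLS; near a good fit
        the two coincide.  Singular directions get infinite variance.
        """
        h = self.model.hessian(self.params) / 2.0
        try:
            hinv = np.linalg.inv(h)
        except np.linalg.LinAlgError:
            hinv = np.linalg.pinv(h)
        return self.scale() * hinv

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Relative pose (NLLS over se(3))",
            "=" * 46,
            f"pixels in Omega      {self.model.nobs}",
            f"mode                 {self.model.config.mode}",
            f"objective            {self.final_objective:.6e}",
            f"gradient inf-norm    {self.gradient_norm:.3e}",
            f"iterations           {self.iterations}",
            f"converged            {self.converged}",
            "-" * 46,
            f"{'param':>6} {'estimate':>14} {'std err':>12}",
        ]
        for name, val, s in zip(self.param_names, self.params, se):
            lines.append(f"{name:>6} {val:>14.8f} {s:>12.3e}")
        lines.append("=" * 46)
        return "\n".join(lines)


# ----------------------------------------------------------------------
def solve_pose(
    t_frame: FrameObservation,
    prev_frame: FrameObservation,
    weights: Optional[WeightMaps] = None,
    config: Optional[SolverConfig] = None,
    start=None,
) -> SolverResult:
    """Functional wrapper over ``PoseModel(...).fit(...)``."""
    return PoseModel(t_frame, prev_frame, weights, config).fit(start).as_solver_result()


def run_odometry(
    frames: Sequence[FrameObservation],
    weight_provider: Optional[Callable[[FrameObservation, FrameObservation], WeightMaps]] = None,
    config: Optional[SolverConfig] = None,
    start: Optional[RigidTransform] = None,
) -> tuple[Trajectory, list[PoseResults]]:
    """Chain per-pair pose fits over a sequence into a trajectory.

    ``weight_provider(t_frame, prev_frame)`` supplies weight maps (e.g.
    weight-network inference); it may be None for the ablation modes.
    With ``init_policy='previous'`` each solve starts from the last
    relative pose (constant-velocity assumption).  A failed frame logs a
    warning and falls back to its initialization.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise InvalidArgumentError("odometry needs at least two frames")
    cfg = config or SolverConfig()
    results: list[PoseResults] = []
    rel: list[np.ndarray] = []
    prev_p = np.zeros(6)
    for k in range(1, len(frames)):
        t_frame, prev_frame = frames[k], frames[k - 1]
        weights = weight_provider(t_frame, prev_frame) if weight_provider else None
        init = prev_p if cfg.init_policy == "previous" else np.zeros(6)
        try:
            model = PoseModel(t_frame, prev_frame, weights, cfg)
            fit = model.fit(start=init)
        except DegenerateProblemError as err:
            logger.warning("frame %d: degenerate problem (%s); using init pose", k, err)
            rel.append(init.copy())
            continue
        if not fit.converged:
            logger.warning(
                "frame %d: solver did not reach stationarity (|g|=%.2e)",
                k,
                fit.gradient_norm,
            )
        logger.info(
            "frame %d: f=%.3e |g|=%.2e iters=%d converged=%s",
            k,
            fit.final_objective,
            fit.gradient_norm,
            fit.iterations,
            fit.converged,
        )
        results.append(fit)
        rel.append(fit.params)
        prev_p = fit.params
    traj = chain_relative_poses(rel, start=start)
    return traj, results
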