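"""Trajectory error metrics: ATE-RMSE and relative pose errors.

The absolute trajectory error (ATE) first aligns the estimated
positions onto the ground truth with the closed-form least-squares
rigid transform (SVD/Kabsch, no scale -- stereo provides metric scale)
and reports the RMSE of the remaining position differences; it captures
the overall trajectory shape and accumulates drift.  The relative pose
error (RPE) compares per-step motions: for step ``i`` and span ``delta``
the error transform is ``E = (gt_i^{-1} gt_{i+d})^{-1} (est_i^{-1}
est_{i+d})``; RPE-trans is the norm of E's translation and RPE-rot its
rotation angle in degrees, reported mean +/- std over all steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .lie_se3 import RigidTransform, Trajectory

__all__ = ["align_trajectories", "ate_rmse", "rpe", "RpeStats", "plot_trajectories"]


def _check_matched(gt: Trajectory, est: Trajectory):
    if len(gt) != len(est):
        raise InvalidArgumentError("trajectories must have equal length")
    if not np.allclose(gt.timestamps, est.timestamps):
        raise InvalidArgumentError("trajectory timestamps do not match")


def align_trajectories(gt: Trajectory, est: Trajectory) -> RigidTransform:
    """Least-squares rigid transform g minimizing sum |gt_i - g(est_i)|^2.

    Closed-form solution via SVD of the cross-covariance of the centered
    position clouds (rotation + translation, no scale).
    """
    _check_matched(gt, est)
    if len(gt) < 3:
        raise InvalidArgumentError("alignment needs at least 3 poses")
    a = est.positions()
    b = gt.positions()
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return RigidTransform.from_rt(r, t)


def ate_rmse(gt: Trajectory, est: Trajectory) -> float:
    """Absolute trajectory error: RMSE of positions after alignment."""
    g = align_trajectories(gt, est)
    diff = gt.positions() - est.transformed(g).positions()
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


@dataclass(frozen=True)
class RpeStats:
    trans_mean: float
    trans_std: float
    rot_mean_deg: float
    rot_std_deg: float


def rpe(gt: Trajectory, est: Trajectory, delta: int = 1) -> RpeStats:
    """Relative pose error over spans of ``delta`` frames."""
    _check_matched(gt, est)
    if delta < 1 or len(gt) <= delta:
        raise InvalidArgumentError("need trajectory length > delta >= 1")
    trans, rot = [], []
    for i in range(len(gt) - delta):
        dg = gt[i].inverse() @ gt[i + delta]
        de = est[i].inverse() @ est[i + delta]
        e = dg.inverse() @ de
        trans.append(np.linalg.norm(e.t))
        # atan2 form of the rotation angle: accurate near zero, where
        # arccos of the trace loses half the significant digits
        r = e.R
        s = 0.5 * np.linalg.norm([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
        c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        rot.append(np.degrees(np.arctan2(s, c)))
    trans = np.asarray(trans)
    rot = np.asarray(rot)
    return RpeStats(
        float(trans.mean()),
        float(trans.std()),
        float(rot.mean()),
        float(rot.std()),
    )


def plot_trajectories(gt: Trajectory, est: Trajectory, path: str):
    """Save a simple top-down (x, z) plot of both trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pg, pe = gt.positions(), est.positions()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pg[:, 0], pg[:, 2], "k-", label="ground truth")
    ax.plot(pe[:, 0], pe[:, 2], "r--", label="estimate")
    ax.set_xlabel("x")
    ax.set_ylabel("z")
    ax.legend()
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
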