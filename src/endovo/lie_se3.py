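"""se(3)/SE(3) machinery: twists, rigid transforms, exp/log, pose chaining.

Conventions used throughout the package
---------------------------------------

* A twist is ordered ``(v, w)``: three translation components followed by
  three rotation components (axis-angle scaled, radians).  Translations
  are expressed in normalized depth units whenever the depth maps fed to
  the residuals are normalized.
* The relative pose ``p_t`` of frame ``t`` maps 3-D points expressed in
  the camera frame at time ``t`` into the camera frame at time ``t-1``
  (it aligns view t onto view t-1).  Consequently, with camera-to-world
  poses ``C_t``, ``exp(p_t) = C_{t-1}^{-1} C_t`` and absolute poses chain
  as ``C_t = C_{t-1} @ exp(p_t)``.

The exponential map is implemented on top of :mod:`endovo._autodiff` so
the same code path yields values, first and second derivatives with
respect to the twist -- the differentiability the declarative layer
requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from .exceptions import BranchError, InvalidArgumentError

__all__ = [
    "SMALL_ANGLE",
    "TwistVector",
    "RigidTransform",
    "Trajectory",
    "exp_map",
    "log_map",
    "compose",
    "chain_relative_poses",
    "relative_twists",
]

#: angle threshold below which the Taylor branch of the Rodrigues
#: coefficients is used.  1e-3 keeps both branches at full float64
#: accuracy: below it the 3-term series truncates at ~1e-21 relative,
#: above it the trigonometric forms (with the half-angle identity for
#: 1 - cos) are exact to roundoff.
SMALL_ANGLE = 1e-3

_ORTHO_TOL = 1e-9


def as_twist(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (6,):
        raise InvalidArgumentError(f"twist must have 6 components, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("twist has non-finite components")
    return p


@dataclass(frozen=True)
class TwistVector:
    """A relative pose in se(3): translation ``v`` then rotation ``w``."""

    data: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "data", as_twist(self.data))

    @property
    def v(self) -> np.ndarray:
        return self.data[:3]

    @property
    def w(self) -> np.ndarray:
        return self.data[3:]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid transform with validated structure."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidArgumentError("RigidTransform expects a 4x4 matrix")
        if not np.all(m[3] == np.array([0.0, 0.0, 0.0, 1.0])):
            raise InvalidArgumentError("last row must be exactly (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidArgumentError("rotation block is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > _ORTHO_TOL:
            raise InvalidArgumentError("rotation block must have det +1")
        object.__setattr__(self, "matrix", m)

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rt(cls, r: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = t
        return cls(m)

    @property
    def R(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r, t = self.R, self.t
        return RigidTransform.from_rt(r.T, -r.T @ t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points of shape (3, n) or (3,)."""
        pts = np.asarray(points, dtype=float)
        return self.R @ pts + (self.t[:, None] if pts.ndim == 2 else self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)


# ----------------------------------------------------------------------
# Rodrigues coefficients as smooth functions of the squared angle.
#
# A = sin(t)/t, B = (1-cos(t))/t^2, C = (t-sin(t))/t^3 = (1-A)/t^2.
# Working with u = t^2 keeps everything smooth through u -> 0 once the
# Taylor branch takes over, so the autodiff path stays exact.
def _rodrigues_coefficients(u):
    if ad.value(u) > SMALL_ANGLE**2:
        theta = ad.sqrt(u)
        a = ad.sin(theta) / theta
        half = ad.sin(theta * 0.5)
        b = 2.0 * (half * half) / u  # (1 - cos t)/t^2 without cancellation
        c = (1.0 - a) / u
    else:  # 3-term Taylor expansions in u = theta^2
        a = 1.0 - u / 6.0 + (u * u) / 120.0
        b = 0.5 - u / 24.0 + (u * u) / 720.0
        c = 1.0 / 6.0 - u / 120.0 + (u * u) / 5040.0
    return a, b, c


def _cross(w, x):
    """Cross product of a 3-vector ``w`` with rows ``x`` (lists of length 3)."""
    return [
        w[1] * x[2] - w[2] * x[1],
        w[2] * x[0] - w[0] * x[2],
        w[0] * x[1] - w[1] * x[0],
    ]


def se3_apply(p, points: np.ndarray):
    """Apply ``exp(p)`` to constant points (3, n); works for HD twists.

    Returns a list of three rows (HD or ndarray).  This is the
    differentiable core used by the residual/objective code.
    """
    v = [p[0], p[1], p[2]]
    w = [p[3], p[4], p[5]]
    u = w[0] * w[0] + w[1] * w[1] + w[2] * w[2]
    a, b, c = _rodrigues_coefficients(u)

    rows = [points[0], points[1], points[2]]
    wx = _cross(w, rows)
    wwx = _cross(w, wx)
    # translation part of exp(p) is V v with V = I + B K + C K^2
    wv = _cross(w, v)
    wwv = _cross(w, wv)
    out = []
    for i in range(3):
        trans = v[i] + b * wv[i] + c * wwv[i]
        out.append(rows[i] + a * wx[i] + b * wwx[i] + trans)
    return out


def exp_map(p) -> RigidTransform:
    """Closed-form se(3) exponential (Rodrigues with small-angle fallback)."""
    p = np.asarray(getattr(p, "data", p), dtype=float)
    p = as_twist(p)
    v, w = p[:3], p[3:]
    u = float(w @ w)
    a, b, c = _rodrigues_coefficients(u)
    k = np.array([[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]])
    k2 = k @ k
    r = np.eye(3) + a * k + b * k2
    vmat = np.eye(3) + b * k + c * k2
    return RigidTransform.from_rt(r, vmat @ v)


def log_map(transform: RigidTransform) -> TwistVector:
    """Inverse of :func:`exp_map` on the principal branch (angle < pi)."""
    r, t = transform.R, transform.t
    cos_theta = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta >= np.pi - 1e-9:
        raise BranchError("rotation angle too close to pi for a unique logarithm")
    skew = (r - r.T) / 2.0
    vee = np.array([skew[2, 1], skew[0, 2], skew[1, 0]])
    if theta < SMALL_ANGLE:
        w = vee * (1.0 + theta**2 / 6.0)
    else:
        w = vee * theta / np.sin(theta)
    u = float(w @ w)
    a, b, c = _rodrigues_coefficients(u)
    k = np.array([[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]])
    # V^{-1} = I - K/2 + (1/u)(1 - A/(2B)) K^2   (smooth limit 1/12 at u=0)
    if u > SMALL_ANGLE**2:
        coef = (1.0 - a / (2.0 * b)) / u
    else:
        coef = 1.0 / 12.0 + u / 720.0
    vinv = np.eye(3) - 0.5 * k + coef * (k @ k)
    return TwistVector(np.concatenate([vinv @ t, w]))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return RigidTransform(a.matrix @ b.matrix)


# ----------------------------------------------------------------------
@dataclass
class Trajectory:
    """Timestamped absolute camera-to-world poses."""

    timestamps: np.ndarray
    poses: list

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) != len(self.poses):
            raise InvalidArgumentError("timestamps and poses must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i) -> RigidTransform:
        return self.poses[i]

    def positions(self) -> np.ndarray:
        """Camera positions, shape (n, 3)."""
        return np.stack([p.t for p in self.poses])

    def transformed(self, g: RigidTransform) -> "Trajectory":
        """Apply a common rigid transform ``g`` on the left."""
        return Trajectory(self.timestamps.copy(), [g @ p for p in self.poses])

    def scaled_translation(self, factor: float) -> "Trajectory":
        """Scale all translations (e.g. normalized depth units -> mm)."""
        return Trajectory(
            self.timestamps.copy(),
            [RigidTransform.from_rt(p.R, p.t * factor) for p in self.poses],
        )


def chain_relative_poses(
    rel: Sequence, start: RigidTransform | None = None, timestamps=None
) -> Trajectory:
    """Chain relative poses ``p_t`` (mapping frame t into frame t-1) into
    absolute camera-to-world poses: ``C_t = C_{t-1} @ exp(p_t)``."""
    rel = list(rel)
    if not rel:
        raise InvalidArgumentError("need at least one relative pose")
    start = RigidTransform.identity() if start is None else start
    poses = [start]
    for p in rel:
        t_rel = p if isinstance(p, RigidTransform) else exp_map(p)
        poses.append(poses[-1] @ t_rel)
    if timestamps is None:
        timestamps = np.arange(len(poses), dtype=float)
    return Trajectory(timestamps, poses)


def relative_twists(traj: Trajectory) -> list:
    """Per-step twists ``log(C_{t-1}^{-1} C_t)`` -- inverse of chaining."""
    return [
        log_map(traj[i - 1].inverse() @ traj[i]) for i in range(1, len(traj))
    ]
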