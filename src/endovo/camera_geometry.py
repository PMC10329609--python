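"""Pinhole camera geometry: projection, back-projection, stereo depth,
depth normalization and bilinear sampling.

Pixel convention: 0-based, pixel centers at integer coordinates, ``x``
is the column index and ``y`` the row index (arrays are indexed
``[y, x]``).  This matches the convention of Middlebury ``.flo`` flow
files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "CameraIntrinsics",
    "DepthMap",
    "FlowField",
    "PixelMask",
    "backproject_3d",
    "project_2d",
    "disparity_to_depth",
    "normalize_depth",
    "bilinear_sample",
]

#: minimum depth (normalized units) for a point to count as in front of
#: the camera.
Z_EPS = 1e-6


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of a rectified stereo pair (left camera)."""

    fx: float
    fy: float
    cx: float
    cy: float
    baseline: float  # same physical unit as unnormalized depth
    width: int  # X, number of columns
    height: int  # Y, number of rows

    def __post_init__(self):
        if min(self.fx, self.fy, self.baseline) <= 0:
            raise InvalidArgumentError("fx, fy and baseline must be positive")
        if not (0 < self.cx < self.width and 0 < self.cy < self.height):
            raise InvalidArgumentError("principal point must lie inside the image")

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics after resizing the image by ``factor`` (e.g. 0.5)."""
        return CameraIntrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=self.cx * factor,
            cy=self.cy * factor,
            baseline=self.baseline,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
        )


@dataclass
class DepthMap:
    """A per-pixel depth grid with an explicit validity mask.

    ``values`` is (height, width).  ``normalized`` records whether values
    were divided by ``max_expected_depth``; the residuals require
    normalized depth.  Pixels whose normalized depth exceeds 1 keep
    their value but are flagged in ``out_of_range`` and dropped from the
    validity mask, which keeps the pose objective smooth.
    """

    values: np.ndarray
    valid: Optional[np.ndarray] = None
    normalized: bool = False
    max_expected_depth: Optional[float] = None
    out_of_range: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("depth values must be a 2-D grid")
        if self.valid is None:
            self.valid = np.isfinite(self.values) & (self.values > 0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise InvalidArgumentError("validity mask shape mismatch")
        if self.out_of_range is None:
            self.out_of_range = np.zeros_like(self.valid)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class FlowField:
    """A dense displacement field ``(dx, dy)`` in pixels.

    ``role`` is ``"temporal"`` (maps frame-t pixels toward frame t-1) or
    ``"parallax"`` (left -> right stereo displacement).
    """

    uv: np.ndarray  # (height, width, 2), ordering (dx, dy)
    role: str = "temporal"
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.uv = np.asarray(self.uv, dtype=float)
        if self.uv.ndim != 3 or self.uv.shape[2] != 2:
            raise InvalidArgumentError("flow field must have shape (H, W, 2)")
        if self.role not in ("temporal", "parallax"):
            raise InvalidArgumentError(f"unknown flow role {self.role!r}")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.uv), axis=2)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.uv.shape[:2]:
                raise InvalidArgumentError("flow validity mask shape mismatch")

    @property
    def shape(self):
        return self.uv.shape[:2]


@dataclass
class PixelMask:
    """Boolean per-pixel mask; ``True`` marks a usable pixel."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidArgumentError("pixel mask must be a 2-D grid")

    @property
    def shape(self):
        return self.values.shape


# ----------------------------------------------------------------------
def backproject_3d(depth: DepthMap, coords: np.ndarray, intrinsics: CameraIntrinsics):
    """Back-project pixels to homogeneous 3-D points.

    ``coords`` has shape (2, n) as (x, y) pixel coordinates (integers).
    Returns ``(points, valid)`` where points is (4, n) with last row 1
    and ``valid`` flags pixels with usable depth.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    x, y = coords[0], coords[1]
    xi = np.round(x).astype(int)
    yi = np.round(y).astype(int)
    inside = (xi >= 0) & (xi < intrinsics.width) & (yi >= 0) & (yi < intrinsics.height)
    if not np.all(inside):
        raise InvalidArgumentError("back-projection coordinates outside image bounds")
    d = depth.values[yi, xi]
    valid = depth.valid[yi, xi]
    px = d * (x - intrinsics.cx) / intrinsics.fx
    py = d * (y - intrinsics.cy) / intrinsics.fy
    points = np.stack([px, py, d, np.ones_like(d)])
    points[:3, ~valid] = 0.0  # flagged, never NaN
    return points, valid


def project_2d(points, intrinsics: CameraIntrinsics, eps: float = Z_EPS):
    """Project homogeneous (or Euclidean) 3-D points to pixels.

    Accepts (3, n) or (4, n).  Returns ``(pixels, valid)`` where pixels
    is (2, n); points with ``z <= eps`` are flagged invalid (their pixel
    values are computed against a clamped z so no NaN propagates).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    x, y, z = pts[0], pts[1], pts[2]
    valid = z > eps
    zs = np.where(valid, z, eps)
    u = intrinsics.fx * x / zs + intrinsics.cx
    v = intrinsics.fy * y / zs + intrinsics.cy
    return np.stack([u, v]), valid


def disparity_to_depth(
    parallax: FlowField, intrinsics: CameraIntrinsics, eps: float = 1e-6
) -> DepthMap:
    """Convert the horizontal component of a parallax flow to depth.

    depth = fx * baseline / |dx|; near-zero disparities are flagged
    invalid rather than producing huge depths.
    """
    if parallax.role != "parallax":
        raise InvalidArgumentError("disparity_to_depth expects a parallax flow")
    disp = np.abs(parallax.uv[..., 0])
    ok = parallax.valid & (disp > eps)
    safe = np.where(ok, disp, 1.0)
    depth = np.where(ok, intrinsics.fx * intrinsics.baseline / safe, 0.0)
    return DepthMap(values=depth, valid=ok, normalized=False)


def normalize_depth(depth: DepthMap, max_expected_depth: float) -> DepthMap:
    """Divide depth values by the maximum expected depth.

    Normalization puts translation and rotation components of the twist
    on the same order of magnitude, which conditions the pose
    optimization.  Values above 1 are retained but flagged out-of-range
    and removed from the validity mask.
    """
    if max_expected_depth <= 0:
        raise InvalidArgumentError("max_expected_depth must be positive")
    if depth.normalized:
        raise InvalidArgumentError("depth map is already normalized")
    values = depth.values / max_expected_depth
    out = values > 1.0
    return DepthMap(
        values=values,
        valid=depth.valid & ~out,
        normalized=True,
        max_expected_depth=max_expected_depth,
        out_of_range=out,
    )


def bilinear_sample(field: np.ndarray, coords: np.ndarray, valid: np.ndarray | None = None):
    """Sample a grid at fractional pixel coordinates.

    ``field`` is (H, W) or (H, W, C); ``coords`` is (2, n) as (x, y).
    Returns ``(samples, ok)`` with samples (n,) or (n, C).  Coordinates
    outside ``[0, W-1] x [0, H-1]`` are flagged; when a per-pixel
    ``valid`` grid is given, a sample is accepted only if all four
    neighbours are valid (conservative, keeps interpolation exact).
    """
    field = np.asarray(field, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    h, w = field.shape[:2]
    x, y = coords[0], coords[1]
    ok = np.isfinite(x) & np.isfinite(y) & (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    xc = np.clip(x, 0, w - 1)
    yc = np.clip(y, 0, h - 1)
    x0 = np.clip(np.floor(xc).astype(int), 0, w - 2) if w > 1 else np.zeros_like(xc, int)
    y0 = np.clip(np.floor(yc).astype(int), 0, h - 2) if h > 1 else np.zeros_like(yc, int)
    x1, y1 = x0 + (1 if w > 1 else 0), y0 + (1 if h > 1 else 0)
    ax = (xc - x0)[..., None] if field.ndim == 3 else xc - x0
    ay = (yc - y0)[..., None] if field.ndim == 3 else yc - y0
    f00, f10 = field[y0, x0], field[y0, x1]
    f01, f11 = field[y1, x0], field[y1, x1]
    top = f00 * (1 - ax) + f10 * ax
    bot = f01 * (1 - ax) + f11 * ax
    samples = top * (1 - ay) + bot * ay
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        ok = ok & valid[y0, x0] & valid[y0, x1] & valid[y1, x0] & valid[y1, x1]
    return samples, ok
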