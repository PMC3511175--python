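"""Analytic two-parameter model of LV short-axis wall motion.

The model composes two maps acting on material points of the myocardium,
expressed in an LV-centered physical frame (millimetres, x to the right,
y up, as displayed on screen):

* an isotropic radial contraction with parameter ``alpha`` (mm): a point
  at end-diastolic radius ``r`` is scaled by ``1 - alpha**2 / r**2``, so
  its radial displacement is ``alpha**2 / r`` — larger near the
  endocardium than the epicardium (1/r law);
* a radially non-uniform rotation with parameter ``beta`` (mm): a
  rotation by the angle ``theta = beta / r``, positive ``beta`` meaning
  clockwise when the slice is viewed head-to-toe.

Both the contraction factor and the rotation angle are evaluated at the
ORIGINAL end-diastolic radius ``r = hypot(x, y)``.  Note that the angle
law ``beta / r`` produces a *larger* rotation angle at smaller radii;
physiological descriptions of twist have the epicardium leading, so the
sign/magnitude profile across the wall is an empirical choice of this
model, not a statement about fibre mechanics.

The model is only valid for ``|p| > alpha`` (positive contraction
factor); out-of-domain evaluation raises :class:`ValueError`.

Chirality note: in this right-handed physical frame a *clockwise*
rotation (head-to-toe view) decreases the mathematical angle.  Image
arrays index rows downward; that flip is handled once, in the mesh
rasterizer's coordinate mapping, never here.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "Point2",
    "ModelParams",
    "radial_map",
    "rotation_map",
    "forward_transform",
    "inverse_transform",
    "displacement_magnitude",
    "forward_points",
    "inverse_points",
]


@dataclasses.dataclass(frozen=True)
class Point2:
    """A point in the LV-centered physical frame (mm; x right, y up)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2 components must be finite, got ({self.x}, {self.y})")

    @property
    def r(self) -> float:
        """Distance to the LV center."""
        return math.hypot(self.x, self.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The model state at one cardiac phase.

    Parameters
    ----------
    alpha:
        Radial contraction parameter, mm, >= 0.
    beta:
        Rotation parameter, mm; positive = clockwise viewed head-to-toe.
    t:
        Time since end-diastole, seconds (informational).
    """

    alpha: float
    beta: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


# ---------------------------------------------------------------------------
# vectorized kernels (no domain checks; callers validate)

def _forward_xy(x, y, alpha: float, beta: float):
    r = np.hypot(x, y)
    scale = 1.0 - (alpha * alpha) / (r * r)
    theta = beta / r
    c, s = np.cos(theta), np.sin(theta)
    # clockwise-positive rotation in the right-handed physical frame
    xp = scale * (x * c + y * s)
    yp = scale * (-x * s + y * c)
    return xp, yp


def _inverse_xy(xp, yp, alpha: float, beta: float):
    rp = np.hypot(xp, yp)
    # positive root of r**2 - rp*r - alpha**2 = 0
    r = 0.5 * rp * (1.0 + np.sqrt(1.0 + 4.0 * (alpha * alpha) / (rp * rp)))
    theta = beta / r
    c, s = np.cos(theta), np.sin(theta)
    # counter-clockwise un-rotation, then undo the radial scaling
    xu = xp * c - yp * s
    yu = xp * s + yp * c
    scale = r / rp
    return xu * scale, yu * scale


# ---------------------------------------------------------------------------
# scalar API

def radial_map(p: Point2, alpha: float) -> Point2:
    """Isotropic radial contraction: scale ``p`` by ``1 - alpha**2/r**2``.

    The output radius is ``r - alpha**2/r``; the direction is unchanged.
    Requires ``|p| > alpha`` so the contraction factor stays positive.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    r = p.r
    if r == 0.0:
        raise ValueError("radial_map is undefined at the origin")
    if r <= alpha:
        raise ValueError(
            f"point radius {r:g} mm is inside the model's validity domain bound "
            f"(requires |p| > alpha = {alpha:g} mm)"
        )
    scale = 1.0 - (alpha * alpha) / (r * r)
    return Point2(scale * p.x, scale * p.y)


def rotation_map(p: Point2, beta: float, r_eval: float) -> Point2:
    """Rotate ``p`` by the angle ``theta = beta / r_eval``.

    Positive ``beta`` rotates clockwise in the head-to-toe view; the
    radius of ``p`` is preserved exactly.
    """
    if r_eval <= 0:
        raise ValueError(f"r_eval must be > 0, got {r_eval}")
    theta = beta / r_eval
    c, s = math.cos(theta), math.sin(theta)
    return Point2(p.x * c + p.y * s, -p.x * s + p.y * c)


def forward_transform(p: Point2, params: ModelParams) -> Point2:
    """Full forward map: radial contraction then rotation.

    Both the contraction factor ``1 - alpha**2/r**2`` and the rotation
    angle ``beta / r`` use the original end-diastolic radius ``r = |p|``.
    """
    contracted = radial_map(p, params.alpha)
    return rotation_map(contracted, params.beta, p.r)


def inverse_transform(p_prime: Point2, params: ModelParams) -> Point2:
    """Invert :func:`forward_transform`.

    Recovers the end-diastolic radius as the positive root of
    ``r**2 - r'*r - alpha**2 = 0``, i.e.
    ``r = r' * (1 + sqrt(1 + 4*alpha**2/r'**2)) / 2``, un-rotates by
    ``beta / r`` and un-scales.  Exact round trip with the forward map
    to numerical tolerance.
    """
    rp = p_prime.r
    if rp == 0.0:
        raise ValueError("inverse_transform is undefined at the origin")
    x, y = _inverse_xy(p_prime.x, p_prime.y, params.alpha, params.beta)
    return Point2(float(x), float(y))


def displacement_magnitude(r: float, alpha: float) -> float:
    """Radial displacement ``alpha**2 / r`` of a point at radius ``r``."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if alpha != 0.0 and r <= alpha:
        raise ValueError(f"requires r > alpha (got r={r}, alpha={alpha})")
    return (alpha * alpha) / r


# ---------------------------------------------------------------------------
# array API (used by the mesh, fit and phantom modules)

def forward_points(xy: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Apply the forward map to an ``(N, 2)`` array of points (mm).

    Raises :class:`ValueError` if any point violates ``|p| > alpha``,
    reporting the first offending point.
    """
    xy = np.asarray(xy, dtype=float)
    r = np.hypot(xy[:, 0], xy[:, 1])
    bad = r <= alpha
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"point {tuple(xy[i])} at radius {r[i]:g} mm violates |p| > alpha = {alpha:g} mm"
        )
    xp, yp = _forward_xy(xy[:, 0], xy[:, 1], alpha, beta)
    return np.column_stack([xp, yp])


def inverse_points(xy_prime: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Apply the inverse map to an ``(N, 2)`` array of points (mm)."""
    xy_prime = np.asarray(xy_prime, dtype=float)
    rp = np.hypot(xy_prime[:, 0], xy_prime[:, 1])
    if (rp == 0).any():
        raise ValueError("inverse map is undefined at the origin")
    x, y = _inverse_xy(xy_prime[:, 0], xy_prime[:, 1], alpha, beta)
    return np.column_stack([x, y])
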