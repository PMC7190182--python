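"""Weighted total-least-squares canal planes and angle conventions.

A canal's functional plane is the plane minimizing

    f(a, b, c, d) = sum_i | w_i * n . (x_i - c_i) |^2

over unit normals n = (a, b, c), where x_i are points of the canal's
volumetric cloud, c_i is the nearest point of the canal's centroid path and
w_i = 1 / A_i^2 is the inverse squared cross-sectional area of the nearest
canal division. Down-weighting wide divisions makes the fit track the narrow
lumen that dominates endolymph flow, approximating the canal's maximal
response plane.

Angle conventions (AC-PC frame, RAS):

* inter-canal angles are ``theta = arccos(n1 . n2)`` of the *oriented*
  normals and are deliberately not folded to <= 90 deg;
* lateral-canal normals are oriented with n_z > 0, superior and posterior
  normals with sign(n_x) matching the side (+x for right);
* the lateral inclination is the angle between the canal plane and the
  axial plane, signed positive when the plane's anterior edge tilts
  superiorly (sign of -n_y once n_z > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitPlane",
    "fit_weighted_plane_points",
    "plane_angle",
    "lateral_inclination",
    "orient_normal",
]

_SIDE_SIGN = {"R": 1.0, "L": -1.0}


@dataclass
class FitPlane:
    """Plane a x + b y + c z + d = 0 with unit normal (a, b, c)."""

    normal: np.ndarray
    offset: float
    weighted_residual: float = 0.0

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("plane normal must be unit length")
        self.normal = self.normal / n
        if self.weighted_residual < 0:
            raise ValueError("weighted residual must be >= 0")


def fit_weighted_plane_points(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    centers: np.ndarray | None = None,
) -> FitPlane:
    """Fit the plane minimizing ``sum |w_i n.(x_i - c)|^2`` over unit n.

    Parameters
    ----------
    points
        (N, 3) cloud points x_i.
    weights
        Per-point weights w_i (>= 0). Uniform if omitted. The weight
        multiplies the residual *inside* the square, so points enter the
        second-moment matrix with w_i^2.
    centers
        Residual centre(s). Default: the w^2-weighted centroid of the
        cloud, for which the uniform-weight fit coincides exactly with the
        classic total-least-squares plane (smallest principal component).
        A per-point (N, 3) array measures deviations relative to a matched
        reference path instead.

    Returns
    -------
    FitPlane
        Normal = eigenvector of ``sum w_i^2 d_i d_i^T`` (d_i = x_i - c_i)
        with the smallest eigenvalue; ``weighted_residual`` = attained f;
        ``offset`` = -n . (w^2-weighted centroid).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.shape[0] < 4:
        raise ValueError("need at least 4 points to fit a plane")
    if weights is None:
        w2 = np.ones(x.shape[0])
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        w2 = w * w
    if w2.sum() <= 0:
        raise ValueError("all weights are zero")
    xbar = np.average(x, axis=0, weights=w2)
    if centers is None:
        c = np.broadcast_to(xbar, x.shape)
    else:
        c = np.broadcast_to(np.asarray(centers, dtype=float).reshape(-1, 3), x.shape)
    d = x - c
    M = (d * w2[:, None]).T @ d
    evals, evecs = np.linalg.eigh(M)
    # collinear clouds leave the normal undetermined in a 2D subspace
    scale = max(evals[-1], 1e-300)
    if evals[1] / scale < 1e-12:
        raise ValueError("points are collinear; plane normal undetermined")
    n = evecs[:, 0]
    return FitPlane(n, float(-n @ xbar), float(max(evals[0], 0.0)))


def orient_normal(n: np.ndarray, canal: str, side: str) -> np.ndarray:
    """Resolve the +/- n ambiguity of a fitted plane normal.

    Lateral normals point superiorly (n_z > 0); superior and posterior
    normals point toward their own side (sign of n_x = side sign), which
    makes inter-canal angles reproducible without folding at 90 deg.
    """
    n = np.asarray(n, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    if canal == "lateral":
        key = n[2] if abs(n[2]) > 1e-12 else n[1]
    else:
        s = _SIDE_SIGN[side]
        key = s * n[0] if abs(n[0]) > 1e-12 else n[1]
    return -n if key < 0 else n


def plane_angle(p1: FitPlane | np.ndarray, p2: FitPlane | np.ndarray) -> float:
    """Angle (degrees) between two oriented plane normals, in [0, 180].

    Not folded at 90 deg: with the orientation convention above, values on
    either side of 90 deg are meaningful.
    """
    n1 = p1.normal if isinstance(p1, FitPlane) else np.asarray(p1, dtype=float)
    n2 = p2.normal if isinstance(p2, FitPlane) else np.asarray(p2, dtype=float)
    cosang = float(np.clip(n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2)), -1, 1))
    return float(np.degrees(np.arccos(cosang)))


def lateral_inclination(p: FitPlane | np.ndarray) -> float:
    """Signed angle (degrees) between a lateral-canal plane and the axial plane.

    Positive when the anterior edge of the plane tilts superiorly. Invariant
    under flipping the stored normal.
    """
    n = p.normal if isinstance(p, FitPlane) else np.asarray(p, dtype=float)
    n = n / np.linalg.norm(n)
    if n[2] < 0 or (n[2] == 0 and n[1] < 0):
        n = -n
    mag = float(np.degrees(np.arccos(np.clip(n[2], -1, 1))))
    sign = 1.0 if -n[1] >= 0 else -1.0
    return sign * mag
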