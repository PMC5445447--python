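"""Small geometric helpers shared across modules.

Coordinate conventions
----------------------
Points are ``(x, y)`` with ``x`` to the right and ``y`` down (image
convention), 0-based.  Angles handed to users are degrees measured
counterclockwise from +x in the mathematical y-up frame; the flip happens
at the reporting boundary via :func:`angle_deg_yup`.
"""

from __future__ import annotations

import numpy as np


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return float(a) if np.ndim(deg) == 0 else a


def angle_deg_yup(vec: np.ndarray) -> float:
    """Direction of an image-coordinate vector, reported in y-up degrees."""
    vx, vy = float(vec[0]), float(vec[1])
    return float(np.degrees(np.arctan2(-vy, vx)))


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def rotation_matrix(deg: float) -> np.ndarray:
    """Rotation by ``deg`` degrees in raw (x, y) coordinates."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s], [s, c]])


def polygon_signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (n, 2) vertices."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals at every vertex of a closed polygon.

    Tangents use central differences over the closed chain; the normal is the
    tangent rotated by 90 degrees, with its sign fixed by the polygon's
    orientation so it points away from the interior.
    """
    tang = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]
    # rotate tangent by -90 deg (image coords): (tx, ty) -> (ty, -tx)
    nrm = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    if polygon_signed_area(points) > 0:  # y-down: positive area = CCW on screen
        nrm = -nrm
    # sign sanity: flip globally if normals point toward the centroid
    c = points.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", nrm, points - c)) < 0:
        nrm = -nrm
    return nrm


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Least-squares similarity transform (scale, rotation, translation).

    Returns ``(scale, theta_deg, translation)`` minimizing
    ``sum || s R src_i + t - dst_i ||^2`` without reflection.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    # complex formulation: z = x + iy
    zsrc = (src[:, 0] - cs[0]) + 1j * (src[:, 1] - cs[1])
    zdst = (dst[:, 0] - cd[0]) + 1j * (dst[:, 1] - cd[1])
    denom = np.sum(np.abs(zsrc) ** 2)
    if denom == 0:
        return 1.0, 0.0, cd - cs
    coef = np.sum(np.conj(zsrc) * zdst) / denom
    scale = float(np.abs(coef))
    theta = float(np.degrees(np.angle(coef)))
    if scale == 0:
        scale = 1.0
        theta = 0.0
    R = rotation_matrix(theta)
    t = cd - scale * (R @ cs)
    return scale, theta, t


def apply_similarity(points: np.ndarray, scale: float, theta_deg: float,
                     t: np.ndarray) -> np.ndarray:
    R = rotation_matrix(theta_deg)
    return scale * (points @ R.T) + np.asarray(t, dtype=float)


def invert_similarity(scale: float, theta_deg: float, t: np.ndarray):
    """Parameters of the inverse similarity transform."""
    R = rotation_matrix(-theta_deg)
    inv_scale = 1.0 / scale
    inv_t = -inv_scale * (R @ np.asarray(t, dtype=float))
    return inv_scale, -theta_deg, inv_t
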