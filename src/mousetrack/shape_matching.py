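"""Articulation-insensitive shape matching of closed contours.

Each contour is resampled to ``n`` equidistant boundary points and described
at every point by a log-polar histogram (shape context) of the remaining
points.  Plain Euclidean geometry is replaced by the *inner distance* — the
length of the shortest path between two boundary points that stays inside
the silhouette — and the *inner angle* — the angle between the boundary
tangent and the initial direction of that path.  Both are insensitive to
bending of an articulated body, which is exactly the deformation a mouse
spine produces.  Histograms are compared with the chi-square statistic and
the optimal one-to-one correspondence is found by solving the linear
assignment problem on the resulting cost matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import shortest_path
from shapely.geometry import Polygon

from ._geometry import wrap_angle

DEFAULT_N_POINTS = 100
DEFAULT_N_R = 5
DEFAULT_N_THETA = 12
# radial bin range as multiples of the mean inner distance
R_INNER, R_OUTER = 0.125, 2.0


@dataclass
class Contour:
    """Closed polygon of ``n`` approximately equidistant boundary points."""

    points: np.ndarray  # (n, 2) float, (x, y)

    @property
    def n(self) -> int:
        return len(self.points)

    def reversed(self) -> "Contour":
        """Same polygon traversed in the opposite direction (point 0 kept)."""
        return Contour(np.roll(self.points[::-1], 1, axis=0))


@dataclass
class ShapeDescriptor:
    histograms: np.ndarray          # (n, n_r * n_theta) int counts
    n_r: int
    n_theta: int
    distances: np.ndarray = field(repr=False, default=None)  # inner distances
    angles: np.ndarray = field(repr=False, default=None)     # inner angles, deg


@dataclass
class MatchResult:
    permutation: np.ndarray   # pi: index i of A -> pi[i] of B
    total_cost: float         # H
    pair_costs: np.ndarray    # C[i, pi[i]]


def resample_contour(boundary: np.ndarray, n: int = DEFAULT_N_POINTS) -> Contour:
    """Resample a closed boundary chain to ``n`` equal-arc-length points.

    The first input point is preserved as the first output point.
    """
    if n < 8:
        raise ValueError("contours need at least 8 sample points")
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < n and len(pts) < 3:
        raise ValueError("boundary too short to resample")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate boundary with zero length")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return Contour(np.stack([x, y], axis=1))


def _cross2(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _segments_properly_intersect(p1, p2, q1, q2):
    """Vectorized proper-intersection test of one segment (p1, p2) against
    arrays of segments (q1, q2); strict inequalities, shared endpoints do not
    count."""
    d1 = _cross2(q2 - q1, p1 - q1)
    d2 = _cross2(q2 - q1, p2 - q1)
    d3 = _cross2(p2 - p1, q1 - p1)
    d4 = _cross2(p2 - p1, q2 - p1)
    return ((d1 * d2) < 0) & ((d3 * d4) < 0)


def visibility_matrix(points: np.ndarray) -> np.ndarray:
    """Boolean matrix: True where the open segment between vertices i and j
    lies inside the closed polygon.

    A chord is visible when (a) it points into the polygon's interior
    angular sector at both endpoints and (b) it properly crosses no
    non-incident polygon edge.  Both conditions are pure sign tests on
    cross products, so the graph is stable under rigid transforms of the
    vertex set (no interior point sampling).  Consecutive boundary vertices
    are always mutually visible.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not Polygon(pts).is_valid:
        raise ValueError("contour polygon is self-intersecting")
    # orientation sign: make interior-sector tests orientation-agnostic
    s = 1.0 if 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                            - np.roll(pts[:, 0], -1) * pts[:, 1]) > 0 else -1.0
    a = pts - np.roll(pts, 1, axis=0)        # incoming edge vector at i
    b = np.roll(pts, -1, axis=0) - pts       # outgoing edge vector at i
    D = pts[None, :, :] - pts[:, None, :]    # D[i, j] = P[j] - P[i]
    ca = s * (a[:, None, 0] * D[..., 1] - a[:, None, 1] * D[..., 0])
    cb = s * (b[:, None, 0] * D[..., 1] - b[:, None, 1] * D[..., 0])
    convex = (s * _cross2(a, b) >= 0)[:, None]
    local = np.where(convex, (ca >= 0) & (cb >= 0), (ca >= 0) | (cb >= 0))
    vis = local & local.T

    e1 = pts
    e2 = np.roll(pts, -1, axis=0)
    edge_idx = np.arange(n)[None, :]
    idx = np.arange(n)
    scale = np.abs(pts).max() + 1.0
    for i in range(n - 1):
        js = idx[i + 1:]
        crosses = _segments_properly_intersect(
            pts[i][None, None, :], pts[js][:, None, :],
            e1[None, :, :], e2[None, :, :])
        incident_i = (edge_idx == i) | (edge_idx == (i - 1) % n)
        incident_j = (edge_idx == js[:, None]) | (edge_idx == (js[:, None] - 1) % n)
        crosses &= ~(incident_i | incident_j)
        # a chord through an intermediate vertex must also lie inside that
        # vertex's local cone in both directions (it can otherwise slip
        # through an opening whose rim it touches only at vertices)
        d_ij = pts[js] - pts[i]                       # (m, 2)
        rel = pts[None, :, :] - pts[i]                # (1, n, 2)
        cr = d_ij[:, None, 0] * rel[..., 1] - d_ij[:, None, 1] * rel[..., 0]
        t = (rel[..., 0] * d_ij[:, None, 0] + rel[..., 1] * d_ij[:, None, 1]) \
            / np.einsum("md,md->m", d_ij, d_ij)[:, None]
        through = (np.abs(cr) <= 1e-9 * scale * scale) & (t > 1e-12) \
            & (t < 1 - 1e-12)
        through[:, i] = False
        through[np.arange(len(js)), js] = False
        if through.any():
            # local(v, j)=True means direction P[j]-P[v] is inside at v;
            # both the forward and backward chord directions must be
            m_idx, v_idx = np.nonzero(through)
            ok_v = local[v_idx, js[m_idx]] & local[v_idx, i]
            bad = np.zeros(len(js), dtype=bool)
            np.logical_or.at(bad, m_idx, ~ok_v)
            crosses[bad, 0] = True
        blocked = js[crosses.any(axis=1)]
        vis[i, blocked] = False
        vis[blocked, i] = False
    vis[idx, (idx + 1) % n] = True
    vis[(idx + 1) % n, idx] = True
    np.fill_diagonal(vis, False)
    return vis


def inner_geometry(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """Inner-distance and inner-angle matrices of a simple polygon.

    ``dist[i, j]`` is the length of the shortest path from vertex i to
    vertex j constrained to the silhouette (visibility graph + Dijkstra);
    ``angle[i, j]`` is the angle in degrees, wrapped to (-180, 180], between
    the boundary tangent at i and the first leg of that path.
    """
    pts = contour.points
    n = len(pts)
    vis = visibility_matrix(pts)
    diff = pts[None, :, :] - pts[:, None, :]
    eucl = np.linalg.norm(diff, axis=2)
    graph = np.where(vis, eucl, 0.0)
    dist, pred = shortest_path(graph, method="D", directed=False,
                               return_predecessors=True)
    if not np.all(np.isfinite(dist)):
        raise ValueError("inner-distance graph is disconnected")

    # first hop along each shortest path, resolved in order of distance
    first = np.full((n, n), -1, dtype=int)
    order = np.argsort(dist, axis=1)
    for i in range(n):
        fi = first[i]
        pi = pred[i]
        for j in order[i]:
            if j == i:
                continue
            p = pi[j]
            fi[j] = j if p == i else fi[p]

    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang_ang = np.degrees(np.arctan2(tang[:, 1], tang[:, 0]))
    hop = first.copy()
    np.fill_diagonal(hop, np.arange(n))
    step = pts[hop] - pts[:, None, :]
    step_ang = np.degrees(np.arctan2(step[..., 1], step[..., 0]))
    angles = wrap_angle(step_ang - tang_ang[:, None])
    np.fill_diagonal(angles, 0.0)
    np.fill_diagonal(dist, 0.0)
    return dist, angles


def shape_context(contour: Contour, n_r: int = DEFAULT_N_R,
                  n_theta: int = DEFAULT_N_THETA,
                  geometry: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> ShapeDescriptor:
    """Log-polar inner-distance shape-context descriptor at every point.

    Distances are normalized by the mean inner distance (making the
    descriptor scale-invariant) and binned on a log scale between
    ``R_INNER`` and ``R_OUTER`` of that mean; values outside the range are
    clamped into the extreme bins so every histogram counts all ``n - 1``
    other points.
    """
    dist, ang = geometry if geometry is not None else inner_geometry(contour)
    n = len(dist)
    off = ~np.eye(n, dtype=bool)
    mean_d = dist[off].mean()
    r = dist / mean_d
    redges = np.logspace(np.log10(R_INNER), np.log10(R_OUTER), n_r + 1)
    rbin = np.clip(np.searchsorted(redges, r, side="right") - 1, 0, n_r - 1)
    # angular bins uniform over (-180, 180]; angles that sit exactly on a
    # bin edge (paths straight along the boundary give exactly 0 or 180
    # degrees) are snapped to the edge so float wobble under rigid motion
    # cannot flip their bin
    width = 360.0 / n_theta
    ang = np.where(np.abs(np.abs(ang) - 180.0) < 1e-9, 180.0, ang)
    k = np.round((ang + 180.0) / width)
    near = np.abs(ang + 180.0 - k * width) < 1e-9
    ang = np.where(near, k * width - 180.0, ang)
    tbin = np.floor((ang + 180.0) / width).astype(int)
    tbin = np.clip(tbin, 0, n_theta - 1)
    k = rbin * n_theta + tbin
    hist = np.zeros((n, n_r * n_theta), dtype=int)
    rows = np.repeat(np.arange(n), n - 1)
    cols = k[off]
    np.add.at(hist, (rows, cols), 1)
    return ShapeDescriptor(histograms=hist, n_r=n_r, n_theta=n_theta,
                           distances=dist, angles=ang)


def chi2_cost(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """Chi-square cost of matching two histograms (0 for identical ones)."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    s = h_i + h_j
    d = np.zeros_like(s)
    nz = s > 0
    d[nz] = (h_i[nz] - h_j[nz]) ** 2 / s[nz]
    return 0.5 * float(d.sum())


def chi2_cost_matrix(A: ShapeDescriptor, B: ShapeDescriptor) -> np.ndarray:
    ha = A.histograms.astype(float)
    hb = B.histograms.astype(float)
    s = ha[:, None, :] + hb[None, :, :]
    num = (ha[:, None, :] - hb[None, :, :]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s > 0, num / np.where(s > 0, s, 1.0), 0.0)
    return 0.5 * frac.sum(axis=2)


def optimal_assignment(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost bijection of a square cost matrix (Hungarian-type)."""
    cost = np.asarray(cost, dtype=float)
    if cost.shape[0] != cost.shape[1]:
        raise ValueError("assignment requires a square cost matrix")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


def match_shapes(A: ShapeDescriptor, B: ShapeDescriptor) -> MatchResult:
    """Optimal point correspondence between two equally sampled shapes."""
    if A.histograms.shape != B.histograms.shape:
        raise ValueError("descriptors must have identical size")
    cost = chi2_cost_matrix(A, B)
    perm, H = optimal_assignment(cost)
    return MatchResult(permutation=perm, total_cost=H,
                       pair_costs=cost[np.arange(len(perm)), perm])


def describe(points: np.ndarray, n_points: int = DEFAULT_N_POINTS,
             n_r: int = DEFAULT_N_R, n_theta: int = DEFAULT_N_THETA
             ) -> tuple[Contour, ShapeDescriptor]:
    """Convenience: resample a raw boundary chain and build its descriptor."""
    c = resample_contour(points, n_points)
    return c, shape_context(c, n_r=n_r, n_theta=n_theta)
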