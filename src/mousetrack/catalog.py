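"""Runtime shape catalog: landmark transfer, viewing direction, cost gating
and vertical alignment of accepted shapes.

While the two animals are spatially separated, every segmented body contour
is matched to a single user-annotated reference shape.  The match transfers
the reference landmarks (nose, tail base, both ears) onto the new contour
and yields a total matching cost ``H``.  Contours with ``H`` below the gate
``rho_max`` are re-indexed into reference point order, rotated so the
tail-to-nose axis points straight down, centered, and stored.  The stored
set is the training sample for the active shape model.

Because a mouse silhouette is nearly fore-aft symmetric, a raw match may
swap nose and tail.  The ambiguity is resolved against the morphologically
localized tail base when one is available, and against the orientation of
the previous frame otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import shape_matching as sm
from ._geometry import rotation_matrix, wrap_angle

LANDMARK_NAMES = ("nose", "tail_base", "ear_left", "ear_right")


class OrientationUnresolvedError(ValueError):
    """Neither a tail-base hint nor a previous orientation is available."""


@dataclass
class ReferenceShape:
    """User-annotated reference contour with four landmark indices."""

    contour: sm.Contour
    nose: int
    tail_base: int
    ear_left: int
    ear_right: int
    _descriptor: sm.ShapeDescriptor | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.contour.n
        idx = self.landmark_indices
        if len(set(idx.values())) != 4 or any(not (0 <= i < n) for i in idx.values()):
            raise ValueError("reference needs four distinct landmark indices in [0, n)")

    @property
    def landmark_indices(self) -> dict[str, int]:
        return {"nose": self.nose, "tail_base": self.tail_base,
                "ear_left": self.ear_left, "ear_right": self.ear_right}

    def descriptor(self, n_r: int = sm.DEFAULT_N_R,
                   n_theta: int = sm.DEFAULT_N_THETA) -> sm.ShapeDescriptor:
        if self._descriptor is None:
            self._descriptor = sm.shape_context(self.contour, n_r=n_r, n_theta=n_theta)
        return self._descriptor


@dataclass
class TransferResult:
    """Landmarks transferred onto a new contour through a match."""

    landmarks: dict[str, np.ndarray]      # name -> (x, y) on the new contour
    landmark_points_idx: dict[str, int]   # name -> index into the new contour
    corresponded: np.ndarray              # (n, 2) new contour in reference order
    total_cost: float
    permutation: np.ndarray
    flipped: bool


@dataclass
class CatalogEntry:
    aligned: np.ndarray               # (n, 2), reference order, nose at index 0
    corresponded_image: np.ndarray    # (n, 2) in image coordinates
    cost: float
    frame_index: int
    profiles: np.ndarray | None = None  # (n, 2k) normalized profile derivatives


@dataclass
class CatalogConfig:
    """Gating configuration: give either a fixed cost gate ``rho_max`` or a
    target acceptance ratio ``c_v`` (calibrated from a warm-up cost sample)."""

    rho_max: float | None = None
    c_v: float | None = 0.5
    max_entries: int = 3000

    def __post_init__(self) -> None:
        if (self.rho_max is None) == (self.c_v is None):
            raise ValueError("set exactly one of catalog.rho_max / catalog.c_v")
        if self.c_v is not None and not (0.0 < self.c_v < 1.0):
            raise ValueError("catalog.c_v must be in (0, 1)")


def _circ_median(vals: np.ndarray, n: int) -> int:
    """Median of index values living on the cyclic group Z_n."""
    vals = np.asarray(vals, dtype=float)
    d = np.abs(vals[:, None] - vals[None, :])
    d = np.minimum(d, n - d)
    return int(vals[np.argmin(d.sum(axis=1))])


def _coherent_correspondence(inv: np.ndarray, tol: int = 6) -> np.ndarray:
    """Snap a correspondence to its dominant global cyclic shift.

    On nearly fore-aft-symmetric bodies the optimal assignment can return a
    mixture of the two symmetric solutions (half the points matched with
    one cyclic shift, half with the shift displaced by half the contour),
    which yields geometric nonsense like a collapsed nose-tail chord.  The
    dominant shift is voted for with a +/-``tol`` tolerance; entries that
    disagree with it are replaced by cyclic interpolation between the
    agreeing ones.
    """
    n = len(inv)
    idx = np.arange(n)
    o = (inv - idx) % n
    half = n // 2
    d_all = np.abs((o[None, :] - idx[:, None] + half) % n - half)
    votes = (d_all <= tol).sum(axis=1)
    s_star = int(np.argmax(votes))
    d = np.abs((o - s_star + half) % n - half)
    good = d <= tol
    rel = ((o - s_star + half) % n) - half
    rel_interp = np.interp(idx, idx[good], rel[good], period=n)
    o2 = (s_star + np.round(rel_interp).astype(int)) % n
    return (idx + o2) % n


def _consensus_correspondence(inv: np.ndarray, window: int = 3) -> np.ndarray:
    """Outlier-robust smoothing of a contour correspondence.

    A correct correspondence between two closed contours sampled at equal
    arc length is locally close to a cyclic shift, so each point's matched
    index should agree with its neighbours' matched indices shifted by the
    index offset.  Each entry is replaced by the circular median of the
    predictions made by a small neighbourhood, which removes isolated
    assignment outliers without disturbing smooth regions.
    """
    n = len(inv)
    out = np.empty(n, dtype=int)
    offs = np.arange(-window, window + 1)
    for k in range(n):
        preds = (inv[(k + offs) % n] - offs) % n
        out[k] = _circ_median(preds, n)
    return out


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points, endpoints preserved."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, cum[-1], n)
    return np.stack([np.interp(t, cum, pts[:, 0]),
                     np.interp(t, cum, pts[:, 1])], axis=1)


def _arclength_reparam(corresponded: np.ndarray, nose: int, tail: int
                       ) -> np.ndarray:
    """Even arc-length spacing on each side between the nose and tail
    anchors.

    Point-to-point matching leaves small tangential jitter along the
    boundary; stacked into a shape model that jitter becomes spurious
    variance modes that let a fitted contour slide along the silhouette.
    Re-spacing each nose-to-tail side by arc length (landmark positions
    kept) removes the jitter while preserving the geometry.
    """
    n = len(corresponded)
    seq = np.roll(corresponded, -nose, axis=0)   # starts at the nose
    k = (tail - nose) % n
    side1 = _resample_polyline(seq[:k + 1], k + 1)
    side2 = _resample_polyline(np.vstack([seq[k:], seq[:1]]), n - k + 1)
    new_seq = np.vstack([side1[:-1], side2[:-1]])
    return np.roll(new_seq, nose, axis=0)


def _orientation_of(landmarks: dict[str, np.ndarray]) -> float:
    """Tail-to-nose direction in image-coordinate degrees (internal)."""
    v = landmarks["nose"] - landmarks["tail_base"]
    return float(np.degrees(np.arctan2(v[1], v[0])))


def transfer_landmarks(new_contour: sm.Contour, ref: ReferenceShape,
                       tail_hint: np.ndarray | None = None,
                       prev_orientation: float | None = None,
                       n_r: int = sm.DEFAULT_N_R,
                       n_theta: int = sm.DEFAULT_N_THETA) -> TransferResult:
    """Match a new contour to the reference and read off its landmarks.

    Two candidate correspondences are considered: the plain match and the
    match against the contour traversed in reverse order (which exchanges the
    roles of nose and tail on near-symmetric bodies).  With a ``tail_hint``
    (image point from tail-base localization) the candidate whose transferred
    tail lies closer to the hint than its nose wins; without one, the
    candidate whose tail-to-nose orientation is closer to
    ``prev_orientation`` (image-coordinate degrees) wins.
    """
    if tail_hint is None and prev_orientation is None:
        raise OrientationUnresolvedError(
            "first frame must have a localizable tail base (no orientation prior)")
    ref_desc = ref.descriptor(n_r=n_r, n_theta=n_theta)

    def candidate(contour: sm.Contour, flipped: bool) -> TransferResult:
        desc = sm.shape_context(contour, n_r=n_r, n_theta=n_theta)
        match = sm.match_shapes(desc, ref_desc)
        inv = np.empty(contour.n, dtype=int)
        inv[match.permutation] = np.arange(contour.n)
        inv = _coherent_correspondence(inv)
        inv = _consensus_correspondence(inv)
        corresponded = _arclength_reparam(contour.points[inv],
                                          ref.nose, ref.tail_base)
        lms = {name: corresponded[idx].copy()
               for name, idx in ref.landmark_indices.items()}
        return TransferResult(landmarks=lms,
                              landmark_points_idx=dict(ref.landmark_indices),
                              corresponded=corresponded,
                              total_cost=match.total_cost,
                              permutation=match.permutation, flipped=flipped)

    fwd = candidate(new_contour, flipped=False)
    if tail_hint is not None:
        hint = np.asarray(tail_hint, dtype=float)
        d_tail = np.linalg.norm(fwd.landmarks["tail_base"] - hint)
        d_nose = np.linalg.norm(fwd.landmarks["nose"] - hint)
        if d_tail <= d_nose:
            return fwd
        rev = candidate(new_contour.reversed(), flipped=True)
        d_tail_r = np.linalg.norm(rev.landmarks["tail_base"] - hint)
        d_nose_r = np.linalg.norm(rev.landmarks["nose"] - hint)
        return rev if d_tail_r <= d_nose_r or d_tail_r < d_tail else fwd
    rev = candidate(new_contour.reversed(), flipped=True)
    d_fwd = abs(wrap_angle(_orientation_of(fwd.landmarks) - prev_orientation))
    d_rev = abs(wrap_angle(_orientation_of(rev.landmarks) - prev_orientation))
    return fwd if d_fwd <= d_rev else rev


def viewing_direction(nose: np.ndarray, ear_left: np.ndarray,
                      ear_right: np.ndarray) -> float:
    """Viewing angle: direction from the ear midpoint to the nose, degrees.

    Pure geometry in whatever planar convention the inputs use; callers
    holding image (y-down) coordinates flip y before calling if they want
    the mathematical y-up angle.
    """
    ear_left = np.asarray(ear_left, dtype=float)
    ear_right = np.asarray(ear_right, dtype=float)
    nose = np.asarray(nose, dtype=float)
    if np.allclose(ear_left, ear_right):
        raise ValueError("ear landmarks coincide")
    mid = 0.5 * (ear_left + ear_right)
    v = nose - mid
    if np.linalg.norm(v) == 0:
        raise ValueError("nose coincides with the ear midpoint")
    return float(np.degrees(np.arctan2(v[1], v[0])))


def align_vertical(corresponded: np.ndarray, nose_idx: int,
                   tail_idx: int) -> np.ndarray:
    """Rotate about the centroid so tail->nose points along +y (image down,
    i.e. the nose ends up below the tail on screen), then translate so the
    tail-nose midpoint sits at the origin."""
    pts = np.asarray(corresponded, dtype=float)
    v = pts[nose_idx] - pts[tail_idx]
    ang = np.degrees(np.arctan2(v[1], v[0]))
    R = rotation_matrix(90.0 - ang)
    centroid = pts.mean(axis=0)
    rot = (pts - centroid) @ R.T + centroid
    mid = 0.5 * (rot[nose_idx] + rot[tail_idx])
    return rot - mid


def gate_and_align(corresponded: np.ndarray, ref: ReferenceShape, H: float,
                   rho_max: float, frame_index: int = -1,
                   profiles: np.ndarray | None = None) -> CatalogEntry | None:
    """Accept a corresponded contour into the catalog iff ``H < rho_max``.

    Accepted contours are vertically aligned, centered on the tail-nose
    midpoint and cyclically rolled so index 0 is the nose correspondence.
    Returns ``None`` on rejection.
    """
    if not H < rho_max:
        return None
    aligned = align_vertical(corresponded, ref.nose, ref.tail_base)
    n = len(aligned)
    roll = -ref.nose % n
    aligned = np.roll(aligned, roll, axis=0)
    rolled_profiles = None if profiles is None else np.roll(profiles, roll, axis=0)
    return CatalogEntry(aligned=aligned,
                        corresponded_image=np.asarray(corresponded, dtype=float),
                        cost=float(H), frame_index=frame_index,
                        profiles=rolled_profiles)


def rolled_landmark_indices(ref: ReferenceShape) -> dict[str, int]:
    """Landmark indices valid for catalog entries (nose rolled to index 0)."""
    n = ref.contour.n
    return {name: (idx - ref.nose) % n for name, idx in ref.landmark_indices.items()}


def calibrate_rho(costs, c_v: float) -> float:
    """Cost gate such that a fraction ``c_v`` of the sample falls strictly
    below it (the complement quantile of the warm-up cost sample)."""
    costs = np.sort(np.asarray(list(costs), dtype=float))
    N = len(costs)
    if N < 10:
        raise ValueError("need at least 10 warm-up costs to calibrate rho_max")
    k = int(round(c_v * N))
    if k <= 0:
        return float(costs[0])
    if k >= N:
        return float(costs[-1] + max(1e-9, 1e-9 * abs(costs[-1])))
    return float(0.5 * (costs[k - 1] + costs[k]))


class ShapeCatalog:
    """Bounded store of accepted, aligned, corresponded contours."""

    def __init__(self, ref: ReferenceShape, cfg: CatalogConfig,
                 rng: np.random.Generator | None = None):
        self.ref = ref
        self.cfg = cfg
        self.entries: list[CatalogEntry] = []
        self.landmark_indices = rolled_landmark_indices(ref)
        self._rng = rng or np.random.default_rng(0)
        self._seen = 0

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: CatalogEntry) -> None:
        """Reservoir-style insertion bounded by ``max_entries``."""
        self._seen += 1
        if len(self.entries) < self.cfg.max_entries:
            self.entries.append(entry)
        else:
            j = int(self._rng.integers(0, self._seen))
            if j < self.cfg.max_entries:
                self.entries[j] = entry

    def stacked(self) -> np.ndarray:
        """Shapes as an (s, 2n) matrix of interleaved (x1, y1, ..., xn, yn)."""
        return np.stack([e.aligned.reshape(-1) for e in self.entries])
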