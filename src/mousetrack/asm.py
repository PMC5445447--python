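"""Active shape model: point-distribution model plus grey-profile model.

The point-distribution part is a PCA of the vertically aligned catalog
shapes: mean shape ``x_bar``, orthonormal eigenvectors ``P`` of the sample
covariance (1/(s-1) normalization) and eigenvalues ``lambda_i``.  A shape is
``x = x_bar + P b`` with each coefficient clamped to ``|b_i| <= m sqrt(lambda_i)``,
and the retained mode count ``t`` is the smallest prefix whose eigenvalue
sum reaches a fraction ``f_v`` of the total variance.

The grey-profile part models, per landmark, the normalized first derivative
of the intensity profile sampled along the contour normal.  Fitting moves
every free landmark to the offset along its normal that minimizes the
Mahalanobis distance to the landmark's profile statistics, then
re-estimates the similarity pose and projects/clamps the shape
coefficients.  Landmarks inside an occlusion region can be frozen: they do
not search, but still take part in pose estimation and are regularized by
the model constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from ._geometry import apply_similarity, fit_similarity, invert_similarity, \
    outward_normals

DEFAULT_M = 3.0
DEFAULT_F_V = 0.98
DEFAULT_N_MAX = 60
DEFAULT_PROFILE_K = 5
DEFAULT_SEARCH_L = 7
# covariance shrinkage toward the scaled identity: raw per-landmark sample
# covariances are rank-deficient and overfit, which makes the Mahalanobis
# metric reject even perfect edges
PROFILE_SHRINKAGE = 0.2


@dataclass
class ActiveShapeModel:
    mean: np.ndarray                 # (2n,) interleaved mean shape
    eigvecs: np.ndarray              # (2n, t) orthonormal columns
    eigvals: np.ndarray              # (t,) descending, >= 0
    t: int
    f_v: float
    m: float
    total_variance: float
    profile_mean: np.ndarray | None = None    # (n, 2k)
    profile_icov: np.ndarray | None = field(default=None, repr=False)  # (n, 2k, 2k)
    profile_k: int = DEFAULT_PROFILE_K
    landmark_indices: dict | None = None      # nose/tail/ears indices, nose = 0

    @property
    def n_points(self) -> int:
        return len(self.mean) // 2

    @property
    def mean_points(self) -> np.ndarray:
        return self.mean.reshape(-1, 2)


@dataclass
class ShapeInstance:
    """A posed model instance: similarity pose + clamped coefficients."""

    scale: float
    theta_deg: float
    translation: np.ndarray
    b: np.ndarray

    def realize(self, model: ActiveShapeModel) -> np.ndarray:
        shape = (model.mean + model.eigvecs[:, :len(self.b)] @ self.b).reshape(-1, 2)
        return apply_similarity(shape, self.scale, self.theta_deg, self.translation)


def mode_count(eigvals: np.ndarray, f_v: float) -> int:
    """Smallest t with sum(lambda_1..t) >= f_v * sum(lambda), at least 1."""
    lam = np.asarray(eigvals, dtype=float)
    total = lam.sum()
    if total <= 0:
        return 1
    csum = np.cumsum(lam)
    t = int(np.searchsorted(csum, f_v * total - 1e-12) + 1)
    return max(1, min(t, len(lam)))


def build_shape_model(shapes: np.ndarray, f_v: float = DEFAULT_F_V,
                      m: float = DEFAULT_M) -> ActiveShapeModel:
    """PCA of stacked aligned shapes, (s, 2n) -> point-distribution model."""
    X = np.asarray(shapes, dtype=float)
    s = len(X)
    if s < 3:
        raise ValueError("shape model needs at least 3 training shapes")
    mean = X.mean(axis=0)
    D = X - mean
    cov = (D.T @ D) / (s - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    t = mode_count(vals, f_v)
    return ActiveShapeModel(mean=mean, eigvecs=vecs, eigvals=vals, t=t,
                            f_v=f_v, m=m, total_variance=float(vals.sum()))


def project(x: np.ndarray, model: ActiveShapeModel,
            t: int | None = None) -> np.ndarray:
    """Coefficients b = P^T (x - x_bar) of an aligned, corresponded shape."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if len(x) != len(model.mean):
        raise ValueError("shape dimension does not match the model")
    t = model.t if t is None else t
    return model.eigvecs[:, :t].T @ (x - model.mean)


def reconstruct(b: np.ndarray, model: ActiveShapeModel) -> np.ndarray:
    """Shape x_bar + P b as an (n, 2) point array."""
    b = np.asarray(b, dtype=float)
    return (model.mean + model.eigvecs[:, :len(b)] @ b).reshape(-1, 2)


def clamp(b: np.ndarray, model: ActiveShapeModel,
          m: float | None = None) -> np.ndarray:
    """Clip each coefficient to the plausibility box |b_i| <= m sqrt(lambda_i)."""
    m = model.m if m is None else m
    lim = m * np.sqrt(model.eigvals[:len(b)])
    return np.clip(np.asarray(b, dtype=float), -lim, lim)


# ---------------------------------------------------------------------------
# grey-profile model


def sample_profiles(image: np.ndarray, contour: np.ndarray, k: int,
                    normals: np.ndarray | None = None) -> np.ndarray:
    """Normalized first-derivative intensity profiles at every contour point.

    Samples ``2k + 1`` intensities at 1-px spacing along the outward normal
    (bilinear interpolation), takes first differences and normalizes by the
    sum of absolute values.  Flat profiles come back as zero vectors.
    """
    pts = np.asarray(contour, dtype=float)
    if normals is None:
        normals = outward_normals(pts)
    offsets = np.arange(-k, k + 1, dtype=float)
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    # map_coordinates wants (row, col) = (y, x)
    vals = map_coordinates(np.asarray(image, dtype=float),
                           [coords[..., 1].ravel(), coords[..., 0].ravel()],
                           order=1, mode="nearest").reshape(len(pts), 2 * k + 1)
    deriv = np.diff(vals, axis=1)
    denom = np.abs(deriv).sum(axis=1, keepdims=True)
    # flatness floor relative to the local intensity scale: interpolation
    # round-off on a constant image must normalize to zero, not to noise
    flat = denom <= 1e-8 * (np.abs(vals).max() + 1.0)
    denom[flat] = 1.0
    out = deriv / denom
    out[flat[:, 0]] = 0.0
    return out


def build_profile_model(profiles: np.ndarray, k: int,
                        shrinkage: float = PROFILE_SHRINKAGE
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-landmark mean and regularized inverse covariance of profiles.

    ``profiles`` is (s, n, 2k): one normalized derivative profile per entry
    per landmark.  Covariances are shrunk toward the scaled identity,
    ``(1 - a) S + a (tr S / d) I``, before inversion: raw sample covariances
    are near-singular and make the Mahalanobis metric reject even perfect
    edges (degenerate catalogs additionally get a tiny absolute ridge).
    """
    G = np.asarray(profiles, dtype=float)
    if G.ndim != 3 or len(G) < 2:
        raise ValueError("profile model needs at least 2 entries of (n, 2k) profiles")
    s, n, d = G.shape
    mean = G.mean(axis=0)
    icov = np.empty((n, d, d))
    eye = np.eye(d)
    for i in range(n):
        Dm = G[:, i, :] - mean[i]
        S = (Dm.T @ Dm) / max(s - 1, 1)
        S = (1.0 - shrinkage) * S + shrinkage * (np.trace(S) / d) * eye
        icov[i] = np.linalg.inv(S + 1e-9 * eye)
    return mean, icov


def attach_profile_model(model: ActiveShapeModel, profiles: np.ndarray,
                         k: int = DEFAULT_PROFILE_K) -> ActiveShapeModel:
    mean, icov = build_profile_model(profiles, k)
    model.profile_mean = mean
    model.profile_icov = icov
    model.profile_k = k
    return model


def profile_quality(g: np.ndarray, mean: np.ndarray, icov: np.ndarray) -> float:
    """Mahalanobis distance of one profile to a landmark's statistics."""
    d = np.asarray(g, dtype=float) - mean
    return float(d @ icov @ d)


# ---------------------------------------------------------------------------
# fitting


def _pose_and_shape_update(model: ActiveShapeModel, targets: np.ndarray,
                           b0: np.ndarray | None = None,
                           inner_iters: int = 6) -> ShapeInstance:
    """Best similarity pose + clamped coefficients explaining ``targets``.

    When the model carries nose/tail landmark indices the pose is closed
    form: the training shapes were normalized by rotating the tail-to-nose
    axis onto the vertical and centering its midpoint, so applying exactly
    that normalization to the targets puts them in the model frame (least
    squares is ambiguous here because bending modes look like rotations).
    Without landmarks, pose and shape are alternated to convergence.
    """
    lm = model.landmark_indices or {}
    if "nose" in lm and "tail_base" in lm:
        from ._geometry import rotation_matrix
        ni, ti = lm["nose"], lm["tail_base"]
        v = targets[ni] - targets[ti]
        theta = float(np.degrees(np.arctan2(v[1], v[0])) - 90.0)
        R = rotation_matrix(theta)
        # translation from all landmarks (the two axis anchors alone are
        # blind to displacements orthogonal to their own normals)
        b = (np.zeros(model.t) if b0 is None
             else np.asarray(b0, dtype=float)[:model.t].copy())
        trans = np.zeros(2)
        for _ in range(3):
            shape = reconstruct(b, model)
            trans = targets.mean(axis=0) - (shape @ R.T).mean(axis=0)
            local = (targets - trans) @ R
            b = clamp(project(local, model), model)
        return ShapeInstance(scale=1.0, theta_deg=theta, translation=trans, b=b)
    t = model.t
    b = np.zeros(t) if b0 is None else np.asarray(b0, dtype=float).copy()
    scale, theta, trans = 1.0, 0.0, np.zeros(2)
    for _ in range(inner_iters):
        shape = reconstruct(b, model)
        scale, theta, trans = fit_similarity(shape, targets)
        inv = invert_similarity(scale, theta, trans)
        local = apply_similarity(targets, *inv)
        b_new = clamp(project(local, model, t=t), model)
        if np.allclose(b_new, b, atol=1e-9):
            b = b_new
            break
        b = b_new
    shape = reconstruct(b, model)
    scale, theta, trans = fit_similarity(shape, targets)
    return ShapeInstance(scale=scale, theta_deg=theta,
                         translation=np.asarray(trans, dtype=float), b=b)


def instance_from_contour(model: ActiveShapeModel, contour: np.ndarray
                          ) -> ShapeInstance:
    """Initialize an instance (pose + clamped b) from an image-space contour
    in model point order."""
    return _pose_and_shape_update(model, np.asarray(contour, dtype=float))


def fit_step(model: ActiveShapeModel, image: np.ndarray,
             instance: ShapeInstance, search_l: int = DEFAULT_SEARCH_L,
             frozen: np.ndarray | None = None,
             max_step: float | None = 1.5) -> ShapeInstance:
    """One ASM iteration: profile search along normals, pose fit, clamp.

    ``frozen`` is a boolean mask of landmarks that keep their position
    during the search (occluded landmarks); they still enter the pose fit
    and are moved by the model constraints afterwards.  ``max_step`` caps
    the per-iteration displacement: candidates are evaluated over the full
    search range, but the applied move is damped, which keeps high-curvature
    regions (ears, nose tip) from latching onto a neighbouring edge.
    """
    if model.profile_mean is None:
        raise ValueError("model has no grey-profile statistics; cannot fit")
    k = model.profile_k
    pts = instance.realize(model)
    n = len(pts)
    normals = outward_normals(pts)
    offsets = np.arange(-(search_l + k), search_l + k + 1, dtype=float)
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = map_coordinates(np.asarray(image, dtype=float),
                           [coords[..., 1].ravel(), coords[..., 0].ravel()],
                           order=1, mode="nearest").reshape(n, len(offsets))
    deriv = np.diff(vals, axis=1)           # (n, 2(l+k))
    # windows of length 2k centered at each candidate offset
    idx = np.arange(2 * search_l + 1)[:, None] + np.arange(2 * k)[None, :]
    windows = deriv[:, idx]                 # (n, 2l+1, 2k)
    strength = np.abs(windows).sum(axis=2)  # un-normalized edge energy
    denom = strength[..., None].copy()
    denom[denom <= 1e-8 * (np.abs(vals).max() + 1.0)] = 1.0
    windows = windows / denom
    diffs = windows - model.profile_mean[:, None, :]
    dm = np.einsum("nok,nkl,nol->no", diffs, model.profile_icov, diffs)
    # anchor the search to real edges: candidate windows with little edge
    # energy (flat interior/exterior) are not eligible, and a landmark that
    # sees no edge at all stays put instead of drifting
    smax = strength.max(axis=1)
    floor = 0.05 * np.percentile(smax, 90)
    dm[strength < 0.25 * smax[:, None]] = np.inf
    best = np.argmin(dm, axis=1) - search_l
    best[smax < floor] = 0
    # landmarks on a smooth contour must move coherently: a circular median
    # filter removes isolated jumps caused by weak-edge profile statistics
    win = np.arange(-2, 3)
    stacked = best[(np.arange(n)[:, None] + win[None, :]) % n]
    best = np.median(stacked, axis=1).astype(int)
    # sub-pixel refinement: parabola through d_M at the argmin and neighbours
    move = best.astype(float)
    col = best + search_l
    ok = (col > 0) & (col < 2 * search_l)
    rows = np.arange(n)[ok]
    c0, cm, cp = dm[rows, col[ok]], dm[rows, col[ok] - 1], dm[rows, col[ok] + 1]
    finite = np.isfinite(cm) & np.isfinite(cp)
    cm = np.where(finite, cm, 0.0)
    cp = np.where(finite, cp, 0.0)
    denom2 = cm - 2 * c0 + cp
    good = finite & (denom2 > 1e-12)
    delta = np.zeros(len(rows))
    delta[good] = 0.5 * (cm[good] - cp[good]) / denom2[good]
    move[ok] += np.clip(delta, -0.5, 0.5)
    if max_step is not None:
        move = np.clip(move, -max_step, max_step)
    if frozen is not None:
        move = np.where(np.asarray(frozen, dtype=bool), 0.0, move)
    targets = pts + move[:, None] * normals
    return _pose_and_shape_update(model, targets, b0=instance.b)


def fit(model: ActiveShapeModel, image: np.ndarray, init: ShapeInstance,
        n_max: int = DEFAULT_N_MAX, search_l: int = DEFAULT_SEARCH_L,
        frozen: np.ndarray | None = None, average_last: int = 10) -> ShapeInstance:
    """Run ``n_max`` ASM iterations from ``init`` on one image.

    The discrete profile search settles into a small limit cycle around the
    optimum rather than a fixed point; averaging the realized contours of
    the last ``average_last`` iterates collapses that cycle to its center.
    """
    inst = init
    tail: list[np.ndarray] = []
    for i in range(n_max):
        inst = fit_step(model, image, inst, search_l=search_l, frozen=frozen)
        if n_max - i <= max(1, average_last):
            tail.append(inst.realize(model))
    if len(tail) > 1:
        inst = _pose_and_shape_update(model, np.mean(tail, axis=0), b0=inst.b)
    return inst


def save_model(path, model: ActiveShapeModel) -> None:
    np.savez_compressed(
        path, mean=model.mean, eigvecs=model.eigvecs, eigvals=model.eigvals,
        t=model.t, f_v=model.f_v, m=model.m, total_variance=model.total_variance,
        profile_mean=(model.profile_mean if model.profile_mean is not None
                      else np.zeros(0)),
        profile_icov=(model.profile_icov if model.profile_icov is not None
                      else np.zeros(0)),
        profile_k=model.profile_k,
        landmark_names=np.array(list((model.landmark_indices or {}).keys())),
        landmark_values=np.array(list((model.landmark_indices or {}).values()),
                                 dtype=int))


def load_model(path) -> ActiveShapeModel:
    z = np.load(path, allow_pickle=False)
    lm = {str(k): int(v) for k, v in zip(z["landmark_names"], z["landmark_values"])}
    return ActiveShapeModel(
        mean=z["mean"], eigvecs=z["eigvecs"], eigvals=z["eigvals"],
        t=int(z["t"]), f_v=float(z["f_v"]), m=float(z["m"]),
        total_variance=float(z["total_variance"]),
        profile_mean=z["profile_mean"] if z["profile_mean"].size else None,
        profile_icov=z["profile_icov"] if z["profile_icov"].size else None,
        profile_k=int(z["profile_k"]), landmark_indices=lm or None)
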