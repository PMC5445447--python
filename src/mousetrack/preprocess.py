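"""Frame preprocessing: illumination normalization, background model,
foreground segmentation, blob extraction and tail localization.

The pipeline assumes a static bright arena observed from the top with dark
animals moving in it (the polarity is actually irrelevant: segmentation
thresholds the absolute background difference).  The temporal median of the
normalized frames serves as the background estimate; a per-frame global
intensity rescaling removes slow illumination drift before the median is
taken, so the two steps commute with flicker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu


class DegenerateFrameError(ValueError):
    """Raised for frames that carry no usable signal (e.g. all zero)."""


@dataclass
class PreprocessConfig:
    """Segmentation parameters.

    b_min : minimum blob area in px^2; smaller components are speckle.
    r_S : radius of the disc structuring element used for tail removal;
        should exceed half the tail diameter but stay below half the body
        width.
    threshold : ``"auto"`` for between-class-variance (Otsu) thresholding of
        the absolute difference image, or a fixed numeric level.
    target_mean : global mean intensity every frame is rescaled to.
    """

    b_min: int = 50
    r_S: int = 4
    threshold: float | str = "auto"
    target_mean: float = 128.0

    def __post_init__(self) -> None:
        if self.b_min <= 0:
            raise ValueError("preprocess.b_min must be > 0")
        if self.r_S < 1:
            raise ValueError("preprocess.r_S must be >= 1")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ValueError("preprocess.threshold must be 'auto' or a number")


@dataclass
class BackgroundModel:
    median_image: np.ndarray
    n_frames_used: int


@dataclass
class Blob:
    """A connected foreground component (8-connectivity)."""

    pixel_mask: np.ndarray          # full-frame boolean mask of this blob only
    area: int
    centroid: np.ndarray            # (x, y)
    boundary: np.ndarray = field(repr=False, default=None)  # (m, 2) closed chain


def normalize_illumination(frame: np.ndarray, target_mean: float = 128.0) -> np.ndarray:
    """Rescale a grayscale frame so its global mean equals ``target_mean``.

    Removes frame-to-frame multiplicative illumination drift while preserving
    the spatial pattern up to a global scale.
    """
    frame = np.asarray(frame, dtype=float)
    m = frame.mean()
    if not np.isfinite(m) or m <= 0:
        raise DegenerateFrameError("frame mean is zero or non-finite")
    return frame * (target_mean / m)


def build_background(frames) -> BackgroundModel:
    """Pixel-wise temporal median over a sequence of frames."""
    frames = list(frames)
    if len(frames) < 3:
        raise ValueError("background model needs at least 3 frames")
    shape = np.asarray(frames[0]).shape
    for f in frames:
        if np.asarray(f).shape != shape:
            raise ValueError("all frames must share dimensions")
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    return BackgroundModel(median_image=np.median(stack, axis=0),
                           n_frames_used=len(frames))


def segment_foreground(frame: np.ndarray, bg: BackgroundModel,
                       cfg: PreprocessConfig) -> np.ndarray:
    """Threshold the absolute background difference into a boolean mask."""
    diff = np.abs(np.asarray(frame, dtype=float) - bg.median_image)
    if cfg.threshold == "auto":
        if diff.max() <= 0:
            return np.zeros(diff.shape, dtype=bool)
        thr = threshold_otsu(diff)
    else:
        thr = float(cfg.threshold)
    return diff > thr


def extract_blobs(mask: np.ndarray, b_min: int) -> list[Blob]:
    """8-connected components of ``mask`` with area >= b_min, largest first.

    Each blob carries its own full-frame mask and a closed outer boundary
    chain traced at sub-pixel resolution.
    """
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    blobs: list[Blob] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < b_min:
            continue
        ys, xs = np.nonzero(comp)
        centroid = np.array([xs.mean(), ys.mean()])
        blobs.append(Blob(pixel_mask=comp, area=area, centroid=centroid,
                          boundary=trace_boundary(comp)))
    blobs.sort(key=lambda b: -b.area)
    return blobs


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary of the largest component of ``mask`` as (m, 2)
    ``(x, y)`` points (sub-pixel, from the 0.5 iso-contour)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no foreground to trace")
    chain = max(contours, key=len)
    # find_contours returns (row, col); undo padding, convert to (x, y)
    pts = np.stack([chain[:, 1] - 1.0, chain[:, 0] - 1.0], axis=1)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def locate_tail(mask: np.ndarray, r_S: int,
                min_tail_area: int = 10) -> tuple[np.ndarray, np.ndarray | None]:
    """Split a single-animal mask into body and tail; return the tail base.

    The body is the morphological opening of the mask with a disc of radius
    ``r_S``; the tail is what the opening removed.  The tail base is the
    centroid of the intersection between the dilated tail and the body.
    Returns ``(body_mask, tail_base)`` with ``tail_base = None`` when no tail
    component larger than ``min_tail_area`` px^2 touches the body.
    """
    mask = np.asarray(mask, dtype=bool)
    disc = morphology.disk(r_S)
    body = morphology.opening(mask, footprint=disc)
    if not body.any():
        return body, None
    tail = mask & ~body
    # keep only the largest tail component; ignore speckle
    labels, n = ndi.label(tail, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return body, None
    sizes = ndi.sum_labels(tail, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] <= min_tail_area:
        return body, None
    tail_main = labels == best
    inter = morphology.dilation(tail_main, footprint=disc) & body
    if not inter.any():
        return body, None
    ys, xs = np.nonzero(inter)
    return body, np.array([xs.mean(), ys.mean()])
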