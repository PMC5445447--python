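"""Per-frame social/non-social condition classification and event building.

Conditions C1-C5 are geometric predicates on the two trajectories (nose and
tail-base positions, viewing directions, silhouette overlap), with distance
thresholds expressed in body-length units so one configuration generalizes
across arenas and camera scales:

C1  nose-to-nose contact
C2  anogenital sniffing (nose of one animal at the other's tail base)
C3  side-by-side contact (close body centers, parallel or anti-parallel)
C4  following (nose behind the leader's tail base, aligned headings,
    sustained over the smoothing window)
C5  mating posture (large silhouette overlap with aligned headings)

Self-grooming (C6) is not geometric: it is read from the shape model's
eigencoefficients (a compressed body posture shows up as a strongly
negative squash/stretch mode) with a class-weighted RBF support-vector
machine, validated interval-wise: each time interval is predicted by a
model trained on all the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import BehaviorSection
from ._geometry import wrap_angle


@dataclass
class BehaviorEvent:
    condition: str
    animal: str
    start: int
    end: int            # inclusive
    duration_s: float


def _heading_diff(phi_a, phi_b):
    return np.abs(wrap_angle(np.asarray(phi_a) - np.asarray(phi_b)))


def body_length(record: pd.DataFrame) -> float:
    """Median nose-to-tail distance over separated frames (the unit used by
    all distance thresholds)."""
    sep = record[record["regime"] == "separated"]
    if len(sep) == 0:
        sep = record
    d = np.hypot(sep["nose_x"] - sep["tail_x"], sep["nose_y"] - sep["tail_y"])
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("record carries no usable nose/tail positions")
    return float(np.median(d))


def classify_social(record_a: pd.DataFrame, record_b: pd.DataFrame,
                    cfg: BehaviorSection, fps: float = 25.0,
                    bl: float | None = None) -> pd.DataFrame:
    """Per-frame condition flags for C1-C5.

    ``record_a`` / ``record_b`` are per-animal slices of the track record,
    aligned on frame.  Directional conditions are reported both ways
    (``C2_ab`` = A's nose at B's tail, etc.); the plain column is their OR.
    Frames where either animal is lost assert nothing.
    """
    a = record_a.sort_values("frame").reset_index(drop=True)
    b = record_b.sort_values("frame").reset_index(drop=True)
    if not np.array_equal(a["frame"].values, b["frame"].values):
        raise ValueError("records must cover the same frames")
    bl = body_length(pd.concat([a, b])) if bl is None else bl
    ok = (a["regime"] != "lost").values & (b["regime"] != "lost").values
    ok &= np.isfinite(a["nose_x"]).values & np.isfinite(b["nose_x"]).values

    nose_a = a[["nose_x", "nose_y"]].values
    nose_b = b[["nose_x", "nose_y"]].values
    tail_a = a[["tail_x", "tail_y"]].values
    tail_b = b[["tail_x", "tail_y"]].values
    cen_a = 0.5 * (nose_a + tail_a)
    cen_b = 0.5 * (nose_b + tail_b)
    phi_a = a["phi_deg"].values
    phi_b = b["phi_deg"].values
    hd = _heading_diff(phi_a, phi_b)
    overlap = a.get("overlap_frac", pd.Series(np.zeros(len(a)))).values

    dist = lambda p, q: np.hypot(*(p - q).T)
    out = pd.DataFrame({"frame": a["frame"].values})
    out["C1"] = ok & (dist(nose_a, nose_b) < cfg.nose_nose * bl)
    out["C2_ab"] = ok & (dist(nose_a, tail_b) < cfg.nose_tail * bl)
    out["C2_ba"] = ok & (dist(nose_b, tail_a) < cfg.nose_tail * bl)
    aligned = (hd < cfg.side_angle) | (hd > 180.0 - cfg.side_angle)
    out["C3"] = ok & (dist(cen_a, cen_b) < cfg.side_center * bl) & aligned
    raw4_ab = ok & (dist(nose_a, tail_b) < cfg.follow_dist * bl) \
        & (hd < cfg.follow_angle)
    raw4_ba = ok & (dist(nose_b, tail_a) < cfg.follow_dist * bl) \
        & (hd < cfg.follow_angle)
    sustain = max(1, int(round(cfg.follow_sustain_s * fps)))
    out["C4_ab"] = _sustained(raw4_ab, sustain)
    out["C4_ba"] = _sustained(raw4_ba, sustain)
    out["C5"] = ok & (overlap > cfg.mating_overlap) & (hd < cfg.mating_angle)
    out["C2"] = out["C2_ab"] | out["C2_ba"]
    out["C4"] = out["C4_ab"] | out["C4_ba"]
    return out


def _sustained(flags: np.ndarray, window: int) -> np.ndarray:
    """True where the predicate holds over a full run of >= window frames."""
    flags = np.asarray(flags, dtype=bool)
    if window <= 1:
        return flags
    out = np.zeros_like(flags)
    n = len(flags)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= window:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def smooth_flags(flags: np.ndarray, window: int) -> np.ndarray:
    """Majority vote over a centered window of odd length."""
    flags = np.asarray(flags, dtype=bool)
    if window <= 1:
        return flags.copy()
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window)
    votes = np.convolve(flags.astype(float), kernel, mode="same")
    counts = np.convolve(np.ones(len(flags)), kernel, mode="same")
    return votes > counts / 2.0


def frames_to_events(flags, cfg: BehaviorSection, fps: float = 25.0,
                     condition: str = "", animal: str = "",
                     frames: np.ndarray | None = None) -> list[BehaviorEvent]:
    """Maximal runs of active frames after majority smoothing; runs shorter
    than the minimum event duration are dropped."""
    flags = smooth_flags(np.asarray(flags, dtype=bool), cfg.smooth_frames)
    frames = np.arange(len(flags)) if frames is None else np.asarray(frames)
    min_frames = max(1, int(round(cfg.min_event_s * fps)))
    events = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_frames:
                events.append(BehaviorEvent(
                    condition=condition, animal=animal,
                    start=int(frames[i]), end=int(frames[j - 1]),
                    duration_s=(j - i) / fps))
            i = j
        else:
            i += 1
    return events


def duration_error(t_est: float, t_gt: float) -> float:
    """Relative absolute duration error |T_est - T_gt| / T_gt."""
    if t_gt <= 0:
        raise ValueError("duration error is undefined for zero ground truth; "
                         "report such intervals separately")
    return abs(t_est - t_gt) / t_gt


def detect_grooming(b_series: np.ndarray, labels: np.ndarray,
                    interval_frames: int, seed: int = 0) -> np.ndarray:
    """Interval-wise cross-validated grooming prediction from shape
    coefficients.

    The frame axis is cut into consecutive intervals of ``interval_frames``;
    each interval is predicted by an RBF-kernel SVM with balanced class
    weights trained on all remaining frames.  Frames whose coefficients are
    missing (NaN) are predicted negative.
    """
    X = np.asarray(b_series, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("b_series must be (frames, t) aligned with labels")
    usable = np.all(np.isfinite(X), axis=1)
    if y[usable].all() or not y[usable].any():
        raise ValueError("training labels must contain both classes")
    n = len(y)
    pred = np.zeros(n, dtype=bool)
    starts = range(0, n, interval_frames)
    scale = np.nanstd(X[usable], axis=0)
    # drop (near-)constant coefficient dimensions: low-variance modes pin
    # against their plausibility bounds and carry no postural information,
    # but would blow up under standardization
    keep = scale > 1e-6 * max(scale.max(), 1e-12)
    if not keep.any():
        raise ValueError("all coefficient dimensions are constant")
    X = X[:, keep]
    scale = scale[keep]
    for s in starts:
        e = min(s + interval_frames, n)
        test = np.zeros(n, dtype=bool)
        test[s:e] = True
        train = usable & ~test
        if y[train].all() or not y[train].any():
            raise ValueError("an interval's training split is single-class")
        clf = SVC(kernel="rbf", class_weight="balanced", random_state=seed)
        clf.fit(X[train] / scale, y[train])
        sel = test & usable
        if sel.any():
            pred[sel] = clf.predict(X[sel] / scale)
    return pred


def events_table(events: list[BehaviorEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": e.condition, "animal": e.animal, "start_frame": e.start,
          "end_frame": e.end, "duration_s": e.duration_s} for e in events],
        columns=["condition", "animal", "start_frame", "end_frame", "duration_s"])
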