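"""Validation metrics against ground truth: landmark distances, angular
deviation, the aggregate tracking error and precision curves.

Ground truth is a per-frame, per-animal table of nose and tail-base
positions and viewing angles (typically every fifth frame of a labeled
video).  Identity correspondence is resolved before distances are taken,
so identity switches do not contaminate positional precision; they are
counted separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._geometry import wrap_angle

TRUTH_COLUMNS = ["frame", "animal_id", "nose_x", "nose_y",
                 "tail_x", "tail_y", "phi_deg"]


def _paired(record: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join record and truth per frame with identity correspondence resolved
    by minimal total nose distance (the two-permutation choice per frame)."""
    frames = sorted(set(record["frame"]) & set(truth["frame"]))
    rows = []
    skipped = 0
    for f in frames:
        r = record[record["frame"] == f]
        t = truth[truth["frame"] == f]
        if len(r) != 2 or len(t) != 2 or not np.isfinite(
                r[["nose_x", "nose_y"]].values).all():
            skipped += 1
            continue
        rv = r.sort_values("animal_id").reset_index(drop=True)
        tv = t.sort_values("animal_id").reset_index(drop=True)
        d = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                d[i, j] = np.hypot(rv.loc[i, "nose_x"] - tv.loc[j, "nose_x"],
                                   rv.loc[i, "nose_y"] - tv.loc[j, "nose_y"])
        mapping = (0, 1) if d[0, 0] + d[1, 1] <= d[0, 1] + d[1, 0] else (1, 0)
        for i, j in enumerate(mapping):
            rows.append({
                "frame": f,
                "nose_pred": rv.loc[i, ["nose_x", "nose_y"]].values.astype(float),
                "tail_pred": rv.loc[i, ["tail_x", "tail_y"]].values.astype(float),
                "phi_pred": float(rv.loc[i, "phi_deg"]),
                "nose_gt": tv.loc[j, ["nose_x", "nose_y"]].values.astype(float),
                "tail_gt": tv.loc[j, ["tail_x", "tail_y"]].values.astype(float),
                "phi_gt": float(tv.loc[j, "phi_deg"]),
            })
    out = pd.DataFrame(rows)
    out.attrs["skipped_frames"] = skipped
    return out


def landmark_errors(record: pd.DataFrame, truth: pd.DataFrame
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-(frame, animal) Euclidean nose and tail-base distances to truth."""
    paired = _paired(record, truth)
    if len(paired) == 0:
        return np.array([]), np.array([])
    d_nose = np.array([np.linalg.norm(r["nose_pred"] - r["nose_gt"])
                       for _, r in paired.iterrows()])
    d_tail = np.array([np.linalg.norm(r["tail_pred"] - r["tail_gt"])
                       for _, r in paired.iterrows()])
    return d_nose, d_tail


def angle_error(record: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Per-(frame, animal) absolute viewing-angle deviation in [0, 180]."""
    paired = _paired(record, truth)
    if len(paired) == 0:
        return np.array([])
    return np.array([abs(wrap_angle(r["phi_pred"] - r["phi_gt"]))
                     for _, r in paired.iterrows()])


def mean_error(d_nose: np.ndarray, d_tail: np.ndarray,
               literal_sum: bool = False) -> float:
    """Aggregate tracking error: the average of (nose + tail)/2 distances.

    With ``literal_sum=True`` the per-frame half-sums are summed instead of
    averaged (an alternative normalization kept for comparability).
    """
    d_nose = np.asarray(d_nose, dtype=float)
    d_tail = np.asarray(d_tail, dtype=float)
    if len(d_nose) == 0 or len(d_nose) != len(d_tail):
        raise ValueError("need equally many non-empty nose and tail errors")
    halves = 0.5 * (d_nose + d_tail)
    return float(halves.sum()) if literal_sum else float(halves.mean())


def precision_curve(errors: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Fraction of frames with error below each threshold (monotone in the
    threshold, reaching 1 at infinity)."""
    errors = np.asarray(errors, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(errors) == 0:
        return np.zeros(len(thresholds))
    return np.array([(errors < t).mean() for t in thresholds])


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ground-truth CSV lacks columns: {missing}")
    return df
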