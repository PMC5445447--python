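"""Two-animal tracking state machine.

Frames fall into two regimes.  While the animals are *separated* (two
qualifying blobs), each body contour is matched to the reference shape:
the match yields landmarks, the viewing direction and a matching cost, and
cheap matches feed the shape catalog.  When the blobs merge (*crossing*),
an active shape model trained from the catalog is fitted to both animals
with alternating iterations; landmarks inside the contour-overlap region
are frozen during the profile search so the two models cannot collapse
onto each other.  Identity follows maximum contour overlap between
successive frames while separated and is carried by the per-animal model
instance during crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from . import asm as asm_mod
from . import catalog as cat_mod
from . import preprocess as pre
from . import shape_matching as sm
from .config import PipelineConfig


B_COLS = 10  # fixed number of shape-coefficient columns in the track record


class CatalogTooSmallError(RuntimeError):
    pass


def classify_regime(blobs, floor: float, crossing_area: float) -> str:
    """Map a frame's blob list to ``separated`` / ``crossing`` / ``lost``."""
    big = [b for b in blobs if b.area >= floor]
    if len(big) >= 2:
        return "separated"
    if len(big) == 1 and big[0].area >= crossing_area:
        return "crossing"
    return "lost"


def assign_identities(prev_contours: dict[str, np.ndarray],
                      new_contours: list[np.ndarray]) -> list[str]:
    """Assign previous identity labels to two new contours by maximum total
    polygon overlap; ties keep the incoming order."""
    labels = sorted(prev_contours)
    polys_prev = {k: Polygon(v).buffer(0) for k, v in prev_contours.items()}
    polys_new = [Polygon(c).buffer(0) for c in new_contours]

    def total(mapping):
        s = 0.0
        for lab, poly in zip(mapping, polys_new):
            s += polys_prev[lab].intersection(poly).area
        return s

    straight = [labels[0], labels[1]]
    swapped = [labels[1], labels[0]]
    return straight if total(straight) >= total(swapped) else swapped


def count_identity_switches(record: pd.DataFrame, truth: pd.DataFrame) -> int:
    """Number of flips of the predicted-to-true identity mapping across the
    evaluated frames (nose-proximity resolves the mapping per frame)."""
    switches = 0
    prev_map = None
    frames = sorted(set(record["frame"]) & set(truth["frame"]))
    for f in frames:
        r = record[record["frame"] == f].set_index("animal_id")
        t = truth[truth["frame"] == f].set_index("animal_id")
        if len(r) != 2 or len(t) != 2:
            continue
        rl, tl = sorted(r.index), sorted(t.index)
        d = np.zeros((2, 2))
        for i, a in enumerate(rl):
            for j, b in enumerate(tl):
                d[i, j] = np.hypot(r.loc[a, "nose_x"] - t.loc[b, "nose_x"],
                                   r.loc[a, "nose_y"] - t.loc[b, "nose_y"])
        mapping = (0, 1) if d[0, 0] + d[1, 1] <= d[0, 1] + d[1, 0] else (1, 0)
        if prev_map is not None and mapping != prev_map:
            switches += 1
        prev_map = mapping
    return switches


@dataclass
class AnimalState:
    label: str
    contour: np.ndarray | None = None      # (n, 2) image coords, nose at idx 0
    landmarks: dict = field(default_factory=dict)
    phi: float = np.nan                    # reported viewing angle (y-up deg)
    orientation_img: float = np.nan        # tail->nose angle, image coords
    b: np.ndarray | None = None
    match_cost: float = np.nan
    instance: asm_mod.ShapeInstance | None = None


@dataclass
class TrackResult:
    record: pd.DataFrame
    catalog: cat_mod.ShapeCatalog
    model: asm_mod.ActiveShapeModel | None
    rho_max: float | None                 # final calibrated cost gate
    warmup_costs: list[float]
    all_costs: list[float]                # every separated match cost (c_v mode)
    acceptance_fraction: float | None     # realized on the warm-up candidates


class Tracker:
    """Stateful frame-by-frame tracker for one two-animal session."""

    def __init__(self, ref: cat_mod.ReferenceShape, cfg: PipelineConfig,
                 rng: np.random.Generator | None = None):
        cfg.validate()
        self.ref = ref
        self.cfg = cfg
        self.rng = rng or np.random.default_rng(cfg.seed)
        cat_cfg = cat_mod.CatalogConfig(rho_max=cfg.catalog.rho_max,
                                        c_v=cfg.catalog.c_v,
                                        max_entries=cfg.catalog.max_entries)
        self.catalog = cat_mod.ShapeCatalog(ref, cat_cfg, rng=self.rng)
        self.rho_max: float | None = cfg.catalog.rho_max
        self.model: asm_mod.ActiveShapeModel | None = None
        self.states = {"A": AnimalState("A"), "B": AnimalState("B")}
        self.warmup_costs: list[float] = []
        self._all_costs: list[float] = []     # full cost history (c_v mode)
        self._recal_at = 0                    # cost count at last calibration
        self._pending: list[tuple] = []       # candidates awaiting calibration
        self._areas: list[int] = []           # separated single-blob areas
        self._sep_since_train = 0
        self._n = cfg.match.n_points
        self._roll = (-ref.nose) % ref.contour.n
        self.lm_idx = cat_mod.rolled_landmark_indices(ref)
        self.rows: list[dict] = []
        self.acceptance_fraction: float | None = None

    # -- helpers ----------------------------------------------------------

    def _median_area(self) -> float | None:
        return float(np.median(self._areas)) if len(self._areas) >= 4 else None

    def _floor(self) -> float:
        med = self._median_area()
        if med is None:
            return float(self.cfg.preprocess.b_min)
        return self.cfg.tracker.floor_factor * med

    def _crossing_area(self) -> float:
        med = self._median_area()
        if med is None:
            return float(self.cfg.preprocess.b_min)
        return self.cfg.tracker.crossing_factor * med

    def _phi_from_landmarks(self, lms: dict) -> float:
        flip = lambda p: np.array([p[0], -p[1]])
        return cat_mod.viewing_direction(flip(lms["nose"]), flip(lms["ear_left"]),
                                         flip(lms["ear_right"]))

    def _record_row(self, f: int, st: AnimalState, regime: str,
                    overlap: float) -> None:
        row = {"frame": f, "animal_id": st.label, "regime": regime,
               "nose_x": np.nan, "nose_y": np.nan, "tail_x": np.nan,
               "tail_y": np.nan, "phi_deg": st.phi,
               "match_cost": st.match_cost, "overlap_frac": overlap}
        if st.landmarks:
            row.update(nose_x=st.landmarks["nose"][0],
                       nose_y=st.landmarks["nose"][1],
                       tail_x=st.landmarks["tail_base"][0],
                       tail_y=st.landmarks["tail_base"][1])
        for i in range(B_COLS):
            row[f"b_{i + 1}"] = (float(st.b[i]) if st.b is not None
                                 and i < len(st.b) else np.nan)
        self.rows.append(row)

    # -- separated regime -------------------------------------------------

    def _process_blob(self, blob: pre.Blob, norm: np.ndarray, state: AnimalState):
        body, tail_base = pre.locate_tail(blob.pixel_mask, self.cfg.preprocess.r_S)
        boundary = pre.trace_boundary(body if body.any() else blob.pixel_mask)
        contour = sm.resample_contour(boundary, self._n)
        prev = state.orientation_img if np.isfinite(state.orientation_img) else None
        res = cat_mod.transfer_landmarks(
            contour, self.ref, tail_hint=tail_base, prev_orientation=prev,
            n_r=self.cfg.match.n_r, n_theta=self.cfg.match.n_theta)
        profiles = asm_mod.sample_profiles(norm, res.corresponded,
                                           self.cfg.asm.profile_k)
        return res, profiles

    def _maybe_calibrate(self) -> None:
        if self.rho_max is not None:
            return
        if len(self.warmup_costs) < max(self.cfg.catalog.warmup_costs, 10):
            return
        self.rho_max = cat_mod.calibrate_rho(self.warmup_costs,
                                             self.cfg.catalog.c_v)
        self._recal_at = len(self._all_costs)
        accepted = 0
        for corresponded, H, profiles, f in self._pending:
            entry = cat_mod.gate_and_align(corresponded, self.ref, H,
                                           self.rho_max, frame_index=f,
                                           profiles=profiles)
            if entry is not None:
                self.catalog.add(entry)
                accepted += 1
        self.acceptance_fraction = accepted / len(self._pending)
        self._pending.clear()

    def _step_separated(self, f: int, blobs, norm: np.ndarray) -> None:
        floor = self._floor()
        big = [b for b in blobs if b.area >= floor][:2]
        self._areas.extend(int(b.area) for b in big)
        # identity assignment: by overlap with previous contours when known
        have_prev = all(self.states[k].contour is not None for k in "AB")
        if have_prev:
            labels = assign_identities(
                {k: self.states[k].contour for k in "AB"},
                [b.boundary for b in big])
        else:
            order = np.argsort([b.centroid[0] for b in big])
            labels = [None, None]
            labels[order[0]] = "A"
            labels[order[1]] = "B"
        for blob, label in zip(big, labels):
            state = self.states[label]
            try:
                res, profiles = self._process_blob(blob, norm, state)
            except (ValueError, cat_mod.OrientationUnresolvedError):
                self._record_row(f, state, "lost", 0.0)
                continue
            rolled = np.roll(res.corresponded, self._roll, axis=0)
            state.contour = rolled
            state.landmarks = {k: res.landmarks[k] for k in res.landmarks}
            state.match_cost = res.total_cost
            v = res.landmarks["nose"] - res.landmarks["tail_base"]
            state.orientation_img = float(np.degrees(np.arctan2(v[1], v[0])))
            state.phi = self._phi_from_landmarks(res.landmarks)
            state.instance = None
            # shape coefficients of the aligned contour, for behavior analysis
            if self.model is not None:
                aligned = cat_mod.align_vertical(res.corresponded, self.ref.nose,
                                                 self.ref.tail_base)
                aligned = np.roll(aligned, self._roll, axis=0)
                state.b = asm_mod.clamp(
                    asm_mod.project(aligned, self.model), self.model)
            else:
                state.b = None
            # catalog growth
            if self.cfg.catalog.c_v is not None:
                self._all_costs.append(res.total_cost)
            if self.rho_max is None:
                self.warmup_costs.append(res.total_cost)
                self._pending.append((res.corresponded, res.total_cost,
                                      profiles, f))
                self._maybe_calibrate()
            else:
                # the warm-up sample is small and early; periodically refit
                # the gate on the full cost history so the realized
                # acceptance ratio keeps tracking the configured target
                if (self.cfg.catalog.c_v is not None
                        and len(self._all_costs) - self._recal_at >= 100):
                    self.rho_max = cat_mod.calibrate_rho(
                        self._all_costs, self.cfg.catalog.c_v)
                    self._recal_at = len(self._all_costs)
                entry = cat_mod.gate_and_align(res.corresponded, self.ref,
                                               res.total_cost, self.rho_max,
                                               frame_index=f, profiles=profiles)
                if entry is not None:
                    self.catalog.add(entry)
            self._record_row(f, state, "separated", 0.0)
        self._sep_since_train += 1

    # -- crossing regime --------------------------------------------------

    def _train_model(self) -> None:
        if len(self.catalog) < self.cfg.tracker.min_catalog:
            raise CatalogTooSmallError(
                f"catalog has {len(self.catalog)} entries; "
                f"{self.cfg.tracker.min_catalog} required before the first "
                "crossing can be handled")
        model = asm_mod.build_shape_model(self.catalog.stacked(),
                                         f_v=self.cfg.asm.f_v, m=self.cfg.asm.m)
        profiles = np.stack([e.profiles for e in self.catalog.entries])
        asm_mod.attach_profile_model(model, profiles, k=self.cfg.asm.profile_k)
        model.landmark_indices = dict(self.lm_idx)
        self.model = model
        self._sep_since_train = 0

    def _ensure_model(self) -> None:
        if self.model is None or (
                self._sep_since_train >= self.cfg.tracker.refresh_every
                and len(self.catalog) >= self.cfg.tracker.min_catalog):
            self._train_model()

    def _frozen_mask(self, pts: np.ndarray, other_poly) -> np.ndarray:
        if other_poly.is_empty:
            return np.zeros(len(pts), dtype=bool)
        region = other_poly.buffer(self.cfg.tracker.overlap_margin)
        return shapely.contains_xy(region, pts[:, 0], pts[:, 1])

    def _step_crossing(self, f: int, norm: np.ndarray) -> None:
        self._ensure_model()
        model = self.model
        for k in "AB":
            st = self.states[k]
            if st.instance is None:
                if st.contour is None:
                    raise RuntimeError("crossing before any separated frame")
                st.instance = asm_mod.instance_from_contour(model, st.contour)
        order = ["A", "B"] if f % 2 == 0 else ["B", "A"]
        insts = {k: self.states[k].instance for k in "AB"}
        for _ in range(self.cfg.asm.N_max):
            for k in order:
                other = "B" if k == "A" else "A"
                pts_self = insts[k].realize(model)
                pts_other = insts[other].realize(model)
                overlap = Polygon(pts_self).buffer(0).intersection(
                    Polygon(pts_other).buffer(0))
                frozen = self._frozen_mask(pts_self, overlap)
                insts[k] = asm_mod.fit_step(model, norm, insts[k],
                                            search_l=self.cfg.asm.search_l,
                                            frozen=frozen)
        polys = {k: Polygon(insts[k].realize(model)).buffer(0) for k in "AB"}
        inter = polys["A"].intersection(polys["B"]).area
        denom = min(polys["A"].area, polys["B"].area)
        ovl = inter / denom if denom > 0 else 0.0
        for k in "AB":
            st = self.states[k]
            st.instance = insts[k]
            contour = insts[k].realize(model)
            st.contour = contour
            st.landmarks = {name: contour[idx].copy()
                            for name, idx in self.lm_idx.items()}
            st.b = insts[k].b.copy()
            st.match_cost = np.nan
            v = st.landmarks["nose"] - st.landmarks["tail_base"]
            st.orientation_img = float(np.degrees(np.arctan2(v[1], v[0])))
            st.phi = self._phi_from_landmarks(st.landmarks)
            self._record_row(f, st, "crossing", ovl)

    # -- main loop --------------------------------------------------------

    def process_frame(self, f: int, frame: np.ndarray,
                      bg: pre.BackgroundModel) -> None:
        norm = pre.normalize_illumination(frame, self.cfg.preprocess.target_mean)
        mask = pre.segment_foreground(norm, bg, pre.PreprocessConfig(
            b_min=self.cfg.preprocess.b_min, r_S=self.cfg.preprocess.r_S,
            threshold=self.cfg.preprocess.threshold,
            target_mean=self.cfg.preprocess.target_mean))
        blobs = pre.extract_blobs(mask, self.cfg.preprocess.b_min)
        regime = classify_regime(blobs, self._floor(), self._crossing_area())
        if regime == "separated":
            self._step_separated(f, blobs, norm)
        elif regime == "crossing":
            self._step_crossing(f, norm)
        else:
            for k in "AB":
                self._record_row(f, self.states[k], "lost", 0.0)

    def result(self) -> TrackResult:
        rho = self.rho_max
        if self.cfg.catalog.c_v is not None and len(self._all_costs) >= 10:
            rho = cat_mod.calibrate_rho(self._all_costs, self.cfg.catalog.c_v)
        return TrackResult(record=pd.DataFrame(self.rows), catalog=self.catalog,
                           model=self.model, rho_max=rho,
                           warmup_costs=list(self.warmup_costs),
                           all_costs=list(self._all_costs),
                           acceptance_fraction=self.acceptance_fraction)


def build_background_subsampled(frames, max_frames: int = 120,
                                target_mean: float = 128.0) -> pre.BackgroundModel:
    """Background from an evenly subsampled, illumination-normalized subset."""
    n = len(frames)
    step = max(1, n // max_frames)
    subset = [pre.normalize_illumination(frames[i], target_mean)
              for i in range(0, n, step)]
    return pre.build_background(subset)


def track_frames(frames, ref: cat_mod.ReferenceShape, cfg: PipelineConfig,
                 rng: np.random.Generator | None = None,
                 model: asm_mod.ActiveShapeModel | None = None) -> TrackResult:
    """Track a full in-memory frame sequence; the main library entry point.

    A previously trained shape model may be supplied; the catalog still
    grows and the model is refreshed on the usual schedule.
    """
    tracker = Tracker(ref, cfg, rng=rng)
    if model is not None:
        tracker.model = model
    bg = build_background_subsampled(frames,
                                     target_mean=cfg.preprocess.target_mean)
    for f, frame in enumerate(frames):
        tracker.process_frame(f, frame, bg)
    return tracker.result()
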