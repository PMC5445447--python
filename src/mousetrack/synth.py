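"""Synthetic top-view arena sessions with articulated mouse silhouettes.

Every pipeline stage is testable against this generator: it renders two
dark, mouse-shaped blobs (bendable spine, squash/stretch, elliptical head
with ear bumps, thin tapering tail) over a static bright background with
optional multiplicative illumination drift and Gaussian sensor noise, and
returns per-frame ground truth (nose, tail base, ears, viewing direction,
identity, silhouette overlap) plus scripted behavior-episode labels.

Default rendering emulates the recording conditions of the real system: a
480x480 px arena, body length 80 px, background grey 200, animal grey 40
(120 in the low-contrast variant), noise sigma 3 and 25 fps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon

from ._geometry import rotation_matrix

ARENA = 480
BG_GREY = 200.0
MOUSE_GREY = 40.0
LOW_CONTRAST_GREY = 120.0
NOISE_SIGMA = 3.0
FPS = 25.0
BODY_LENGTH = 80.0
BODY_WIDTH = 30.0


@dataclass
class MouseShapeParams:
    body_length: float = BODY_LENGTH
    body_width: float = BODY_WIDTH
    bend_deg: float = 0.0          # + bends the spine to the left of heading
    stretch: float = 1.0           # < 1 compresses the body (grooming posture)
    head_scale: float = 1.0
    ear_radius: float = 6.0
    tail_length: float = 55.0
    tail_width: float = 3.0

    def __post_init__(self) -> None:
        if abs(self.bend_deg) > 120.0:
            raise ValueError("spine bend beyond 120 degrees self-intersects")
        for name in ("body_length", "body_width", "stretch", "head_scale",
                     "ear_radius", "tail_length", "tail_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SessionScript:
    """Deterministic frame-by-frame choreography for two animals."""

    pos: np.ndarray        # (F, 2, 2) anchor (spine midpoint), image coords
    heading: np.ndarray    # (F, 2) viewing direction, degrees, y-up convention
    bend: np.ndarray       # (F, 2) degrees
    stretch: np.ndarray    # (F, 2)
    labels: list = field(default_factory=list)  # dicts: condition/animal/start/end
    arena: int = ARENA
    bg_grey: float = BG_GREY
    mouse_grey: float = MOUSE_GREY
    noise_sigma: float = NOISE_SIGMA
    drift_amp: float = 0.02
    drift_period: float = 200.0
    fps: float = FPS
    seed: int = 0
    name: str = "custom"

    @property
    def n_frames(self) -> int:
        return len(self.pos)


def _spine(params: MouseShapeParams, n: int = 129) -> np.ndarray:
    """Spine polyline in local coordinates (math y-up, heading along +x,
    nose at the origin), from tail base (index 0) to nose (index -1)."""
    L = params.body_length * params.stretch
    bend = np.radians(params.bend_deg)
    t = np.linspace(0.0, 1.0, n)
    # heading along the spine: psi(1) = 0 at the nose, psi(0) = -bend
    psi = bend * (t - 1.0)
    # integrate backwards from the nose
    dpsi = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    seg = L / (n - 1)
    pts = np.zeros((n, 2))
    pts[:-1] = -np.cumsum((dpsi[1:] * seg)[::-1], axis=0)[::-1]
    return pts


def render_mouse(params: MouseShapeParams, pose: tuple[float, float, float]
                 ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Silhouette polygon and true landmarks for one posed mouse.

    ``pose = (x, y, heading_deg)`` places the spine midpoint at ``(x, y)``
    (image coordinates, y down) with the viewing direction ``heading_deg``
    in the y-up degree convention.  Returns ``(polygon_xy, landmarks)`` with
    landmarks ``nose``, ``tail_base``, ``ear_left``, ``ear_right`` exactly
    consistent with the viewing-direction definition (the ear midpoint lies
    on the nose tangent line).
    """
    spine = _spine(params)
    n = len(spine)
    w = params.body_width / np.sqrt(params.stretch)
    t = np.linspace(0.0, 1.0, n)
    tang = np.gradient(spine, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    # body: teardrop between tail base and shoulder (t <= 0.78)
    body_sel = t <= 0.78
    tb = t[body_sel] / 0.78
    half_w = 0.5 * w * np.sin(np.pi * np.clip(tb, 0, 1)) ** 0.55
    half_w[0] = 0.0
    left = spine[body_sel] + half_w[:, None] * normal[body_sel]
    right = spine[body_sel] - half_w[:, None] * normal[body_sel]
    body_poly = Polygon(np.vstack([left, right[::-1]])).buffer(0)

    # head: ellipse whose +x extreme is exactly the nose
    a_h = 0.30 * params.body_length * params.head_scale * params.stretch ** 0.5
    b_h = 0.40 * w * params.head_scale
    c_h = np.array([-a_h, 0.0])
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    head = np.stack([c_h[0] + a_h * np.cos(th), c_h[1] + b_h * np.sin(th)], axis=1)
    head_poly = Polygon(head)

    # ears: discs placed symmetrically about the nose tangent line
    d_e = 1.05 * a_h
    e_off = b_h + 0.35 * params.ear_radius
    ear_l_c = np.array([-d_e, +e_off])   # left of heading in y-up frame
    ear_r_c = np.array([-d_e, -e_off])
    ear_polys = [Polygon(np.stack([c[0] + params.ear_radius * np.cos(th),
                                   c[1] + params.ear_radius * np.sin(th)],
                                  axis=1)) for c in (ear_l_c, ear_r_c)]

    # tail: thin tapering strip continuing backwards from the tail base
    tail_dir = -tang[0]
    tail_n = np.array([-tail_dir[1], tail_dir[0]])
    ts = np.linspace(0.0, 1.0, 24)
    # root the strip 5 px inside the body so the union stays one polygon
    tail_spine = (spine[0] - 5.0 * tail_dir
                  + np.outer(ts * (params.tail_length + 5.0), tail_dir))
    tail_hw = 0.5 * params.tail_width * (1.0 - 0.4 * ts) + 0.3
    tail_left = tail_spine + tail_hw[:, None] * tail_n
    tail_right = tail_spine - tail_hw[:, None] * tail_n
    tail_poly = Polygon(np.vstack([tail_left, tail_right[::-1]])).buffer(0)

    merged = unary_union([body_poly, head_poly, *ear_polys, tail_poly]).buffer(0)
    if merged.geom_type != "Polygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    local = np.asarray(merged.exterior.coords)[:-1]

    landmarks_local = {
        "nose": np.array([0.0, 0.0]),
        "tail_base": spine[0].copy(),
        "ear_left": ear_l_c,
        "ear_right": ear_r_c,
    }
    anchor = spine[len(spine) // 2]

    x0, y0, heading = pose
    R = rotation_matrix(heading)  # rotation in the y-up frame

    def to_image(p: np.ndarray) -> np.ndarray:
        q = (p - anchor) @ R.T
        return np.stack([x0 + q[..., 0], y0 - q[..., 1]], axis=-1)

    poly_img = to_image(local)
    lms_img = {k: to_image(v) for k, v in landmarks_local.items()}
    if not Polygon(poly_img).is_valid:
        raise ValueError("rendered silhouette self-intersects (extreme bend)")
    return poly_img, lms_img


_SUPERSAMPLE = 4


def rasterize_alpha(polygons, shape: tuple[int, int],
                    ss: int = _SUPERSAMPLE) -> np.ndarray:
    """Anti-aliased occupancy of a polygon union in [0, 1] per pixel.

    Rasterized on an ``ss``-times finer grid and block-averaged, which
    emulates the partial-pixel coverage a real camera's optics produce and
    gives sub-pixel edge localization downstream.
    """
    H, W = shape
    alpha = np.zeros((H, W), dtype=float)
    for poly in polygons:
        pts = np.asarray(poly, dtype=float)
        # rasterize on a fine grid restricted to the polygon's bounding box
        x0 = max(int(np.floor(pts[:, 0].min())) - 1, 0)
        y0 = max(int(np.floor(pts[:, 1].min())) - 1, 0)
        x1 = min(int(np.ceil(pts[:, 0].max())) + 2, W)
        y1 = min(int(np.ceil(pts[:, 1].max())) + 2, H)
        if x1 <= x0 or y1 <= y0:
            continue
        h, w = y1 - y0, x1 - x0
        big = np.zeros((h * ss, w * ss), dtype=bool)
        rr, cc = draw_polygon((pts[:, 1] - y0) * ss + (ss - 1) / 2.0,
                              (pts[:, 0] - x0) * ss + (ss - 1) / 2.0,
                              shape=big.shape)
        big[rr, cc] = True
        local = big.reshape(h, ss, w, ss).mean(axis=(1, 3))
        np.maximum(alpha[y0:y1, x0:x1], local, out=alpha[y0:y1, x0:x1])
    return alpha


def render_frame(script: SessionScript, f: int,
                 rng: np.random.Generator | None = None,
                 with_truth: bool = False):
    """Render one frame (float array); optionally return truth rows too."""
    H = W = script.arena
    drift = 1.0 + script.drift_amp * np.sin(2 * np.pi * f / script.drift_period)
    polys = []
    poly_pts = []
    truth_rows = []
    for a, animal in enumerate("AB"):
        params = MouseShapeParams(bend_deg=float(script.bend[f, a]),
                                  stretch=float(script.stretch[f, a]))
        poly, lms = render_mouse(params, (float(script.pos[f, a, 0]),
                                          float(script.pos[f, a, 1]),
                                          float(script.heading[f, a])))
        if (poly < 0).any() or (poly[:, 0] >= W).any() or (poly[:, 1] >= H).any():
            raise ValueError(f"animal {animal} leaves the arena at frame {f}")
        poly_pts.append(poly)
        polys.append(Polygon(poly))
        if with_truth:
            truth_rows.append({
                "frame": f, "animal_id": animal,
                "nose_x": lms["nose"][0], "nose_y": lms["nose"][1],
                "tail_x": lms["tail_base"][0], "tail_y": lms["tail_base"][1],
                "ear_left_x": lms["ear_left"][0], "ear_left_y": lms["ear_left"][1],
                "ear_right_x": lms["ear_right"][0], "ear_right_y": lms["ear_right"][1],
                "phi_deg": float(script.heading[f, a]),
            })
    alpha = rasterize_alpha(poly_pts, (H, W))
    frame = drift * (script.bg_grey * (1.0 - alpha) + script.mouse_grey * alpha)
    if rng is not None and script.noise_sigma > 0:
        frame = frame + rng.normal(0.0, script.noise_sigma, frame.shape)
    frame = np.clip(frame, 0.0, 255.0)
    if with_truth:
        inter = polys[0].intersection(polys[1]).area
        ovl = inter / min(polys[0].area, polys[1].area)
        for row in truth_rows:
            row["overlap_frac"] = ovl
        return frame, truth_rows
    return frame


def session_truth(script: SessionScript) -> pd.DataFrame:
    """Ground-truth table (landmarks, angles, overlap) without rasterizing.

    Useful when only trajectories are needed, e.g. for behavior-predicate
    checks on scripted sessions.
    """
    rows = []
    for f in range(script.n_frames):
        polys = []
        for a, animal in enumerate("AB"):
            params = MouseShapeParams(bend_deg=float(script.bend[f, a]),
                                      stretch=float(script.stretch[f, a]))
            poly, lms = render_mouse(params, (float(script.pos[f, a, 0]),
                                              float(script.pos[f, a, 1]),
                                              float(script.heading[f, a])))
            polys.append(Polygon(poly))
            rows.append({
                "frame": f, "animal_id": animal,
                "nose_x": lms["nose"][0], "nose_y": lms["nose"][1],
                "tail_x": lms["tail_base"][0], "tail_y": lms["tail_base"][1],
                "ear_left_x": lms["ear_left"][0],
                "ear_left_y": lms["ear_left"][1],
                "ear_right_x": lms["ear_right"][0],
                "ear_right_y": lms["ear_right"][1],
                "phi_deg": float(script.heading[f, a]),
            })
        inter = polys[0].intersection(polys[1]).area
        ovl = inter / min(polys[0].area, polys[1].area)
        rows[-1]["overlap_frac"] = ovl
        rows[-2]["overlap_frac"] = ovl
    return pd.DataFrame(rows)


def render_session(script: SessionScript
                   ) -> tuple[list[np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render all frames of a script.

    Returns ``(frames, truth, labels)``: uint8 grayscale frames, a per-frame
    per-animal ground-truth table (landmarks, viewing angle, silhouette
    overlap fraction) and the scripted behavior intervals.
    """
    rng = np.random.default_rng(script.seed)
    frames = []
    rows = []
    for f in range(script.n_frames):
        frame, truth_rows = render_frame(script, f, rng=rng, with_truth=True)
        frames.append(np.round(frame).astype(np.uint8))
        rows.extend(truth_rows)
    truth = pd.DataFrame(rows)
    labels = pd.DataFrame(script.labels,
                          columns=["condition", "animal", "start", "end"])
    return frames, truth, labels


# ---------------------------------------------------------------------------
# script library


def _smooth_noise(rng, n, period, amp):
    """Band-limited noise: a few random sinusoids, deterministic per rng."""
    out = np.zeros(n)
    f = np.arange(n)
    for _ in range(3):
        ph = rng.uniform(0, 2 * np.pi)
        p = period * rng.uniform(0.7, 1.4)
        out += np.sin(2 * np.pi * f / p + ph)
    return amp * out / 3.0


def _circle_motion(n, center, radius, omega, phase):
    f = np.arange(n)
    ang = phase + omega * f
    pos = np.stack([center[0] + radius * np.cos(ang),
                    center[1] + radius * np.sin(ang)], axis=1)
    # heading = direction of motion (image coords -> y-up angle)
    vel = np.gradient(pos, axis=0)
    heading = np.degrees(np.arctan2(-vel[:, 1], vel[:, 0]))
    return pos, heading


def separated_only(n_frames: int = 200, seed: int = 0, **kw) -> SessionScript:
    """Two animals wandering on disjoint halves of the arena; no contact."""
    rng = np.random.default_rng(seed)
    posA, headA = _circle_motion(n_frames, (130, 240), 55, 0.045, 0.3)
    posB, headB = _circle_motion(n_frames, (350, 240), 55, -0.045, 2.4)
    bend = np.stack([_smooth_noise(rng, n_frames, 70, 25),
                     _smooth_noise(rng, n_frames, 80, 25)], axis=1)
    stretch = 1.0 + np.stack([_smooth_noise(rng, n_frames, 60, 0.10),
                              _smooth_noise(rng, n_frames, 65, 0.10)], axis=1)
    return SessionScript(pos=np.stack([posA, posB], axis=1),
                         heading=np.stack([headA, headB], axis=1),
                         bend=bend, stretch=stretch, seed=seed,
                         name="separated_only", **kw)


def crossings_k(k: int = 3, n_frames: int = 300, seed: int = 0,
                dy: float = 22.0, lead_frac: float = 0.2,
                **kw) -> SessionScript:
    """The two animals sweep horizontally past each other ``k`` times,
    merging into a single blob with moderate (<= ~50%) silhouette overlap
    at every pass.

    ``lead_frac`` sets the fraction of the session spent circling apart
    before the sweeps begin; the default suffices for the catalog to fill
    at the default acceptance ratio, while low-acceptance studies need a
    longer lead.
    """
    rng = np.random.default_rng(seed)
    f = np.arange(n_frames)
    x_lo, x_hi = 110.0, 370.0
    # lead-in: the animals circle slowly on their own sides long enough for
    # the shape catalog to fill, then sweep k half-cycles past each other
    lead = int(n_frames * lead_frac)
    u = np.clip((f - lead) / (n_frames - 1 - lead), 0.0, 1.0)
    phase = np.pi * k * u
    xa = x_lo + (x_hi - x_lo) * 0.5 * (1 - np.cos(phase))
    xb = x_hi - (x_hi - x_lo) * 0.5 * (1 - np.cos(phase))
    ya = np.full(n_frames, 240.0 - dy / 2)
    yb = np.full(n_frames, 240.0 + dy / 2)
    # small circles ending exactly at the sweep start points
    r_c = 25.0
    turns = max(1, round(lead / 60))   # keep circling speed ~2.6 px/frame
    theta = 2 * np.pi * turns * np.clip(lead - f, 0, None) / max(lead, 1)
    # circles bulge toward the arena center so tails stay inside the frame
    circ = np.stack([r_c * (1.0 - np.cos(theta)), r_c * np.sin(theta)], axis=1)
    in_lead = f < lead
    xa[in_lead] += circ[in_lead, 0]
    ya[in_lead] += circ[in_lead, 1]
    xb[in_lead] -= circ[in_lead, 0]
    yb[in_lead] -= circ[in_lead, 1]
    posA = np.stack([xa, ya], axis=1)
    posB = np.stack([xb, yb], axis=1)
    velA = np.gradient(posA, axis=0)
    velB = np.gradient(posB, axis=0)
    headA = np.degrees(np.arctan2(-velA[:, 1], velA[:, 0]))
    headB = np.degrees(np.arctan2(-velB[:, 1], velB[:, 0]))
    bend = np.stack([_smooth_noise(rng, n_frames, 90, 15),
                     _smooth_noise(rng, n_frames, 85, 15)], axis=1)
    stretch = 1.0 + np.stack([_smooth_noise(rng, n_frames, 70, 0.06),
                              _smooth_noise(rng, n_frames, 75, 0.06)], axis=1)
    return SessionScript(pos=np.stack([posA, posB], axis=1),
                         heading=np.stack([headA, headB], axis=1),
                         bend=bend, stretch=stretch, seed=seed,
                         name=f"crossings_{k}", **kw)


def _two_episode_script(n_frames, seed, build_episode, condition, animal,
                        **kw) -> SessionScript:
    """Base pattern: far-apart idling with two scripted contact episodes."""
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_frames, 2, 2))
    heading = np.zeros((n_frames, 2))
    # idle posture: far corners, facing away from each other
    pos[:, 0] = (120.0, 120.0)
    pos[:, 1] = (360.0, 360.0)
    heading[:, 0] = 180.0
    heading[:, 1] = 0.0
    labels = []
    third = n_frames // 3
    ep_len = third // 2
    for e, start in enumerate((third - ep_len // 2, 2 * third)):
        end = start + ep_len
        build_episode(pos, heading, start, end)
        labels.append({"condition": condition, "animal": animal,
                       "start": start, "end": end - 1})
    bend = np.stack([_smooth_noise(rng, n_frames, 90, 10),
                     _smooth_noise(rng, n_frames, 95, 10)], axis=1)
    stretch = np.ones((n_frames, 2))
    return SessionScript(pos=pos, heading=heading, bend=bend, stretch=stretch,
                         labels=labels, seed=seed, name=condition, **kw)


def nose_nose(n_frames: int = 240, seed: int = 0, **kw) -> SessionScript:
    """Two head-on contact episodes (noses ~10 px apart)."""
    def ep(pos, heading, start, end):
        # facing each other along x; spine midpoint ~ 40 px behind the nose
        pos[start:end, 0] = (240.0 - 5.0 - 40.0, 240.0)
        pos[start:end, 1] = (240.0 + 5.0 + 40.0, 240.0)
        heading[start:end, 0] = 0.0
        heading[start:end, 1] = 180.0
    return _two_episode_script(n_frames, seed, ep, "C1", "A-B", **kw)


def nose_anogenital(n_frames: int = 240, seed: int = 0, **kw) -> SessionScript:
    """Two episodes of B sniffing A's tail base from behind."""
    def ep(pos, heading, start, end):
        pos[start:end, 0] = (240.0 + 40.0, 240.0)   # A heading +x, tail base ~240
        heading[start:end, 0] = 0.0
        # B behind A, heading +x, nose 10 px behind A's tail base
        pos[start:end, 1] = (240.0 - 10.0 - 40.0, 240.0)
        heading[start:end, 1] = 0.0
    return _two_episode_script(n_frames, seed, ep, "C2", "B-A", **kw)


def side_by_side(n_frames: int = 240, seed: int = 0, **kw) -> SessionScript:
    """Two episodes of parallel side-by-side contact (centers ~35 px)."""
    def ep(pos, heading, start, end):
        pos[start:end, 0] = (240.0, 222.0)
        pos[start:end, 1] = (240.0, 257.0)
        heading[start:end, 0] = 0.0
        heading[start:end, 1] = 0.0
    return _two_episode_script(n_frames, seed, ep, "C3", "A-B", **kw)


def following(n_frames: int = 240, seed: int = 0, **kw) -> SessionScript:
    """Two episodes of B trailing A at half a body length, aligned headings."""
    script = _two_episode_script(n_frames, seed, lambda *a: None, "C4", "B-A", **kw)
    script.labels.clear()
    third = n_frames // 3
    ep_len = third // 2
    for start in (third - ep_len // 2, 2 * third):
        end = start + ep_len
        f = np.arange(start, end)
        # B's nose (pos + 40) trails A's tail base (pos - 40) by 25 px
        x = 140.0 + 3.0 * (f - start)
        script.pos[start:end, 0] = np.stack([x + 105.0,
                                             np.full_like(x, 240.0)], axis=1)
        script.pos[start:end, 1] = np.stack([x, np.full_like(x, 240.0)], axis=1)
        script.heading[start:end] = 0.0
        script.labels.append({"condition": "C4", "animal": "B-A",
                              "start": start, "end": end - 1})
    return script


def mating_posture(n_frames: int = 240, seed: int = 0, **kw) -> SessionScript:
    """Two episodes of high-overlap mounting with aligned headings."""
    def ep(pos, heading, start, end):
        pos[start:end, 0] = (240.0, 240.0)
        pos[start:end, 1] = (240.0 + 14.0, 240.0 + 8.0)
        heading[start:end, 0] = 0.0
        heading[start:end, 1] = 10.0
    return _two_episode_script(n_frames, seed, ep, "C5", "B-A", **kw)


def grooming(n_frames: int = 400, seed: int = 0, **kw) -> SessionScript:
    """Separated wandering with self-grooming episodes of animal A
    (body compressed to stretch ~0.7; labeled where stretch < 0.85)."""
    script = separated_only(n_frames, seed, **kw)
    script.name = "grooming"
    third = n_frames // 3
    ep_len = third // 2
    for start in (third - ep_len // 2, 2 * third):
        end = start + ep_len
        f = np.arange(start, end)
        ramp = np.minimum(1.0, np.minimum(f - start, end - 1 - f) / 6.0)
        script.stretch[start:end, 0] = 1.0 - 0.32 * ramp
        script.bend[start:end, 0] *= 0.3
        # freeze A's motion during the episode: posture, not motion, is the cue
        script.pos[start:end, 0] = script.pos[start, 0]
        script.heading[start:end, 0] = script.heading[start, 0]
    # label exactly the frames with a compressed posture
    compressed = script.stretch[:, 0] < 0.85
    edges = np.flatnonzero(np.diff(compressed.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2]
    for s, e in zip(starts, ends):
        script.labels.append({"condition": "C6", "animal": "A",
                              "start": int(s), "end": int(e)})
    return script


def low_contrast(n_frames: int = 200, seed: int = 0, **kw) -> SessionScript:
    """Separated wandering with reduced animal/background contrast."""
    script = separated_only(n_frames, seed, mouse_grey=LOW_CONTRAST_GREY, **kw)
    script.name = "low_contrast"
    return script


SCRIPTS = {
    "separated_only": separated_only,
    "crossings_1": lambda **kw: crossings_k(1, **kw),
    "crossings_3": lambda **kw: crossings_k(3, **kw),
    "following": following,
    "nose_nose": nose_nose,
    "nose_anogenital": nose_anogenital,
    "side_by_side": side_by_side,
    "mating_posture": mating_posture,
    "grooming": grooming,
    "low_contrast": low_contrast,
}


def script_library() -> dict[str, object]:
    """Named canned scripts (factories accepting ``n_frames`` and ``seed``)."""
    return dict(SCRIPTS)


def generator_correspondence(poly: np.ndarray, landmarks: dict,
                             n: int = 100, tail_index: int = 50) -> np.ndarray:
    """Model-order contour directly from a generator silhouette.

    Resamples the polygon, fixes the traversal handedness, rolls the nose to
    index 0 and re-spaces each nose-to-tail side by arc length so the result
    is directly comparable to catalog entries (``tail_index`` must be the
    catalog's rolled tail-base index).  Bypasses segmentation and matching:
    useful for testing shape-space operations against generator truth.
    """
    from ._geometry import polygon_signed_area
    from .catalog import _resample_polyline
    from .shape_matching import resample_contour

    c = resample_contour(poly, 2 * n).points
    if polygon_signed_area(c) < 0:
        c = c[::-1]
    ni = int(np.argmin(np.linalg.norm(c - landmarks["nose"], axis=1)))
    seq = np.roll(c, -ni, axis=0)
    ti = int(np.argmin(np.linalg.norm(seq - landmarks["tail_base"], axis=1)))
    side1 = _resample_polyline(seq[:ti + 1], tail_index + 1)
    side2 = _resample_polyline(np.vstack([seq[ti:], seq[:1]]),
                               n - tail_index + 1)
    return np.vstack([side1[:-1], side2[:-1]])


def make_reference(n_points: int = 100, r_S: int = 4,
                   params: MouseShapeParams | None = None):
    """Annotated reference shape from a noise-free straight rendering.

    Renders one straight mouse, removes the tail morphologically (the same
    operation the tracker applies), traces and resamples the body contour
    and marks the landmark indices nearest to the true landmark positions.
    This plays the role of the one-time user annotation.
    """
    from . import preprocess as pre
    from . import shape_matching as sm
    from .catalog import ReferenceShape

    params = params or MouseShapeParams()
    pose = (ARENA / 2, ARENA / 2, 0.0)
    poly, lms = render_mouse(params, pose)
    from skimage.draw import polygon as _poly
    mask = np.zeros((ARENA, ARENA), dtype=bool)
    rr, cc = _poly(poly[:, 1], poly[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    body, _tail = pre.locate_tail(mask, r_S)
    boundary = pre.trace_boundary(body)
    contour = sm.resample_contour(boundary, n_points)

    def nearest(p):
        return int(np.argmin(np.linalg.norm(contour.points - p, axis=1)))

    idx = {k: nearest(lms[k]) for k in ("nose", "tail_base",
                                        "ear_left", "ear_right")}
    if len(set(idx.values())) != 4:
        raise ValueError("degenerate reference annotation (landmarks collide)")
    return ReferenceShape(contour=contour, nose=idx["nose"],
                          tail_base=idx["tail_base"], ear_left=idx["ear_left"],
                          ear_right=idx["ear_right"])
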