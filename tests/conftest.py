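"""Shared fixtures: synthetic reference shape, rendered catalogs and models.

Everything is generated programmatically at test time from the synthetic
mouse renderer, with fixed seeds for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from mousetrack import asm
from mousetrack import catalog as cat
from mousetrack import preprocess as pre
from mousetrack import shape_matching as sm
from mousetrack import synth


def render_frame_from_polys(polys, bg=200.0, fg=40.0, arena=480,
                            noise=0.0, rng=None):
    """Anti-aliased grayscale frame from silhouette polygons."""
    alpha = synth.rasterize_alpha(polys, (arena, arena))
    frame = bg * (1.0 - alpha) + fg * alpha
    if noise > 0:
        frame = frame + (rng or np.random.default_rng(0)).normal(
            0.0, noise, frame.shape)
    return frame


@pytest.fixture(scope="session")
def reference():
    return synth.make_reference()


def build_catalog_entries(reference, n_entries=60, seed=1, noise=3.0):
    """Catalog entries through the full separated-frame pipeline:
    render -> segment -> tail removal -> match -> gate."""
    rng = np.random.default_rng(seed)
    entries = []
    while len(entries) < n_entries:
        bend = rng.uniform(-25, 25)
        stretch = rng.uniform(0.9, 1.1)
        pose = (240.0 + rng.uniform(-40, 40), 240.0 + rng.uniform(-40, 40),
                rng.uniform(0, 360))
        poly, _ = synth.render_mouse(
            synth.MouseShapeParams(bend_deg=bend, stretch=stretch), pose)
        frame = render_frame_from_polys([poly], noise=noise, rng=rng)
        body, tail = pre.locate_tail(frame < 120, 4)
        contour = sm.resample_contour(pre.trace_boundary(body), 100)
        res = cat.transfer_landmarks(contour, reference, tail_hint=tail,
                                     prev_orientation=0 if tail is None else None)
        profiles = asm.sample_profiles(frame, res.corresponded, 5)
        entry = cat.gate_and_align(res.corresponded, reference, res.total_cost,
                                   np.inf, len(entries), profiles)
        entries.append(entry)
    return entries


@pytest.fixture(scope="session")
def mouse_catalog(reference):
    return build_catalog_entries(reference)


@pytest.fixture(scope="session")
def mouse_model(reference, mouse_catalog):
    """Shape + profile model trained from the pipeline-built catalog."""
    shapes = np.stack([e.aligned.reshape(-1) for e in mouse_catalog])
    model = asm.build_shape_model(shapes, f_v=0.98, m=3.0)
    asm.attach_profile_model(
        model, np.stack([e.profiles for e in mouse_catalog]), k=5)
    model.landmark_indices = cat.rolled_landmark_indices(reference)
    return model


@pytest.fixture(scope="session")
def random_simple_polygons():
    """20 random star-shaped simple polygons with n = 40 vertices."""
    rng = np.random.default_rng(42)
    polys = []
    for _ in range(20):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 40))
        rad = rng.uniform(20, 60, 40)
        # smooth the radii so shapes stay simple but non-convex
        rad = np.convolve(np.r_[rad[-2:], rad, rad[:2]],
                          np.ones(5) / 5, mode="valid")
        pts = np.stack([100 + rad * np.cos(ang), 100 + rad * np.sin(ang)],
                       axis=1)
        polys.append(pts)
    return polys
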