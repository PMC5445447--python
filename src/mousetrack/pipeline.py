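"""End-to-end runs: annotate -> track -> artifacts on disk."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import asm as asm_mod
from . import io as mio
from . import preprocess as pre
from . import shape_matching as sm
from .catalog import ReferenceShape
from .config import PipelineConfig
from .tracker import build_background_subsampled, track_frames


def annotate_reference(frames, frame_index: int, clicks: dict[str, tuple],
                       cfg: PipelineConfig) -> ReferenceShape:
    """Build the reference shape from user-provided landmark positions.

    ``clicks`` maps landmark names (nose, tail_base, ear_left, ear_right) to
    pixel positions on the chosen frame.  The frame is segmented, the blob
    containing (or nearest to) the nose click is selected, its tail is
    removed, and the resampled body contour is annotated with the indices
    nearest to the clicked points.
    """
    cfg.validate()
    bg = build_background_subsampled(frames,
                                     target_mean=cfg.preprocess.target_mean)
    norm = pre.normalize_illumination(frames[frame_index],
                                      cfg.preprocess.target_mean)
    pcfg = pre.PreprocessConfig(b_min=cfg.preprocess.b_min,
                                r_S=cfg.preprocess.r_S,
                                threshold=cfg.preprocess.threshold,
                                target_mean=cfg.preprocess.target_mean)
    mask = pre.segment_foreground(norm, bg, pcfg)
    blobs = pre.extract_blobs(mask, cfg.preprocess.b_min)
    if not blobs:
        raise ValueError("no blob found in the chosen annotation frame")
    nose = np.asarray(clicks["nose"], dtype=float)
    blob = min(blobs, key=lambda b: np.linalg.norm(b.centroid - nose))
    body, _ = pre.locate_tail(blob.pixel_mask, cfg.preprocess.r_S)
    contour = sm.resample_contour(pre.trace_boundary(body),
                                  cfg.match.n_points)

    def nearest(p):
        return int(np.argmin(np.linalg.norm(
            contour.points - np.asarray(p, dtype=float), axis=1)))

    idx = {k: nearest(v) for k, v in clicks.items()}
    return ReferenceShape(contour=contour, nose=idx["nose"],
                          tail_base=idx["tail_base"],
                          ear_left=idx["ear_left"],
                          ear_right=idx["ear_right"])


def run_pipeline(video: str | Path, reference: str | Path,
                 cfg: PipelineConfig, out_dir: str | Path,
                 save_model: bool = True,
                 load_model: str | Path | None = None):
    """Track a video and write track CSV, model archive and provenance."""
    cfg.validate()
    ref = mio.load_reference(reference)   # fails before any frame is decoded
    frames = mio.load_frames(video)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    model = asm_mod.load_model(load_model) if load_model else None
    result = track_frames(frames, ref, cfg, rng=rng, model=model)
    mio.write_track_csv(result.record, out / "track.csv")
    if save_model and result.model is not None:
        asm_mod.save_model(out / "model.npz", result.model)
    mio.write_provenance(out / "provenance.json", cfg, cfg.seed,
                         extra={"n_frames": len(frames),
                                "rho_max": result.rho_max,
                                "catalog_size": len(result.catalog)})
    return result
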