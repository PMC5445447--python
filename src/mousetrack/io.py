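"""File I/O glue: frame sources, reference-annotation JSON, track CSVs and
provenance records."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .catalog import ReferenceShape
from .shape_matching import Contour

FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


def load_frames(path: str | Path) -> list[np.ndarray]:
    """Load grayscale frames from a directory of numbered images
    (lexicographic order) or from a video container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video input not found: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in FRAME_EXTENSIONS)
        if not files:
            raise FileNotFoundError(f"no image frames in directory {path}")
        return [_to_gray(iio.imread(p)) for p in files]
    frames = iio.imread(path)  # video container via imageio plugins
    return [_to_gray(f) for f in frames]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return img.astype(float)


def save_frames(frames, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        iio.imwrite(out / f"frame_{i:06d}.png",
                    np.clip(np.asarray(f), 0, 255).astype(np.uint8))


def save_reference(path: str | Path, ref: ReferenceShape) -> None:
    data = {"points": ref.contour.points.tolist(),
            "landmarks": ref.landmark_indices}
    Path(path).write_text(json.dumps(data))


def load_reference(path: str | Path) -> ReferenceShape:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference annotation not found: {path}")
    data = json.loads(path.read_text())
    lm = data["landmarks"]
    return ReferenceShape(contour=Contour(np.asarray(data["points"], dtype=float)),
                          nose=int(lm["nose"]), tail_base=int(lm["tail_base"]),
                          ear_left=int(lm["ear_left"]),
                          ear_right=int(lm["ear_right"]))


def write_track_csv(record: pd.DataFrame, path: str | Path) -> None:
    record.to_csv(path, index=False, float_format="%.6g")


def read_track_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_provenance(path: str | Path, cfg, seed: int,
                     extra: dict | None = None) -> None:
    info = {"package": "mousetrack", "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__, "seed": seed,
            "config_hash": cfg.digest(), "config": cfg.to_dict()}
    info.update(extra or {})
    Path(path).write_text(json.dumps(info, indent=2, default=str))
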