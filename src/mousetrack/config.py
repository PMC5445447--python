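"""Structured pipeline configuration with validation and YAML round-trips.

All tunables of the pipeline live in one nested structure with documented
defaults.  Unknown keys and type mismatches are rejected with the offending
key named, so a typo in a config file fails loudly instead of silently
running with defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessSection:
    b_min: int = 200            # minimum blob area, px^2
    r_S: int = 4                # tail-removal disc radius, px
    threshold: float | str = "auto"
    target_mean: float = 128.0


@dataclass
class MatchSection:
    n_points: int = 100         # contour samples per shape
    n_r: int = 5                # radial log-polar bins
    n_theta: int = 12           # angular bins


@dataclass
class CatalogSection:
    rho_max: float | None = None   # fixed cost gate; exclusive with c_v
    c_v: float | None = 0.5        # target acceptance ratio
    max_entries: int = 3000
    warmup_costs: int = 60         # cost samples collected before calibration


@dataclass
class AsmSection:
    m: float = 3.0              # coefficient clamp, multiples of sqrt(lambda)
    f_v: float = 0.98           # retained variance fraction
    N_max: int = 60             # fit iterations per animal per frame
    profile_k: int = 5          # profile half-length, samples
    search_l: int = 7           # profile search half-range, px


@dataclass
class TrackerSection:
    min_catalog: int = 50       # entries required before the ASM may train
    refresh_every: int = 500    # separated frames between model refreshes
    floor_factor: float = 0.4   # single-animal area floor vs median blob area
    crossing_factor: float = 1.2  # merged-blob area vs median single area
    overlap_margin: float = 2.0   # px; landmarks this close to overlap freeze


@dataclass
class BehaviorSection:
    # distance thresholds in body-length units (body length = median
    # nose-tail distance over separated frames)
    nose_nose: float = 0.25       # C1
    nose_tail: float = 0.25       # C2
    side_center: float = 0.6      # C3 center distance
    side_angle: float = 30.0      # C3 heading alignment window, deg
    follow_dist: float = 0.5      # C4 nose-behind-tail distance
    follow_angle: float = 45.0    # C4 heading difference window, deg
    follow_sustain_s: float = 0.5  # C4 minimum sustained time
    mating_overlap: float = 0.4   # C5 contour-overlap fraction
    mating_angle: float = 45.0    # C5 heading window, deg
    min_event_s: float = 0.2      # events shorter than this are dropped
    smooth_frames: int = 5        # majority-vote smoothing window


@dataclass
class EvaluationSection:
    literal_sum: bool = False   # use the summed (not mean) tracking error


@dataclass
class SynthSection:
    arena: int = 480
    n_frames: int = 200
    script: str = "separated_only"


@dataclass
class PipelineConfig:
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    match: MatchSection = field(default_factory=MatchSection)
    catalog: CatalogSection = field(default_factory=CatalogSection)
    asm: AsmSection = field(default_factory=AsmSection)
    tracker: TrackerSection = field(default_factory=TrackerSection)
    behavior: BehaviorSection = field(default_factory=BehaviorSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    synth: SynthSection = field(default_factory=SynthSection)
    seed: int = 0
    fps: float = 25.0

    def validate(self) -> "PipelineConfig":
        if self.preprocess.b_min <= 0:
            raise ConfigError("preprocess.b_min must be > 0")
        if self.preprocess.r_S < 1:
            raise ConfigError("preprocess.r_S must be >= 1")
        thr = self.preprocess.threshold
        if isinstance(thr, str) and thr != "auto":
            raise ConfigError("preprocess.threshold must be 'auto' or a number")
        if self.match.n_points < 8:
            raise ConfigError("match.n_points must be >= 8")
        cat = self.catalog
        if (cat.rho_max is None) == (cat.c_v is None):
            raise ConfigError("set exactly one of catalog.rho_max / catalog.c_v")
        if cat.c_v is not None and not (0.0 < cat.c_v < 1.0):
            raise ConfigError("catalog.c_v must be in (0, 1)")
        if not (0.0 < self.asm.f_v <= 1.0):
            raise ConfigError("asm.f_v must be in (0, 1]")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


_SECTIONS = {f.name: f for f in dataclasses.fields(PipelineConfig)
             if f.default_factory is not dataclasses.MISSING}


def _fill_section(cls, data: dict, prefix: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key: {prefix}{key}")
        f = known[key]
        default = f.default if f.default is not dataclasses.MISSING else None
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{prefix}{key} must be a boolean")
        elif isinstance(default, int) and not isinstance(default, bool):
            if isinstance(value, bool) or not isinstance(value, (int,)):
                raise ConfigError(f"{prefix}{key} must be an integer")
        elif isinstance(default, float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"{prefix}{key} must be a number")
            value = float(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for name, f in list(_SECTIONS.items()):
        if name in data:
            sec = data.pop(name)
            if sec is None:
                sec = {}
            if not isinstance(sec, dict):
                raise ConfigError(f"config section '{name}' must be a mapping")
            kwargs[name] = _fill_section(type(f.default_factory()), sec, f"{name}.")
    for scalar in ("seed", "fps"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigError(f"unknown config key: {sorted(data)[0]}")
    return PipelineConfig(**kwargs).validate()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig().validate()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping at top level")
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
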