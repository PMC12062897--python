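"""Pipeline configuration: defaults, validation, YAML loading.

The whole method is driven by a small number of adjustable parameters; the
only required setting is the input directory. Unknown keys are rejected so
a typo like ``wormness_lo`` fails loudly instead of silently using the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .io import DEFAULT_BF_PATTERN, DEFAULT_FL_PATTERN
from .preprocess import PreprocessParams
from .shape import FilterBand


class ConfigError(ValueError):
    """Invalid, missing, or unknown configuration keys."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted batch configuration."""

    input_dir: str
    output_dir: str = "findwormz_out"
    key_path: str | None = None
    bf_pattern: str = DEFAULT_BF_PATTERN
    fl_pattern: str = DEFAULT_FL_PATTERN
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    polarity: str = "dark_foreground"
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    max_hole_area: int = 100
    min_speck_area: int = 20
    connectivity: int = 8
    band: FilterBand = field(default_factory=FilterBand)
    exclude_border: bool = False
    debug_overlays: bool = False
    rgb_channel: int | None = None
    seed: int = 0


# flat keys accepted by validate_config, mapping onto nested dataclasses
_PREPROCESS_KEYS = {
    "contrast_low_pct",
    "contrast_high_pct",
    "illum_sigma",
    "illum_mode",
    "blur_sigma",
}
_BAND_KEYS = {"worminess_lo", "worminess_hi", "min_area", "max_area"}
_TOP_KEYS = {
    "input_dir",
    "output_dir",
    "key_path",
    "bf_pattern",
    "fl_pattern",
    "polarity",
    "threshold_method",
    "fixed_threshold",
    "max_hole_area",
    "min_speck_area",
    "connectivity",
    "exclude_border",
    "debug_overlays",
    "rgb_channel",
    "seed",
}


def validate_config(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat mapping.

    Every unset field takes its documented default; unknown keys raise
    :class:`ConfigError`.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS - _PREPROCESS_KEYS - _BAND_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "input_dir" not in raw or not raw["input_dir"]:
        raise ConfigError("input_dir is required")
    try:
        pre = PreprocessParams(**{k: raw.pop(k) for k in list(raw) if k in _PREPROCESS_KEYS})
        band = FilterBand(**{k: raw.pop(k) for k in list(raw) if k in _BAND_KEYS})
        cfg = PipelineConfig(preprocess=pre, band=band, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.polarity not in ("dark_foreground", "bright_foreground"):
        raise ConfigError(f"invalid polarity {cfg.polarity!r}")
    if cfg.threshold_method not in ("otsu", "fixed"):
        raise ConfigError(f"invalid threshold_method {cfg.threshold_method!r}")
    if cfg.threshold_method == "fixed" and cfg.fixed_threshold is None:
        raise ConfigError("threshold_method 'fixed' requires fixed_threshold")
    if cfg.connectivity not in (4, 8):
        raise ConfigError("connectivity must be 4 or 8")
    return cfg


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Read a YAML config file and apply CLI overrides on top of it."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in (overrides or {}).items() if v is not None})
    return validate_config(raw)
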