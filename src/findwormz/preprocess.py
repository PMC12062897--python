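"""Brightfield preparation: contrast stretch, illumination flattening, blur.

Worms are transparent, so transmitted light leaves very light and very dark
patches inside the same animal; a slight blur evens these out enough that a
single global threshold separates worm from background. The fixed stage
order is contrast -> illumination -> blur. All stages operate on (and
return) float arrays on the [0, 1] working scale; the raw fluorescence
channel is never preprocessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import RasterImage

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables for the three brightfield stages.

    ``illum_sigma`` must be much larger than ``blur_sigma``: illumination
    varies slowly across the field while worm texture varies fast. When
    ``illum_sigma`` is None it defaults to 1/8 of the image's shorter side.
    """

    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    illum_sigma: float | None = None
    illum_mode: str = "divide"  # brightfield shading is multiplicative
    blur_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.contrast_low_pct < 50:
            raise ValueError("contrast_low_pct must be in [0, 50)")
        if not 50 < self.contrast_high_pct <= 100:
            raise ValueError("contrast_high_pct must be in (50, 100]")
        if self.illum_mode not in ("divide", "subtract"):
            raise ValueError("illum_mode must be 'divide' or 'subtract'")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def _as_float01(img: RasterImage | np.ndarray) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.normalized()
    return np.asarray(img, dtype=np.float64)


def enhance_contrast(
    img: RasterImage | np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Percentile stretch onto [0, 1], clipping beyond the percentiles.

    A constant image has equal percentiles and is returned unchanged (on the
    [0, 1] scale) with a warning.
    """
    a = _as_float01(img)
    lo, hi = np.percentile(a, [low_pct, high_pct])
    if hi <= lo:
        log.warning("enhance_contrast: constant image, returning unchanged")
        return a.copy()
    return np.clip((a - lo) / (hi - lo), 0.0, 1.0)


def correct_illumination(
    img: np.ndarray, illum_sigma: float | None = None, mode: str = "divide"
) -> np.ndarray:
    """Flatten slowly varying background lighting.

    The background estimate is a very wide Gaussian smoothing of the image
    itself. Division is the default because shading in transmitted light is
    multiplicative; ``mode='subtract'`` is available for additive offsets.
    The output is renormalized so its median equals the input's, then
    clipped to [0, 1].
    """
    a = np.asarray(img, dtype=np.float64)
    if illum_sigma is None:
        illum_sigma = min(a.shape) / 8.0
    bg = ndimage.gaussian_filter(a, sigma=illum_sigma, mode="reflect")
    if mode == "divide":
        n_small = int(np.sum(bg < _EPS))
        if n_small:
            log.warning("correct_illumination: %d near-zero background pixels", n_small)
        out = a / np.maximum(bg, _EPS)
    else:
        out = a - bg
    med_in, med_out = np.median(a), np.median(out)
    if abs(med_out) > _EPS:
        out = out * (med_in / med_out) if mode == "divide" else out + (med_in - med_out)
    else:
        out = out + med_in
    return np.clip(out, 0.0, 1.0)


def blur(img: np.ndarray, blur_sigma: float = 2.0) -> np.ndarray:
    """Slight Gaussian smoothing; sigma 0 is the identity.

    Reflective border padding avoids dark rims that would otherwise create
    spurious objects along the image edge.
    """
    a = np.asarray(img, dtype=np.float64)
    if blur_sigma == 0:
        return a.copy()
    return ndimage.gaussian_filter(a, sigma=blur_sigma, mode="reflect")


def preprocess_brightfield(
    img: RasterImage | np.ndarray, params: PreprocessParams | None = None
) -> np.ndarray:
    """Full brightfield pipeline in the fixed order contrast -> illumination -> blur."""
    p = params or PreprocessParams()
    a = enhance_contrast(img, p.contrast_low_pct, p.contrast_high_pct)
    a = correct_illumination(a, p.illum_sigma, p.illum_mode)
    return blur(a, p.blur_sigma)
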