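"""Per-worm fluorescence statistics and the step-2 background rule.

The kept worm masks are transferred unchanged onto the raw fluorescence
image (no preprocessing ever touches the measured channel). One background
is estimated per image as the mean fluorescence over every pixel *not*
thresholded as foreground at the cleanup stage — i.e. the complement of ALL
detected objects, including debris later rejected by the worminess and size
filters. Using that early mask is deliberate: debris is excluded from the
background even though it never appears in the measurements, so bright or
dark junk cannot bias the per-image background estimate.

Background-subtracted means may be negative and are reported as-is;
clamping at zero would bias condition means near background upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import RasterImage
from .segmentation import LabeledComponents
from .shape import ObjectShape

log = logging.getLogger(__name__)


class BackgroundError(ValueError):
    """No background pixels available (mask covers the whole image)."""


@dataclass(frozen=True)
class ImageBackground:
    pair_id: str
    background_fl: float
    n_background_px: int


@dataclass(frozen=True)
class WormMeasurement:
    """One kept worm: intensity statistics joined to geometry and provenance.

    ``worm_number`` matches the number drawn on the QC overlay. ``sd_fl`` is
    the population standard deviation (divide by n). ``mean_fl_bgsub`` is
    exactly ``mean_fl - background_fl``.
    """

    pair_id: str
    worm_number: int
    condition: str
    mean_fl: float
    sd_fl: float
    area: float
    perimeter: float
    worminess: float
    background_fl: float
    mean_fl_bgsub: float


def _pixels(img: RasterImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, RasterImage) else np.asarray(img)


def background_mean(
    fluor: RasterImage | np.ndarray, step2_mask: np.ndarray, pair_id: str = ""
) -> ImageBackground:
    """Mean raw fluorescence over the complement of the step-2 mask."""
    fl = _pixels(fluor)
    mask = np.asarray(step2_mask, dtype=bool)
    if fl.shape != mask.shape:
        raise ValueError(f"shape mismatch: fluor {fl.shape} vs mask {mask.shape}")
    bg_px = fl[~mask]
    if bg_px.size == 0:
        raise BackgroundError(
            f"{pair_id or 'image'}: mask covers every pixel, no background region"
        )
    return ImageBackground(
        pair_id=pair_id,
        background_fl=float(bg_px.mean()),
        n_background_px=int(bg_px.size),
    )


def measure_fluorescence(
    fluor: RasterImage | np.ndarray,
    kept: LabeledComponents,
    shapes: list[ObjectShape],
    bg: ImageBackground,
    condition: str = "",
) -> list[WormMeasurement]:
    """Mean/SD of raw fluorescence under each kept object's mask.

    ``worm_number`` is assigned 1..k in label order, the same numbering the
    overlay renders. Shapes whose labels are absent from the label image are
    an internal consistency error.
    """
    fl = _pixels(fluor)
    labels = kept.labels
    if fl.shape != labels.shape:
        raise ValueError(f"shape mismatch: fluor {fl.shape} vs labels {labels.shape}")
    out: list[WormMeasurement] = []
    for n, shape in enumerate(sorted(shapes, key=lambda s: s.label), start=1):
        px = fl[labels == shape.label]
        if px.size == 0:
            raise ValueError(f"label {shape.label} has no pixels in the label image")
        mean = float(px.mean())
        out.append(
            WormMeasurement(
                pair_id=bg.pair_id,
                worm_number=n,
                condition=condition,
                mean_fl=mean,
                sd_fl=float(px.std(ddof=0)),
                area=shape.area,
                perimeter=shape.perimeter,
                worminess=shape.worminess,
                background_fl=bg.background_fl,
                mean_fl_bgsub=mean - bg.background_fl,
            )
        )
    if not out:
        log.info("%s: no kept objects to measure", bg.pair_id or "image")
    return out


def minmax_scale(values) -> list[float]:
    """Rescale to [0, 1] via (v - min) / (max - min).

    Used to compare quantifications of the same image that are in different
    arbitrary units (e.g. manual tracing vs automated masks).
    """
    v = np.asarray(list(values), dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values to min-max scale")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("constant values cannot be min-max scaled")
    return list((v - lo) / (hi - lo))
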