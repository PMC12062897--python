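"""Thresholding, mask cleanup, and connected-component labeling.

The preprocessed brightfield image is thresholded into a binary foreground
mask (worms plus any debris dark enough to detect), small holes are filled
and isolated specks removed, and the cleaned mask is labeled into candidate
objects. The cleaned mask from this stage — *before* any shape or size
filtering — is what later defines the fluorescence background region, so
debris detected here never contaminates the background estimate.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_holes, remove_small_objects

log = logging.getLogger(__name__)


class LabeledComponents(NamedTuple):
    """Integer label image (0 = background, 1..n_objects = objects)."""

    labels: np.ndarray
    n_objects: int


def threshold_binary(
    img: np.ndarray,
    polarity: str = "dark_foreground",
    method: str = "otsu",
    fixed_t: float | None = None,
) -> np.ndarray:
    """Binarize a [0, 1] image; foreground is the worm side of the threshold.

    Otsu's criterion picks the threshold maximizing between-class variance
    of the intensity histogram. After illumination correction and blurring,
    worms read darker than the backlit background, hence the
    ``dark_foreground`` default; invert the polarity for other optics.
    A constant image has no defined threshold and yields an empty mask.
    """
    a = np.asarray(img, dtype=np.float64)
    if polarity not in ("dark_foreground", "bright_foreground"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if method == "fixed":
        if fixed_t is None:
            raise ValueError("fixed threshold method requires fixed_t")
        t = fixed_t
    elif method == "otsu":
        if np.ptp(a) == 0:
            log.warning("threshold_binary: constant image, returning empty mask")
            return np.zeros(a.shape, dtype=bool)
        # quantized images (8/16-bit data) get an exact histogram over their
        # distinct values so the threshold is not displaced by bin edges
        vals, counts = np.unique(a, return_counts=True)
        if vals.size <= 4096:
            t = threshold_otsu(hist=(counts, vals))
        else:
            t = threshold_otsu(a, nbins=256)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return a <= t if polarity == "dark_foreground" else a > t


def clean_mask(
    mask: np.ndarray, max_hole_area: int = 100, min_speck_area: int = 20
) -> np.ndarray:
    """Fill enclosed holes of area <= max_hole_area, then drop foreground
    specks of area < min_speck_area, in that order."""
    m = np.asarray(mask, dtype=bool)
    if max_hole_area > 0:
        m = remove_small_holes(m, max_size=int(max_hole_area))
    if min_speck_area > 1:
        # speck removal is strict (< min_speck_area), hence the -1
        m = remove_small_objects(m, max_size=int(min_speck_area) - 1)
    return m


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledComponents:
    """Connected-component labeling with deterministic raster-scan order.

    8-connectivity is the default: a worm's 1-px-wide diagonal sections must
    not fragment into separate objects.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = sk_label(
        np.asarray(mask, dtype=bool),
        connectivity=1 if connectivity == 4 else 2,
        return_num=True,
    )
    return LabeledComponents(labels=labels, n_objects=int(n))
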