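"""Synthetic ground-truth plates: worm-shaped tubes, debris, specks.

The generator emulates what the pipeline consumes in practice: a
brightfield image of dark, elongated, gently curved animals on a brighter
background with a multiplicative illumination ramp and sensor noise, paired
with a fluorescence image carrying a planted background level and a planted
per-worm mean intensity. Worms are placed pairwise non-touching (default
12 px clearance, comfortably past the blur kernel's bridging distance),
matching the method's requirement that animals be pushed apart before
imaging. Round debris (worminess near the 0.89 circle floor, well
below the 1.5 acceptance bound) and sub-threshold specks exercise the two
filters; debris is non-fluorescent by default so background-estimation
tests isolate the step-2 mask rule.

Every random draw flows from the single integer seed in the spec through a
named ``numpy.random.Generator``; the same spec yields bit-identical
images.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .io import RasterImage, save_image
from .quantify import WormMeasurement
from .segmentation import LabeledComponents
from .shape import measure_shapes

log = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Could not place all worms without touching; use fewer/smaller worms."""


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Full parameterization of one generated field of view.

    Defaults emulate a 16-bit acquisition of adult worms at the method's
    working magnification: tubes of length 120 px and width 10-15 px
    (aspect 8-12, inside the default worminess band), a bright background
    with a 0.85-1.15 multiplicative illumination ramp, and fluorescence
    noise at about 1% of the 16-bit dynamic range.
    """

    image_size: tuple[int, int] = (700, 900)
    n_worms: int = 20
    worm_length: float = 120.0
    worm_width: tuple[float, float] = (10.0, 15.0)
    curvature: float = 0.2
    conditions: tuple[tuple[str, float], ...] = (("ctrl", 8000.0),)
    background_fl: float = 1000.0
    noise_sd: float = 300.0
    illumination_gradient: tuple[float, float] = (0.85, 1.15)
    n_round_debris: int = 2
    debris_radius: float = 22.0
    debris_fl: float = 0.0  # debris occludes the background glow
    n_specks: int = 3
    #: minimum clearance between planted objects; must exceed the blur
    #: kernel's bridging distance or "pushed apart" worms would re-merge
    #: into single components during segmentation
    min_gap_px: int = 12
    mottled: bool = False
    fluorescent_debris: bool = False
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.worm_width
        for w in (lo, hi):
            aspect = self.worm_length / w
            if not 6 <= aspect <= 14:
                raise ValueError(
                    f"worm length/width aspect {aspect:.1f} outside [6, 14]; "
                    "planted shapes must fall in the default worminess band"
                )


@dataclass
class GroundTruth:
    """What was actually planted: the answer key for evaluation."""

    labels: np.ndarray  # planted worm label image (1..n_worms)
    worm_mean_fl: dict[int, float]  # planted fluorescence mean per worm id
    worm_condition: dict[int, str]
    background_fl: float
    debris_mask: np.ndarray

    @property
    def n_worms(self) -> int:
        return len(self.worm_mean_fl)


@dataclass(frozen=True)
class DetectionScore:
    n_true: int
    n_detected: int
    iou_per_worm: tuple[float, ...]
    recall: float
    precision: float
    intensity_rmse: float
    precision_undefined: bool = False


def generate_worm_mask(
    length: float, width: float, curvature: float, seed: int
) -> np.ndarray:
    """Rasterize one worm: a filled tube of the given width around a smooth
    sinusoidally bent midline of the given arc length.

    The bend amplitude is drawn uniformly in [0, curvature * length]. The
    resulting shape is a (possibly bent) capsule whose worminess follows
    the closed-form straight-capsule value
    ``(2L + pi*w - 2w) / (4*sqrt(L*w - w^2 + pi*w^2/4))`` to within
    discretization error.
    """
    if not length > width >= 3:
        raise ValueError(f"need length > width >= 3, got {length}, {width}")
    rng = np.random.default_rng(seed)
    amp = curvature * length * rng.uniform()
    phase = rng.uniform(0, math.pi)

    def midline(Lx: float, n: int = 4000) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(0.0, Lx, n)
        y = amp * np.sin(np.pi * x / Lx + phase) if amp > 0 else np.zeros_like(x)
        return x, y

    if amp > 0:
        def arclen_err(Lx: float) -> float:
            x, y = midline(Lx)
            return float(np.hypot(np.diff(x), np.diff(y)).sum()) - length

        Lx = brentq(arclen_err, length * 0.25, length * 1.001, xtol=1e-3)
    else:
        Lx = length
    x, y = midline(Lx)
    pad = int(width) + 4
    h = int(math.ceil(y.max() - y.min() + width)) + 2 * pad
    w = int(math.ceil(Lx + width)) + 2 * pad
    grid = np.zeros((h, w), dtype=bool)
    rows = np.round(y - y.min() + pad).astype(int)
    cols = np.round(x + pad).astype(int)
    grid[rows, cols] = True
    dist = ndimage.distance_transform_edt(~grid)
    mask = dist <= width / 2.0
    # trim to the tight bounding box of the tube
    rs, cs = np.nonzero(mask)
    return mask[rs.min() : rs.max() + 1, cs.min() : cs.max() + 1]


def _place(
    canvas_labels: np.ndarray,
    occupied_dilated: np.ndarray,
    mask: np.ndarray,
    value: int,
    rng: np.random.Generator,
    gap: int = 3,
    max_tries: int = 300,
) -> bool:
    """Drop ``mask`` at a random rotation/position keeping >= gap px clearance."""
    H, W = canvas_labels.shape
    struct = ndimage.iterate_structure(ndimage.generate_binary_structure(2, 2), gap)
    for _ in range(max_tries):
        angle = rng.uniform(0, 180)
        rot = ndimage.rotate(mask, angle, order=0, reshape=True)
        rs, cs = np.nonzero(rot)
        if rs.size == 0:
            continue
        rot = rot[rs.min() : rs.max() + 1, cs.min() : cs.max() + 1]
        mh, mw = rot.shape
        if mh >= H - 2 or mw >= W - 2:
            continue
        r0 = rng.integers(1, H - mh - 1)
        c0 = rng.integers(1, W - mw - 1)
        region = occupied_dilated[r0 : r0 + mh, c0 : c0 + mw]
        if np.any(region & rot):
            continue
        canvas_labels[r0 : r0 + mh, c0 : c0 + mw][rot] = value
        # dilate on a gap-padded canvas so the clearance margin is not
        # clipped at the object's own bounding box
        padded = np.zeros((mh + 2 * gap, mw + 2 * gap), dtype=bool)
        padded[gap : gap + mh, gap : gap + mw] = rot
        grown = ndimage.binary_dilation(padded, structure=struct)
        pr0, pc0 = max(r0 - gap, 0), max(c0 - gap, 0)
        pr1, pc1 = min(r0 + mh + gap, H), min(c0 + mw + gap, W)
        occupied_dilated[pr0:pr1, pc0:pc1] |= grown[
            pr0 - (r0 - gap) : pr1 - (r0 - gap), pc0 - (c0 - gap) : pc1 - (c0 - gap)
        ]
        return True
    return False


def generate_plate(
    spec: SyntheticPlateSpec,
) -> tuple[RasterImage, RasterImage, GroundTruth]:
    """Render a brightfield/fluorescence pair plus its ground truth.

    Brightfield: bright background x illumination ramp with worms, debris
    and specks rendered darker, plus Gaussian noise. Fluorescence: planted
    background everywhere, planted per-worm means on worm pixels, debris
    dark unless ``fluorescent_debris``, plus Gaussian noise of ``noise_sd``.
    """
    # placement and noise use separate streams so adding debris or specks
    # never perturbs worm positions or the noise fields
    rng = np.random.default_rng([spec.seed, 1])
    noise_rng = np.random.default_rng([spec.seed, 2])
    H, W = spec.image_size
    labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)
    debris_canvas = np.zeros((H, W), dtype=np.int32)
    speck_canvas = np.zeros((H, W), dtype=np.int32)

    worm_mean: dict[int, float] = {}
    worm_cond: dict[int, str] = {}
    conditions = list(spec.conditions)
    for i in range(spec.n_worms):
        width = rng.uniform(*spec.worm_width)
        mask = generate_worm_mask(
            spec.worm_length, width, spec.curvature, seed=int(rng.integers(2**31 - 1))
        )
        if not _place(labels, occupied, mask, i + 1, rng, gap=spec.min_gap_px):
            raise PlacementError(
                f"could not place worm {i + 1}/{spec.n_worms}; "
                "reduce n_worms or worm_length"
            )
        label_name, mean_fl = conditions[i % len(conditions)]
        worm_mean[i + 1] = float(mean_fl)
        worm_cond[i + 1] = label_name

    for j in range(spec.n_round_debris):
        r = spec.debris_radius
        d = int(2 * r + 3)
        yy, xx = np.mgrid[0:d, 0:d]
        disk = (yy - d / 2) ** 2 + (xx - d / 2) ** 2 <= r**2
        if not _place(debris_canvas, occupied, disk, j + 1, rng, gap=spec.min_gap_px):
            log.warning("could not place debris %d; skipping", j + 1)
    for k in range(spec.n_specks):
        speck = np.ones((2, 2), dtype=bool)
        if not _place(speck_canvas, occupied, speck, k + 1, rng, gap=spec.min_gap_px):
            log.warning("could not place speck %d; skipping", k + 1)

    hi = 2**spec.bit_depth - 1
    # brightfield on [0,1] then quantized
    g0, g1 = spec.illumination_gradient
    ramp = np.linspace(g0, g1, W)[None, :] * np.ones((H, 1))
    bf = 0.80 * np.ones((H, W))
    worm_px = labels > 0
    bf[worm_px] = 0.35
    if spec.mottled:
        # light/dark patches inside each animal, emulating transparency
        mottle = 0.25 * np.sin(np.linspace(0, 40 * np.pi, W))
        bf[worm_px] = np.clip(0.35 + mottle[np.nonzero(worm_px)[1]], 0.05, 0.75)
    bf[debris_canvas > 0] = 0.30
    bf[speck_canvas > 0] = 0.30
    bf = bf * ramp + noise_rng.normal(0, 0.01, (H, W))
    bf_img = RasterImage(
        np.clip(bf * hi, 0, hi).round().astype(np.uint16 if spec.bit_depth == 16 else np.uint8),
        bit_depth=spec.bit_depth,
    )

    fl = np.full((H, W), spec.background_fl, dtype=np.float64)
    for wid, mean_fl in worm_mean.items():
        fl[labels == wid] = mean_fl
    fl[debris_canvas > 0] = (
        spec.background_fl * 5 if spec.fluorescent_debris else spec.debris_fl
    )
    if spec.noise_sd > 0:
        fl += noise_rng.normal(0, spec.noise_sd, (H, W))
    fl_img = RasterImage(
        np.clip(fl, 0, hi).round().astype(np.uint16 if spec.bit_depth == 16 else np.uint8),
        bit_depth=spec.bit_depth,
    )
    truth = GroundTruth(
        labels=labels,
        worm_mean_fl=worm_mean,
        worm_condition=worm_cond,
        background_fl=spec.background_fl,
        debris_mask=debris_canvas > 0,
    )
    return bf_img, fl_img, truth


def evaluate_detection(
    kept: LabeledComponents,
    measurements: list[WormMeasurement],
    truth: GroundTruth,
    iou_threshold: float = 0.6,
) -> DetectionScore:
    """Score detections against the planted worms.

    Greedy one-to-one matching by descending IoU; a match counts when
    IoU >= iou_threshold. Intensity RMSE compares each matched worm's
    background-subtracted mean against (planted mean - planted background).
    With zero detections precision is undefined and reported as 0 with the
    ``precision_undefined`` flag set.
    """
    det_labels = sorted(set(np.unique(kept.labels)) - {0})
    true_ids = sorted(truth.worm_mean_fl)
    pairs = []
    for d in det_labels:
        dm = kept.labels == d
        for t in true_ids:
            tm = truth.labels == t
            inter = np.count_nonzero(dm & tm)
            if inter == 0:
                continue
            union = np.count_nonzero(dm | tm)
            pairs.append((inter / union, d, t))
    pairs.sort(reverse=True)
    matched_d: dict[int, int] = {}
    matched_t: set[int] = set()
    ious: dict[int, float] = {}
    for iou, d, t in pairs:
        if d in matched_d or t in matched_t or iou < iou_threshold:
            continue
        matched_d[d] = t
        matched_t.add(t)
        ious[t] = iou
    n_true, n_det, n_match = len(true_ids), len(det_labels), len(matched_d)
    meas_by_label = {}
    for n, d in enumerate(det_labels, start=1):
        meas_by_label[d] = next((m for m in measurements if m.worm_number == n), None)
    errs = []
    for d, t in matched_d.items():
        m = meas_by_label.get(d)
        if m is not None:
            planted = truth.worm_mean_fl[t] - truth.background_fl
            errs.append(m.mean_fl_bgsub - planted)
    return DetectionScore(
        n_true=n_true,
        n_detected=n_det,
        iou_per_worm=tuple(ious.get(t, 0.0) for t in true_ids),
        recall=(n_match / n_true) if n_true else 1.0,
        precision=(n_match / n_det) if n_det else 0.0,
        intensity_rmse=float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan"),
        precision_undefined=(n_det == 0),
    )


def worm_mask_suite(
    n: int = 50,
    first_seed: int = 1,
    length: float = 120.0,
    width_range: tuple[float, float] = (10.0, 15.0),
    curvature: float = 0.2,
) -> list[float]:
    """Worminess scores of ``n`` seeded synthetic worm masks.

    Per seed, a tube width is drawn uniformly from ``width_range`` (aspect
    8-12 at the default length) and the mask's worminess is measured with
    the pipeline's own estimator — the calibration suite for the default
    acceptance band.
    """
    scores: list[float] = []
    for seed in range(first_seed, first_seed + n):
        rng = np.random.default_rng([seed, 3])
        width = float(rng.uniform(*width_range))
        mask = generate_worm_mask(length, width, curvature, seed=seed)
        (s,) = measure_shapes(LabeledComponents((mask).astype(np.int32), 1))
        scores.append(s.worminess)
    return scores


def write_plate_folder(
    out_dir: str | Path,
    n_images: int = 1,
    spec: SyntheticPlateSpec | None = None,
    seed: int = 0,
) -> Path:
    """Write a ready-to-run input folder: BF/Fl TIFF pairs, key.csv, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = spec or SyntheticPlateSpec()
    key_rows = ["filename,condition"]
    truth_meta = {}
    for i in range(n_images):
        # one condition per image, cycling through the spec's condition list
        cond, mean_fl = base.conditions[i % len(base.conditions)]
        s = SyntheticPlateSpec(**{**asdict(base), "seed": seed + i,
                                  "conditions": ((cond, mean_fl),)})
        bf, fl, truth = generate_plate(s)
        stem = f"plate{i + 1:02d}"
        save_image(bf, out / f"{stem}_BF.tif")
        save_image(fl, out / f"{stem}_Fl.tif")
        key_rows.append(f"{stem},{cond}")
        truth_meta[stem] = {
            "n_worms": truth.n_worms,
            "background_fl": truth.background_fl,
            "worm_mean_fl": {str(k): v for k, v in truth.worm_mean_fl.items()},
        }
    (out / "key.csv").write_text("\n".join(key_rows) + "\n")
    (out / "truth.json").write_text(json.dumps(truth_meta, indent=2, sort_keys=True))
    return out
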