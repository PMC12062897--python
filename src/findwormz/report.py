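"""QC overlay rendering and output tables.

Each kept worm is tinted with a palette color on top of the original
brightfield image and annotated with its worm number — the same number used
in the measurements table — so a user can visually confirm that every
recorded object is in fact a worm. A JSON sidecar per overlay stores the
number -> centroid -> color mapping so downstream tooling (and tests) never
have to OCR the rendered text.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .io import RasterImage
from .quantify import ImageBackground, WormMeasurement
from .segmentation import LabeledComponents
from .shape import ObjectShape

log = logging.getLogger(__name__)

# default palette: 10 well-separated hues (matplotlib "tab10" values)
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
)

REJECTED_COLOR: tuple[int, int, int] = (255, 0, 255)

MEASUREMENT_COLUMNS = [
    "pair_id",
    "worm_number",
    "condition",
    "mean_fl",
    "sd_fl",
    "area",
    "perimeter",
    "worminess",
    "background_fl",
    "mean_fl_bgsub",
    "brightfield_file",
    "fluorescence_file",
]


@dataclass(frozen=True)
class OverlayStyle:
    alpha: float = 0.5
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    font_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if len(self.palette) < 8:
            raise ValueError("palette must have at least 8 colors")


def _bf_to_rgb(bf: RasterImage | np.ndarray) -> np.ndarray:
    if isinstance(bf, RasterImage):
        a = (bf.normalized() * 255).round().astype(np.uint8)
    else:
        a = np.asarray(bf)
        if a.dtype != np.uint8:
            a = (np.clip(a, 0, 1) * 255).round().astype(np.uint8)
    return np.stack([a, a, a], axis=-1)


def render_overlay(
    bf: RasterImage | np.ndarray,
    kept: LabeledComponents,
    shapes: list[ObjectShape],
    style: OverlayStyle | None = None,
    rejected: list[ObjectShape] | None = None,
    all_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Render the color-coded QC image.

    Returns ``(rgb, sidecar)`` where *rgb* is an (H, W, 3) uint8 array and
    *sidecar* is the machine-readable worm_number -> centroid -> color map.
    Pixels outside kept (and optionally rejected-debug) objects are the
    unmodified brightfield. Colors cycle deterministically by worm number.
    """
    style = style or OverlayStyle()
    rgb = _bf_to_rgb(bf).astype(np.float64)
    labels = kept.labels
    sidecar: dict = {"worms": [], "palette_alpha": style.alpha}
    ordered = sorted(shapes, key=lambda s: s.label)
    for n, shape in enumerate(ordered, start=1):
        color = style.palette[(n - 1) % len(style.palette)]
        m = labels == shape.label
        rgb[m] = (1 - style.alpha) * rgb[m] + style.alpha * np.array(color, float)
        sidecar["worms"].append(
            {
                "worm_number": n,
                "centroid": [round(shape.centroid[0], 2), round(shape.centroid[1], 2)],
                "color": list(color),
            }
        )
    if rejected and all_labels is not None:
        for shape in rejected:
            m = all_labels == shape.label
            rgb[m] = (1 - style.alpha) * rgb[m] + style.alpha * np.array(
                REJECTED_COLOR, float
            )
    out = Image.fromarray(rgb.round().astype(np.uint8))
    draw = ImageDraw.Draw(out)
    for entry in sidecar["worms"]:
        r, c = entry["centroid"]
        draw.text((c, r), str(entry["worm_number"]), fill=(255, 255, 255))
    return np.asarray(out), sidecar


def measurements_frame(
    measurements: list[WormMeasurement],
    files: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate measurements with deterministic (pair_id, worm_number) order."""
    rows = []
    for m in measurements:
        row = asdict(m)
        bf_file, fl_file = (files or {}).get(m.pair_id, ("", ""))
        row["brightfield_file"] = bf_file
        row["fluorescence_file"] = fl_file
        rows.append(row)
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df.sort_values(["pair_id", "worm_number"], kind="stable").reset_index(
        drop=True
    )


def backgrounds_frame(backgrounds: list[ImageBackground]) -> pd.DataFrame:
    df = pd.DataFrame(
        [asdict(b) for b in backgrounds],
        columns=["pair_id", "background_fl", "n_background_px"],
    )
    return df.sort_values("pair_id", kind="stable").reset_index(drop=True)


def write_outputs(
    measurements: list[WormMeasurement],
    backgrounds: list[ImageBackground],
    out_dir: str | Path,
    overlays: dict[str, tuple[np.ndarray, dict]] | None = None,
    files: dict[str, tuple[str, str]] | None = None,
) -> list[Path]:
    """Write measurements.csv, backgrounds.csv, and per-image overlay
    PNG + JSON sidecars; returns every path written.

    The writability of ``out_dir`` is probed before anything is written so
    an I/O failure cannot leave a partial combined CSV behind.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")
    written: list[Path] = []
    mpath = out_dir / "measurements.csv"
    measurements_frame(measurements, files).to_csv(mpath, index=False)
    written.append(mpath)
    bpath = out_dir / "backgrounds.csv"
    backgrounds_frame(backgrounds).to_csv(bpath, index=False)
    written.append(bpath)
    for pair_id, (rgb, sidecar) in (overlays or {}).items():
        opath = out_dir / f"{pair_id}_overlay.png"
        Image.fromarray(rgb).save(opath)
        written.append(opath)
        spath = out_dir / f"{pair_id}_overlay.json"
        spath.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        written.append(spath)
    return written
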