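"""The per-image pipeline and the batch driver.

``run_image`` executes the fixed stage order:

    preprocess -> threshold -> clean -> label -> measure_shapes
    -> filter_worminess -> filter_size -> background_mean (step-2 mask)
    -> measure_fluorescence -> render_overlay

``run_batch`` maps that over every brightfield/fluorescence pair in a
folder, joins condition labels from the key file, and writes the combined
outputs. A failing image is logged and skipped — one corrupt file must not
abort a large acquisition — and is reflected in a nonzero exit status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import PipelineConfig
from .preprocess import preprocess_brightfield
from .quantify import ImageBackground, WormMeasurement, background_mean, measure_fluorescence
from .report import OverlayStyle, render_overlay, write_outputs
from .segmentation import LabeledComponents, clean_mask, label_components, threshold_binary
from .shape import ObjectShape, filter_size, filter_worminess, measure_shapes

log = logging.getLogger(__name__)

#: canonical stage order, recorded by ImageResult for conformance checks
STAGES = (
    "preprocess",
    "threshold",
    "clean",
    "label",
    "measure_shapes",
    "filter_worminess",
    "filter_size",
    "background_mean",
    "measure_fluorescence",
    "render_overlay",
)


@dataclass
class ImageResult:
    """Everything one field of view produces."""

    pair_id: str
    measurements: list[WormMeasurement]
    background: ImageBackground
    overlay: np.ndarray
    sidecar: dict
    shape_table: pd.DataFrame
    kept: LabeledComponents
    step2_mask: np.ndarray
    stage_log: tuple[str, ...] = STAGES


@dataclass
class BatchReport:
    processed: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    n_kept: int = 0
    n_removed_worminess: int = 0
    n_removed_size: int = 0
    written: list = field(default_factory=list)

    @property
    def exit_status(self) -> int:
        return 1 if self.failed else 0


def _shape_table(
    pair_id: str,
    shapes: list[ObjectShape],
    kept: list[ObjectShape],
    removed_worm: list[ObjectShape],
    removed_size: list[ObjectShape],
) -> pd.DataFrame:
    status = {s.label: "kept" for s in kept}
    status.update({s.label: "removed_worminess" for s in removed_worm})
    status.update({s.label: "removed_size" for s in removed_size})
    number = {s.label: n for n, s in enumerate(sorted(kept, key=lambda s: s.label), 1)}
    rows = [
        {
            "pair_id": pair_id,
            "worm_number": number.get(s.label, 0),
            "area_px": s.area,
            "perimeter_px": s.perimeter,
            "worminess": s.worminess,
            "touches_border": s.touches_border,
            "filter_status": status[s.label],
        }
        for s in shapes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "worm_number",
            "area_px",
            "perimeter_px",
            "worminess",
            "touches_border",
            "filter_status",
        ],
    )


def run_image(pair: fio.ImagePairRecord, cfg: PipelineConfig) -> ImageResult:
    """Run the full pipeline on one brightfield/fluorescence pair."""
    bf = fio.load_image(pair.brightfield_path, rgb_channel=cfg.rgb_channel)
    fl = fio.load_image(pair.fluorescence_path, rgb_channel=cfg.rgb_channel)
    if bf.pixels.shape != fl.pixels.shape:
        raise ValueError(
            f"{pair.pair_id}: brightfield {bf.pixels.shape} and fluorescence "
            f"{fl.pixels.shape} dimensions differ"
        )

    prepped = preprocess_brightfield(bf, cfg.preprocess)
    raw_mask = threshold_binary(
        prepped, polarity=cfg.polarity, method=cfg.threshold_method,
        fixed_t=cfg.fixed_threshold,
    )
    step2 = clean_mask(raw_mask, cfg.max_hole_area, cfg.min_speck_area)
    components = label_components(step2, cfg.connectivity)
    shapes = measure_shapes(components)
    if cfg.exclude_border:
        shapes = [s for s in shapes if not s.touches_border]
    kept_w, removed_w = filter_worminess(shapes, cfg.band)
    kept_final, removed_s = filter_size(kept_w, cfg.band.min_area, cfg.band.max_area)
    for s in removed_w:
        log.debug("%s: label %d removed by worminess (%.3f)", pair.pair_id, s.label, s.worminess)
    for s in removed_s:
        log.debug("%s: label %d removed by size (%.0f px)", pair.pair_id, s.label, s.area)

    kept_labels = {s.label for s in kept_final}
    kept_img = np.where(np.isin(components.labels, sorted(kept_labels)), components.labels, 0)
    kept = LabeledComponents(labels=kept_img, n_objects=len(kept_labels))

    bg = background_mean(fl, step2, pair_id=pair.pair_id)
    measurements = measure_fluorescence(fl, kept, kept_final, bg, condition=pair.condition)
    if not measurements:
        log.warning("%s: no worms detected", pair.pair_id)

    overlay, sidecar = render_overlay(
        bf,
        kept,
        kept_final,
        OverlayStyle(),
        rejected=(removed_w + removed_s) if cfg.debug_overlays else None,
        all_labels=components.labels if cfg.debug_overlays else None,
    )
    table = _shape_table(pair.pair_id, shapes, kept_final, removed_w, removed_s)
    return ImageResult(
        pair_id=pair.pair_id,
        measurements=measurements,
        background=bg,
        overlay=overlay,
        sidecar=sidecar,
        shape_table=table,
        kept=kept,
        step2_mask=step2,
    )


def run_batch(cfg: PipelineConfig, write: bool = True) -> tuple[BatchReport, list[ImageResult]]:
    """Pair channels, join conditions, run every image, write combined outputs."""
    records, unmatched = fio.pair_channels(cfg.input_dir, cfg.bf_pattern, cfg.fl_pattern)
    if not records:
        raise FileNotFoundError(f"{cfg.input_dir}: no brightfield/fluorescence pairs found")
    if cfg.key_path:
        key = fio.read_condition_key(cfg.key_path)
        missing = [r.pair_id for r in records if r.pair_id not in key]
        if missing:
            log.warning("no condition for stems: %s", ", ".join(missing))
        records = [
            fio.ImagePairRecord(
                r.pair_id, r.brightfield_path, r.fluorescence_path,
                key.get(r.pair_id, ""),
            )
            for r in records
        ]
    else:
        log.info("no condition key supplied; condition column left empty")

    report = BatchReport()
    results: list[ImageResult] = []
    for rec in records:
        try:
            res = run_image(rec, cfg)
        except Exception as exc:  # noqa: BLE001 - any stage error fails this image only
            log.error("%s failed: %s", rec.pair_id, exc)
            report.failed[rec.pair_id] = str(exc)
            continue
        results.append(res)
        report.processed.append(rec.pair_id)
        counts = res.shape_table["filter_status"].value_counts()
        report.n_kept += int(counts.get("kept", 0))
        report.n_removed_worminess += int(counts.get("removed_worminess", 0))
        report.n_removed_size += int(counts.get("removed_size", 0))

    if write:
        files = {
            r.pair_id: (r.brightfield_path, r.fluorescence_path) for r in records
        }
        report.written = write_outputs(
            [m for r in results for m in r.measurements],
            [r.background for r in results],
            cfg.output_dir,
            overlays={r.pair_id: (r.overlay, r.sidecar) for r in results},
            files=files,
        )
        shapes = pd.concat(
            [r.shape_table for r in results], ignore_index=True
        ) if results else pd.DataFrame()
        spath = Path(cfg.output_dir) / "shapes.csv"
        shapes.to_csv(spath, index=False)
        report.written.append(spath)
    log.info(
        "batch done: %d processed, %d failed, %d worms kept "
        "(%d removed by worminess, %d by size); %d unmatched files",
        len(report.processed), len(report.failed), report.n_kept,
        report.n_removed_worminess, report.n_removed_size, len(unmatched),
    )
    return report, results
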