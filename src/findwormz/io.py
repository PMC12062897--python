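"""Raster image I/O, channel pairing, and the condition-key table.

Images are single-channel grayscale TIFF or PNG at 8 or 16 bit. A field of
view is a *pair* of files — one brightfield (used only to locate worms) and
one fluorescence (the measured channel) — matched by a shared filename stem
after stripping a channel suffix such as ``_BF`` / ``_Fl``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

log = logging.getLogger(__name__)

#: default channel-suffix patterns; a stem is the filename with the matched
#: suffix removed (case-insensitive)
DEFAULT_BF_PATTERN = r"(?i)^(?P<stem>.+?)_bf$"
DEFAULT_FL_PATTERN = r"(?i)^(?P<stem>.+?)_fl$"


class ImageFormatError(ValueError):
    """Unsupported layout (multi-channel without a selection rule, bad dtype)."""


class PairingError(ValueError):
    """Ambiguous brightfield/fluorescence file matching."""


class ConditionKeyError(ValueError):
    """Malformed or self-contradictory condition-key table."""


@dataclass(frozen=True)
class RasterImage:
    """A single-channel intensity image with its native bit depth.

    ``pixels`` keeps the raw integer intensities exactly as stored on disk;
    nothing in the reader rescales them.
    """

    pixels: np.ndarray
    bit_depth: int
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ImageFormatError(
                f"expected a single-channel 2-D image, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1 pixels")
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        hi = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > hi:
            raise ImageFormatError(
                f"intensities outside [0, {hi}] for bit depth {self.bit_depth}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Float copy on the [0, 1] working scale used by preprocessing."""
        return self.pixels.astype(np.float64) / self.max_value


@dataclass(frozen=True)
class ImagePairRecord:
    """One field of view: a brightfield file, its fluorescence partner, and
    the experimental condition (empty when no key entry exists)."""

    pair_id: str
    brightfield_path: str
    fluorescence_path: str
    condition: str = ""


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    # Some writers store 8-bit data as signed or wider ints; accept if in range.
    if np.issubdtype(arr.dtype, np.integer):
        lo, hi = int(arr.min()), int(arr.max())
        if 0 <= lo and hi <= 255:
            return 8
        if 0 <= lo and hi <= 65535:
            return 16
    raise ImageFormatError(f"{path}: unsupported pixel dtype {arr.dtype}")


def load_image(path: str | Path, rgb_channel: int | None = None) -> RasterImage:
    """Read a grayscale TIFF or PNG preserving its native bit depth.

    Parameters
    ----------
    path
        File to read; suffix decides the decoder (.tif/.tiff vs .png).
    rgb_channel
        Index of the channel to extract from a multi-channel file. By
        default multi-channel input is rejected rather than silently
        averaged, since collapsing channels could mix fluorescence signals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder-specific errors vary
        raise ImageFormatError(f"{path}: cannot decode image ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if rgb_channel is None:
            raise ImageFormatError(
                f"{path}: multi-channel image; set rgb_channel to select one plane"
            )
        arr = arr[..., rgb_channel]
    elif arr.ndim != 2:
        raise ImageFormatError(f"{path}: unsupported dimensionality {arr.ndim}")
    depth = _bit_depth_of(arr, path)
    dtype = np.uint8 if depth == 8 else np.uint16
    return RasterImage(arr.astype(dtype), bit_depth=depth, source_path=str(path))


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write back at native bit depth; round-trips pixel values exactly."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    data = img.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def _match_stem(name: str, pattern: str) -> str | None:
    m = re.match(pattern, name)
    if not m:
        return None
    if "stem" in m.groupdict():
        return m.group("stem")
    return m.group(1) if m.groups() else name


def pair_channels(
    directory: str | Path,
    bf_pattern: str = DEFAULT_BF_PATTERN,
    fl_pattern: str = DEFAULT_FL_PATTERN,
) -> tuple[list[ImagePairRecord], list[str]]:
    """Match brightfield to fluorescence files by shared stem.

    Returns ``(records, unmatched)`` where *unmatched* lists files that
    matched a channel pattern but have no partner; they are reported, never
    silently dropped. Records are sorted by stem for determinism.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    bf: dict[str, list[Path]] = {}
    fl: dict[str, list[Path]] = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        s = _match_stem(p.stem, bf_pattern)
        if s is not None:
            bf.setdefault(s, []).append(p)
            continue
        s = _match_stem(p.stem, fl_pattern)
        if s is not None:
            fl.setdefault(s, []).append(p)
    for stem, cands in list(bf.items()) + list(fl.items()):
        if len(cands) > 1:
            raise PairingError(
                f"stem {stem!r} matches multiple files: "
                + ", ".join(c.name for c in cands)
            )
    records = []
    unmatched = []
    for stem in sorted(set(bf) | set(fl)):
        if stem in bf and stem in fl:
            records.append(
                ImagePairRecord(
                    pair_id=stem,
                    brightfield_path=str(bf[stem][0]),
                    fluorescence_path=str(fl[stem][0]),
                )
            )
        else:
            missing = bf.get(stem, fl.get(stem))[0]
            unmatched.append(missing.name)
            log.warning("unmatched channel file: %s", missing.name)
    return records, unmatched


def read_condition_key(path: str | Path) -> dict[str, str]:
    """Parse the CSV mapping filename stems to condition labels.

    Expects a header row with ``filename`` and ``condition`` columns.
    Stems are normalized by stripping a trailing channel suffix so users may
    list either the pair stem or a full channel filename.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    cols = {c.lower().strip(): c for c in df.columns}
    if "filename" not in cols or "condition" not in cols:
        raise ConditionKeyError(
            f"{path}: need 'filename' and 'condition' columns, found {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        name = str(row[cols["filename"]]).strip()
        stem = Path(name).stem
        stem = re.sub(r"(?i)_(bf|fl)$", "", stem)
        cond = str(row[cols["condition"]]).strip()
        if stem in mapping and mapping[stem] != cond:
            raise ConditionKeyError(
                f"{path}: stem {stem!r} mapped to both "
                f"{mapping[stem]!r} and {cond!r}"
            )
        mapping[stem] = cond
    return mapping
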