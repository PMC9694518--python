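"""Image and table input/output, plus the batch run configuration.

Images come off slide scanners as RGB rasters (TIFF/PNG/JPEG). Label maps
are written as single-channel TIFF with background 0 and stable integer
tissue ids, area tables as plain CSV, and color renders as PNG, so every
output survives a round trip through standard viewers and spreadsheets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Physical pixel edge length of the reference slide-scanner setup, in µm.
DEFAULT_PIXEL_SIZE_UM = 5.17


class InputError(ValueError):
    """Raised for unreadable or structurally invalid input images."""


@dataclass
class RgbImage:
    """An RGB brightfield image with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Channel intensities in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel in micrometers.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RunConfig:
    """Configuration of a batch segmentation run.

    At least one ``emit_*`` flag must be set. Threshold overrides, when
    given, are strictly increasing cut lists in [0, 1] defining three
    saturation / value bins (see :mod:`fasgaseg.pixel_classes`).
    """

    input_dir: Path
    output_dir: Path
    emit_tissue_map: bool = True
    emit_region_map_5: bool = False
    emit_legland_map_4: bool = False
    emit_color_render: bool = False
    emit_area_table: bool = True
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    s_cuts: list[float] | None = None
    v_cuts: list[float] | None = None
    h_red: tuple[float, float] | None = None
    h_blue: tuple[float, float] | None = None
    catalogue_path: Path | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not any(
            (
                self.emit_tissue_map,
                self.emit_region_map_5,
                self.emit_legland_map_4,
                self.emit_color_render,
                self.emit_area_table,
            )
        ):
            raise ValueError("at least one emit_* flag must be set")
        for name in ("s_cuts", "v_cuts"):
            cuts = getattr(self, name)
            if cuts is None:
                continue
            arr = np.asarray(cuts, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing within [0, 1]")


def read_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RgbImage:
    """Read a raster image into an :class:`RgbImage`.

    16-bit inputs are rescaled to [0, 255] (``v // 257``), an alpha channel
    is dropped, and single-channel images are rejected — tissue thresholds
    are defined on color, so a grayscale scan cannot be segmented.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input image not found: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - decoding failures vary by backend
        raise InputError(f"could not decode image {path}: {exc}") from exc
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        warnings.warn(
            f"{path.name}: JPEG is lossy; chroma compression can shift H/S values "
            "near thresholds — prefer TIFF or PNG",
            stacklevel=2,
        )
    if arr.ndim == 2:
        raise InputError(f"single-channel image cannot be color-segmented: {path}")
    if arr.ndim != 3:
        raise InputError(f"unsupported image layout {arr.shape}: {path}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise InputError(f"expected 3 color channels, got {arr.shape[2]}: {path}")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return RgbImage(arr, pixel_size_um=pixel_size_um)


def write_label_map(path: str | Path, labels: np.ndarray) -> Path:
    """Write an integer label image as a single-channel TIFF (lossless)."""
    path = Path(path)
    labels = np.asarray(labels)
    dtype = np.uint8 if labels.max(initial=0) <= 255 else np.uint16
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def write_area_table(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a tissue area table as CSV (comma separator, '.' decimal, UTF-8)."""
    path = Path(path)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def write_png(path: str | Path, pixels: np.ndarray) -> Path:
    path = Path(path)
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))
    return path


def write_run_log(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
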