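"""Per-channel statistics of image regions.

The measurement step of the workflow photographs one color patch at a
time and reduces a region of interest (ROI, roughly 500 kpixel in
practice) to its per-channel mean and standard deviation.  Histograms and
block-averaged intensity surfaces support the lighting diagnostics: a
well-controlled light box shows single-peaked channel histograms and a
flat intensity surface (no light gradient across the patch).

Coordinates are 0-based, row-major, half-open: an ROI covers pixel columns
``[x0, x0 + width)`` and rows ``[y0, y0 + height)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError

from .exceptions import ImageFormatError

__all__ = [
    "RegionSpec",
    "RegionStats",
    "IntensitySurface",
    "read_image",
    "region_stats",
    "channel_histogram",
    "intensity_surface",
    "MIN_RECOMMENDED_AREA",
]

#: Recommended minimum ROI area (pixels) for stable patch statistics.
MIN_RECOMMENDED_AREA = 500_000


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular ROI: top-left (x0, y0), extent width x height pixels."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.width < 1 or self.height < 1:
            raise ValueError(f"invalid region {self}")

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class RegionStats:
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    n_pixels: int


@dataclass(frozen=True)
class IntensitySurface:
    """Block-averaged channel means over a tiled ROI.

    ``means`` has shape (n_rows, n_cols, 3); ``gradient`` is the per-channel
    spread max(block mean) - min(block mean), the light-gradient metric.
    """

    means: np.ndarray
    gradient: tuple[float, float, float]
    cell: int


def read_image(path) -> np.ndarray:
    """Read a JPEG/PNG photograph into an (H, W, 3) uint8 RGB grid.

    Alpha is dropped; EXIF orientation is honored.  CMYK and >8-bit images
    raise :class:`ImageFormatError` naming the problem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = Image.open(path)
        img.load()
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    img = ImageOps.exif_transpose(img)
    if img.mode in ("CMYK", "YCCK"):
        raise ImageFormatError(f"{path}: CMYK input is not supported, convert to RGB")
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
        raise ImageFormatError(f"{path}: >8-bit images are not supported ({img.mode})")
    if img.mode == "RGBA":
        img = img.convert("RGB")
    elif img.mode != "RGB":
        try:
            img = img.convert("RGB")
        except ValueError as exc:
            raise ImageFormatError(f"{path}: unsupported mode {img.mode}") from exc
    return np.asarray(img, dtype=np.uint8)


def _slice_roi(image: np.ndarray, roi: RegionSpec) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"image must be (H, W, 3), got shape {image.shape}")
    h, w = image.shape[:2]
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValueError(
            f"region {roi} exceeds image bounds {w}x{h} "
            f"(needs x<{roi.x0 + roi.width}, y<{roi.y0 + roi.height})"
        )
    return image[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]


def region_stats(
    image: np.ndarray,
    roi: RegionSpec,
    sample_sd: bool = False,
    warn_below: int | None = None,
) -> RegionStats:
    """Per-channel mean and SD over the ROI.

    Population SD by default (``ddof=0``, the pixel-statistics convention);
    ``sample_sd=True`` switches to ddof=1.  ``warn_below`` emits a warning
    for ROIs smaller than that pixel count (e.g. ``MIN_RECOMMENDED_AREA``).
    """
    block = _slice_roi(image, roi).astype(float)
    if warn_below is not None and roi.area < warn_below:
        warnings.warn(
            f"ROI has {roi.area} pixels, below the recommended {warn_below}",
            stacklevel=2,
        )
    ddof = 1 if sample_sd else 0
    if sample_sd and roi.area < 2:
        sd = (float("nan"),) * 3
    else:
        sd = tuple(float(v) for v in block.std(axis=(0, 1), ddof=ddof))
    return RegionStats(
        mean=tuple(float(v) for v in block.mean(axis=(0, 1))),
        sd=sd,
        n_pixels=roi.area,
    )


def channel_histogram(image: np.ndarray, roi: RegionSpec) -> np.ndarray:
    """Exact 256-bin counts per channel over the ROI; shape (3, 256)."""
    block = _slice_roi(image, roi)
    return np.stack(
        [np.bincount(block[..., ch].ravel(), minlength=256) for ch in range(3)]
    )


def intensity_surface(image: np.ndarray, roi: RegionSpec, cell: int) -> IntensitySurface:
    """Tile the ROI into cell x cell blocks and average each block.

    Ragged edge blocks are included.  The summary ``gradient`` (max block
    mean minus min block mean, per channel) quantifies light gradients: 0
    for perfectly uniform illumination.
    """
    if cell < 1:
        raise ValueError("cell must be >= 1")
    block = _slice_roi(image, roi).astype(float)
    ny = -(-roi.height // cell)
    nx = -(-roi.width // cell)
    means = np.empty((ny, nx, 3))
    for by in range(ny):
        for bx in range(nx):
            tile = block[by * cell : (by + 1) * cell, bx * cell : (bx + 1) * cell]
            means[by, bx] = tile.mean(axis=(0, 1))
    flat = means.reshape(-1, 3)
    gradient = tuple(float(v) for v in flat.max(axis=0) - flat.min(axis=0))
    return IntensitySurface(means=means, gradient=gradient, cell=cell)
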