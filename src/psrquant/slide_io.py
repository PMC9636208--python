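"""Slide and mask I/O plus deterministic tile iteration.

Whole-slide rasters are held in memory as ``uint8`` RGB arrays (row-major,
origin at the top-left, ``x`` = column, ``y`` = row).  Physical scale is a
single µm/pixel value resolved, in order of precedence, from an explicit
override and then from TIFF resolution tags; it is never guessed.  Supported
containers are plain/tiled TIFF and PNG — proprietary scanner formats (NDPI,
SVS) are expected to be converted upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import imageio.v3 as iio
import tifffile


class SlideFormatError(ValueError):
    """Raised when a file cannot be interpreted as a slide or mask."""


class MissingResolutionError(ValueError):
    """Raised when no µm/pixel is available for a slide."""


@dataclass
class WholeSlideImage:
    """An RGB whole-slide raster with its physical pixel size.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    um_per_pixel : float
        Physical edge length of one pixel in µm (e.g. 0.452 at 20X,
        0.226 at 40X on the scanner emulated here).
    source_path : str
        Provenance; empty for in-memory slides.
    """

    pixels: np.ndarray
    um_per_pixel: float
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise SlideFormatError(f"slide raster must be (H, W, 3), got {px.shape}")
        if px.dtype != np.uint8:
            raise SlideFormatError(f"slide raster must be uint8, got {px.dtype}")
        if not (self.um_per_pixel > 0):
            raise ValueError("um_per_pixel must be positive")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class TileWindow:
    """Half-open pixel window [x0, x1) × [y0, y1) in level-0 coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate tile window {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def slice(self) -> tuple[slice, slice]:
        """Numpy index (rows, cols) for this window."""
        return (slice(self.y0, self.y1), slice(self.x0, self.x1))


def _um_per_pixel_from_tiff(path: str) -> Optional[float]:
    """Extract µm/pixel from TIFF resolution tags, if present and sane."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" not in tags or "ResolutionUnit" not in tags:
            return None
        num, den = tags["XResolution"].value
        if num == 0 or den == 0:
            return None
        pixels_per_unit = num / den
        unit = tags["ResolutionUnit"].value  # 2 = inch, 3 = centimeter
        unit = getattr(unit, "value", unit)
        if unit == 3:
            um_per_unit = 1.0e4
        elif unit == 2:
            um_per_unit = 2.54e4
        else:
            return None
        return um_per_unit / pixels_per_unit


def read_slide(path: str, um_per_pixel_override: Optional[float] = None) -> WholeSlideImage:
    """Read a PNG or TIFF slide, promoting greyscale to RGB.

    µm/pixel is resolved as: explicit ``um_per_pixel_override`` first, then
    TIFF resolution tags.  A slide with neither raises
    :class:`MissingResolutionError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoding failure is a format error
        raise SlideFormatError(f"cannot decode {path!r} as an image: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SlideFormatError(f"{path!r}: expected RGB or greyscale raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise SlideFormatError(f"{path!r}: expected 8-bit pixels, got {arr.dtype}")

    um_pp = um_per_pixel_override
    if um_pp is None and path.lower().endswith((".tif", ".tiff")):
        um_pp = _um_per_pixel_from_tiff(path)
    if um_pp is None:
        raise MissingResolutionError(
            f"{path!r} carries no µm/pixel metadata (no TIFF resolution tags); "
            "pass um_per_pixel_override explicitly"
        )
    return WholeSlideImage(pixels=arr, um_per_pixel=float(um_pp), source_path=path)


def write_slide(slide: WholeSlideImage, path: str) -> None:
    """Write a slide as PNG or TIFF; TIFF embeds µm/pixel as resolution tags."""
    if path.lower().endswith((".tif", ".tiff")):
        pixels_per_cm = 1.0e4 / slide.um_per_pixel
        tifffile.imwrite(
            path,
            slide.pixels,
            photometric="rgb",
            resolution=(pixels_per_cm, pixels_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        iio.imwrite(path, slide.pixels)


def iter_tiles(width_px: int, height_px: int, tile_px: int) -> Iterator[TileWindow]:
    """Row-major, non-overlapping windows exactly covering the raster.

    Edge tiles are truncated.  The sequence is a deterministic partition of
    the pixel grid for every (size, tile) combination.
    """
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    if width_px < 1 or height_px < 1:
        raise ValueError("raster must be nonempty")
    for y0 in range(0, height_px, tile_px):
        y1 = min(y0 + tile_px, height_px)
        for x0 in range(0, width_px, tile_px):
            x1 = min(x0 + tile_px, width_px)
            yield TileWindow(x0, y0, x1, y1)


def write_mask(mask: np.ndarray, path: str) -> None:
    """Write a boolean raster as single-channel 8-bit PNG/TIFF (True -> 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise SlideFormatError(f"mask must be a 2-D boolean raster, got {mask.shape} {mask.dtype}")
    out = np.where(mask, np.uint8(255), np.uint8(0))
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out, photometric="minisblack")
    else:
        iio.imwrite(path, out)


def read_mask(path: str) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; lossless round-trip."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise SlideFormatError(f"{path!r}: mask must be single-channel, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise SlideFormatError(f"{path!r}: mask must be 8-bit, got {arr.dtype}")
    values = np.unique(arr)
    if not np.all(np.isin(values, [0, 255])):
        raise SlideFormatError(f"{path!r}: mask pixels must be 0 or 255, found {values[:10]}")
    return arr == 255
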