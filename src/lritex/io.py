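"""16-bit grayscale TIFF I/O for detector frames."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: Detector pixel pitch giving a 4.80 x 6.51 mm field of view at 300 x 407
#: pixels (16 um per pixel).
DEFAULT_PIXEL_SIZE_MM = 0.016


@dataclass
class Image:
    """A single-channel detector frame in integer counts.

    ``pixels`` is a 2D non-negative array; ``pixel_size_mm`` and
    ``acquisition_time_s`` travel as metadata in the TIFF description tag.
    """

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    acquisition_time_s: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D grayscale frame, got ndim={self.pixels.ndim}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def write_image(image: Image, path: str | Path) -> None:
    """Write a frame as uncompressed 16-bit grayscale TIFF (lossless)."""
    pixels = np.asarray(image.pixels)
    if pixels.size and (pixels.max() > 65535 or pixels.min() < 0):
        raise ValueError("pixel values outside the 16-bit range [0, 65535]")
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "acquisition_time_s": image.acquisition_time_s,
    }
    tifffile.imwrite(path, pixels.astype(np.uint16), description=json.dumps(meta))


def read_image(path: str | Path) -> Image:
    """Read a 16-bit grayscale TIFF; rejects RGB or higher-dimensional data."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        description = tif.pages[0].description
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape}"
        )
    pixel_size = DEFAULT_PIXEL_SIZE_MM
    acq_time = None
    if description:
        try:
            meta = json.loads(description)
            pixel_size = float(meta.get("pixel_size_mm", pixel_size))
            acq_time = meta.get("acquisition_time_s")
        except (ValueError, TypeError, AttributeError):
            pass
    return Image(pixels=arr, pixel_size_mm=pixel_size, acquisition_time_s=acq_time)
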