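"""ROI grid geometry for feature extraction.

Coordinates are row-major, 0-based, origin at the top-left pixel; ROI
windows are half-open pixel ranges. The defaults mirror the classification
workflow: 20 x 20 pixel ROIs in a 6 x 13 grid (78 ROIs per tissue sample),
non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ROI_SHAPE = (20, 20)
DEFAULT_GRID_SHAPE = (6, 13)


@dataclass(frozen=True)
class ROI:
    """A rectangular pixel window addressed by its grid cell (i, j)."""

    grid_index: tuple[int, int]
    row0: int
    col0: int
    n_rows: int
    n_cols: int
    sample: str | None = None

    @property
    def window(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.n_rows), slice(self.col0, self.col0 + self.n_cols))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass(frozen=True)
class ROIGrid:
    """A regular grid of rectangular ROIs.

    ``stride`` defaults to ``roi_shape`` (non-overlapping windows);
    smaller strides yield overlapping ROIs.
    """

    origin: tuple[int, int] = (0, 0)
    roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE
    stride: tuple[int, int] | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if min(self.roi_shape) < 1 or min(self.grid_shape) < 1:
            raise ValueError("roi_shape and grid_shape must be strictly positive")
        if self.stride is not None and min(self.stride) < 1:
            raise ValueError("stride must be strictly positive")

    @property
    def effective_stride(self) -> tuple[int, int]:
        return self.stride if self.stride is not None else self.roi_shape

    @property
    def n_rois(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def rois(self) -> list[ROI]:
        """All ROIs in row-major grid order."""
        sr, sc = self.effective_stride
        out = []
        for i in range(self.grid_shape[0]):
            for j in range(self.grid_shape[1]):
                out.append(
                    ROI(
                        grid_index=(i, j),
                        row0=self.origin[0] + i * sr,
                        col0=self.origin[1] + j * sc,
                        n_rows=self.roi_shape[0],
                        n_cols=self.roi_shape[1],
                        sample=self.sample,
                    )
                )
        return out


def _image_shape(image) -> tuple[int, int]:
    pixels = getattr(image, "pixels", image)
    return np.asarray(pixels).shape


def make_roi_grid(
    image,
    origin: tuple[int, int] = (0, 0),
    roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE,
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    stride: tuple[int, int] | None = None,
    sample: str | None = None,
) -> ROIGrid:
    """Build an ROI grid, validating that every cell lies inside the image."""
    grid = ROIGrid(
        origin=origin, roi_shape=roi_shape, grid_shape=grid_shape, stride=stride, sample=sample
    )
    rows, cols = _image_shape(image)
    for roi in grid.rois():
        if roi.row0 < 0 or roi.col0 < 0 or roi.row0 + roi.n_rows > rows or roi.col0 + roi.n_cols > cols:
            raise ValueError(
                f"grid cell {roi.grid_index} spans rows {roi.row0}:{roi.row0 + roi.n_rows}, "
                f"cols {roi.col0}:{roi.col0 + roi.n_cols}, outside image shape {(rows, cols)}"
            )
    return grid


def extract_roi(image, roi: ROI) -> np.ndarray:
    """Copy the pixel window of a ROI (mutating it never touches the source)."""
    pixels = np.asarray(getattr(image, "pixels", image))
    rows, cols = pixels.shape
    if roi.row0 < 0 or roi.col0 < 0 or roi.row0 + roi.n_rows > rows or roi.col0 + roi.n_cols > cols:
        raise ValueError(f"ROI {roi.grid_index} window out of image bounds {(rows, cols)}")
    return pixels[roi.window].copy()
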