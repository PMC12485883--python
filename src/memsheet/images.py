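"""Core containers for membrane-sheet image analysis.

A membrane sheet is imaged as a set of co-registered single-channel 2D
grayscale frames (e.g. TMA-DPH membrane marker, a GFP-tagged protein and an
mCherry-tagged PIP2 reporter).  All quantification downstream works on square
pixel-aligned regions of interest placed on such frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "ChannelImage",
    "SquareROI",
    "SheetRecord",
    "ROIBoundsError",
    "InvalidParameterError",
    "read_channel_tiff",
    "write_channel_tiff",
]


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain."""


class ROIBoundsError(ValueError):
    """An ROI does not fit entirely inside the image it is applied to."""


@dataclass(frozen=True)
class SquareROI:
    """Square analysis window, 0-based top-left corner, half-open extent.

    The ROI covers rows ``row0 .. row0+side_px-1`` and the analogous columns.
    """

    row0: int
    col0: int
    side_px: int

    def __post_init__(self) -> None:
        if self.side_px < 1:
            raise InvalidParameterError(f"side_px must be >= 1, got {self.side_px}")
        if self.row0 < 0 or self.col0 < 0:
            raise InvalidParameterError(
                f"ROI corner must be non-negative, got ({self.row0}, {self.col0})"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side_px),
            slice(self.col0, self.col0 + self.side_px),
        )

    def require_inside(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row0 + self.side_px > rows or self.col0 + self.side_px > cols:
            raise ROIBoundsError(
                f"ROI {self} does not fit inside image of shape {shape}"
            )

    def overlaps(self, other: "SquareROI") -> bool:
        return not (
            self.row0 + self.side_px <= other.row0
            or other.row0 + other.side_px <= self.row0
            or self.col0 + self.side_px <= other.col0
            or other.col0 + other.side_px <= self.col0
        )


@dataclass
class ChannelImage:
    """One fluorescence channel of a sheet: a 2D float field plus metadata."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InvalidParameterError(
                f"pixels must be a 2D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidParameterError("pixels contain non-finite values")
        if not (self.pixel_size_nm > 0):
            raise InvalidParameterError(
                f"pixel_size_nm must be positive, got {self.pixel_size_nm}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def roi_view(self, roi: SquareROI) -> np.ndarray:
        roi.require_inside(self.shape)
        return self.pixels[roi.slices]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return ChannelImage(
            pixels=pixels,
            pixel_size_nm=self.pixel_size_nm,
            channel_label=self.channel_label,
        )


@dataclass
class SheetRecord:
    """All co-registered channels of one membrane sheet plus its condition."""

    channels: Mapping[str, ChannelImage]
    construct: str = ""
    condition: str = "directly_fixed"
    treatment: str = "none"
    replicate_id: str = ""
    sheet_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.channels.values()}
        sizes = {im.pixel_size_nm for im in self.channels.values()}
        if len(shapes) > 1 or len(sizes) > 1:
            raise InvalidParameterError(
                "all channels of a sheet must share shape and pixel size; "
                f"got shapes {shapes} and pixel sizes {sizes}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def read_channel_tiff(
    path: str | Path, pixel_size_nm: float, channel_label: str = ""
) -> ChannelImage:
    """Load a single-channel grayscale TIFF as a float image."""
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise InvalidParameterError(
            f"{path}: expected a single-plane grayscale TIFF, got shape {data.shape}"
        )
    return ChannelImage(
        pixels=data.astype(np.float64),
        pixel_size_nm=pixel_size_nm,
        channel_label=channel_label or Path(path).stem,
    )


def write_channel_tiff(path: str | Path, image: ChannelImage) -> None:
    """Write a channel as 16-bit grayscale TIFF (values clipped to [0, 65535])."""
    data = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)
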