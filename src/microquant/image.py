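"""Core in-memory containers for micrographs.

An :class:`Image2D` is a single-channel 2-D intensity raster plus the two
pieces of metadata every downstream measurement needs: the physical pixel
size (µm per pixel) and a *bit-depth hint* that records whether the values
live on a display-scaled 8-bit grid (integers in [0, 255]) or on the
camera's native scale.  All filters preserve shape and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = ["Image2D", "ZStack", "TimeSeries", "as_image"]

#: allowed values of ``Image2D.bit_depth_hint``
BIT_DEPTH_HINTS = ("native", "8bit")


@dataclass
class Image2D:
    """A single-channel 2-D fluorescence image.

    Parameters
    ----------
    pixels:
        2-D array of finite, non-negative intensities (stored as float64).
    pixel_size:
        Physical pixel size in µm/px, or ``None`` when uncalibrated
        (treated as 1.0 µm/px where a calibrated length is required).
    bit_depth_hint:
        ``"8bit"`` if the values are integers on a 0–255 display scale,
        ``"native"`` otherwise.  Operators that clamp (e.g. unsharp
        masking) use this to pick the valid output range.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    bit_depth_hint: str = "native"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Image2D intensities must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("Image2D intensities must be non-negative")
        if self.bit_depth_hint not in BIT_DEPTH_HINTS:
            raise ValueError(f"bit_depth_hint must be one of {BIT_DEPTH_HINTS}")
        if self.bit_depth_hint == "8bit":
            if arr.size and (arr.max() > 255 or not np.allclose(arr, np.round(arr))):
                raise ValueError("8-bit image must hold integers in [0, 255]")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = arr

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, arr: np.ndarray, bit_depth_hint: Optional[str] = None) -> "Image2D":
        """Return a copy of this image carrying new pixel data."""
        return replace(
            self,
            pixels=np.asarray(arr, dtype=np.float64),
            bit_depth_hint=bit_depth_hint or self.bit_depth_hint,
        )

    def px2_to_um2(self, area_px2: float) -> float:
        """Convert an area in px² to µm² (pixel size defaults to 1 µm/px)."""
        ps = 1.0 if self.pixel_size is None else self.pixel_size
        return float(area_px2) * ps * ps


@dataclass
class ZStack:
    """An ordered stack of equally spaced z-slices."""

    slices: list
    slice_spacing_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("ZStack requires at least one slice")
        shape = self.slices[0].shape
        for s in self.slices:
            if s.shape != shape:
                raise ValueError("all z-slices must share one shape")

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i: int) -> Image2D:
        return self.slices[i]


@dataclass
class TimeSeries:
    """An ordered time-lapse of frames taken at a fixed interval (minutes)."""

    frames: list
    frame_interval_min: float = 5.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("TimeSeries requires at least one frame")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be positive")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Image2D:
        return self.frames[i]

    def times_min(self) -> np.ndarray:
        return np.arange(len(self.frames), dtype=float) * self.frame_interval_min


ImageLike = Union[Image2D, np.ndarray]


def as_image(obj: ImageLike, pixel_size: Optional[float] = None,
             bit_depth_hint: str = "native") -> Image2D:
    """Coerce an array (or pass through an :class:`Image2D`) to Image2D."""
    if isinstance(obj, Image2D):
        return obj
    return Image2D(np.asarray(obj, dtype=np.float64), pixel_size=pixel_size,
                   bit_depth_hint=bit_depth_hint)


def _unwrap(img: ImageLike) -> tuple:
    """Return (array, template-or-None) for functions that accept both kinds."""
    if isinstance(img, Image2D):
        return img.pixels, img
    return np.asarray(img, dtype=np.float64), None


def _rewrap(arr: np.ndarray, template, bit_depth_hint: Optional[str] = None):
    """Wrap a result array like its input (Image2D in, Image2D out)."""
    if template is None:
        return arr
    return template.with_pixels(arr, bit_depth_hint=bit_depth_hint)
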