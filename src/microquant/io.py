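"""File I/O: TIFF images/stacks, CSV tables, JSON reports, provenance.

Pixel values round-trip exactly; the pixel size is read from TIFF
resolution tags when present, falls back to a configured default, and
otherwise defaults to 1.0 µm/px with a warning.  All writers are
deterministic: identical inputs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .image import Image2D, TimeSeries, ZStack

__all__ = ["read_image", "write_image", "write_table", "write_json",
           "write_mask", "file_sha256"]


def _pixel_size_from_tags(page) -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or num == den:
        return None  # 1 px/unit is the "no calibration" placeholder
    px_per_unit = num / den
    unit = tags.get("ResolutionUnit")
    unit_val = getattr(unit, "value", 2)
    unit_val = getattr(unit_val, "value", unit_val)  # enum -> int
    if unit_val == 3:        # centimetre
        um_per_unit = 1e4
    elif unit_val == 2:      # inch
        um_per_unit = 25_400.0
    else:                    # unitless: treat resolution as px per µm
        um_per_unit = 1.0
    return um_per_unit / px_per_unit


def read_image(path: Union[str, Path], axes: Optional[str] = None,
               pixel_size: Optional[float] = None,
               frame_interval_min: float = 5.0,
               slice_spacing_um: Optional[float] = None,
               bit_depth_hint: Optional[str] = None):
    """Read a TIFF as Image2D (1 page), ZStack (axes="z") or TimeSeries (axes="t").

    Multi-page files require ``axes`` to disambiguate z from t.  Values
    are preserved exactly.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_ps = _pixel_size_from_tags(tif.pages[0])
    if pixel_size is None:
        pixel_size = tag_ps
    if pixel_size is None:
        warnings.warn(f"{path.name}: no resolution tag and no configured pixel "
                      "size; assuming 1.0 µm/px")
        pixel_size = 1.0
    if bit_depth_hint is None:
        bit_depth_hint = "8bit" if data.dtype == np.uint8 else "native"

    if data.ndim == 2:
        return Image2D(data.astype(np.float64), pixel_size=pixel_size,
                       bit_depth_hint=bit_depth_hint)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: unsupported image dimensionality {data.ndim}")
    if axes not in ("z", "t"):
        raise ValueError(
            f"{path.name} has {data.shape[0]} pages; pass axes='z' or axes='t'"
        )
    planes = [Image2D(p.astype(np.float64), pixel_size=pixel_size,
                      bit_depth_hint=bit_depth_hint) for p in data]
    if axes == "z":
        return ZStack(planes, slice_spacing_um=slice_spacing_um)
    return TimeSeries(planes, frame_interval_min=frame_interval_min)


def _resolution_kwargs(pixel_size: Optional[float]) -> dict:
    if pixel_size is None:
        return {}
    px_per_cm = 1e4 / pixel_size
    return {"resolution": (px_per_cm, px_per_cm), "resolutionunit": "CENTIMETER"}


def write_image(obj, path: Union[str, Path]) -> None:
    """Write Image2D / ZStack / TimeSeries to (multi-page) TIFF.

    8-bit-hinted images are stored as uint8, others as float32."""
    path = Path(path)
    if isinstance(obj, Image2D):
        planes, ps = [obj], obj.pixel_size
    elif isinstance(obj, (ZStack, TimeSeries)):
        planes = obj.slices if isinstance(obj, ZStack) else obj.frames
        ps = planes[0].pixel_size
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r} as an image")
    hint8 = all(p.bit_depth_hint == "8bit" for p in planes)
    dtype = np.uint8 if hint8 else np.float32
    data = np.stack([p.pixels.astype(dtype) for p in planes])
    if len(planes) == 1:
        data = data[0]
    # photometric must be explicit: a 3-page stack would otherwise be
    # guessed as an RGB image with separate component planes
    tifffile.imwrite(path, data, photometric="minisblack",
                     **_resolution_kwargs(ps))


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a binary mask as a 0/255 uint8 TIFF (round-trips exactly)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a measurement table as CSV with a stable column order."""
    table.to_csv(Path(path), index=False, lineterminator="\n", float_format="%.6g")


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Write a report/truth dictionary as deterministic, sorted JSON."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)!r}")


def file_sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
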