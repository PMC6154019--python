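"""Image and table I/O: ImageJ-compatible TIFF, CSV tables, YAML config."""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import tifffile

from .core import DEFAULT_PIXEL_SIZE, Image, ImageStack


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pixel size in μm from ImageJ metadata or resolution tags."""
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value  # (num, den) px per unit
        unit = page.tags.get("ResolutionUnit")
        num, den = xres
        if num and den:
            px = den / num  # units per pixel
            # ImageJ writes resolution in px/unit with unit in metadata
            ij = tf.imagej_metadata or {}
            if ij.get("unit") in ("micron", "um", "µm") or unit is None:
                return float(px)
    except (KeyError, ZeroDivisionError, TypeError):
        pass
    return None


def read_image(path: str | os.PathLike, pixel_size: float | None = None) -> Image:
    """Read a single-page grayscale TIFF; pixel size from metadata if present,
    else from the argument, else the package default."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_tiff(tf)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path}: RGB input without a channel selector is not supported"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-page grayscale TIFF")
    px = pixel_size or meta_px or DEFAULT_PIXEL_SIZE
    return Image(arr.astype(float), px)


def read_stack(
    path: str | os.PathLike,
    pixel_size: float | None = None,
    frame_interval: float = 1.0,
) -> ImageStack:
    """Read a multi-page TIFF as a timed stack.

    Timestamps come from ImageJ ``finterval`` metadata when present, else
    ``frame_interval`` seconds between frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_tiff(tf)
        ij = tf.imagej_metadata or {}
    if arr.ndim == 2:
        arr = arr[None]
    interval = float(ij.get("finterval", frame_interval)) or frame_interval
    times = np.arange(arr.shape[0]) * interval
    px = pixel_size or meta_px or DEFAULT_PIXEL_SIZE
    return ImageStack(arr.astype(float), times, px)


def write_image(path: str | os.PathLike, image: Image) -> None:
    """Write an ImageJ-compatible 32-bit float TIFF with pixel size."""
    res = 1.0 / image.pixel_size
    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "micron"},
    )


def write_stack(path: str | os.PathLike, stack: ImageStack) -> None:
    """Write a multi-page ImageJ TIFF with frame interval metadata."""
    res = 1.0 / stack.pixel_size
    dt = (
        float(np.median(np.diff(stack.timestamps)))
        if len(stack) > 1
        else 1.0
    )
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "micron", "finterval": dt, "axes": "TYX"},
    )


def write_json(path: str | os.PathLike, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
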