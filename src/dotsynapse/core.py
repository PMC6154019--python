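"""Core containers shared by every analysis stage.

Conventions
-----------
* All physical lengths are in micrometres (μm); pixel coordinates follow the
  ``(row, col)`` convention of scikit-image. A point in physical units is a
  pair ``(row_um, col_um) = (row_px, col_px) * pixel_size``.
* Intensities are arbitrary fluorescence units for TIRF/epi channels and
  dimensionless gray levels (0..1 full scale) for RICM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: default physical pixel size in μm/px (100x objective, 16 μm camera pixels)
DEFAULT_PIXEL_SIZE = 0.16


class DotsynapseError(Exception):
    """Base class for all package-specific errors."""


@dataclass(frozen=True)
class Image:
    """A single-channel 2-D intensity image with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite intensity values.
    pixel_size
        Physical size of one pixel in μm.
    channel
        Free-form channel label (e.g. ``"NaV"``, ``"RICM"``, ``"TCR"``).
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical field size ``(height_um, width_um)``."""
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass(frozen=True)
class ImageStack:
    """An ordered time series of same-shaped frames.

    ``frames`` is stored as a 3-D array ``(t, row, col)``; ``timestamps`` are
    seconds, strictly increasing, starting at or after 0.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        if fr.ndim != 3:
            raise ValueError("frames must be a (t, row, col) array")
        if ts.ndim != 1 or ts.size != fr.shape[0]:
            raise ValueError("timestamps must match the number of frames")
        if ts.size and ts[0] < 0:
            raise ValueError("timestamps must start at >= 0")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Image:
        return Image(self.frames[i], self.pixel_size, self.channel)


@dataclass(frozen=True)
class CellMask:
    """A segmented cell contact zone (one connected component)."""

    mask: np.ndarray
    pixel_size: float
    area_um2: float = field(init=False)
    centroid_um: tuple[float, float] = field(init=False)
    equivalent_diameter_um: float = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("mask is empty")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "mask", m)
        n = int(m.sum())
        area = n * self.pixel_size**2
        rows, cols = np.nonzero(m)
        centroid = (rows.mean() * self.pixel_size, cols.mean() * self.pixel_size)
        object.__setattr__(self, "area_um2", area)
        object.__setattr__(self, "centroid_um", centroid)
        object.__setattr__(self, "equivalent_diameter_um", 2.0 * np.sqrt(area / np.pi))


def as_points_um(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Coerce a sequence of (row_um, col_um) points into an (N, 2) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.shape[1] != 2:
        raise ValueError("points must be (N, 2) (row_um, col_um)")
    return pts
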