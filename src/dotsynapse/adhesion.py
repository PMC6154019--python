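"""RICM adhesion analysis: contact-zone segmentation and texture class.

In RICM, dark pixels report tight membrane–substrate contact and gray pixels
the bare substrate. The contact zone is segmented by a local spatial variance
filter (the cell edge and any internal texture carry variance that the smooth
background lacks) followed by Otsu thresholding, hole filling and a
morphological erosion that undoes the outward smear of the variance window.
A cell is classified *textured* when at least 7 dark patches compatible in
size and spacing with the ligand-dot lattice are found inside the contact
zone, otherwise *uniform*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .core import CellMask, DotsynapseError, Image


class NoCellError(DotsynapseError):
    """No adherent cell found in the image."""


@dataclass(frozen=True)
class AdhesionClassification:
    label: str  # "uniform" | "textured"
    n_qualifying_patches: int
    patch_centroids_um: np.ndarray

    #: minimum number of qualifying dark patches for textured adhesion
    TEXTURED_MIN_PATCHES = 7


def _local_variance(img: np.ndarray, radius: int) -> np.ndarray:
    """Variance of the image inside a disc of the given pixel radius."""
    selem = disk(radius).astype(float)
    selem /= selem.sum()
    m = ndimage.convolve(img, selem, mode="reflect")
    m2 = ndimage.convolve(img * img, selem, mode="reflect")
    return np.clip(m2 - m * m, 0.0, None)


def segment_cell_ricm(
    image: Image,
    variance_radius: int = 4,
    min_area_um2: float = 20.0,
) -> CellMask:
    """Segment the cell contact zone from an RICM image.

    Local variance (disc of ``variance_radius`` px) → Otsu threshold → hole
    filling → erosion by ``variance_radius − 1`` px → the qualifying
    component whose centroid lies closest to the image centre. The erosion
    undoes the outward smear of the variance window: the Otsu-thresholded
    variance ring of a step edge extends about one window radius minus one
    pixel beyond the true contour (calibrated on discs of known radius,
    residual bias < 2% for cell radii 4–12 μm).
    """
    var = _local_variance(image.pixels, variance_radius)
    thr = threshold_otsu(var)
    binary = var > thr
    # Otsu always splits something: demand real structure (the variance of a
    # cell edge is orders of magnitude above the noise floor)
    if binary.any() and var[binary].mean() < 3.0 * var[~binary].mean():
        raise NoCellError("no cell: variance map has no structure")
    filled = ndimage.binary_fill_holes(binary)
    eroded = ndimage.binary_erosion(
        filled, structure=disk(max(variance_radius - 1, 1))
    )
    lab = label(eroded)
    props = regionprops(lab)
    min_px = min_area_um2 / image.pixel_size**2
    candidates = [p for p in props if p.area >= min_px]
    if not candidates:
        raise NoCellError("no cell: no component above the minimum area")
    center = np.array(image.shape, dtype=float) / 2.0
    best = min(
        candidates,
        key=lambda p: float(np.hypot(*(np.asarray(p.centroid) - center))),
    )
    return CellMask(lab == best.label, image.pixel_size)


def classify_adhesion(
    image: Image,
    mask: CellMask,
    pitch: float = 2.0,
    dot_fwhm: float = 0.75,
    size_window: tuple[float, float] = (0.5, 1.5),
    spacing_window: tuple[float, float] = (0.7, 1.3),
) -> AdhesionClassification:
    """Uniform vs textured adhesion by the dark-patch rule.

    Candidate patches are connected regions inside the contact zone that are
    dark relative to both the outside background (mean − 2 SD) and the cell's
    own adhesion level (median − 3×1.4826 MAD, robust to the patches
    themselves; at 2 robust sigmas the noise tail alone seeds spurious
    candidate specks). A candidate qualifies iff its equivalent diameter lies in
    ``size_window``×dot_fwhm *and* the distance to its nearest other
    qualifying candidate lies in ``spacing_window``×pitch. The label is
    textured iff at least 7 patches qualify.
    """
    px = image.pixel_size
    img = image.pixels
    inside = mask.mask
    outside = ~inside
    bg_mean = float(img[outside].mean())
    bg_sd = float(img[outside].std())
    in_med = float(np.median(img[inside]))
    in_mad = float(np.median(np.abs(img[inside] - in_med)))
    thr = min(bg_mean - 2.0 * bg_sd, in_med - 3.0 * 1.4826 * in_mad)

    dark = (img < thr) & inside
    lab = label(dark, connectivity=2)
    props = regionprops(lab)
    lo_d, hi_d = size_window[0] * dot_fwhm, size_window[1] * dot_fwhm
    sized = [
        p for p in props if lo_d <= p.equivalent_diameter_area * px <= hi_d
    ]
    if len(sized) >= 2:
        cents = np.array([p.centroid for p in sized]) * px
        d, _ = cKDTree(cents).query(cents, k=2)
        lo_s, hi_s = spacing_window[0] * pitch, spacing_window[1] * pitch
        ok = (d[:, 1] >= lo_s) & (d[:, 1] <= hi_s)
        qualifying = cents[ok]
    else:
        qualifying = np.zeros((0, 2))
    n = len(qualifying)
    lab_out = (
        "textured" if n >= AdhesionClassification.TEXTURED_MIN_PATCHES else "uniform"
    )
    return AdhesionClassification(lab_out, n, qualifying)
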