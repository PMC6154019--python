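"""Lipid diffusion constant from continuous-photobleaching (CPB) movies.

Under steady illumination through a partially closed diaphragm, fluorophores
inside the aperture bleach at rate k while unbleached lipid diffuses in from
outside, forming a bright rim along the aperture edge. In the quasi-steady
regime the rim profile follows the 1-D reaction–diffusion balance
I(x) = B·exp(−x/λ) + c with decay length λ = √(D/k), so the diffusion
constant is D = λ²k. The analysis fits k from the central decay and λ from
the late-time edge profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .core import DotsynapseError, ImageStack


class NoBleachingError(DotsynapseError):
    """Central intensity trace does not decay."""


class ProfileFitError(DotsynapseError):
    """Rim profile cannot be fit to a decaying exponential."""


@dataclass(frozen=True)
class BleachRate:
    k: float  # 1/s
    k_stderr: float
    amplitude: float
    offset: float


@dataclass(frozen=True)
class EdgeProfile:
    """Late-time rim profile vs distance inward from the aperture edge."""

    x_um: np.ndarray
    intensity: np.ndarray  # normalized to the bin nearest the edge
    depleted_fraction: float  # 1 - center_late/center_initial
    early_window: bool  # True if the center had not yet depleted by >= 90%


@dataclass(frozen=True)
class DiffusionFit:
    D: float  # μm²/s
    k: float  # 1/s
    lam: float  # μm
    fit_window_um: tuple[float, float]
    residual: float  # RMS of profile fit
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _exp_decay(t, a, k, c):
    return a * np.exp(-k * t) + c


def estimate_bleach_rate(
    stack: ImageStack, aperture: np.ndarray, central_fraction: float = 0.25
) -> BleachRate:
    """Bleach rate k from the central intensity decay.

    The mean intensity of the central ``central_fraction`` (by radius) of
    the aperture is fit to A·exp(−kt) + c by least squares.
    """
    if len(stack) < 10:
        raise ValueError("need >= 10 frames to fit a bleach rate")
    aperture = np.asarray(aperture, dtype=bool)
    dist = ndimage.distance_transform_edt(aperture) * stack.pixel_size
    r_ap = dist.max()
    central = dist >= (1.0 - central_fraction) * r_ap
    trace = stack.frames[:, central].mean(axis=1)
    t = stack.timestamps
    # log-linear initialisation on the background-subtracted trace
    a0 = trace[0] - trace[-1]
    if a0 <= 0:
        raise NoBleachingError("no bleaching detected (trace does not decay)")
    k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    try:
        popt, pcov = curve_fit(
            _exp_decay,
            t,
            trace,
            p0=(a0, k0, trace[-1]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise NoBleachingError("exponential fit failed") from exc
    a, k, c = popt
    if k <= 0:
        raise NoBleachingError("no bleaching detected (fitted k <= 0)")
    k_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return BleachRate(float(k), k_err, float(a), float(c))


def edge_profile(
    stack: ImageStack, aperture: np.ndarray, t_window: float = 0.2
) -> EdgeProfile:
    """Mean late-time intensity vs distance inward from the aperture edge.

    Pixels inside the aperture are binned (1-pixel bins) by their distance
    to the aperture edge; bin values are averaged over the last ``t_window``
    fraction of frames and normalized to the bin nearest the edge. If the
    centre has not yet lost >= 90% of its initial intensity the rim is not
    quasi-stationary and the profile is flagged.
    """
    aperture = np.asarray(aperture, dtype=bool)
    px = stack.pixel_size
    dist_px = ndimage.distance_transform_edt(aperture)
    n_late = max(1, int(round(t_window * len(stack))))
    late = stack.frames[-n_late:].mean(axis=0)

    r_ap = dist_px.max()
    central = dist_px >= 0.75 * r_ap
    c0 = stack.frames[0][central].mean()
    c_late = late[central].mean()
    depleted = 1.0 - (c_late / c0 if c0 > 0 else 0.0)

    # boundary pixels of the mask sit at EDT distance 1, so shift by one
    # pixel to measure distance inward from the aperture edge
    d_in = np.clip(dist_px - 1.0, 0.0, None)
    nbins = int(d_in.max())
    b = np.floor(d_in).astype(int)
    sel = aperture & (b < nbins)
    sums = np.bincount(b[sel], weights=late[sel], minlength=nbins)
    counts = np.bincount(b[sel], minlength=nbins)
    ok = counts > 0
    vals = sums[ok] / counts[ok]
    x_um = ((np.arange(nbins) + 0.5) * px)[ok]
    norm = vals[0] if vals[0] > 0 else 1.0
    return EdgeProfile(x_um, vals / norm, float(depleted), depleted < 0.9)


def _exp_profile(x, b, lam, c):
    return b * np.exp(-x / lam) + c


def fit_diffusion(profile: EdgeProfile, k: float) -> DiffusionFit:
    """Fit the rim profile to B·exp(−x/λ)+c and return D = λ²·k.

    λ is initialised from the log-slope of the first bins and the fit is
    restricted to x in [0, 5λ_init].
    """
    x, y = profile.x_um, profile.intensity
    if len(x) < 4:
        raise ProfileFitError("profile too short to fit")
    # λ initialisation: 1/e crossing of the plateau-subtracted profile (the
    # deep interior of the aperture sits on a bleached plateau, not at zero)
    n_tail = max(1, len(y) // 4)
    plateau = float(y[-n_tail:].mean())
    amp0 = y[0] - plateau
    if amp0 <= 0:
        raise ProfileFitError("non-decaying profile (no rim)")
    below = np.nonzero(y - plateau < amp0 / np.e)[0]
    lam0 = float(x[below[0]]) if len(below) else float(x[-1] / 2.0)
    lam0 = max(lam0, float(x[1] - x[0]))
    x_hi = min(5.0 * lam0, x[-1])
    sel = x <= x_hi
    try:
        popt, _ = curve_fit(
            _exp_profile,
            x[sel],
            y[sel],
            p0=(amp0, lam0, plateau),
            bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ProfileFitError("profile fit did not converge") from exc
    b, lam, c = popt
    if lam <= 0:
        raise ProfileFitError("fitted decay length is non-positive")
    resid = float(np.sqrt(np.mean((_exp_profile(x[sel], *popt) - y[sel]) ** 2)))
    warns: list[str] = []
    if profile.early_window:
        warns.append("window-too-early: center not yet depleted by 90%")
    r_ap = x[-1]  # max distance inward ≈ aperture radius
    if r_ap < 5.0 * lam:
        warns.append(
            f"aperture radius ({r_ap:.1f} μm) < 5λ ({5 * lam:.1f} μm); "
            "curvature correction omitted"
        )
    return DiffusionFit(
        D=float(lam**2 * k),
        k=float(k),
        lam=float(lam),
        fit_window_um=(0.0, float(x_hi)),
        residual=resid,
        warnings=tuple(warns),
    )


def analyze_cpb(
    stack: ImageStack, aperture: np.ndarray | None = None, t_window: float = 0.2
) -> DiffusionFit:
    """Full CPB analysis: bleach rate, edge profile, diffusion fit.

    If ``aperture`` is None it is taken as the non-zero footprint of the
    first frame (the movie records only inside the diaphragm).
    """
    if aperture is None:
        aperture = stack.frames[0] > 0
        aperture = ndimage.binary_fill_holes(aperture)
    rate = estimate_bleach_rate(stack, aperture)
    prof = edge_profile(stack, aperture, t_window)
    return fit_diffusion(prof, rate.k)
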