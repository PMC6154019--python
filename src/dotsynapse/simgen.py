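"""Synthetic microscopy generator with known ground truth.

Every analysis stage of the package consumes images of one of five kinds:
hexagonal ligand-dot arrays (epi-fluorescence of the labelled linker protein),
sparse single-molecule calibration frames, RICM images of adherent T cells,
TIRF images of receptor clusters or F-actin, and continuous-photobleaching
(CPB) movies of a supported lipid bilayer. This module emulates each of them
with a simple physical forward model — molecular surface densities rendered
through a Gaussian spot profile, a Poisson shot-noise camera with additive
Gaussian read noise — and returns the exact ground truth alongside the image,
so recovery can be asserted quantitatively.

The defaults encode the study conditions of the substrate system being
emulated: 2 μm hexagonal pitch, 700–800 nm dot FWHM, ~40 molecules/μm² inside
the dots vs ~10 outside, lipid diffusion of a few μm²/s, and cell-area cohorts
with log-normal spread around the printed medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import DEFAULT_PIXEL_SIZE, CellMask, DotsynapseError, Image, ImageStack

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: RICM gray-level conventions (fraction of full scale). Only the ordering
#: patch < tight adhesion < proximal membrane < background is meaningful.
RICM_BACKGROUND = 0.5
RICM_TIGHT_ADHESION = 0.15
RICM_PROXIMAL_MEMBRANE = 0.35
RICM_PATCH = 0.10
RICM_NOISE_SD = 0.02

DEFAULT_READ_NOISE = 2.0  # photons rms, additive Gaussian


class SimulationError(DotsynapseError):
    """Raised when generator preconditions are violated."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeSpec:
    """Hexagonal dot-array geometry and molecular densities.

    ``amp_in`` is the peak molecular density at a dot centre and ``amp_out``
    the background density between dots, both in molecules/μm².
    """

    pitch: float = 2.0
    dot_fwhm: float = 0.75
    origin: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0
    amp_in: float = 40.0
    amp_out: float = 10.0

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError("pitch must be > 0")
        if not self.dot_fwhm > 0:
            raise ValueError("dot_fwhm must be > 0")
        if self.dot_fwhm >= self.pitch:
            raise ValueError("dot_fwhm must be smaller than the pitch")
        if not (self.amp_in >= self.amp_out >= 0):
            raise ValueError("require amp_in >= amp_out >= 0")

    @property
    def sigma(self) -> float:
        """Gaussian σ of the dot profile in μm."""
        return self.dot_fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class CPBParams:
    """Continuous-photobleaching simulation parameters.

    The movie integrates ∂c/∂t = D ∇²c − k·χ_aperture·c with an explicit
    scheme, so ``dt`` must respect the stability bound dt < px²/(4D).
    ``frame_interval`` is the camera read-out period (defaults to
    duration/100); it is distinct from the integration step.
    """

    D: float = 5.0  # μm²/s
    k: float = 0.5  # 1/s inside the aperture
    aperture_radius: float = 15.0  # μm
    duration: float = 50.0  # s
    dt: float = 1e-3  # s
    initial_density: float = 100.0  # fluorophores/μm²
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if self.D < 0 or self.k < 0:
            raise ValueError("D and k must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.initial_density < 0:
            raise ValueError("initial_density must be >= 0")
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be > 0")


@dataclass(frozen=True)
class CohortGroup:
    """Target summary statistics for one experimental condition."""

    median: float  # μm²
    sd: float  # μm²
    n_samples: int = 8
    cells_per_sample: int = 14
    outlier_offset: float = 0.0  # μm² added to every cell of one sample
    outlier_sample: int = 0  # index of the sample receiving the offset

    def __post_init__(self) -> None:
        if not (self.median > 0 and self.sd >= 0):
            raise ValueError("median must be > 0 and sd >= 0")
        if self.n_samples < 1 or self.cells_per_sample < 1:
            raise ValueError("need at least one sample and one cell")


CohortSpec = Mapping[str, CohortGroup]


# ---------------------------------------------------------------------------
# geometry and rendering helpers
# ---------------------------------------------------------------------------


def hex_lattice_points(
    lattice: LatticeSpec,
    shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    margin_um: float = 0.0,
) -> np.ndarray:
    """All hexagonal lattice sites (row_um, col_um) inside the field.

    Sites are kept if they lie at least ``margin_um`` inside the field
    boundary.
    """
    h, w = shape[0] * pixel_size, shape[1] * pixel_size
    p = lattice.pitch
    a1 = np.array([0.0, p])
    a2 = np.array([p * math.sqrt(3.0) / 2.0, p / 2.0])
    c, s = math.cos(lattice.angle), math.sin(lattice.angle)
    rot = np.array([[c, -s], [s, c]])
    a1, a2 = rot @ a1, rot @ a2
    nmax = int(math.ceil((h + w) / p)) + 2
    i = np.arange(-nmax, nmax + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pts = (
        np.asarray(lattice.origin, dtype=float)
        + ii[..., None] * a1
        + jj[..., None] * a2
    ).reshape(-1, 2)
    keep = (
        (pts[:, 0] >= margin_um)
        & (pts[:, 0] <= h - margin_um)
        & (pts[:, 1] >= margin_um)
        & (pts[:, 1] <= w - margin_um)
    )
    return pts[keep]


def _render_spots(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amps: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Sum of radial (super-)Gaussian spots, rendered in local windows.

    ``order=1`` is a plain Gaussian; ``order=2`` a steep-walled
    super-Gaussian exp(−(r²/2σ²)²).
    """
    canvas = np.zeros(shape, dtype=float)
    half = int(math.ceil(5.0 * sigma_px)) + 1
    amps = np.broadcast_to(np.asarray(amps, dtype=float), (len(centers_px),))
    for (r0, c0), amp in zip(centers_px, amps):
        r_lo, r_hi = int(math.floor(r0)) - half, int(math.floor(r0)) + half + 1
        c_lo, c_hi = int(math.floor(c0)) - half, int(math.floor(c0)) + half + 1
        r_lo, c_lo = max(r_lo, 0), max(c_lo, 0)
        r_hi, c_hi = min(r_hi, shape[0]), min(c_hi, shape[1])
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        u = (rr**2 + cc**2) / (2.0 * sigma_px**2)
        canvas[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-(u**order))
    return canvas


def _camera(
    rng: np.random.Generator,
    mean_photons: np.ndarray,
    read_noise: float = DEFAULT_READ_NOISE,
) -> np.ndarray:
    """Poisson shot noise plus additive Gaussian read noise.

    Values are offset-subtracted camera counts: the read noise is symmetric
    around zero, so dark pixels may go slightly negative (clipping them
    would bias every low-signal photometric measurement upward).
    """
    img = rng.poisson(np.clip(mean_photons, 0.0, None)).astype(float)
    if read_noise > 0:
        img += rng.normal(0.0, read_noise, size=img.shape)
    return img


def _disc_mask(
    shape: tuple[int, int], center_um: tuple[float, float], radius_um: float,
    pixel_size: float,
) -> np.ndarray:
    rr = (np.arange(shape[0]) + 0.5) * pixel_size - center_um[0]
    cc = (np.arange(shape[1]) + 0.5) * pixel_size - center_um[1]
    return rr[:, None] ** 2 + cc[None, :] ** 2 <= radius_um**2


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_dot_array_image(
    lattice: LatticeSpec,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    photons_per_molecule: float = 50.0,
    seed: int = 0,
    jitter_um: float = 0.0,
    read_noise: float = DEFAULT_READ_NOISE,
) -> tuple[Image, np.ndarray]:
    """Epi-fluorescence image of a hexagonal ligand-dot array.

    The molecular density map is ``amp_out`` plus Gaussian dots of FWHM
    ``lattice.dot_fwhm`` peaking at ``amp_in``; each pixel is Poisson with
    mean density × photons_per_molecule × pixel area. Returns the image and
    the true dot centroids (row_um, col_um), optionally jittered by an
    isotropic Gaussian of σ ``jitter_um``.
    """
    if not photons_per_molecule > 0:
        raise SimulationError("photons_per_molecule must be > 0")
    rng = np.random.default_rng(seed)
    sites = hex_lattice_points(lattice, shape, pixel_size)
    if len(sites) < 49:
        raise SimulationError(
            f"field holds only {len(sites)} lattice sites; need >= 49 (7x7)"
        )
    if jitter_um > 0:
        sites = sites + rng.normal(0.0, jitter_um, size=sites.shape)
    sigma_px = lattice.sigma / pixel_size
    density = lattice.amp_out + _render_spots(
        shape, sites / pixel_size, sigma_px, lattice.amp_in - lattice.amp_out
    )
    mean = density * photons_per_molecule * pixel_size**2
    img = Image(_camera(rng, mean, read_noise), pixel_size, channel="NaV")
    return img, sites


def make_calibration_image(
    spot_density: float,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    photons_per_molecule: float = 50.0,
    psf_fwhm: float = 0.3,
    seed: int = 0,
    read_noise: float = DEFAULT_READ_NOISE,
) -> tuple[Image, int]:
    """Sparse single-molecule frame for intensity calibration.

    Each spot is one molecule: an isotropic Gaussian PSF whose *integrated*
    intensity is ``photons_per_molecule``. The expected nearest-neighbour
    distance of a Poisson point process, 0.5/√ρ, must exceed 4× the PSF FWHM
    or the frame is useless for calibration and the call is rejected.
    """
    if spot_density < 0:
        raise SimulationError("spot_density must be >= 0")
    if spot_density > 0 and 0.5 / math.sqrt(spot_density) <= 4.0 * psf_fwhm:
        raise SimulationError(
            "spot density too high for single-molecule isolation "
            f"(mean NN distance {0.5 / math.sqrt(spot_density):.2f} μm "
            f"<= 4 x PSF FWHM {4 * psf_fwhm:.2f} μm)"
        )
    rng = np.random.default_rng(seed)
    h, w = shape[0] * pixel_size, shape[1] * pixel_size
    n = int(rng.poisson(spot_density * h * w))
    sigma_px = psf_fwhm * FWHM_TO_SIGMA / pixel_size
    mean = np.zeros(shape, dtype=float)
    if n > 0:
        pos = rng.uniform([0.0, 0.0], [h, w], size=(n, 2))
        # peak amplitude so the 2-D integral equals photons_per_molecule
        peak = photons_per_molecule / (2.0 * math.pi * (psf_fwhm * FWHM_TO_SIGMA) ** 2)
        mean = _render_spots(shape, pos / pixel_size, sigma_px, peak * pixel_size**2)
    img = Image(_camera(rng, mean, read_noise), pixel_size, channel="calibration")
    return img, n


def _patch_sites_under_cell(
    lattice: LatticeSpec,
    center_um: tuple[float, float],
    cell_radius: float,
    shape: tuple[int, int],
    pixel_size: float,
    n_patches: int,
) -> np.ndarray:
    sites = hex_lattice_points(lattice, shape, pixel_size)
    d = np.hypot(sites[:, 0] - center_um[0], sites[:, 1] - center_um[1])
    inside = sites[d <= cell_radius - lattice.dot_fwhm]
    if n_patches > len(inside):
        raise SimulationError(
            f"requested {n_patches} patches but only {len(inside)} lattice "
            "sites lie under the cell"
        )
    order = np.argsort(
        np.hypot(inside[:, 0] - center_um[0], inside[:, 1] - center_um[1])
    )
    return inside[order[:n_patches]]


def make_ricm_image(
    adhesion_class: str,
    lattice: LatticeSpec,
    cell_radius: float = 8.0,
    n_patches: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    noise_sd: float = RICM_NOISE_SD,
) -> tuple[Image, CellMask, np.ndarray]:
    """RICM image of one adherent cell: gray background, darker contact disc.

    ``uniform`` renders the whole disc at the tight-adhesion gray level;
    ``textured`` renders the disc at an intermediate proximal-membrane level
    with ``n_patches`` dark depressions at the lattice sites closest to the
    cell centre. Patches are steep-walled super-Gaussians so their dark
    footprint diameter stays ≈ ``dot_fwhm`` regardless of the detection
    threshold. Returns the image, the true contact mask and the true patch
    sites (row_um, col_um).
    """
    if adhesion_class not in ("uniform", "textured"):
        raise ValueError("adhesion_class must be 'uniform' or 'textured'")
    if adhesion_class == "uniform" and n_patches != 0:
        raise SimulationError("a uniform cell has no dark patches")
    if n_patches < 0:
        raise SimulationError("n_patches must be >= 0")
    rng = np.random.default_rng(seed)
    center = (shape[0] * pixel_size / 2.0, shape[1] * pixel_size / 2.0)
    disc = _disc_mask(shape, center, cell_radius, pixel_size)
    level = (
        RICM_TIGHT_ADHESION if adhesion_class == "uniform" else RICM_PROXIMAL_MEMBRANE
    )
    img = np.full(shape, RICM_BACKGROUND, dtype=float)
    img[disc] = level
    sites = np.zeros((0, 2))
    if adhesion_class == "textured" and n_patches > 0:
        sites = _patch_sites_under_cell(
            lattice, center, cell_radius, shape, pixel_size, n_patches
        )
        depth = level - RICM_PATCH
        img -= _render_spots(
            shape,
            sites / pixel_size,
            lattice.sigma / pixel_size,
            depth,
            order=2,
        )
    img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return (
        Image(img, pixel_size, channel="RICM"),
        CellMask(disc, pixel_size),
        sites,
    )


def make_cluster_image(
    mode: str,
    lattice: LatticeSpec,
    mask: CellMask,
    cluster_amp: float = 150.0,
    diffuse_amp: float = 20.0,
    n_free_clusters: int = 0,
    seed: int = 0,
    amp_jitter: float = 0.3,
    cluster_fwhm: float | None = None,
    read_noise: float = DEFAULT_READ_NOISE,
) -> tuple[Image, np.ndarray]:
    """TIRF image of receptor micro-clusters under a cell.

    ``patterned`` places one cluster on every lattice site under the cell
    (emulating receptor recruitment onto the ligand dots, so clusters are
    dot-sized); ``homogeneous`` scatters ``n_free_clusters`` uniformly under
    the cell at the diffraction-scale 0.4 μm FWHM typical of micro-clusters
    on unpatterned substrates. Cluster peak amplitudes are log-normally
    jittered and statistically independent of the underlying ligand lattice.
    ``diffuse_amp`` adds a membrane-level photon background inside the mask.
    """
    if mode not in ("patterned", "homogeneous"):
        raise ValueError("mode must be 'patterned' or 'homogeneous'")
    rng = np.random.default_rng(seed)
    shape = mask.mask.shape
    px = mask.pixel_size
    if cluster_fwhm is not None:
        fwhm = cluster_fwhm
    else:
        fwhm = lattice.dot_fwhm if mode == "patterned" else 0.4
    # keep clusters a cluster-radius away from the mask edge
    dist_um = ndimage.distance_transform_edt(mask.mask) * px
    interior = dist_um > fwhm
    if mode == "patterned":
        sites = hex_lattice_points(lattice, shape, px)
        idx = np.clip(np.round(sites / px - 0.5).astype(int), 0, None)
        idx[:, 0] = np.minimum(idx[:, 0], shape[0] - 1)
        idx[:, 1] = np.minimum(idx[:, 1], shape[1] - 1)
        centers = sites[interior[idx[:, 0], idx[:, 1]]]
    else:
        rows, cols = np.nonzero(interior)
        if len(rows) == 0:
            raise SimulationError("mask interior too small for clusters")
        pick = rng.choice(len(rows), size=n_free_clusters, replace=True)
        centers = (np.stack([rows[pick], cols[pick]], axis=1) + 0.5) * px
    amps = cluster_amp * rng.lognormal(0.0, amp_jitter, size=len(centers))
    mean = _render_spots(
        shape, centers / px, fwhm * FWHM_TO_SIGMA / px, amps
    )
    mean += diffuse_amp * mask.mask
    img = Image(_camera(rng, mean, read_noise), px, channel="TCR")
    return img, centers


def make_actin_image(
    organization: str,
    mask: CellMask,
    clearance_target: float = 1.0,
    seed: int = 0,
    lattice: LatticeSpec | None = None,
    base_amp: float = 200.0,
    circle_diameter: float = 1.2,
    read_noise: float = DEFAULT_READ_NOISE,
) -> Image:
    """TIRF image of F-actin with a controlled clearance statistic.

    The noiseless radial profile is shaped per ``organization`` (flat,
    centre-depleted peripheral ring, or dots on the lattice sites), then the
    central circle of ``circle_diameter`` is rescaled so the clearance ratio
    I_center/I_rest of the noiseless image equals ``clearance_target``
    exactly; photon noise perturbs the measured value by a few percent.
    """
    if organization not in ("ring", "homogeneous", "dots"):
        raise ValueError("organization must be 'ring', 'homogeneous' or 'dots'")
    if clearance_target < 0:
        raise SimulationError("clearance_target must be >= 0")
    rng = np.random.default_rng(seed)
    shape = mask.mask.shape
    px = mask.pixel_size
    rr = (np.arange(shape[0]) + 0.5) * px - mask.centroid_um[0]
    cc = (np.arange(shape[1]) + 0.5) * px - mask.centroid_um[1]
    r = np.hypot(rr[:, None], cc[None, :])
    rmax = r[mask.mask].max()
    if organization == "homogeneous":
        profile = np.ones(shape)
    elif organization == "ring":
        profile = 0.2 + 0.8 * (r / rmax) ** 2
    else:
        if lattice is None:
            lattice = LatticeSpec()
        sites = hex_lattice_points(lattice, shape, px)
        profile = 0.3 + _render_spots(
            shape, sites / px, lattice.sigma / px, 1.0
        )
    mean = base_amp * profile * mask.mask
    circle = _disc_mask(shape, mask.centroid_um, circle_diameter / 2.0, px)
    if not (circle & mask.mask).any():
        raise SimulationError("central circle does not intersect the mask")
    rest = mask.mask & ~circle
    i_center = mean[circle & mask.mask].mean()
    i_rest = mean[rest].mean()
    if i_center > 0:
        mean = np.where(
            circle & mask.mask, mean * clearance_target * i_rest / i_center, mean
        )
    img = _camera(rng, mean, read_noise)
    return Image(img, px, channel="actin")


def make_cpb_movie(
    params: CPBParams,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    photons_per_fluor: float = 20.0,
    read_noise: float = DEFAULT_READ_NOISE,
) -> ImageStack:
    """Continuous-photobleaching movie of a fluid supported lipid bilayer.

    Integrates the reaction–diffusion equation ∂c/∂t = D∇²c − k·χ_aperture·c
    with an explicit 5-point scheme and no-flux borders; fluorophores outside
    the aperture (the partially closed diaphragm) are never illuminated and
    replenish the bleached zone by diffusion, producing the bright rim at the
    aperture edge whose decay length λ = √(D/k) encodes D. Frames record
    Poisson photon counts inside the aperture only.
    """
    if params.D > 0 and params.dt >= pixel_size**2 / (4.0 * params.D):
        raise SimulationError(
            f"explicit scheme unstable: dt={params.dt} >= "
            f"px²/(4D)={pixel_size ** 2 / (4 * params.D):.2e}"
        )
    h, w = shape[0] * pixel_size, shape[1] * pixel_size
    if 2.0 * params.aperture_radius >= min(h, w):
        raise SimulationError("aperture does not fit inside the field")
    rng = np.random.default_rng(seed)
    center = (h / 2.0, w / 2.0)
    aperture = _disc_mask(shape, center, params.aperture_radius, pixel_size)
    c = np.full(shape, params.initial_density, dtype=float)
    frame_interval = (
        params.frame_interval
        if params.frame_interval is not None
        else params.duration / 100.0
    )
    rec_every = max(1, int(round(frame_interval / params.dt)))
    n_steps = int(round(params.duration / params.dt))
    alpha = params.D * params.dt / pixel_size**2
    decay = params.k * params.dt
    px_area = pixel_size**2

    frames: list[np.ndarray] = []
    times: list[float] = []

    def record(t: float) -> None:
        mean = c * photons_per_fluor * px_area
        frame = _camera(rng, mean, read_noise)
        frame[~aperture] = 0.0
        frames.append(frame)
        times.append(t)

    record(0.0)
    for step in range(1, n_steps + 1):
        cp = np.pad(c, 1, mode="edge")
        lap = (
            cp[:-2, 1:-1] + cp[2:, 1:-1] + cp[1:-1, :-2] + cp[1:-1, 2:] - 4.0 * c
        )
        c += alpha * lap
        c -= decay * np.where(aperture, c, 0.0)
        if step % rec_every == 0:
            record(step * params.dt)
    return ImageStack(
        np.stack(frames), np.asarray(times), pixel_size, channel="SLB"
    )


def lognormal_params(median: float, sd: float) -> tuple[float, float]:
    """(μ, σ) of the log-normal with the given median and standard deviation.

    median = e^μ and sd² = m²·e^{σ²}(e^{σ²}−1), solved in closed form.
    """
    if sd == 0:
        return math.log(median), 0.0
    ratio2 = (sd / median) ** 2
    y = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * ratio2))
    return math.log(median), math.sqrt(math.log(y))


def make_cohort(spec: CohortSpec, seed: int = 0):
    """Per-cell area table for one or more conditions.

    Areas are log-normal with the target median and SD of each condition;
    one sample per condition may carry an additive offset to emulate an
    outlier substrate. Returns a pandas DataFrame with columns
    ``condition, sample_id, cell_id, area_um2``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    records = []
    for condition, grp in spec.items():
        mu, sigma = lognormal_params(grp.median, grp.sd)
        for s in range(grp.n_samples):
            areas = rng.lognormal(mu, sigma, size=grp.cells_per_sample)
            if grp.outlier_offset != 0.0 and s == grp.outlier_sample:
                areas = areas + grp.outlier_offset
            for i, a in enumerate(areas):
                records.append(
                    {
                        "condition": condition,
                        "sample_id": f"{condition}-s{s}",
                        "cell_id": f"{condition}-s{s}-c{i}",
                        "area_um2": float(a),
                    }
                )
    return pd.DataFrame.from_records(records)
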