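# Methods

This note records the models behind each analysis stage, the tunable
parameters and their defaults, what the synthetic generator does and does
not emulate, and the numerical choices made where the underlying recipes
left the design open.

## Imaging model and conventions

All lengths are micrometres; pixel coordinates follow the scikit-image
`(row, col)` convention with the physical position of index *i* taken as
*i*·pixel_size. The default pixel size is 0.16 μm/px (a 100× objective on a
16 μm-pixel EMCCD); every function accepts another value.

The camera model is Poisson shot noise on the expected photon count plus
additive Gaussian read noise (default σ = 2 photons rms). Values are
offset-subtracted counts, so dark pixels can be slightly negative; clipping
at zero would bias every low-signal photometric measurement upward (this
matters for single-molecule calibration and for the late, almost fully
bleached frames of photobleaching movies). EM-gain excess noise is not
modelled.

## Synthetic substrate and cells (`simgen`)

* **Dot arrays.** Molecular density is a hexagonal lattice of isotropic
  Gaussian dots (FWHM = 2√(2 ln 2)·σ) on a constant background,
  defaults 2 μm pitch, 0.75 μm FWHM, 40 molecules/μm² at the dot peak and
  10 between dots. Expected photons per pixel = density ×
  photons_per_molecule × pixel area. The default photon budget is 50
  recorded photons per molecule: epi-fluorescence of a bright organic dye
  easily reaches this, and below ~30 photons the Cramér–Rao bound on dot
  localization exceeds 0.2 px per axis, at which point no estimator can
  place ≥ 98% of dots within half a pixel — the regime the detection
  contract assumes.
* **Calibration frames.** Isolated single-molecule PSFs (Gaussian,
  0.3 μm FWHM) whose integrated intensity is exactly one molecule. The
  generator refuses densities at which the mean nearest-neighbour distance
  of a Poisson process, 0.5/√ρ, falls below 4 PSF FWHM.
* **RICM cells.** Grayscale absorption-like contrast only — interference
  physics is not simulated. Conventions (fractions of full scale):
  background 0.5, tight adhesion 0.15, proximal (non-adherent) membrane
  0.35, dark patches 0.10, Gaussian noise σ = 0.02. Only the ordering
  patch < adhesion < membrane < background is meaningful. Textured cells
  are rendered at the membrane level with patches at the lattice sites
  closest to the cell centre; patches are order-2 super-Gaussians because a
  plain Gaussian's thresholded footprint varies strongly with depth, while
  the steep-walled profile keeps the dark footprint ≈ one dot FWHM for any
  reasonable threshold — which is what the size window of the classifier
  assumes.
* **Cluster images.** Patterned mode puts one cluster (FWHM = dot FWHM) on
  every lattice site under the cell; homogeneous mode scatters clusters of
  0.4 μm FWHM (diffraction-scale, as on unpatterned substrates) uniformly
  under the cell. Peak amplitudes are log-normally jittered (σ = 0.3) and
  independent of the lattice, reproducing the observation that dim dots can
  carry bright clusters and vice versa.
* **Photobleaching movies.** Explicit 5-point finite-difference integration
  of ∂c/∂t = D∇²c − k·χ_aperture·c with no-flux borders; the scheme refuses
  dt ≥ px²/(4D). Frames record photons only inside the aperture. The
  integration step is distinct from the camera frame interval (default
  duration/100).
* **Cohorts.** Cell areas are log-normal — printed spreads are ~50% of the
  means with strictly positive areas, which a normal law cannot produce.
  Given target median m and SD s, μ = ln m and σ² = ln y with
  y = (1 + √(1 + 4(s/m)²))/2 solves the moment equations exactly. One
  sample per condition may carry an additive offset to emulate an outlier
  substrate.

What the generator does **not** emulate: optical aberrations and PSF
asymmetry, EM-gain noise cascades, RICM interference fringes, membrane
topography dynamics, cluster movement, uneven illumination, and
sample-to-sample density variation (cohort samples are exchangeable unless
an offset is planted). Passing tests therefore demonstrate correctness of
the estimators under idealized optics and photon statistics, not robustness
to every artefact of real microscopy.

## Substrate QC (`substrate`)

Detection: difference of Gaussians at the dot scale (σ and 1.6σ), maxima
above median + 5 robust noise sigmas of the filtered image, minimum
separation pitch/2, sub-pixel refinement by intensity-weighted centre of
mass in a 1.5×FWHM window. The noise sigma is estimated from the lower tail
(median − 15.9th percentile) because the dots themselves contaminate a
two-sided MAD when they cover a large area fraction; 5σ rather than 3σ
because a 256² field contains ~10⁴ effective maxima, and a 3σ cut would
admit hundreds of false dots (and a flat field would never report "no
dots"). Maxima whose refinement window would be clipped by the field border
are excluded.

The median dot pools pixels from all detected dots into 1-px radial bins
out to pitch/2 and takes the per-bin median — one hot pixel or outlier dot
cannot move it. FWHM: baseline = mean of the outer 25% of bins, half level
crossed by linear interpolation, FWHM = 2 × crossing radius. I_max/I_min
are the profile peak and that baseline. A peak is required to exceed the
baseline by 3× the SD of the outer bins, otherwise "no peak".

Pitch: the median of the pooled distances to the 6 nearest neighbours (the
full hexagonal coordination shell). The plain nearest-neighbour median —
the *minimum* of six noisy shell distances — is biased low by ~4% already
at 0.05 μm positional jitter, while the shell median is exact on a perfect
lattice and unbiased under symmetric jitter. The plain statistic remains
available as `median_nn_distance`; a coefficient of variation of
nearest-neighbour distances above 0.2 flags a non-lattice point set.

Calibration: spots detected at the PSF scale, isolation filter at 4×FWHM,
integrated intensity over a disc of radius 1.5×FWHM minus the median of a
[1.5, 2.5]×FWHM annulus; the factor is the median over ≥ 10 isolated spots
(fewer is an invalid calibration), dispersion = MAD/median. Density =
areal intensity / factor.

## Photobleaching analysis (`photobleach`)

The fit model is the 1-D quasi-steady reaction–diffusion balance
I(x) = B·e^(−x/λ) + c with D = λ²k; the identity D = λ²k holds exactly for
the returned fields. k is fit (A·e^(−kt) + c, least squares) on the mean
trace of the central 25%-by-radius of the aperture, where rim supply is
negligible as long as the aperture radius is several λ. The edge profile
bins pixels by distance inward from the aperture edge (distance transform,
1-px bins, shifted one pixel because boundary pixels sit at EDT distance 1)
and averages the last 20% of frames; it is flagged "early" if the centre
has not yet lost 90% of its initial intensity. λ is initialised from the
1/e crossing of the plateau-subtracted profile (the deep interior sits on a
bleached plateau, not at zero) and fit over x ∈ [0, 5λ₀]. The curvature
correction for a circular aperture is omitted and a warning is attached
whenever the aperture radius is < 5λ.

Two validity constraints worth knowing: (i) the reservoir outside the
aperture must be large — on a small simulated field the depletion halo
(~√(4Dt)) reaches the no-flux border and inflates λ (a 1-D experiment with
a 5.5 μm reservoir biased D by +37%; with ≳ 20 μm it was exact). CPB
example movies therefore use a 0.32 μm/px, 82 μm field around the 15 μm
aperture, which also keeps the explicit scheme fast. (ii) Protein-scale
diffusion (≪ 0.001 μm²/s) is far below what CPB can quantify and is out of
scope.

## Adhesion (`adhesion`)

Local variance in a disc of radius 4 px → Otsu threshold → hole filling →
erosion by (radius − 1) px → the component (≥ 20 μm²) whose centroid is
closest to the image centre. The erosion radius undoes the outward smear of
the variance window; calibrated on discs of known radius, the residual area
bias is < 2% for cell radii 4–12 μm. Because Otsu always splits something,
segmentation demands real structure: the foreground of the variance map
must exceed 3× the background variance, else "no cell". Bright RICM pixels
(non-adhered membrane, organelles) play no role in this path.

Texture classification: candidate patches are connected regions darker than
both the outside background (mean − 2 SD) and the cell's own level
(median − 3×1.4826·MAD of in-mask pixels; the in-mask reference is required
because the whole contact zone is already far darker than the outside
background, and 3 rather than 2 robust sigmas keeps the Gaussian noise tail
from seeding spurious specks). A candidate qualifies if its equivalent
diameter is within [0.5, 1.5]× dot FWHM *and* its nearest other qualifying
candidate lies within [0.7, 1.3]× pitch — distance compatibility only, not
full lattice geometry. Textured ⇔ at least 7 qualifying patches; the
boundary is exact (6 → uniform, 7 → textured) across pitches 1–4 μm.

## Micro-clusters (`clusters`)

Parameters: size cutoff 10 px, convergence step 0.05, trim 0.8,
8-connectivity. T₀ is the mean intensity under the cell excluding
provisionally bright pixels (> mean + 2 SD), iterated once. The size cutoff
acts as a merge-splitting trigger: a component larger than the cutoff has
its local threshold raised in steps of conv_step × (peak − T₀); if it
splits, the pieces are processed recursively from the separating level, and
if the threshold reaches the peak without ever splitting, the component is
one genuinely large cluster and is kept whole at its entry threshold.
(Raising thresholds until every piece is ≤ 10 px was rejected: it reduces
every isolated bright cluster to a near-peak cap that the trim then erases,
and collapses the cluster count.) The trim keeps the top trim_step fraction
of each component's dynamic range — pixels ≥ T_local + (1 − 0.8)·(peak −
T_local) — retaining the piece that contains the peak. Under this reading a
Gaussian cluster's trimmed footprint is amplitude-independent (the region
above 20% of its own excess), which is what makes the count stable under
10–25% parameter perturbations; the complementary reading collapses to
zero clusters at trim × 1.25 = 1.0. Two guards: trimmed pieces < 2 px are
discarded, and components whose peak is below T₀ + 5 robust background SDs
are treated as shot noise (a mean-level threshold necessarily places half
the background above itself).

Colocalization rasterizes discs of one dot-FWHM diameter at the dot
centroids and reports per-cluster overlap fractions plus their
area-weighted mean; for uniformly scattered clusters this converges to the
dot-mask area fraction π(FWHM/2)² / (√3/2 · p²) ≈ 0.13 at the default
geometry. Size histograms are normalized by total cluster count. Line
profiles sample two co-registered channels along a segment, averaged over a
configurable width, each normalized to its own maximum.

## Morphometrics (`morphometry`)

Clearance = mean intensity in a central circle of diameter 1.2 μm
(read as diameter, not radius; flagged for sensitivity) over the mean in
the rest of the mask. The circle is centred on the mask centroid, moved to
the nearest interior point for concave cells, and must fit inside the mask.
The centralization index uses the same ratio with an adaptive circle of one
third of the cell's equivalent diameter, and every result carries a
`definition_tag` naming the formula, since several incompatible
centralization measures circulate in the field. Both ratios are invariant
under pure gain rescaling and approach 1 on spatially unstructured images.

## Statistics (`stats`)

Summaries use the n−1 sample SD and SEM = sd/√n. Mann–Whitney is two-tailed
with the exact null when the smaller group has ≤ 8 observations and there
are no ties, else the normal approximation with midrank tie correction and
continuity correction (delegated to scipy; an independent brute-force
permutation oracle lives in the test suite). Stars: *** P ≤ 1e-7,
** P ≤ 1e-4, * P ≤ 0.01, NS above — the Methods-style convention; a
figure-caption convention (NS at P ≥ 0.05) is available via
`stars(p, convention="figures")` because both appear in practice. Effect
size is the difference of medians. Outlier vetting compares each sample to
the pooled cells of all *other* samples of its condition (leave-one-out —
including the tested sample would dilute its own deviation) and rejects at
p < 1e-4 in a single pass with no re-iteration; conditions with one sample
pass through with a warning. No multiple-testing correction is applied
across condition pairs.

## Problem sizes

The test suite and the acceptance script run on 256² (or smaller) fields,
single cells of 4–12 μm radius, cluster images with ~30–50 clusters,
cohorts of ~100–500 cells, 150–1000-replicate null simulations, and one
photobleaching movie at the reference conditions (D = 5 μm²/s, k = 0.5/s,
15 μm aperture, 50 s, 256² grid at 0.32 μm/px, dt = 4 ms). These sizes give
sampling errors comfortably inside every stated tolerance while the whole
suite completes in well under a minute of compute.

## Known limitations

* RICM gray levels are conventions; only their ordering is physical.
* The cluster-segmentation recipe is a reconstruction of a plugin whose
  full source was never published; the trim semantics and the
  merge-splitting reading of the size cutoff are the two open
  interpretations, chosen as documented above and validated against the
  count-robustness property the original authors reported.
* The CPB fit ignores aperture curvature (flagged below 5λ) and assumes a
  quasi-stationary rim; movies shorter than ~5/k trigger the early-window
  flag.
* The centralization index is one of several definitions in circulation;
  results are only comparable within a fixed `definition_tag`.
* `estimate_pitch` assumes an approximately hexagonal lattice; for
  arbitrary point sets use `median_nn_distance` and `nn_distance_cv`.
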