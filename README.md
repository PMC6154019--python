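# dotsynapse

Image quantification for T cells interacting with nano-patterned
antigen-presenting substrates: hexagonal arrays of sub-micron anti-CD3
ligand dots (2 μm pitch, ~750 nm FWHM) surrounded by a fluid supported
lipid bilayer (SLB). The package covers every quantitative step of such a
study — substrate quality control, bilayer-fluidity measurement, RICM
adhesion analysis, receptor micro-cluster segmentation, actin/receptor
morphometrics, and cohort statistics — together with a synthetic-microscopy
generator that produces every input with known ground truth, so the entire
pipeline is testable without any raw data.

It is written for quantitative microscopists and immunologists who build or
analyze dot-patterned "artificial antigen-presenting cell" substrates and
want reproducible, scriptable versions of the standard ImageJ-era recipes.

## What it computes

**Substrate QC** (`dotsynapse.substrate`). Ligand dots are detected by a
difference-of-Gaussians band-pass with a robust automatic threshold and
sub-pixel refinement. A *median dot* — the pooled per-bin median radial
profile — yields the dot size as the full width at half maximum (FWHM) and
the contrast I_max/I_min (profile peak over baseline). The lattice pitch p
is estimated from the first coordination shell of the centroids. Absolute
molecular densities come from single-molecule calibration: on a sparse
substrate each fluorescent spot is one molecule, so the median integrated
spot intensity converts areal intensity to molecules/μm².

**Bilayer fluidity** (`dotsynapse.photobleach`). Under continuous
illumination through a partially closed diaphragm, bleaching (rate k) and
diffusion (constant D) balance into a bright rim at the aperture edge with
profile I(x) = B·e^(−x/λ) + c, λ = √(D/k). The analysis fits k from the
central decay, λ from the late-time edge profile, and reports D = λ²k.

**Adhesion** (`dotsynapse.adhesion`). The cell-substrate contact zone is
segmented from RICM images by a spatial variance filter (radius 4 px) +
Otsu threshold; adhesion is classified *textured* when ≥ 7 dark patches
compatible with the dot lattice in size ([0.5, 1.5]×FWHM) and spacing
([0.7, 1.3]×p) are found, else *uniform*.

**Micro-clusters** (`dotsynapse.clusters`). TCR/ZAP-70 clusters are
segmented by iterative thresholding: an initial threshold at the mean
diffuse intensity under the cell, local threshold raising (convergence
step 0.05) to split merged components above a 10-px size cutoff, and a
final trim (0.8) of each cluster's dynamic range. Cluster counts are
robust to 10–25% parameter changes. Derived outputs: normalized
cluster-size histograms, cluster–dot colocalization, paired line profiles.

**Morphometrics** (`dotsynapse.morphometry`). F-actin clearance
I_center/I_rest over a central 1.2 μm circle (< 1 for a peripheral actin
ring) and a receptor centralization index (≈ 1 when no cSMAC forms).

**Statistics** (`dotsynapse.stats`). Two-tailed Wilcoxon–Mann–Whitney
comparisons (exact for small tie-free samples), significance stars
(*** P ≤ 1e-7, ** P ≤ 1e-4, * P ≤ 0.01, else NS), effect size as the
difference of medians, and leave-one-out exclusion of outlier samples at
p < 1e-4.

**Synthetic data** (`dotsynapse.simgen`). Physically motivated generators
for dot arrays, calibration frames, RICM cells, cluster/actin TIRF images,
reaction–diffusion photobleaching movies and log-normal cell-area cohorts —
each returning its exact ground truth.

## Worked example

```python
import numpy as np
from dotsynapse import simgen, substrate, adhesion, clusters, morphometry, stats
from dotsynapse.simgen import LatticeSpec, CohortGroup

lat = LatticeSpec()                 # 2 um pitch, 0.75 um dots, 40/10 mol/um2
img, truth = simgen.make_dot_array_image(lat, seed=1)
cal, _ = simgen.make_calibration_image(0.05, shape=(256, 256), seed=2)

qc = substrate.characterize(img)
factor = substrate.calibrate_intensity(cal)
d_in = substrate.intensity_to_density(qc.i_max / img.pixel_size**2, factor)
d_out = substrate.intensity_to_density(qc.i_min / img.pixel_size**2, factor)
print(f"dots: n={len(qc.centroids_um)}  FWHM={qc.fwhm_um:.2f} um  "
      f"pitch={qc.pitch_um:.2f} um  density in/out={d_in:.1f}/{d_out:.1f} per um2")

ricm, _, _ = simgen.make_ricm_image("textured", lat, cell_radius=8.0,
                                    n_patches=9, seed=3)
mask = adhesion.segment_cell_ricm(ricm)
cls = adhesion.classify_adhesion(ricm, mask)
print(f"cell: area={mask.area_um2:.0f} um2  adhesion={cls.label} "
      f"({cls.n_qualifying_patches} patches)")

tirf, _ = simgen.make_cluster_image("patterned", lat, mask, seed=4)
cs = clusters.segment_clusters(tirf, mask)
_, overlap = clusters.colocalize(cs, qc.centroids_um, lat.dot_fwhm)
cz = morphometry.centralization_index(tirf, mask)
print(f"clusters: n={len(cs)}  median area={np.median(cs.areas_um2):.2f} um2  "
      f"on-dot overlap={overlap:.2f}  centralization={cz.index:.2f}")

cohort = simgen.make_cohort({
    "patterned":   CohortGroup(170.0, 95.0, 12, 20),
    "homogeneous": CohortGroup(130.0, 57.0, 12, 20),
}, seed=5)
cohort, rejected = stats.exclude_outlier_samples(cohort)
a = cohort.loc[cohort.condition == "patterned", "area_um2"]
b = cohort.loc[cohort.condition == "homogeneous", "area_um2"]
r = stats.mann_whitney(a, b)
print(f"cohort: U={r.u_statistic:.0f}  p={r.p_value:.2g} {r.stars}  "
      f"effect size={r.effect_size:.0f} um2  (n={r.n_a} vs {r.n_b})")
```

prints

```
dots: n=460  FWHM=0.76 um  pitch=2.00 um  density in/out=38.7/10.8 per um2
cell: area=197 um2  adhesion=textured (9 patches)
clusters: n=43  median area=0.79 um2  on-dot overlap=0.56  centralization=1.06
cohort: U=36969  p=7.6e-08 ***  effect size=31 um2  (n=240 vs 240)
```

The dot array built at 40/10 molecules/μm² is recovered at 38.7/10.8; the
textured cell shows its planted 9 lattice-spaced dark patches; the
patterned TIRF image yields dot-coincident clusters with no centralization
(index ≈ 1); and the two cell-area cohorts built at medians 170 vs 130 μm²
differ significantly with a median-difference effect size near the true
40 μm² gap.

A command-line interface mirrors the library
(`dotsynapse simgen|substrate|cpb|adhesion|clusters|morpho|stats|pipeline`);
`dotsynapse pipeline --manifest cells.csv` chains RICM segmentation →
adhesion classification → cluster segmentation → morphometrics over matched
per-cell images and writes one CSV row per cell plus a JSON run manifest.

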