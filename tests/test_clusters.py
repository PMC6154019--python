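"""Iterative-threshold micro-cluster segmentation and its derived measures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label

from conftest import PX, gaussian_spot
from dotsynapse import clusters, simgen
from dotsynapse.clusters import (
    Cluster,
    ClusterSet,
    EmptyMaskError,
    NoClustersError,
    cluster_size_histogram,
    colocalize,
    line_profile,
    segment_clusters,
)
from dotsynapse.core import CellMask, Image


def make_cluster_set(areas, mask=None):
    """Hand-built ClusterSet for histogram/bookkeeping tests."""
    if mask is None:
        m = np.zeros((64, 64), dtype=bool)
        m[8:56, 8:56] = True
        mask = CellMask(m, PX)
    cl = tuple(
        Cluster(np.zeros((2, 2), dtype=int), a, (1.0, 1.0), 10.0, 5.0)
        for a in areas
    )
    return ClusterSet(cl, 10, 0.05, 0.8, mask)


@pytest.fixture(scope="module")
def patterned(lattice, cell_mask):
    img, truth = simgen.make_cluster_image("patterned", lattice, cell_mask, seed=2)
    return img, truth, cell_mask


class TestSegmentation:
    def test_single_spot_one_cluster(self):
        m = np.zeros((96, 96), dtype=bool)
        m[8:88, 8:88] = True
        mask = CellMask(m, PX)
        rng = np.random.default_rng(0)
        px = rng.poisson(20.0, (96, 96)).astype(float)
        px += gaussian_spot((96, 96), (48.0, 40.0), 2.0, 200.0)
        cs = segment_clusters(Image(px, PX), mask)
        assert len(cs) == 1
        assert cs.clusters[0].centroid_um == pytest.approx(
            (48 * PX, 40 * PX), abs=2 * PX
        )

    def test_truth_recovery_patterned(self, patterned):
        img, truth, mask = patterned
        cs = segment_clusters(img, mask)
        assert abs(len(cs) - len(truth)) <= 2
        d, _ = cKDTree(truth).query(cs.centroids_um)
        assert (d < 0.75 / 2.0).mean() > 0.95

    @pytest.mark.parametrize("factor,tol", [(0.9, 0.10), (1.1, 0.10),
                                            (0.75, 0.25), (1.25, 0.25)])
    def test_parameter_robustness(self, patterned, factor, tol):
        img, truth, mask = patterned
        base = len(segment_clusters(img, mask))
        n = len(
            segment_clusters(
                img, mask,
                size_cutoff_px=max(1, round(10 * factor)),
                conv_step=0.05 * factor,
                trim_step=min(1.0, 0.8 * factor),
            )
        )
        assert abs(n - base) / base <= tol

    def test_trim_monotonicity(self, patterned):
        # retaining a larger fraction of the dynamic range never shrinks
        # the total clustered area
        img, _, mask = patterned
        areas = [
            segment_clusters(img, mask, trim_step=t).areas_um2.sum()
            for t in (0.6, 0.8, 0.95)
        ]
        assert areas[0] <= areas[1] <= areas[2]

    def test_mask_required(self, patterned):
        img, _, _ = patterned
        tiny = np.zeros((256, 256), dtype=bool)
        tiny[100:103, 100:103] = True
        with pytest.raises(EmptyMaskError):
            segment_clusters(img, CellMask(tiny, PX))

    def test_oracle_equivalence_well_separated(self):
        # no component exceeds the cutoff: output equals plain connected
        # components above T0 followed by the trim
        m = np.zeros((128, 128), dtype=bool)
        m[4:124, 4:124] = True
        mask = CellMask(m, PX)
        px = np.zeros((128, 128))  # noiseless dark background
        centers = [(20, 20), (20, 60), (20, 100), (60, 20), (60, 60),
                   (60, 100), (100, 20), (100, 60), (100, 100)]
        for r, c in centers:
            px += gaussian_spot((128, 128), (r, c), 1.0, 50.0)
        img = Image(px, PX)
        cs = segment_clusters(img, mask)

        # independent oracle
        vals = img.pixels[mask.mask]
        bright = vals > vals.mean() + 2 * vals.std()
        t0 = vals[~bright].mean()
        lab = sk_label((img.pixels > t0) & mask.mask, connectivity=2)
        assert lab.max() == len(centers)
        oracle_areas = []
        for i in range(1, lab.max() + 1):
            comp = lab == i
            assert comp.sum() <= 50  # sanity: spots are small
            peak = img.pixels[comp].max()
            level = t0 + (1 - 0.8) * (peak - t0)
            trimmed = comp & (img.pixels >= level)
            oracle_areas.append(trimmed.sum() * PX**2)
        assert len(cs) == len(centers)
        assert sorted(np.round(cs.areas_um2, 6)) == sorted(
            np.round(oracle_areas, 6)
        )


class TestHistogram:
    def test_hand_counted_fractions(self):
        cs = make_cluster_set([0.1, 0.1, 0.5, 0.9])
        h = cluster_size_histogram(cs, [0.0, 0.25, 0.75, 1.5])
        assert np.allclose(h.fraction, [0.5, 0.25, 0.25])

    def test_single_cluster(self):
        cs = make_cluster_set([0.3])
        h = cluster_size_histogram(cs, [0.0, 0.25, 0.75, 1.5])
        assert h.fraction.sum() == pytest.approx(1.0)
        assert h.fraction[1] == 1.0

    def test_empty_raises(self, cell_mask):
        with pytest.raises(NoClustersError):
            cluster_size_histogram(
                ClusterSet((), 10, 0.05, 0.8, cell_mask), [0, 1]
            )

    @given(st.lists(st.floats(0.01, 2.0), min_size=1, max_size=40))
    def test_fractions_sum_to_one(self, areas):
        h = cluster_size_histogram(make_cluster_set(areas), [0.0, 0.5, 1.0, 2.5])
        assert h.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_patterned_clusters_larger_than_homogeneous(
        self, lattice, cell_mask
    ):
        imgs = {
            "patterned": simgen.make_cluster_image(
                "patterned", lattice, cell_mask, seed=4
            )[0],
            "homogeneous": simgen.make_cluster_image(
                "homogeneous", lattice, cell_mask, n_free_clusters=40, seed=5
            )[0],
        }
        med = {
            k: np.median(segment_clusters(v, cell_mask).areas_um2)
            for k, v in imgs.items()
        }
        assert med["patterned"] > 1.5 * med["homogeneous"]


class TestColocalization:
    def test_constructed_on_dots(self, lattice, cell_mask):
        img, truth = simgen.make_cluster_image(
            "patterned", lattice, cell_mask, seed=6, cluster_fwhm=0.3
        )
        cs = segment_clusters(img, cell_mask)
        _, summary = colocalize(cs, truth, lattice.dot_fwhm)
        assert summary >= 0.9

    def test_random_clusters_match_area_fraction(self, lattice, cell_mask):
        sites = simgen.hex_lattice_points(lattice, cell_mask.mask.shape, PX)
        summaries = []
        for seed in (7, 8, 9):
            img, _ = simgen.make_cluster_image(
                "homogeneous", lattice, cell_mask, n_free_clusters=150,
                seed=seed, cluster_fwhm=0.3,
            )
            cs = segment_clusters(img, cell_mask)
            _, s = colocalize(cs, sites, lattice.dot_fwhm)
            summaries.append(s)
        # expected fraction = dot-disc area / hexagonal unit-cell area
        expect = (np.pi * (0.75 / 2) ** 2) / (np.sqrt(3) / 2 * 2.0**2)
        assert np.mean(summaries) == pytest.approx(expect, abs=0.05)

    def test_no_overlap_case(self, cell_mask):
        cl = Cluster(np.array([[10, 10], [10, 11]]), 2 * PX**2,
                     (10 * PX, 10 * PX), 5.0, 5.0)
        cs = ClusterSet((cl,), 10, 0.05, 0.8, cell_mask)
        frac, summary = colocalize(cs, np.array([[30.0, 30.0]]), 0.75)
        assert frac[0] == 0.0
        assert summary == 0.0

    def test_requires_dots(self, cell_mask):
        cs = make_cluster_set([0.1], cell_mask)
        with pytest.raises(ValueError):
            colocalize(cs, np.zeros((0, 2)), 0.75)


class TestLineProfile:
    def test_identical_images_identical_profiles(self, dot_image):
        img, _ = dot_image
        d, a, b = line_profile(img, img, (5.0, 5.0), (5.0, 20.0))
        assert np.allclose(a, b)

    def test_dot_and_cluster_peaks_coincide(self, lattice, cell_mask, dot_image):
        dots_img, truth = dot_image
        tirf, _ = simgen.make_cluster_image(
            "patterned", lattice, cell_mask, diffuse_amp=0.0, seed=8
        )
        # a segment through collinear lattice sites along a row under the cell
        row = truth[np.isclose(truth[:, 0], 19.0526, atol=0.01)]
        row = row[np.argsort(row[:, 1])]
        center = np.asarray(cell_mask.centroid_um)
        row = row[np.abs(row[:, 1] - center[1]) < 5.0]
        start, end = row[0], row[-1]
        d, a, b = line_profile(dots_img, tirf, start, end, width_px=5)
        pa, pb = np.argmax(a), np.argmax(b)
        assert abs(pa - pb) <= 1
        # peak spacing along the (lightly smoothed) profile equals the pitch
        from scipy.signal import find_peaks

        kern = np.ones(3) / 3.0
        a_s = np.convolve(a, kern, mode="same")
        step = d[1] - d[0]
        peaks, _ = find_peaks(
            a_s, height=0.5 * a_s.max(), distance=int(1.0 / step)
        )
        spacing = np.diff(d[peaks])
        assert np.allclose(spacing, 2.0, atol=0.25)

    def test_segment_outside_raises(self, dot_image):
        img, _ = dot_image
        with pytest.raises(ValueError):
            line_profile(img, img, (5.0, 5.0), (5.0, 80.0))
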