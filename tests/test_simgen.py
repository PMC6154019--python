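"""Generator ground truth: geometry, photon statistics, physics limits."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from dotsynapse import simgen
from dotsynapse.simgen import (
    CohortGroup,
    CPBParams,
    LatticeSpec,
    SimulationError,
    hex_lattice_points,
    lognormal_params,
)

PX = 0.16


class TestLatticeSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            LatticeSpec(pitch=-1)
        with pytest.raises(ValueError):
            LatticeSpec(dot_fwhm=2.5, pitch=2.0)
        with pytest.raises(ValueError):
            LatticeSpec(amp_in=5.0, amp_out=10.0)

    def test_truth_centroids_form_lattice(self, lattice):
        pts = hex_lattice_points(lattice, (256, 256), PX)
        d, _ = cKDTree(pts).query(pts, k=2)
        assert abs(np.median(d[:, 1]) - lattice.pitch) < 0.5 * PX


class TestDotArray:
    def test_determinism(self, lattice):
        a, ta = simgen.make_dot_array_image(lattice, seed=3)
        b, tb = simgen.make_dot_array_image(lattice, seed=3)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(ta, tb)

    def test_inside_brighter_than_outside(self, dot_image):
        img, truth = dot_image
        idx = np.round(truth / PX).astype(int)
        ok = (
            (idx[:, 0] > 3)
            & (idx[:, 0] < 252)
            & (idx[:, 1] > 3)
            & (idx[:, 1] < 252)
        )
        inside = img.pixels[idx[ok, 0], idx[ok, 1]].mean()
        outside = np.median(img.pixels)  # field is mostly between dots
        assert inside > 2.0 * outside

    def test_flat_field_poisson_statistics(self, lattice):
        flat = LatticeSpec(amp_in=40.0, amp_out=40.0)
        img, _ = simgen.make_dot_array_image(flat, seed=5, read_noise=0.0)
        v = img.pixels.ravel()
        assert v.size >= 1e4
        assert v.var() / v.mean() == pytest.approx(1.0, rel=0.1)

    def test_rejects_bad_parameters(self, lattice):
        with pytest.raises(SimulationError):
            simgen.make_dot_array_image(lattice, photons_per_molecule=0.0)
        with pytest.raises(SimulationError):
            simgen.make_dot_array_image(lattice, shape=(40, 40))  # < 7x7 sites


class TestCalibrationImage:
    def test_expected_count_in_poisson_range(self):
        img, n = simgen.make_calibration_image(0.05, shape=(256, 256), seed=2)
        mean = 0.05 * (256 * PX) ** 2  # ≈ 84 spots
        assert abs(n - mean) < 4.0 * np.sqrt(mean)

    def test_zero_density_empty(self):
        img, n = simgen.make_calibration_image(0.0, seed=1, read_noise=0.0)
        assert n == 0
        assert img.pixels.sum() < 1e4  # nothing but shot noise on zero mean

    def test_same_seed_same_truth(self):
        _, n1 = simgen.make_calibration_image(0.05, seed=9)
        _, n2 = simgen.make_calibration_image(0.05, seed=9)
        assert n1 == n2

    def test_isolation_precondition(self):
        with pytest.raises(SimulationError):
            simgen.make_calibration_image(5.0)


class TestRicm:
    def test_truth_mask_area_matches_disc(self, lattice):
        _, mask, _ = simgen.make_ricm_image(
            "uniform", lattice, cell_radius=8.0, seed=1
        )
        disc_area = np.pi * 64.0
        ring = 2.0 * np.pi * 8.0 * PX  # one pixel ring of uncertainty
        assert abs(mask.area_um2 - disc_area) < ring

    def test_patch_sites_on_lattice(self, lattice):
        _, _, sites = simgen.make_ricm_image(
            "textured", lattice, cell_radius=8.0, n_patches=7, seed=2
        )
        assert len(sites) == 7
        lattice_pts = hex_lattice_points(lattice, (256, 256), PX)
        d, _ = cKDTree(lattice_pts).query(sites)
        assert d.max() < 1e-9

    def test_too_many_patches_rejected(self, lattice):
        with pytest.raises(SimulationError):
            simgen.make_ricm_image(
                "textured", lattice, cell_radius=3.0, n_patches=50
            )
        with pytest.raises(SimulationError):
            simgen.make_ricm_image("uniform", lattice, n_patches=3)


class TestClusterImage:
    def test_patterned_centroids_on_lattice_sites(self, lattice, cell_mask):
        _, truth = simgen.make_cluster_image(
            "patterned", lattice, cell_mask, diffuse_amp=0.0, seed=3
        )
        sites = hex_lattice_points(lattice, cell_mask.mask.shape, PX)
        d, _ = cKDTree(sites).query(truth)
        assert d.max() < lattice.dot_fwhm / 2.0

    def test_homogeneous_count(self, lattice, cell_mask):
        _, truth = simgen.make_cluster_image(
            "homogeneous", lattice, cell_mask, n_free_clusters=50, seed=4
        )
        assert len(truth) == 50

    def test_amplitude_jitter_present(self, lattice, cell_mask):
        img, truth = simgen.make_cluster_image(
            "patterned", lattice, cell_mask, seed=5, read_noise=0.0
        )
        peaks = [
            img.pixels[int(r / PX) - 2 : int(r / PX) + 3,
                       int(c / PX) - 2 : int(c / PX) + 3].max()
            for r, c in truth
        ]
        assert np.std(peaks) / np.mean(peaks) > 0.1


class TestActin:
    @pytest.mark.parametrize("org,target", [("homogeneous", 1.0), ("ring", 0.3)])
    def test_clearance_target_round_trip(self, org, target, cell_mask):
        from dotsynapse.morphometry import actin_clearance

        img = simgen.make_actin_image(org, cell_mask, target, seed=6)
        assert actin_clearance(img, cell_mask).ratio == pytest.approx(
            target, rel=0.1
        )

    def test_dots_mode_has_maxima_on_lattice(self, lattice, cell_mask):
        img = simgen.make_actin_image(
            "dots", cell_mask, 1.0, seed=7, lattice=lattice, read_noise=0.0
        )
        sites = hex_lattice_points(lattice, cell_mask.mask.shape, PX)
        from scipy import ndimage

        d = ndimage.distance_transform_edt(cell_mask.mask) * PX
        interior = sites[
            d[np.clip((sites / PX).astype(int), 0, 255)[:, 0],
              np.clip((sites / PX).astype(int), 0, 255)[:, 1]] > 1.5
        ]
        for r, c in interior:
            ri, ci = int(r / PX), int(c / PX)
            win = img.pixels[ri - 3 : ri + 4, ci - 3 : ci + 4]
            ring = img.pixels[ri - 6 : ri + 7, ci - 6 : ci + 7]
            assert win.max() > np.median(ring)

    def test_negative_target_rejected(self, cell_mask):
        with pytest.raises(SimulationError):
            simgen.make_actin_image("ring", cell_mask, -0.5)


class TestCPB:
    def test_stability_violation_rejected(self):
        params = CPBParams(D=5.0, dt=0.01)
        with pytest.raises(SimulationError):
            simgen.make_cpb_movie(params, shape=(128, 128), pixel_size=0.16)

    def test_conservation_without_bleaching(self):
        params = CPBParams(
            D=3.0, k=0.0, aperture_radius=8.0, duration=5.0, dt=0.002,
            frame_interval=0.25,
        )
        st = simgen.make_cpb_movie(params, shape=(128, 128), seed=2)
        tot = st.frames.sum(axis=(1, 2))
        drift = (tot[-4:].mean() - tot[:4].mean()) / tot[:4].mean()
        assert abs(drift) < 0.01

    def test_immobile_limit_pure_exponential(self):
        params = CPBParams(
            D=0.0, k=0.5, aperture_radius=8.0, duration=10.0, dt=0.02,
            frame_interval=0.25,
        )
        st = simgen.make_cpb_movie(params, shape=(128, 128), seed=3)
        ap = st.frames[0] > 0
        trace = st.frames[:, ap].mean(axis=1)
        popt, _ = curve_fit(
            lambda t, a, k, c: a * np.exp(-k * t) + c,
            st.timestamps, trace, p0=(trace[0], 0.3, 0.0),
        )
        assert popt[1] == pytest.approx(0.5, rel=0.05)

    def test_rim_develops_and_decays_inward(self):
        params = CPBParams(
            D=5.0, k=0.5, aperture_radius=10.0, duration=25.0, dt=0.004,
            frame_interval=0.5,
        )
        st = simgen.make_cpb_movie(
            params, shape=(128, 128), pixel_size=0.32, seed=4
        )
        from dotsynapse.photobleach import edge_profile

        prof = edge_profile(st, st.frames[0] > 0)
        # monotone decreasing trend from rim into the bleached interior
        smooth = np.convolve(prof.intensity, np.ones(5) / 5, mode="valid")
        assert smooth[0] > 2.0 * smooth[-1]
        assert np.argmax(prof.intensity) <= 2


class TestCohort:
    def test_lognormal_params_closed_form(self):
        mu, sigma = lognormal_params(170.0, 95.0)
        rng = np.random.default_rng(0)
        v = rng.lognormal(mu, sigma, size=1_000_000)
        assert np.median(v) == pytest.approx(170.0, rel=0.01)
        assert v.std() == pytest.approx(95.0, rel=0.02)

    def test_pooled_median_near_target(self):
        df = simgen.make_cohort({"p": CohortGroup(170.0, 95.0, 8, 14)}, seed=1)
        assert len(df) == 112
        assert np.median(df.area_um2) == pytest.approx(170.0, rel=0.10)

    def test_zero_sd_degenerate(self):
        df = simgen.make_cohort({"p": CohortGroup(100.0, 0.0, 2, 5)}, seed=2)
        assert np.allclose(df.area_um2, 100.0)

    def test_determinism(self):
        spec = {"p": CohortGroup(170.0, 95.0, 3, 10)}
        a = simgen.make_cohort(spec, seed=5)
        b = simgen.make_cohort(spec, seed=5)
        assert a.equals(b)
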