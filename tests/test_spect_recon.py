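"""SPECT chain: projector, FBP, Chang correction, contrast recovery."""

import numpy as np
import pytest

from scintcam import spect_recon as sr
from scintcam.camera import EnergyWindow, make_camera
from scintcam.phantoms import IQPhantomSpec, iq_phantom_scene
from scintcam.spect_recon import (
    ProjectionSet,
    PSFModel,
    VolumeImage,
    acquire_projections,
    chang_correct,
    contrast_recovery,
    fbp,
    voxelize_iq_phantom,
)

VOX = sr.VOXEL_MM


def narrow_psf(sigma=6.0):
    d = np.array([50.0, 400.0])
    return PSFModel(
        isotope="Tc99m", collimator="VXGP", window=(130.0, 151.0),
        distances_mm=d, sigma_core=np.full(2, sigma),
        frac_scatter=np.zeros(2), sigma_scatter=np.full(2, 30.0),
        frac_penetration=np.zeros(2), sigma_penetration=np.full(2, 80.0),
        sensitivity_cps_mbq=60.0,
    )


def disk_sinogram(radius_mm, n_views=120, n_bins=128):
    """Analytic parallel projections of a centered uniform disk."""
    s = (np.arange(n_bins) - (n_bins - 1) / 2.0) * VOX
    proj = 2.0 * np.sqrt(np.clip(radius_mm**2 - s**2, 0.0, None))
    data = np.tile(proj, (n_views, 1, 1))  # (views, 1 axial slice, bins)
    return ProjectionSet(data=data, angles_deg=np.arange(n_views) * 360.0 / n_views,
                         time_per_view_s=15.0)


class TestFBP:
    def test_uniform_disk_mean_within_2_percent(self):
        radius = 150.0
        vol = fbp(disk_sinogram(radius))
        grid = vol.voxels.shape[1]
        ax = (np.arange(grid) + 0.5) * VOX - grid * VOX / 2.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        inner = xx**2 + yy**2 <= (0.8 * radius) ** 2
        assert vol.voxels[0][inner].mean() == pytest.approx(1.0, rel=0.02)

    def test_all_zero_projections_reconstruct_to_zero(self):
        proj = ProjectionSet(
            data=np.zeros((60, 2, 128)),
            angles_deg=np.arange(60) * 6.0, time_per_view_s=30.0)
        vol = fbp(proj)
        assert np.allclose(vol.voxels, 0.0)

    def test_point_reconstruction_is_radially_symmetric(self):
        """A centered point gives the same profile along x and y."""
        n_bins, n_views = 128, 120
        s = (np.arange(n_bins) - (n_bins - 1) / 2.0) * VOX
        proj = np.exp(-0.5 * (s / 8.0) ** 2)
        data = np.tile(proj, (n_views, 1, 1))
        ps = ProjectionSet(data=data, angles_deg=np.arange(n_views) * 3.0,
                           time_per_view_s=15.0)
        sl = fbp(ps).voxels[0]
        c = n_bins // 2
        px = sl[c - 1, :] + sl[c, :]
        py = sl[:, c - 1] + sl[:, c]
        peak = px.max()
        assert np.abs(px - py).max() < 0.05 * peak

    def test_non_uniform_angles_rejected(self):
        with pytest.raises(ValueError, match="equally spaced"):
            ProjectionSet(data=np.zeros((3, 1, 8)),
                          angles_deg=np.array([0.0, 10.0, 30.0]),
                          time_per_view_s=1.0)

    def test_too_few_views_rejected(self):
        with pytest.raises(ValueError, match="views"):
            ProjectionSet(data=np.zeros((1, 1, 8)),
                          angles_deg=np.array([0.0]), time_per_view_s=1.0)


class TestProjector:
    def test_zero_activity_gives_zero_projections(self):
        scene = iq_phantom_scene("Tc99m", 0.0, 9.0)
        cam = make_camera("VXGP", EnergyWindow(130, 151))
        proj = acquire_projections(scene, cam, narrow_psf(), n_views=12,
                                   noise=False)
        assert proj.data.sum() == 0.0

    def test_total_counts_match_budget(self):
        scene = iq_phantom_scene("Tc99m", 137.0, 9.0)
        cam = make_camera("VXGP", EnergyWindow(130, 151))
        budget = 3.0e5
        proj = acquire_projections(scene, cam, narrow_psf(), n_views=12,
                                   seed=4, count_budget=budget, noise=True)
        assert proj.data.sum() == pytest.approx(budget, abs=5 * np.sqrt(budget))

    def test_point_source_roundtrips_psf_width(self, monkeypatch):
        """Projection of a point has the calibrated PSF width."""
        sigma = 8.0
        act = np.zeros((128, 128, 128), dtype=np.float32)
        act[64, 64, 64] = 1.0
        monkeypatch.setattr(
            sr, "voxelize_iq_phantom",
            lambda spec, mu, grid=128, voxel=VOX: (act, np.zeros_like(act)))
        scene = iq_phantom_scene("Tc99m", 137.0, 9.0)
        cam = make_camera("VXGP", EnergyWindow(130, 151))
        proj = acquire_projections(scene, cam, narrow_psf(sigma), n_views=4,
                                   noise=False, count_budget=1e6)
        row = proj.data[0][64]
        from scintcam.nema_metrics import LSFProfile, width_at_fraction

        centers = (np.arange(128) + 0.5) * VOX - 64 * VOX
        fwhm = width_at_fraction(LSFProfile(centers, row), 0.5)
        expected = 2.3548 * np.sqrt(sigma**2 + VOX**2 / 12.0)
        assert fwhm == pytest.approx(expected, rel=0.08)

    def test_wrong_isotope_psf_rejected(self):
        scene = iq_phantom_scene("Ho166", 166.0, 9.0)
        cam = make_camera("HEGP", EnergyWindow(74.6, 86.6))
        with pytest.raises(ValueError, match="calibrat"):
            acquire_projections(scene, cam, narrow_psf(), n_views=4)


class TestChang:
    def test_zero_mu_is_identity(self):
        vol = VolumeImage(np.random.default_rng(0).random((4, 32, 32)))
        out = chang_correct(vol, np.zeros_like(vol.voxels))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_uniform_cylinder_center_equals_exp_mu_r(self):
        """All boundary paths from the center have length r: C = e^(mu*r)."""
        grid, mu_cm, radius = 128, 0.12, 100.0
        ax = (np.arange(grid) + 0.5) * VOX - grid * VOX / 2.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        mu_slice = np.where(xx**2 + yy**2 <= radius**2, mu_cm / 10.0, 0.0)
        vol = VolumeImage(np.ones((1, grid, grid)))
        out = chang_correct(vol, mu_slice[None], n_angles=64)
        center = out.voxels[0, grid // 2, grid // 2]
        assert center == pytest.approx(np.exp(mu_cm * radius / 10.0), rel=0.03)

    def test_correction_at_least_one(self):
        grid = 64
        mu = np.full((1, grid, grid), 0.012)
        vol = VolumeImage(np.ones((1, grid, grid)))
        out = chang_correct(vol, mu, n_angles=32)
        assert np.all(out.voxels >= 1.0 - 1e-12)

    def test_angle_count_converged(self):
        """64 vs 256 directions differ by < 0.5% inside the body."""
        grid = 64
        ax = (np.arange(grid) + 0.5) * VOX - grid * VOX / 2.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        mu_slice = np.where(xx**2 + yy**2 <= 100.0**2, 0.012, 0.0)
        vol = VolumeImage(np.ones((1, grid, grid)))
        a = chang_correct(vol, mu_slice[None], n_angles=64).voxels[0]
        b = chang_correct(vol, mu_slice[None], n_angles=256).voxels[0]
        interior = xx**2 + yy**2 <= 70.0**2
        assert np.abs(a[interior] / b[interior] - 1.0).max() < 0.005

    def test_negative_mu_rejected(self):
        vol = VolumeImage(np.ones((1, 8, 8)))
        with pytest.raises(ValueError):
            chang_correct(vol, np.full((1, 8, 8), -0.01))

    def test_shape_mismatch_rejected(self):
        vol = VolumeImage(np.ones((1, 8, 8)))
        with pytest.raises(ValueError):
            chang_correct(vol, np.zeros((2, 8, 8)))


def ideal_volume(spec: IQPhantomSpec, grid=128):
    """Volume whose sphere ROIs read exactly R and background exactly 1."""
    ax = (np.arange(grid) + 0.5) * VOX - grid * VOX / 2.0
    xx, yy = np.meshgrid(ax, ax, indexing="xy")  # slices are [y, x]
    vol = np.ones((grid, grid, grid))
    central = np.ones((grid, grid))
    for (cx, cy), d in zip(spec.sphere_centers, spec.sphere_diameters_mm):
        pad = d / 2.0 + 1.5 * VOX  # cover every pixel the ROI touches
        central[(xx - cx) ** 2 + (yy - cy) ** 2 <= pad**2] = spec.ratio
    vol[grid // 2] = central
    return VolumeImage(vol)


class TestContrastRecovery:
    SPEC = IQPhantomSpec()

    def test_perfect_image_gives_qh_100(self):
        qh = contrast_recovery(ideal_volume(self.SPEC), self.SPEC)
        for _, _, _, q in qh.entries:
            assert q == pytest.approx(100.0, abs=1e-9)

    def test_uniform_scaling_leaves_qh_unchanged(self):
        vol = ideal_volume(self.SPEC)
        qh1 = contrast_recovery(vol, self.SPEC)
        qh2 = contrast_recovery(VolumeImage(3.7 * vol.voxels), self.SPEC)
        for (_, _, _, a), (_, _, _, b) in zip(qh1.entries, qh2.entries):
            assert a == pytest.approx(b, rel=1e-12)

    def test_roi_outside_small_body_rejected(self):
        small = IQPhantomSpec(body_half_height_mm=60.0, body_straight_mm=20.0)
        with pytest.raises(ValueError, match="outside"):
            contrast_recovery(VolumeImage(np.ones((128, 128, 128))), small)

    def test_background_rois_clear_of_spheres(self):
        """Every background ROI center is at least one ROI diameter away
        from every sphere center and inside the body."""
        spec = self.SPEC
        r_max = max(spec.sphere_diameters_mm) / 2.0
        centers = np.array(sr._BG_CENTERS)
        body = spec.body_mask(centers[:, 0], centers[:, 1])
        assert body.all()
        for bx, by in centers:
            d = np.hypot(spec.sphere_centers[:, 0] - bx,
                         spec.sphere_centers[:, 1] - by)
            assert d.min() >= 2 * r_max

    def test_55_background_rois(self):
        assert len(sr._BG_CENTERS) * len(sr._BG_SLICE_OFFSETS_MM) == 55
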