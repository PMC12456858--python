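"""Transform model, landmark affine, transform application.

The heavier intensity-based recovery checks (full rigid/affine
registration on the default-size phantom) live in the acceptance
suite; here the transform machinery is exercised on small inputs.
"""

import math

import numpy as np
import pytest
import SimpleITK as sitk

from spinalquant.phantom import make_known_chain
from spinalquant.registration import (
    FiducialSet,
    FixedGeometry,
    RegistrationConfig,
    TransformChain,
    TransformStep,
    apply_transform,
    landmark_affine,
    mutual_information,
    register_multistep,
)
from spinalquant.volume import ImageVolume


def _random_affine(rng):
    A = np.eye(3) + rng.uniform(-0.1, 0.1, size=(3, 3))
    t = rng.uniform(-5, 5, size=3)
    return A, t


class TestLandmarkAffine:
    def test_identical_points_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(20, 3))
        step, rms = landmark_affine(FiducialSet(pts, pts))
        assert rms == pytest.approx(0.0, abs=1e-9)
        m = np.asarray(step.transform.GetMatrix()).reshape(3, 3)
        assert np.allclose(m, np.eye(3), atol=1e-9)
        assert np.allclose(step.transform.GetTranslation(), 0, atol=1e-9)

    def test_exact_recovery_of_known_affine(self):
        rng = np.random.default_rng(1)
        atlas = rng.uniform(0, 100, size=(60, 3))        # (z, y, x)
        A, t = _random_affine(rng)
        sample = atlas @ A.T + t
        step, rms = landmark_affine(FiducialSet(sample, atlas))
        assert rms < 1e-6
        # verify pointwise: transform maps atlas physical (x,y,z) to sample
        for p_atlas, p_sample in zip(atlas[:5], sample[:5]):
            got = step.transform.TransformPoint(tuple(p_atlas[::-1]))
            assert np.allclose(got, p_sample[::-1], atol=1e-6)

    def test_noisy_residual_tracks_sigma(self):
        """With isotropic noise sigma on targets, the LS residual RMS
        stays below 1.2 sigma at N=60 (12 dof absorbed by the fit)."""
        rng = np.random.default_rng(2)
        sigma = 2.0
        ratios = []
        for _ in range(30):
            atlas = rng.uniform(0, 100, size=(60, 3))
            A, t = _random_affine(rng)
            sample = atlas @ A.T + t + rng.normal(0, sigma, size=(60, 3))
            _, rms = landmark_affine(FiducialSet(sample, atlas))
            ratios.append(rms / (sigma * np.sqrt(3)))  # per-point 3-D RMS vs sigma*sqrt(3)
        assert np.mean(ratios) <= 1.2
        # and the fit absorbs some noise: residual below the raw noise level
        assert np.mean(ratios) < 1.0

    def test_too_few_points(self):
        pts = np.zeros((3, 3))
        with pytest.raises(ValueError, match=">= 4"):
            landmark_affine(FiducialSet(pts, pts))

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(3)
        atlas = rng.uniform(0, 100, size=(20, 3))
        atlas[:, 0] = 5.0  # all in one z plane
        with pytest.raises(ValueError, match="coplanar|degenerate"):
            landmark_affine(FiducialSet(atlas, atlas))

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        fs = FiducialSet(rng.uniform(0, 50, (10, 3)), rng.uniform(0, 50, (10, 3)))
        path = tmp_path / "fiducials.csv"
        fs.to_csv(path)
        back = FiducialSet.from_csv(path)
        assert np.allclose(back.sample_points, fs.sample_points)
        assert np.allclose(back.atlas_points, fs.atlas_points)


class TestApplyTransform:
    @pytest.fixture
    def volume(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 1000, size=(8, 32, 32)).astype(np.float32)
        return ImageVolume(data, (60.0, 10.0, 10.0))

    def test_identity_nearest_bit_identical(self, volume):
        chain = TransformChain.identity(FixedGeometry.from_volume(volume))
        out = apply_transform(volume, chain, "nearest")
        assert np.array_equal(out.data, volume.data)

    def test_identity_linear_close(self, volume):
        chain = TransformChain.identity(FixedGeometry.from_volume(volume))
        out = apply_transform(volume, chain, "linear")
        assert np.abs(out.data - volume.data).max() <= 1.0

    def test_translation_round_trip(self, volume):
        fwd = make_known_chain(volume.shape, volume.voxel_size_um,
                               translation_vox=(3.0, -4.0))
        inv = make_known_chain(volume.shape, volume.voxel_size_um,
                               translation_vox=(-3.0, 4.0))
        there = apply_transform(volume, fwd, "linear")
        back = apply_transform(there, inv, "linear")
        # compare away from the borders where zero-fill invades
        interior = (slice(None), slice(8, 24), slice(8, 24))
        assert np.abs(back.data[interior] - volume.data[interior]).max() <= 2.0

    def test_nearest_introduces_no_new_labels(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 5, size=(6, 24, 24)).astype(np.int32)
        vol = ImageVolume(labels, (60.0, 10.0, 10.0))
        chain = make_known_chain(vol.shape, vol.voxel_size_um,
                                 translation_vox=(2.5, 1.5), rotation_deg=7.0)
        out = apply_transform(vol, chain, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels))

    def test_unknown_interpolation(self, volume):
        chain = TransformChain.identity(FixedGeometry.from_volume(volume))
        with pytest.raises(ValueError, match="interpolation"):
            apply_transform(volume, chain, "cubic")


class TestTransformChain:
    def test_json_round_trip(self):
        chain = make_known_chain((8, 32, 32), (60.0, 10.0, 10.0),
                                 translation_vox=(3.0, -2.0), rotation_deg=5.0,
                                 scale=(0.95, 1.05), shear=0.01)
        text = chain.to_json()
        back = TransformChain.from_json(text)
        assert back.kinds == chain.kinds
        assert back.fixed_geometry == chain.fixed_geometry
        p = (55.0, 120.0, 200.0)
        assert np.allclose(back.as_composite().TransformPoint(p),
                           chain.as_composite().TransformPoint(p), atol=1e-9)

    def test_negative_determinant_rejected(self):
        t = sitk.AffineTransform(3)
        t.SetMatrix((-1.0, 0, 0, 0, 1.0, 0, 0, 0, 1.0))
        with pytest.raises(ValueError, match="determinant"):
            TransformStep("affine", t)


class TestStagedRegistration:
    def test_metric_improves_stage_by_stage(self):
        """Mutual information does not decrease from rigid to affine to
        b-spline on a deformed phantom pair."""
        from spinalquant.phantom import PhantomConfig, deform_sample, generate_template_phantom

        cfg_p = PhantomConfig(n_sections=10, ny=96, nx=96)
        auto, _ = generate_template_phantom(cfg_p, seed=8)
        moved, _, _ = deform_sample({"auto": auto}, cfg_p, seed=9)
        cfg = RegistrationConfig(pyramid_levels=3, iterations=40,
                                 sampling_fraction=0.2, bspline_iterations=10,
                                 seed=3)
        mi = [mutual_information(auto, moved["auto"])]
        for stages in [("rigid",), ("rigid", "affine"),
                       ("rigid", "affine", "bspline")]:
            chain = register_multistep(moved["auto"], auto, cfg, stages=stages)
            mi.append(mutual_information(auto, moved["auto"], chain.as_composite()))
        assert mi[1] >= mi[0] - 1e-3
        assert mi[2] >= mi[1] - 1e-3
        assert mi[3] >= mi[2] - 1e-3

    def test_landmark_refinement_restores_alignment(self):
        """Prepending the fiducial affine to a chain undoes a known
        affine offset; replace_chain discards the automated stages."""
        from spinalquant.registration import refine_with_landmarks

        rng = np.random.default_rng(12)
        geometry = FixedGeometry((8, 64, 64), (60.0, 10.0, 10.0))
        true = make_known_chain(geometry.shape, geometry.voxel_size_um,
                                translation_vox=(4.0, -3.0), rotation_deg=5.0,
                                scale=(0.95, 1.05))
        atlas_pts = rng.uniform(5, 58, size=(20, 3)) * np.array([0.1, 1, 1])
        comp = true.as_composite()
        sample_pts = []
        for z, y, x in atlas_pts:
            q = comp.TransformPoint((x * 10.0, y * 10.0, z * 60.0))
            sample_pts.append((q[2] / 60.0, q[1] / 10.0, q[0] / 10.0))
        fs = FiducialSet(np.array(sample_pts), atlas_pts)
        empty = TransformChain.identity(geometry)
        refined, rms = refine_with_landmarks(empty, fs,
                                             replace_chain=True)
        assert rms < 1e-6
        p = (200.0, 300.0, 120.0)
        assert np.allclose(refined.as_composite().TransformPoint(p),
                           comp.TransformPoint(p), atol=1e-6)
        # default mode keeps the automated (non-bspline) stages
        base = make_known_chain(geometry.shape, geometry.voxel_size_um,
                                translation_vox=(1.0, 0.0))
        augmented, _ = refine_with_landmarks(base, fs)
        assert augmented.kinds[0] == "landmark_affine"
        assert "rigid" in augmented.kinds


class TestRegisterGuards:
    def test_empty_volume_rejected(self):
        empty = ImageVolume(np.zeros((4, 16, 16), np.float32))
        cfg = RegistrationConfig(pyramid_levels=2, iterations=5, seed=1)
        with pytest.raises(ValueError, match="no .*nonzero content|nonzero"):
            register_multistep(empty, empty, cfg, stages=("rigid",))

    def test_unknown_stage_rejected(self):
        vol = ImageVolume(np.ones((4, 16, 16), np.float32))
        cfg = RegistrationConfig(seed=1)
        with pytest.raises(ValueError, match="unknown registration stage"):
            register_multistep(vol, vol, cfg, stages=("demons",))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(pyramid_levels=0)
        with pytest.raises(ValueError):
            RegistrationConfig(bspline_grid_mm=(0, 1, 1))
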