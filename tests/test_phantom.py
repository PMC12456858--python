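"""Phantom generator: determinism, symmetry, deposition truth, deformation."""

import numpy as np
import pytest

from spinalquant.phantom import (
    PhantomConfig,
    deform_sample,
    deposit_signal,
    generate_cohort,
    generate_template_phantom,
    make_known_chain,
    render_blobs,
)
from spinalquant.registration import apply_transform


class TestTemplatePhantom:
    def test_same_seed_bit_identical(self, small_cfg):
        a1, ann1 = generate_template_phantom(small_cfg, seed=5)
        a2, ann2 = generate_template_phantom(small_cfg, seed=5)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(ann1.labels, ann2.labels)

    def test_noise_free_volume_is_mirror_symmetric(self):
        cfg = PhantomConfig(n_sections=8, ny=96, nx=96, noise_sigma=0, shot_gain=0)
        auto, _ = generate_template_phantom(cfg, seed=1)
        assert np.allclose(auto.data, auto.data[:, :, ::-1])

    @staticmethod
    def _mask_means(auto, ann):
        gray_ids = [r.id for r in ann.ontology if r.tissue_class == "gray"]
        white_ids = [r.id for r in ann.ontology if r.tissue_class == "white"]
        return (auto.data[np.isin(ann.labels, gray_ids)].mean(),
                auto.data[np.isin(ann.labels, white_ids)].mean())

    def test_gray_white_contrast_exact_without_nuisances(self):
        """Mask-wise means reproduce the configured contrast exactly when
        rim, smoothing and noise are disabled."""
        cfg = PhantomConfig(n_sections=8, ny=96, nx=96, border_gain=0,
                            autofluor_smooth_px=0, noise_sigma=0, shot_gain=0,
                            background_offset=0)
        auto, ann = generate_template_phantom(cfg, seed=4)
        gray_mean, white_mean = self._mask_means(auto, ann)
        assert gray_mean / white_mean == pytest.approx(1 + cfg.gray_contrast, rel=1e-6)

    def test_gray_brighter_than_white_with_nuisances(self, small_phantom):
        auto, ann = small_phantom
        gray_mean, white_mean = self._mask_means(auto, ann)
        assert gray_mean > white_mean

    def test_outline_varies_along_z(self, small_phantom):
        _, ann = small_phantom
        areas = [(ann.labels[z] > 0).sum() for z in range(ann.labels.shape[0])]
        assert len(set(areas)) > 1

    def test_grid_too_small_errors(self):
        with pytest.raises(ValueError, match="too small"):
            generate_template_phantom(PhantomConfig(n_sections=4, ny=16, nx=16), seed=1)


class TestDepositSignal:
    def test_zero_density_gives_zero_truth(self, small_cfg, small_phantom):
        _, ann = small_phantom
        cfg = PhantomConfig(**{**small_cfg.__dict__,
                               "puncta_density": {},
                               "axon_count": 0,
                               "somas_per_lamina9_region": 0})
        signal, truth = deposit_signal(ann, cfg, seed=9)
        assert truth.total_deposited() == 0
        # background noise only
        assert signal.data.max() < cfg.background_offset + 8 * cfg.noise_sigma

    def test_single_region_density_concentrates_signal(self):
        """At the default working resolution, signal deposited into one
        region stays >= 99% within that region's mask (the remainder is
        blob tails)."""
        base = PhantomConfig()
        _, ann = generate_template_phantom(base, seed=101)
        target = next(r for r in ann.ontology
                      if r.level == "C4" and r.lamina == 7 and r.hemicord == "left")
        cfg = PhantomConfig(**{**base.__dict__,
                               "puncta_density": {target.id: 10.0},
                               "axon_count": 0,
                               "somas_per_lamina9_region": 0})
        _, truth = deposit_signal(ann, cfg, seed=11)
        total = truth.total_deposited()
        assert total > 0
        assert truth.region_sums[target.id] / total >= 0.99

    def test_conservation_of_truth_sums(self, small_signal):
        """Summed per-region truth equals total pre-noise deposit in the mask."""
        _, truth = small_signal
        assert all(v >= 0 for v in truth.region_sums.values())
        assert truth.total_deposited() > 0
        assert truth.total_deposited() == pytest.approx(truth.masked_total, rel=1e-12)

    def test_doubling_density_doubles_truth(self, small_cfg, small_phantom):
        _, ann = small_phantom
        target = next(r for r in ann.ontology
                      if r.lamina == 7 and r.hemicord == "left"
                      and (ann.labels == r.id).sum() > 200)
        totals = {1.0: [], 2.0: []}
        for mult in totals:
            cfg = PhantomConfig(**{**small_cfg.__dict__,
                                   "puncta_density": {target.id: 40.0 * mult},
                                   "axon_count": 0,
                                   "somas_per_lamina9_region": 0})
            for seed in range(20):
                _, truth = deposit_signal(ann, cfg, seed=1000 + seed)
                totals[mult].append(truth.region_sums[target.id])
        ratio = np.mean(totals[2.0]) / np.mean(totals[1.0])
        assert abs(ratio - 2.0) / 2.0 < 0.10

    def test_unknown_region_in_density_errors(self, small_cfg, small_phantom):
        _, ann = small_phantom
        cfg = PhantomConfig(**{**small_cfg.__dict__, "puncta_density": {12345: 1.0}})
        with pytest.raises(ValueError, match="unknown region"):
            deposit_signal(ann, cfg, seed=1)

    def test_soma_centers_inside_their_regions(self, small_phantom, small_signal):
        _, ann = small_phantom
        _, truth = small_signal
        assert truth.soma_placements
        for p in truth.soma_placements:
            z, y, x = p["center"]
            assert ann.labels[int(round(z)), int(round(y)), int(round(x))] == p["region_id"]


class TestDeform:
    def test_zero_magnitude_is_identity(self, small_cfg, small_phantom):
        auto, ann = small_phantom
        moved, chain, params = deform_sample({"auto": auto}, small_cfg, seed=3,
                                             magnitude=0.0)
        assert np.allclose(moved["auto"].data, auto.data, atol=1.0)
        assert params["rotation_deg"] == 0.0

    def test_known_translation_recovered_by_phase_correlation(self, small_cfg,
                                                              small_phantom):
        from skimage.registration import phase_cross_correlation

        auto, _ = small_phantom
        chain = make_known_chain(auto.shape, auto.voxel_size_um,
                                 translation_vox=(5.0, 7.0))
        moved = apply_transform(auto, chain, "linear")
        z = auto.shape[0] // 2
        shift, *_ = phase_cross_correlation(auto.data[z], moved.data[z])
        # resampling with T shifts content by -T
        assert np.allclose(shift, (5.0, 7.0), atol=0.6)

    def test_same_seed_same_parameters(self, small_cfg, small_phantom):
        auto, _ = small_phantom
        _, _, p1 = deform_sample({"auto": auto}, small_cfg, seed=21)
        _, _, p2 = deform_sample({"auto": auto}, small_cfg, seed=21)
        assert p1 == p2

    def test_out_of_frame_errors(self, small_cfg, small_phantom):
        auto, ann = small_phantom
        cfg = PhantomConfig(**{**small_cfg.__dict__, "translation_vox": 80.0,
                               "rotation_deg": 0.0, "elastic_amp_vox": 0.0})
        with pytest.raises(ValueError, match="out of frame"):
            # large enough translations must eventually clip the cord
            for seed in range(10):
                deform_sample({"annotation": ann}, cfg, seed=seed)


class TestCohort:
    def test_null_effect_groups_similar(self, small_cfg):
        cfg = PhantomConfig(**{**small_cfg.__dict__, "axon_count": 2,
                               "somas_per_lamina9_region": 1})
        samples, _, _ = generate_cohort(cfg, {"a": 2, "b": 2},
                                        {"a": 1.0, "b": 1.0}, seed=5, deform=False)
        tot = {g: np.mean([s.truth.total_deposited()
                           for s in samples if s.group == g]) for g in ("a", "b")}
        assert abs(tot["a"] - tot["b"]) / tot["a"] < 0.25

    def test_effect_multiplier_scales_truth(self, small_cfg, small_phantom):
        _, ann = small_phantom
        target = next(r for r in ann.ontology
                      if r.lamina == 7 and r.hemicord == "left"
                      and (ann.labels == r.id).sum() > 200)
        cfg = PhantomConfig(**{**small_cfg.__dict__,
                               "puncta_density": {target.id: 30.0},
                               "axon_count": 0, "somas_per_lamina9_region": 0})
        ratios = []
        for seed in range(20):
            samples, _, _ = generate_cohort(
                cfg, {"sham": 5, "stroke": 5}, {"stroke": {target.id: 10.0}},
                seed=seed, deform=False)
            mean = {g: np.mean([s.truth.region_sums[target.id]
                                for s in samples if s.group == g])
                    for g in ("sham", "stroke")}
            ratios.append(mean["stroke"] / mean["sham"])
        assert 7.0 <= np.mean(ratios) <= 13.0

    def test_zero_samples_errors(self, small_cfg):
        with pytest.raises(ValueError, match="n_per_group"):
            generate_cohort(small_cfg, {"a": 0}, None, seed=1)

    def test_unknown_effect_group_errors(self, small_cfg):
        with pytest.raises(ValueError, match="unknown groups"):
            generate_cohort(small_cfg, {"a": 1}, {"zzz": 2.0}, seed=1)


def test_render_blobs_mass_matches_gaussian_integral():
    placements = [{"center": (2, 20.0, 20.0), "sigma": 1.5, "amplitude": 100.0}]
    vol = render_blobs((5, 40, 40), placements)
    # 2-D Gaussian integral = amplitude * 2 pi sigma^2 (tails truncated at 3 sigma)
    expected = 100.0 * 2 * np.pi * 1.5 ** 2
    assert abs(vol.sum() - expected) / expected < 0.02
    assert vol[2].sum() == vol.sum()
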