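"""Augmentation chain: mixup, flips, rotation, resize, elastic deformation."""

import numpy as np
import pytest

from prostseg.augment import (
    AugmentConfig,
    DeformationField,
    ElasticConfig,
    TrainingSample,
    apply_field,
    augment_pipeline,
    elastic_field,
    mixup,
    random_hflip,
    random_rotate,
    random_scale_translate,
)
from prostseg.core import SegMask, VolumeImage
from prostseg.phantom import PhantomConfig, generate_phantom


def _sample(img, lab, spacing=(1, 1, 1)):
    return TrainingSample(
        image=VolumeImage(img, spacing=spacing),
        label=SegMask(np.asarray(lab, dtype=float), binary=False, spacing=spacing),
    )


@pytest.fixture
def disk_sample():
    """A centred disk mask with a matching two-level image, 32x32x4."""
    yy, xx = np.mgrid[0:32, 0:32]
    disk = ((yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 9**2).astype(float)
    lab = np.repeat(disk[:, :, None], 4, axis=2)
    return _sample(lab * 2.0 + 1.0, lab)


class TestMixup:
    def test_lambda_one_returns_first_sample(self, disk_sample, rng):
        other = _sample(np.zeros((32, 32, 4)), np.zeros((32, 32, 4)))
        out = mixup(disk_sample, other, lam=1.0)
        np.testing.assert_array_equal(out.image.voxels, disk_sample.image.voxels)
        np.testing.assert_array_equal(out.label.voxels, disk_sample.label.voxels)

    def test_half_lambda_mixes_binary_labels_to_half(self, disk_sample):
        other = _sample(np.zeros((32, 32, 4)), np.zeros((32, 32, 4)))
        out = mixup(disk_sample, other, lam=0.5)
        inside = disk_sample.label.voxels == 1.0
        np.testing.assert_allclose(out.label.voxels[inside], 0.5)

    def test_beta_draws_have_symmetric_mean(self):
        rng = np.random.default_rng(7)
        lams = rng.beta(0.5, 0.5, size=10_000)
        se = lams.std() / np.sqrt(len(lams))
        assert abs(lams.mean() - 0.5) < 3 * se

    def test_shape_mismatch_rejected(self, disk_sample):
        small = _sample(np.zeros((16, 16, 4)), np.zeros((16, 16, 4)))
        with pytest.raises(ValueError):
            mixup(disk_sample, small, lam=0.5)


class TestFlip:
    def test_double_flip_is_identity(self, disk_sample):
        once = random_hflip(disk_sample, flip=True)
        twice = random_hflip(once, flip=True)
        np.testing.assert_array_equal(twice.image.voxels, disk_sample.image.voxels)

    def test_forced_flip_reverses_columns(self):
        lab = np.zeros((4, 4, 1))
        lab[1, 0, 0] = 1.0
        out = random_hflip(_sample(lab.copy(), lab), flip=True)
        assert out.label.voxels[1, 3, 0] == 1.0
        assert out.label.voxels[1, 0, 0] == 0.0

    def test_trigger_frequency_near_half(self):
        lab = np.zeros((8, 8, 1))
        lab[2, 1, 0] = 1.0  # asymmetric marker so a flip is observable
        s = _sample(lab.copy(), lab)
        rng = np.random.default_rng(3)
        flips = sum(
            not np.array_equal(random_hflip(s, rng).label.voxels, s.label.voxels)
            for _ in range(2000)
        )
        assert abs(flips / 2000 - 0.5) < 3 * 0.5 / np.sqrt(2000)


class TestRotate:
    def test_zero_angle_is_identity(self, disk_sample):
        out = random_rotate(disk_sample, angle=0.0)
        np.testing.assert_array_equal(out.label.voxels, disk_sample.label.voxels)

    def test_centered_disk_nearly_invariant(self, disk_sample):
        before = disk_sample.label.voxels.sum()
        out = random_rotate(disk_sample, angle=np.pi / 6)
        assert abs(out.label.voxels.sum() - before) / before < 0.02

    def test_sampler_respects_angle_range(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(-np.pi / 4, np.pi / 4, size=10_000)
        assert np.abs(angles).max() <= np.pi / 4

    def test_image_and_label_share_geometry(self, disk_sample):
        paired = _sample(disk_sample.label.voxels.copy(), disk_sample.label.voxels.copy())
        out = random_rotate(paired, angle=0.4)
        np.testing.assert_allclose(out.image.voxels, out.label.voxels, atol=1e-12)


class TestScaleTranslate:
    def test_identity_parameters(self, disk_sample):
        out = random_scale_translate(disk_sample, scale=1.0, translation=(0.0, 0.0))
        np.testing.assert_array_equal(out.image.voxels, disk_sample.image.voxels)

    def test_scale_area_ratio(self, disk_sample):
        before = disk_sample.label.voxels.sum()
        out = random_scale_translate(disk_sample, scale=1.3, translation=(0.0, 0.0))
        assert out.label.voxels.sum() / before == pytest.approx(1.69, rel=0.05)

    def test_sampler_range(self):
        rng = np.random.default_rng(9)
        scales = rng.uniform(0.7, 1.3, size=10_000)
        assert scales.min() >= 0.7 and scales.max() <= 1.3


class TestElastic:
    def test_zero_alpha_gives_exact_identity_maps(self):
        f = elastic_field((24, 20), ElasticConfig(alpha=0.0))
        yy, xx = np.mgrid[0:24, 0:20]
        np.testing.assert_array_equal(f.map_x, xx)
        np.testing.assert_array_equal(f.map_y, yy)

    def test_output_maps_have_full_resolution(self, rng):
        f = elastic_field((40, 36), ElasticConfig(beta=0.25, sigma=3), rng)
        assert f.shape == (40, 36)

    def test_too_small_downscaled_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            elastic_field((8, 8), ElasticConfig(beta=0.25, sigma=3), rng)

    def test_smoothness_grows_with_sigma(self):
        # roughness = mean squared neighbour difference / variance, which is
        # monotone decreasing in the blur width
        rough = []
        for sigma in (10.0, 50.0, 100.0):
            vals = []
            for seed in range(3):
                f = elastic_field((256, 256),
                                  ElasticConfig(alpha=2000, beta=1.0, sigma=sigma),
                                  np.random.default_rng(seed))
                dx, _ = f.displacement()
                num = np.mean(np.diff(dx, axis=0) ** 2) + np.mean(np.diff(dx, axis=1) ** 2)
                vals.append(num / dx.var())
            rough.append(np.mean(vals))
        assert rough[0] > rough[1] > rough[2]

    def test_identity_field_application_is_identity(self, disk_sample):
        f = elastic_field((32, 32), ElasticConfig(alpha=0.0))
        out = apply_field(disk_sample, f)
        np.testing.assert_allclose(out.image.voxels, disk_sample.image.voxels, atol=1e-12)

    def test_uniform_shift_field(self):
        img = np.zeros((6, 6, 1))
        img[2, 3, 0] = 1.0
        s = _sample(img.copy(), img.copy())
        yy, xx = np.mgrid[0:6, 0:6].astype(float)
        f = DeformationField(map_x=xx + 1.0, map_y=yy)  # sample one column right
        out = apply_field(s, f)
        assert out.image.voxels[2, 2, 0] == 1.0
        assert out.image.voxels[2, 3, 0] == 0.0

    def test_default_parameters_nearly_preserve_mask_volume(self):
        cfg = PhantomConfig(grid_shape=(320, 320, 12), spacing=(0.59, 0.59, 3.3),
                            radii_range_mm=(15, 18), noise_sd=0, bias_amplitude=0, seed=2)
        s = generate_phantom(cfg)
        sample = _sample(s.image.voxels, s.mask.voxels)
        for seed in range(3):
            f = elastic_field((320, 320), ElasticConfig(), np.random.default_rng(seed))
            out = apply_field(sample, f)
            ratio = out.label.voxels.sum() / sample.label.voxels.sum()
            assert 0.9 < ratio < 1.1


class TestPipeline:
    def test_label_values_stay_in_unit_interval(self, disk_sample):
        rng = np.random.default_rng(0)
        other = _sample(np.ones((32, 32, 4)), np.ones((32, 32, 4)))
        for _ in range(5):
            out = augment_pipeline(disk_sample, other, rng)
            assert out.label.voxels.min() >= 0.0
            assert out.label.voxels.max() <= 1.0

    def test_fixed_seed_reproducible(self, disk_sample):
        other = _sample(np.zeros((32, 32, 4)), np.zeros((32, 32, 4)))
        a = augment_pipeline(disk_sample, other, np.random.default_rng(11))
        b = augment_pipeline(disk_sample, other, np.random.default_rng(11))
        np.testing.assert_array_equal(a.image.voxels, b.image.voxels)
        np.testing.assert_array_equal(a.label.voxels, b.label.voxels)

    def test_stage_order_is_mixup_flip_rotate_scale_elastic(self, monkeypatch):
        import prostseg.augment as aug

        calls = []

        def wrap(name, fn):
            def inner(*a, **k):
                calls.append(name)
                return fn(*a, **k)
            return inner

        monkeypatch.setattr(aug, "mixup", wrap("mixup", aug.mixup))
        monkeypatch.setattr(aug, "random_hflip", wrap("hflip", aug.random_hflip))
        monkeypatch.setattr(aug, "random_rotate", wrap("rotate", aug.random_rotate))
        monkeypatch.setattr(aug, "random_scale_translate",
                            wrap("scale", aug.random_scale_translate))
        monkeypatch.setattr(aug, "elastic_field", wrap("elastic", aug.elastic_field))
        lab = np.zeros((32, 32, 4))
        lab[10:20, 10:20, :] = 1
        s = _sample(lab * 2 + 1, lab)
        aug.augment_pipeline(s, s, np.random.default_rng(0))
        assert calls == ["mixup", "hflip", "rotate", "scale", "elastic"]
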