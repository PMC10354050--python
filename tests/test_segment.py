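"""Labelling, lesion extraction, post-processing and the full pipeline."""

import numpy as np
import pytest

from kapurseg import GTOParams, PhantomSpec, generate_phantom
from kapurseg.kapur import compute_histogram, kapur_entropy, to_probabilities
from kapurseg.preprocess import anisotropic_diffusion, correct_iih
from kapurseg.segment import (PipelineConfig, apply_thresholds,
                              decode_thresholds, extract_lesion_mask,
                              fill_regions, localize, segment_image)


class TestApplyThresholds:
    def test_boundary_convention(self):
        img = np.array([[99, 100]])
        labels = apply_thresholds(img, [100])
        assert labels[0, 0] == 0 and labels[0, 1] == 1

    def test_label_histogram_partitions_pixels(self, rng):
        img = rng.integers(0, 256, size=(32, 32))
        labels = apply_thresholds(img, [50, 120, 200])
        assert np.bincount(labels.ravel(), minlength=4).sum() == 32 * 32
        assert labels.min() >= 0 and labels.max() <= 3


class TestDecodeThresholds:
    def test_round_sort_dedupe(self):
        assert list(decode_thresholds(np.array([200.4, 9.6, 10.2]), 3)) == [10, 11, 200]

    def test_clipping(self):
        assert list(decode_thresholds(np.array([-4.0, 300.0]), 2)) == [1, 255]

    def test_unrepairable_returns_none(self):
        assert decode_thresholds(np.full(3, 255.0), 3) is None


class TestExtractAndFill:
    def test_top_class_only(self):
        labels = np.array([[0, 1], [3, 4]])
        mask = extract_lesion_mask(labels, n_thresholds=4, top_k=1)
        assert mask.tolist() == [[False, False], [False, True]]

    def test_top_k_equal_m_excludes_only_background(self):
        labels = np.array([[0, 1], [3, 4]])
        mask = extract_lesion_mask(labels, n_thresholds=4, top_k=4)
        assert mask.tolist() == [[False, True], [True, True]]

    def test_mask_monotone_in_top_k(self, rng):
        labels = rng.integers(0, 5, size=(20, 20))
        m1 = extract_lesion_mask(labels, 4, 1)
        m2 = extract_lesion_mask(labels, 4, 2)
        assert np.all(m2[m1])

    def test_fill_punched_hole(self):
        yy, xx = np.mgrid[:31, :31]
        disk = (yy - 15) ** 2 + (xx - 15) ** 2 <= 100
        punched = disk.copy()
        punched[14:17, 14:17] = False
        assert np.array_equal(fill_regions(punched), disk)

    def test_border_hole_untouched(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[0:3, 4:6] = False  # notch open to the border
        assert np.array_equal(fill_regions(mask), mask)

    def test_fill_idempotent(self, rng):
        mask = rng.random((25, 25)) > 0.5
        once = fill_regions(mask)
        assert np.array_equal(fill_regions(once), once)


class TestLocalize:
    def test_empty_mask_is_grayscale_replica(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        overlay = localize(img, np.zeros_like(img, dtype=bool))
        assert np.array_equal(overlay[..., 0], img)
        assert np.array_equal(overlay[..., 1], img)

    def test_highlight_restricted_to_mask(self, rng):
        img = rng.integers(0, 200, size=(8, 8)).astype(np.uint8)
        mask = np.zeros_like(img, dtype=bool)
        mask[2, 3] = True
        overlay = localize(img, mask)
        changed = np.any(overlay != np.stack([img] * 3, -1), axis=-1)
        assert np.array_equal(changed, mask)


class TestPipeline:
    CFG = dict(optimizer="gtorbl", n_thresholds=2, top_k=1)

    def test_deterministic_masks(self, default_phantom):
        cfg = PipelineConfig(**self.CFG)
        a = segment_image(default_phantom.image, cfg, np.random.default_rng(17))
        b = segment_image(default_phantom.image, cfg, np.random.default_rng(17))
        assert np.array_equal(a.lesion_mask, b.lesion_mask)
        assert np.array_equal(a.thresholds, b.thresholds)

    def test_entropy_consistent_with_thresholds(self, default_phantom):
        cfg = PipelineConfig(**self.CFG)
        res = segment_image(default_phantom.image, cfg, np.random.default_rng(4))
        corrected = correct_iih(
            anisotropic_diffusion(default_phantom.image, cfg.adf_params),
            cfg.iih_window, cfg.iih_sigma)
        p = to_probabilities(compute_histogram(corrected))
        assert res.entropy == pytest.approx(kapur_entropy(p, res.thresholds))
        assert res.entropy == res.optimizer_result.trace[-1][1]

    def test_single_intensity_image_rejected(self):
        img = np.full((64, 64), 128, dtype=np.uint8)
        with pytest.raises(ValueError, match="fewer occupied levels"):
            segment_image(img, PipelineConfig(**self.CFG), np.random.default_rng(0))

    def test_modes_separated_on_clean_phantoms(self):
        """Noiseless bias-free three-mode phantoms: recovered thresholds
        must separate the intensity modes in every seed."""
        spec = PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, intensity_sd=2.0)
        cfg = PipelineConfig(optimizer="gtorbl", n_thresholds=2, top_k=1,
                             gto_params=GTOParams(n_agents=20, max_iters=40))
        for seed in range(5):
            pair = generate_phantom(spec, np.random.default_rng(200 + seed))
            res = segment_image(pair.image, cfg, np.random.default_rng(seed))
            # the top class must be exactly the lesion pixels
            assert res.lesion_mask.sum() > 0
            overlap = (res.lesion_mask & pair.gt_mask).sum()
            assert overlap / pair.gt_mask.sum() > 0.99

    def test_gto_variant_runs(self, default_phantom):
        cfg = PipelineConfig(optimizer="gto", n_thresholds=2, top_k=1,
                             gto_params=GTOParams(n_agents=10, max_iters=15))
        res = segment_image(default_phantom.image, cfg, np.random.default_rng(1))
        assert res.labels.shape == default_phantom.image.shape
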