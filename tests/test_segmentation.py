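"""Detection-chain correctness: oracle equivalence on small fixtures,
stage invariants, and recovery on synthetic scenes."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import as_image
from fcquant.image import LabelMap
from fcquant.quantify import shape_parameters
from fcquant.segmentation import (SegmentationConfig, local_gradient_threshold,
                                  segment_focal_contacts, specificity_filter,
                                  split_touching)
from fcquant.synthetic import CHANNEL_CONTACT, control_spec, generate_scene
from oracles import (brute_local_gradient_threshold, brute_specificity_mask,
                     disk_offsets)


def _gaussian_spot(shape, center, sigma, peak, background=0.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return background + peak * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma ** 2))


# --- fixture battery for oracle equivalence (all <= 32x32) -------------------

def fixture_images():
    imgs = {}
    sq = np.zeros((32, 32))
    sq[10:15, 12:17] = 100.0
    imgs["square_on_zero"] = sq

    two = np.full((32, 32), 10.0)
    two[4:8, 4:8] = 1000.0
    two[22:27, 22:27] = 100.0
    imgs["bright_and_dim"] = two

    imgs["gaussian_spot"] = _gaussian_spot((21, 21), (10, 10), 2.5, 100.0, 10.0)

    rng = np.random.default_rng(77)
    imgs["random_noise"] = rng.integers(90, 130, size=(32, 32)).astype(float)

    blobs = np.full((32, 32), 5.0)
    blobs[6:12, 6:12] = 80.0
    blobs[18:26, 14:24] = 60.0
    imgs["two_blobs"] = blobs
    return imgs


ORACLE_CONFIG = SegmentationConfig(window_radius_px=7, local_k=2.0,
                                   gradient_seed_percentile=90.0,
                                   ring_width_px=2, core_erosion_px=1,
                                   specificity_ratio_min=1.3, min_area_px=4,
                                   split_min_separation_px=3)


class TestLocalGradientThresholdOracle:
    @pytest.mark.parametrize("name", list(fixture_images()))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_pixel_for_pixel(self, name, connectivity):
        img = fixture_images()[name]
        cfg = SegmentationConfig(
            window_radius_px=7, local_k=2.0, gradient_seed_percentile=90.0,
            connectivity=connectivity)
        got = local_gradient_threshold(as_image(img), cfg).labels > 0
        expected = brute_local_gradient_threshold(img, 7, 2.0, 90.0, connectivity)
        np.testing.assert_array_equal(got, expected, err_msg=name)

    def test_uniform_image_empty(self):
        out = local_gradient_threshold(as_image(np.full((32, 32), 42.0)),
                                       ORACLE_CONFIG)
        assert out.n_labels == 0

    def test_square_fully_detected(self):
        """A 5x5 square of 100 on zero background is recovered exactly."""
        img = fixture_images()["square_on_zero"]
        out = local_gradient_threshold(as_image(img), ORACLE_CONFIG)
        assert ((out.labels > 0) & (img > 0)).sum() == 25

    def test_local_not_global(self):
        """Both a 1000-peak and a 100-peak object are detected: thresholds
        adapt locally instead of being set by the global maximum."""
        img = fixture_images()["bright_and_dim"]
        out = local_gradient_threshold(as_image(img), ORACLE_CONFIG)
        lab, n = ndimage.label(out.labels > 0)
        assert n >= 2
        assert (out.labels[5, 5] > 0) and (out.labels[24, 24] > 0)

    def test_oversized_window_rejected(self):
        cfg = SegmentationConfig(window_radius_px=40)
        with pytest.raises(ValueError, match="window"):
            local_gradient_threshold(as_image(np.zeros((32, 32))), cfg)

    def test_brightness_scale_covariance(self):
        """With zero additive background, multiplying the image by c > 0
        leaves the thresholding decision unchanged."""
        img = fixture_images()["square_on_zero"] + 0.0
        base = local_gradient_threshold(as_image(img), ORACLE_CONFIG).labels
        for c in (0.5, 3.0, 17.0):
            scaled = local_gradient_threshold(as_image(img * c), ORACLE_CONFIG).labels
            np.testing.assert_array_equal(base, scaled)


class TestSpecificityFilterOracle:
    @pytest.mark.parametrize("name", list(fixture_images()))
    def test_matches_brute_force(self, name):
        img = fixture_images()[name]
        cfg = ORACLE_CONFIG
        cand = local_gradient_threshold(as_image(img), cfg)
        got = specificity_filter(cand, as_image(img), cfg).labels > 0
        expected = brute_specificity_mask(
            img, np.asarray(cand.labels > 0), cfg.connectivity,
            cfg.core_erosion_px, cfg.ring_width_px,
            cfg.specificity_ratio_min, cfg.min_area_px)
        np.testing.assert_array_equal(got, expected, err_msg=name)

    def test_flat_contrast_component_removed(self):
        """A component whose inside equals its outside (ratio 1.0) fails the
        1.3 contrast requirement."""
        img = np.full((20, 20), 50.0)
        cand = np.zeros((20, 20), dtype=np.int32)
        cand[8:12, 8:12] = 1
        out = specificity_filter(LabelMap(cand), as_image(img), ORACLE_CONFIG)
        assert out.n_labels == 0

    def test_gaussian_spot_retained(self):
        img = fixture_images()["gaussian_spot"]
        cand = local_gradient_threshold(as_image(img), ORACLE_CONFIG)
        out = specificity_filter(cand, as_image(img), ORACLE_CONFIG)
        assert out.n_labels == 1

    def test_empty_input_empty_output(self):
        empty = LabelMap(np.zeros((16, 16), dtype=np.int32))
        out = specificity_filter(empty, as_image(np.ones((16, 16))), ORACLE_CONFIG)
        assert out.n_labels == 0

    def test_retained_pixel_sets_unchanged(self):
        img = fixture_images()["two_blobs"]
        cand = local_gradient_threshold(as_image(img), ORACLE_CONFIG)
        out = specificity_filter(cand, as_image(img), ORACLE_CONFIG)
        # monotone refinement: every retained component is a candidate component
        assert np.all((out.labels > 0) <= (cand.labels > 0))
        lab_in, _ = ndimage.label(cand.labels > 0,
                                  ndimage.generate_binary_structure(2, 2))
        for l in range(1, out.n_labels + 1):
            comp = out.labels == l
            src = np.unique(lab_in[comp])
            assert len(src) == 1  # not merged
            np.testing.assert_array_equal(comp, lab_in == src[0])  # not trimmed


class TestSplitTouching:
    def _disk_pair(self, sep):
        from skimage.draw import disk as skdisk
        m = np.zeros((40, 40), dtype=np.int32)
        rr, cc = skdisk((20, 16), 4.5)
        m[rr, cc] = 1
        rr, cc = skdisk((20, 16 + sep), 4.5)
        m[rr, cc] = 1
        return LabelMap(m)

    def test_overlapping_disks_split_in_two(self):
        lm = self._disk_pair(8)  # 9-px disks overlapping through a neck
        out = split_touching(lm, ORACLE_CONFIG)
        assert out.n_labels == 2

    def test_single_disk_unchanged(self):
        from skimage.draw import disk as skdisk
        m = np.zeros((30, 30), dtype=np.int32)
        rr, cc = skdisk((15, 15), 4.5)
        m[rr, cc] = 1
        out = split_touching(LabelMap(m), ORACLE_CONFIG)
        assert out.n_labels == 1
        np.testing.assert_array_equal(out.labels > 0, m > 0)

    @pytest.mark.parametrize("sep", [6, 8, 12])
    def test_partition_property(self, sep):
        """Splitting never gains or loses a foreground pixel."""
        lm = self._disk_pair(sep)
        out = split_touching(lm, ORACLE_CONFIG)
        np.testing.assert_array_equal(out.labels > 0, lm.labels > 0)
        assert out.n_labels >= 1

    def test_empty_map(self):
        out = split_touching(LabelMap(np.zeros((10, 10), dtype=np.int32)),
                             ORACLE_CONFIG)
        assert out.n_labels == 0


class TestFullChainRecovery:
    def test_twenty_contact_scene_recovered(self, small_scene):
        """~20 true contacts at peak SNR >= 10: detected count within ±10%."""
        channels, truth = small_scene
        labels = segment_focal_contacts(channels[CHANNEL_CONTACT])
        n_true = len(truth.contacts)
        assert n_true == 20
        assert 18 <= labels.n_labels <= 22

    def test_pure_noise_yields_no_detections(self):
        """Median 0 and max <= 2 detections across 20 contact-free noise
        scenes under the default configuration."""
        counts = []
        for seed in range(300, 320):
            spec = control_spec(image_size=(256, 256), cell_radius_um=20.0,
                                fa_count_law=(0.0, 0.0), rng_seed=seed)
            channels, _ = generate_scene(spec)
            counts.append(
                segment_focal_contacts(channels[CHANNEL_CONTACT]).n_labels)
        assert np.median(counts) == 0
        assert max(counts) <= 2

    def test_chain_equals_composition(self, small_scene):
        channels, _ = small_scene
        img = channels[CHANNEL_CONTACT]
        cfg = SegmentationConfig()
        direct = segment_focal_contacts(img, cfg)
        composed = split_touching(
            specificity_filter(local_gradient_threshold(img, cfg), img, cfg), cfg)
        np.testing.assert_array_equal(direct.labels, composed.labels)

    def test_labels_match_record_count(self, small_scene):
        channels, _ = small_scene
        img = channels[CHANNEL_CONTACT]
        labels = segment_focal_contacts(img)
        records = shape_parameters(labels, img)
        assert labels.n_labels == len(records)
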