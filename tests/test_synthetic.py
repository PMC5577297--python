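"""Generator correctness: determinism, ground-truth consistency, group laws,
and the linear fiber-gradient render."""

import dataclasses
import math

import numpy as np
import pytest

from fcquant.image import read_image
from fcquant.synthetic import (CHANNEL_ACTIN, CHANNEL_CONTACT, CHANNEL_FASCIN,
                               CHANNEL_NUCLEI, SceneOvercrowdedError, SceneSpec,
                               control_spec, generate_gradient_fiber_scene,
                               generate_group, generate_nuclei_field,
                               generate_scene, knockdown_spec,
                               truth_contact_label_map, write_scene)


class TestGenerateScene:
    def test_seeded_determinism_bit_exact(self, small_scene_spec):
        ch1, t1 = generate_scene(small_scene_spec)
        ch2, t2 = generate_scene(small_scene_spec)
        for name in ch1:
            np.testing.assert_array_equal(ch1[name].pixels, ch2[name].pixels)
        assert [c.center for c in t1.contacts] == [c.center for c in t2.contacts]

    def test_different_seed_differs(self, small_scene_spec):
        ch1, _ = generate_scene(small_scene_spec)
        ch2, _ = generate_scene(dataclasses.replace(small_scene_spec, rng_seed=8))
        assert not np.array_equal(ch1[CHANNEL_CONTACT].pixels,
                                  ch2[CHANNEL_CONTACT].pixels)

    def test_channel_set(self, small_scene):
        channels, _ = small_scene
        assert set(channels) == {CHANNEL_CONTACT, CHANNEL_ACTIN,
                                 CHANNEL_FASCIN, CHANNEL_NUCLEI}

    def test_zero_count_law_gives_background_only(self):
        spec = control_spec(image_size=(128, 128), cell_radius_um=10.0,
                            fa_count_law=(0.0, 0.0), rng_seed=1)
        channels, truth = generate_scene(spec, apply_noise=False)
        assert truth.contacts == []
        np.testing.assert_allclose(channels[CHANNEL_CONTACT].pixels,
                                   spec.background_level, atol=1e-9)

    def test_contacts_inside_their_cell_footprint(self, small_scene):
        _, truth = small_scene
        cells = {c.cell_id: c for c in truth.cells}
        for ct in truth.contacts:
            r, c = int(round(ct.center[0])), int(round(ct.center[1]))
            assert cells[ct.cell_id].footprint[r, c]

    def test_true_area_is_pi_a_b(self, small_scene):
        _, truth = small_scene
        for ct in truth.contacts:
            assert ct.area_um2 == pytest.approx(
                math.pi * ct.semi_major_um * ct.semi_minor_um, rel=1e-12)

    def test_truth_contacts_visible_above_background(self, small_scene_spec):
        channels, truth = generate_scene(small_scene_spec, apply_noise=False)
        img = channels[CHANNEL_CONTACT].pixels
        bg = small_scene_spec.background_level
        for ct in truth.contacts:
            r, c = int(round(ct.center[0])), int(round(ct.center[1]))
            assert img[r, c] > bg + 0.5 * ct.peak_intensity

    def test_rasterized_mask_area_matches_truth_within_10pct(self, small_scene):
        """Sum of analytic truth areas vs pixel count of the rasterized
        half-peak ellipses."""
        _, truth = small_scene
        lab = truth_contact_label_map(truth)
        px2 = truth.spec.pixel_size_um ** 2
        raster_area = float((lab.labels > 0).sum()) * px2
        true_area = sum(ct.area_um2 for ct in truth.contacts)
        assert abs(raster_area - true_area) / true_area <= 0.10

    def test_overcrowded_scene_raises(self):
        spec = control_spec(image_size=(96, 96), cell_radius_um=8.0,
                            fa_count_law=(500.0, 0.0), rng_seed=2)
        with pytest.raises(SceneOvercrowdedError, match="overcrowded"):
            generate_scene(spec)

    def test_too_many_cells_rejected(self):
        with pytest.raises(ValueError, match="cannot hold"):
            SceneSpec(n_cells=50).validate()


class TestGenerateGroup:
    def test_single_scene_per_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            generate_group(control_spec(), knockdown_spec(), 1, 0)

    def test_spurious_spec_difference_warns(self):
        a = control_spec(image_size=(128, 128), cell_radius_um=10.0,
                         fa_count_law=(5, 0))
        b = dataclasses.replace(a, background_level=55.0)
        with pytest.warns(UserWarning, match="differ"):
            generate_group(a, b, 2, 0)

    def test_count_law_recovered_within_3_se(self):
        """Sample mean of true per-cell counts lands within 3 standard errors
        of the generating law (CLT bound), and the true percent reduction of
        the group means is ~36%."""
        ctrl = control_spec(image_size=(256, 256), cell_radius_um=20.0,
                            fa_count_law=(49.0, 3.75), fa_area_law_um2=(1.48, 0.30))
        kd = dataclasses.replace(ctrl, fa_count_law=(31.25, 3.0),
                                 fa_area_law_um2=(1.19, 0.25))
        # scaled geometry keeps the count/area laws' RATIO structure: the
        # reduction target 1 - 31.25/49 = 36.2% matches the full-size laws
        control, test = generate_group(ctrl, kd, 50, rng_seed=99, apply_noise=False)
        counts_c = np.array([len(t.contacts) for _, t in control])
        counts_k = np.array([len(t.contacts) for _, t in test])
        for counts, law in ((counts_c, ctrl.fa_count_law), (counts_k, kd.fa_count_law)):
            se = law[1] / math.sqrt(len(counts))
            assert abs(counts.mean() - law[0]) <= 3.0 * se + 0.5  # +0.5: integer rounding
        reduction = 100.0 * (1.0 - counts_k.mean() / counts_c.mean())
        assert reduction == pytest.approx(36.2, abs=4.0)

    def test_seeds_derived_reproducibly(self):
        a = control_spec(image_size=(128, 128), cell_radius_um=10.0,
                         fa_count_law=(5, 1))
        b = dataclasses.replace(a, fa_count_law=(3, 1))
        g1 = generate_group(a, b, 2, rng_seed=5)
        g2 = generate_group(a, b, 2, rng_seed=5)
        for (ch1, _), (ch2, _) in zip(g1[0] + g1[1], g2[0] + g2[1]):
            np.testing.assert_array_equal(ch1[CHANNEL_CONTACT].pixels,
                                          ch2[CHANNEL_CONTACT].pixels)


@pytest.fixture(scope="module")
def scene():
    spec = control_spec(image_size=(256, 256), cell_radius_um=20.0,
                        morphology_mode="stretched", fa_count_law=(0.0, 0.0),
                        gradient_slopes=(-80.0, 80.0),
                        fiber_base_intensity=(100.0, 20.0),
                        background_level=0.0, rng_seed=11)
    return spec, generate_gradient_fiber_scene(spec, apply_noise=False)


class TestGradientFiberScene:
    def test_requires_stretched_mode(self):
        with pytest.raises(ValueError, match="stretched"):
            generate_gradient_fiber_scene(control_spec())

    def test_requires_opposite_slopes(self):
        spec = control_spec(morphology_mode="stretched",
                            gradient_slopes=(80.0, 80.0))
        with pytest.raises(ValueError, match="opposite"):
            generate_gradient_fiber_scene(spec)

    def test_negative_intensity_law_rejected(self):
        spec = control_spec(morphology_mode="stretched",
                            gradient_slopes=(-150.0, 80.0),
                            fiber_base_intensity=(100.0, 20.0))
        with pytest.raises(ValueError, match="negative"):
            generate_gradient_fiber_scene(spec)

    def test_midpoint_interpolation(self, scene):
        """Slopes (-80, +80) over bases (100, 20): both channels read 60 at
        each fiber's midpoint in the noiseless render."""
        spec, (channels, truth) = scene
        for fib in truth.fibers:
            mid = (fib.vertices[0] + fib.vertices[-1]) / 2.0
            r, c = int(round(mid[0])), int(round(mid[1]))
            for name in (CHANNEL_ACTIN, CHANNEL_FASCIN):
                assert channels[name].pixels[r, c] == pytest.approx(60.0, abs=1.0)

    def test_noiseless_profile_matches_linear_law(self, scene):
        """Sampled on-axis intensity deviates <= 1 unit from the recorded
        endpoint interpolation."""
        spec, (channels, truth) = scene
        for fib in truth.fibers:
            v0, v1 = fib.vertices[0], fib.vertices[-1]
            length = np.hypot(*(v1 - v0))
            for t in np.linspace(0.05, 0.95, 19):
                p = v0 + t * (v1 - v0)
                r, c = int(round(p[0])), int(round(p[1]))
                for ci, name in enumerate((CHANNEL_ACTIN, CHANNEL_FASCIN)):
                    start, end = fib.endpoint_intensities[ci]
                    expected = start + t * (end - start)
                    assert abs(channels[name].pixels[r, c] - expected) <= 1.0, \
                        f"fiber {fib.fiber_id} t={t}"

    def test_zero_slopes_constant_fibers(self):
        spec = control_spec(image_size=(256, 256), cell_radius_um=20.0,
                            morphology_mode="stretched", fa_count_law=(0.0, 0.0),
                            gradient_slopes=(0.0, 0.0),
                            fiber_base_intensity=(100.0, 20.0),
                            background_level=0.0, rng_seed=11)
        channels, truth = generate_scene(spec, apply_noise=False)
        actin = channels[CHANNEL_ACTIN].pixels
        on_fiber = actin[actin > 0]
        np.testing.assert_allclose(on_fiber, 100.0)

    def test_fibers_start_at_arc(self, scene):
        _, (_, truth) = scene
        arcs = {c.cell_id: c.arc for c in truth.cells}
        for fib in truth.fibers:
            arc = arcs[fib.cell_id]
            assert np.hypot(fib.vertices[0][0] - arc[0],
                            fib.vertices[0][1] - arc[1]) < 1e-9


class TestNucleiField:
    def test_deterministic_and_counted(self):
        spec = control_spec(image_size=(256, 256), nucleus_radius_um=2.0)
        img1, pts1 = generate_nuclei_field(spec, 12, rng_seed=4)
        img2, pts2 = generate_nuclei_field(spec, 12, rng_seed=4)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        assert pts1.shape == (12, 2)
        np.testing.assert_array_equal(pts1, pts2)

    def test_overcrowding_raises(self):
        spec = control_spec(image_size=(128, 128), nucleus_radius_um=10.0)
        with pytest.raises(SceneOvercrowdedError):
            generate_nuclei_field(spec, 100, rng_seed=4)


class TestWriteScene:
    def test_scene_directory_contents(self, tmp_path, small_scene):
        channels, truth = small_scene
        write_scene(channels, truth, tmp_path)
        img = read_image(tmp_path / f"{CHANNEL_CONTACT}.tiff")
        assert img.pixel_size_um == pytest.approx(truth.spec.pixel_size_um, rel=1e-6)
        assert (tmp_path / "truth_contacts.csv").exists()
        assert (tmp_path / "scene.json").exists()
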