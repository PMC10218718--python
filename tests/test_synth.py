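"""The synthetic slide/patch generator and its ground-truth guarantees."""

from __future__ import annotations

import numpy as np
import pytest

from tsr_slide.datatypes import LABEL_CODES
from tsr_slide.stain import (
    DEFAULT_REFERENCE,
    estimate_stain_matrix,
    rgb_to_od,
    solve_concentrations,
    stain_model_angles_deg,
)
from tsr_slide.synth import (
    SyntheticLayout,
    TextureParams,
    make_domain_pair,
    make_patch_dataset,
    make_slide,
    rotate_stain_model,
)


class TestLayouts:
    def test_blob_fractions_exact(self):
        fr = {"tumor": 0.4, "stroma": 0.35, "other": 0.15, "background": 0.1}
        labels = SyntheticLayout.blobs(fr, 400, 300, seed=1).label_map()
        for name, f in fr.items():
            got = np.count_nonzero(labels == LABEL_CODES[name]) / labels.size
            assert got == pytest.approx(f, abs=1e-4)

    def test_every_pixel_classed(self):
        labels = SyntheticLayout.vertical_bands(
            [("tumor", 0.5), ("stroma", 0.5)], 300, 300
        ).label_map()
        assert set(np.unique(labels)) <= set(LABEL_CODES.values())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticLayout.blobs({"tumor": 0.5}, 300, 300)


class TestMakeSlide:
    def test_canvas_smaller_than_patch_rejected(self):
        layout = SyntheticLayout.uniform("tumor", 100, 100)
        with pytest.raises(ValueError, match="smaller than one"):
            make_slide(layout)

    def test_pure_background_is_near_white(self):
        slide, truth = make_slide(SyntheticLayout.uniform("background", 300, 300))
        assert slide.pixels.min() >= 0.85 * 255
        assert truth.region_areas["background"] == 300 * 300
        assert truth.expected_tsr is None

    def test_half_tumor_half_stroma_expected_tsr(self):
        layout = SyntheticLayout.vertical_bands(
            [("tumor", 0.5), ("stroma", 0.5)], 448, 448
        )
        _, truth = make_slide(layout)
        assert truth.expected_tsr == 0.5
        assert truth.pixel_tsr == 0.5

    def test_label_map_matches_regions_exactly(self):
        layout = SyntheticLayout.vertical_bands(
            [("tumor", 0.25), ("stroma", 0.5), ("other", 0.25)], 400, 300
        )
        _, truth = make_slide(layout)
        labels = truth.annotation.labels
        assert (labels[:, :100] == LABEL_CODES["tumor"]).all()
        assert (labels[:, 100:300] == LABEL_CODES["stroma"]).all()
        assert (labels[:, 300:] == LABEL_CODES["other"]).all()

    def test_region_areas_sum_to_canvas(self, blob_slide):
        _, truth = blob_slide
        assert sum(truth.region_areas.values()) == truth.annotation.labels.size

    def test_adipose_near_white(self, blob_slide):
        slide, truth = blob_slide
        adipose = truth.annotation.labels == LABEL_CODES["adipose"]
        assert slide.pixels[adipose].min() >= 0.85 * 255 - 5  # sensor noise margin

    def test_unquantized_render_od_roundtrip(self):
        """Mean OD per class equals stain matrix times mean concentrations."""
        layout = SyntheticLayout.vertical_bands(
            [("tumor", 0.5), ("stroma", 0.5)], 300, 300, seed=4
        )
        slide, truth = make_slide(layout, quantize=False)
        od = rgb_to_od(slide.pixels)
        for name in ("tumor", "stroma"):
            sel = truth.annotation.labels == LABEL_CODES[name]
            mean_od = od[sel].mean(axis=0)
            expected = truth.stains.stain_matrix @ np.array(
                truth.class_mean_concentrations[name]
            )
            assert np.allclose(mean_od, expected, atol=1e-6)

    def test_stain_recovery_from_slide(self, blob_slide):
        slide, truth = blob_slide
        est = estimate_stain_matrix(rgb_to_od(slide.pixels[::3, ::3]))
        ang = stain_model_angles_deg(est, truth.stains)
        assert max(ang) < 2.0


class TestPatchDatasets:
    def test_counts_and_shape(self, small_patchset):
        assert len(small_patchset) == 60
        assert small_patchset.class_counts() == {"tumor": 20, "stroma": 20, "other": 20}
        assert small_patchset.patches.shape[1:] == (224, 224, 3)

    def test_deterministic_for_fixed_seed(self):
        a = make_patch_dataset(3, seed=42)
        b = make_patch_dataset(3, seed=42)
        assert np.array_equal(a.patches, b.patches)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError, match="n_per_class"):
            make_patch_dataset(0)

    def test_same_seed_different_stains_same_concentrations(self):
        other = rotate_stain_model(DEFAULT_REFERENCE, 12.0)
        a = make_patch_dataset(2, stains=DEFAULT_REFERENCE, seed=5)
        b = make_patch_dataset(2, stains=other, seed=5)
        assert not np.array_equal(a.patches, b.patches)  # colors differ
        # decomposing each rendering against its own stain model recovers the
        # same underlying concentration maps
        ca = solve_concentrations(rgb_to_od(a.patches[0]), DEFAULT_REFERENCE.stain_matrix)
        cb = solve_concentrations(rgb_to_od(b.patches[0]), other.stain_matrix)
        assert np.abs(ca - cb).mean() < 0.01


class TestDomainPair:
    def test_default_pair_has_ten_degree_stain_shift(self):
        set_a, set_b = make_domain_pair(n_per_class=6, seed=0)
        est_a = estimate_stain_matrix(rgb_to_od(set_a.patches.reshape(-1, 3)[::13]))
        est_b = estimate_stain_matrix(rgb_to_od(set_b.patches.reshape(-1, 3)[::13]))
        ang = stain_model_angles_deg(est_a, est_b)
        assert 7.0 < max(ang) < 13.0

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            make_domain_pair(n_per_class=0)

    def test_classifier_trained_on_target_degrades_on_source(self):
        """The domain shift is large enough to cost a target-only classifier
        accuracy on the shifted source dataset (deterministic desk-scale run)."""
        from tsr_slide.nn import SmallCNN
        from tsr_slide.util import downsample_patches

        a, b = make_domain_pair(n_per_class=60, seed=2)
        xa, ya = downsample_patches(a.patches), a.labels
        xb, yb = downsample_patches(b.patches), b.labels
        idx = np.random.default_rng(0).permutation(180)
        train_idx, heldout_idx = idx[:135], idx[135:]
        net = SmallCNN(seed=0)
        net.fit(xa[train_idx], ya[train_idx], epochs=8, lr=0.005, seed=1)
        acc_a = net.accuracy(xa[heldout_idx], ya[heldout_idx])
        acc_b = net.accuracy(xb, yb)
        assert acc_b < acc_a

    def test_identical_parameters_warn_but_return(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            a, b = make_domain_pair(
                textures_a=TextureParams(), textures_b=TextureParams(),
                stains_b=DEFAULT_REFERENCE, n_per_class=1, seed=1,
            )
        assert len(a) == len(b) == 3
        assert any("identical" in r.message for r in caplog.records)
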