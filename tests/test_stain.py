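"""Macenko stain normalization: OD transform, estimation, normalization."""

from __future__ import annotations

import numpy as np
import pytest

from tsr_slide.datatypes import StainModel
from tsr_slide.stain import (
    DEFAULT_REFERENCE,
    InsufficientTissueError,
    estimate_stain_matrix,
    normalize_patch,
    od_to_rgb,
    rgb_to_od,
    solve_concentrations,
    stain_model_angles_deg,
)
from tsr_slide.synth import rotate_stain_model


def _stain_cloud(
    stains: StainModel,
    n: int = 20000,
    seed: int = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """RGB pixel cloud rendered from a stain model.

    Mixes mostly-hematoxylin, mostly-eosin and mixed pixels, mimicking the
    composition of counterstained tissue (nuclei, collagen, cytoplasm).
    """
    rng = np.random.default_rng(seed)
    thirds = n // 3
    ch = np.concatenate([
        rng.uniform(0.4, 0.95, thirds),        # nuclei: strong H
        rng.uniform(0.0, 0.03, thirds),        # collagen: almost no H
        rng.uniform(0.1, 0.6, n - 2 * thirds), # mixed
    ])
    ce = np.concatenate([
        rng.uniform(0.0, 0.03, thirds),
        rng.uniform(0.4, 0.95, thirds),
        rng.uniform(0.1, 0.6, n - 2 * thirds),
    ])
    conc = np.stack([ch, ce], axis=1) * scale
    od = conc @ stains.stain_matrix.T
    return od_to_rgb(od)


class TestOpticalDensity:
    def test_known_values(self):
        assert np.allclose(rgb_to_od(np.array([255.0, 255.0, 255.0])), 0.0)
        assert np.allclose(rgb_to_od(np.array([25.5, 25.5, 25.5])), 1.0)

    def test_round_trip_within_one_intensity_unit(self, rng):
        patch = rng.integers(1, 256, size=(40, 40, 3)).astype(np.uint8)
        back = od_to_rgb(rgb_to_od(patch))
        assert np.abs(back - patch).max() <= 1.0

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            rgb_to_od(np.zeros((10, 10)))


class TestEstimateStainMatrix:
    def test_recovers_known_model_within_two_degrees(self):
        truth = rotate_stain_model(DEFAULT_REFERENCE, 5.0)
        est = estimate_stain_matrix(rgb_to_od(_stain_cloud(truth)))
        ang_h, ang_e = stain_model_angles_deg(est, truth)
        assert ang_h < 2.0 and ang_e < 2.0

    def test_concentration_scaling_leaves_directions_changes_maxima(self):
        base = estimate_stain_matrix(rgb_to_od(_stain_cloud(DEFAULT_REFERENCE, scale=0.5)))
        doubled = estimate_stain_matrix(rgb_to_od(_stain_cloud(DEFAULT_REFERENCE, scale=1.0)))
        ang = stain_model_angles_deg(base, doubled)
        assert max(ang) < 1.0
        ratio = doubled.max_concentrations / base.max_concentrations
        assert np.allclose(ratio, 2.0, rtol=0.1)

    def test_single_pure_stain_is_degenerate(self, rng):
        conc = rng.uniform(0.3, 1.0, size=(5000, 1))
        od = conc @ DEFAULT_REFERENCE.stain_matrix[:, :1].T
        with pytest.raises(InsufficientTissueError):
            estimate_stain_matrix(od)

    def test_blank_patch_raises_insufficient_tissue(self):
        white = np.full((64, 64, 3), 255.0)
        with pytest.raises(InsufficientTissueError, match="insufficient tissue"):
            estimate_stain_matrix(rgb_to_od(white))

    def test_pixel_order_invariance(self, rng):
        cloud = _stain_cloud(DEFAULT_REFERENCE, n=5000)
        od = rgb_to_od(cloud)
        shuffled = od[rng.permutation(len(od))]
        a = estimate_stain_matrix(od)
        b = estimate_stain_matrix(shuffled)
        assert np.allclose(a.stain_matrix, b.stain_matrix, atol=1e-9)
        assert np.allclose(a.max_concentrations, b.max_concentrations, atol=1e-9)

    def test_hematoxylin_column_is_blue_heavy(self):
        est = estimate_stain_matrix(rgb_to_od(_stain_cloud(DEFAULT_REFERENCE)))
        assert est.stain_matrix[2, 0] >= est.stain_matrix[2, 1]


class TestNormalizePatch:
    def test_identity_when_source_matches_reference(self, rng):
        # patch drawn from the reference model with concentrations whose 99th
        # percentile matches the reference maxima -> normalization is a no-op
        cloud = _stain_cloud(DEFAULT_REFERENCE, n=64 * 64, seed=3)
        # stretch so the 99th percentile of each concentration is ~1 (= ref max)
        conc = solve_concentrations(rgb_to_od(cloud), DEFAULT_REFERENCE.stain_matrix)
        conc /= np.percentile(conc, 99, axis=0, keepdims=True)
        patch = od_to_rgb((conc @ DEFAULT_REFERENCE.stain_matrix.T)).reshape(64, 64, 3)
        out = normalize_patch(patch)
        assert np.abs(out - patch).max() <= 2.0

    def test_collapses_stain_variation(self):
        rng = np.random.default_rng(9)
        conc = np.stack(
            [rng.uniform(0.0, 0.9, 48 * 48), rng.uniform(0.0, 0.9, 48 * 48)], axis=1
        )
        # make sure pure pixels exist so each rendering is well estimated
        conc[:200, 1] = 0.02
        conc[:200, 0] = rng.uniform(0.6, 0.9, 200)
        conc[200:400, 0] = 0.02
        conc[200:400, 1] = rng.uniform(0.6, 0.9, 200)
        model_a = rotate_stain_model(DEFAULT_REFERENCE, -8.0)
        model_b = rotate_stain_model(DEFAULT_REFERENCE, 8.0)
        patch_a = od_to_rgb(conc @ model_a.stain_matrix.T).reshape(48, 48, 3)
        patch_b = od_to_rgb(conc @ model_b.stain_matrix.T).reshape(48, 48, 3)
        out_a = normalize_patch(patch_a)
        out_b = normalize_patch(patch_b)
        assert np.abs(out_a - out_b).mean() < 4.0

    def test_idempotent_within_two_units(self, small_patchset):
        patch = small_patchset.patches[0].astype(float)
        once = normalize_patch(patch)
        twice = normalize_patch(once)
        assert np.abs(twice - once).max() <= 2.0

    def test_blank_patch_fallback_passthrough(self, caplog):
        white = np.full((32, 32, 3), 255, dtype=np.uint8)
        out = normalize_patch(white, fallback="passthrough")
        assert out is white
        with pytest.raises(InsufficientTissueError):
            normalize_patch(white, fallback="error")
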