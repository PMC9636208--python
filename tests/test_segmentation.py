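"""Segmentation stages against ground truth and independent linear-algebra oracles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage as ndi

from psrquant import (
    SegmentationConfig,
    WholeSlideImage,
    delineate_tissue,
    estimate_background,
    fit_stain_axes,
    project_third_axis,
    segment_slide,
    threshold_collagen,
    to_optical_density,
)
from psrquant.segmentation import InsufficientTissueError, stain_basis_from_od, _od_lut


def _uniform_slide(rgb, shape=(64, 64), um=0.452):
    px = np.empty((*shape, 3), np.uint8)
    px[:] = rgb
    return WholeSlideImage(px, um_per_pixel=um)


class TestOpticalDensity:
    def test_od_of_background_is_zero(self):
        assert np.allclose(to_optical_density((240, 240, 240), (240, 240, 240)), 0.0)

    def test_od_of_tenth_intensity_is_one(self):
        assert np.allclose(to_optical_density((24, 24, 24), (240, 240, 240)), 1.0)

    def test_eps_guards_zero_intensity(self):
        od = to_optical_density((0, 0, 0), (240, 240, 240), eps=0.5)
        assert np.allclose(od, 2.68124123738, atol=1e-9)  # log10(480)

    def test_lut_matches_elementwise_definition(self):
        lut = _od_lut((246.0, 240.0, 250.0), 0.5)
        for c, i0 in enumerate((246.0, 240.0, 250.0)):
            assert np.allclose(lut[c], [np.log10(i0 / max(i, 0.5)) for i in range(256)])


class TestBackground:
    def test_constant_image(self, cfg):
        assert estimate_background(_uniform_slide((245, 245, 245)), cfg) == (245.0, 245.0, 245.0)

    def test_all_black_clamps_to_one(self, cfg):
        assert estimate_background(_uniform_slide((0, 0, 0)), cfg) == (1.0, 1.0, 1.0)

    def test_synthetic_fixture_within_2_of_glass(self, default_slide, cfg):
        I0 = estimate_background(default_slide.as_wsi(), cfg)
        for c in range(3):
            assert abs(I0[c] - 245.0) <= 2.0


class TestTissueDelineation:
    def test_glass_only_slide_is_empty(self, cfg):
        mask = delineate_tissue(_uniform_slide((245, 245, 245), (128, 128)),
                                (245.0, 245.0, 245.0), cfg)
        assert not mask.any()

    def test_dice_against_ground_truth(self, default_slide, default_result):
        truth = default_slide.tissue_truth
        mask = default_result.tissue_mask
        dice = 2 * np.count_nonzero(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_no_hole_smaller_than_fill_area(self, default_result, default_slide, cfg):
        """Brute-force hole enumeration: every remaining hole exceeds hole_fill_um2."""
        mask = default_result.tissue_mask
        um = default_slide.params.um_per_pixel
        hole_px = cfg.hole_fill_um2 / um**2
        complement = ~mask
        labels, n = ndi.label(complement)
        border = set(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        sizes = ndi.sum_labels(complement, labels, index=np.arange(1, n + 1))
        for lab, size in zip(range(1, n + 1), sizes):
            if lab not in border:  # an enclosed hole
                assert size > hole_px


class TestStainAxes:
    def test_rank2_cloud_third_vector_is_nullspace(self):
        rng = np.random.default_rng(0)
        coeffs = rng.random((400, 2))
        od = coeffs @ np.array([[1.0, 0, 0], [0, 1.0, 0]])
        basis = stain_basis_from_od(od)
        assert np.allclose(np.abs(basis.v3), [0, 0, 1], atol=1e-10)
        assert basis.s3 == pytest.approx(0.0, abs=1e-8)

    def test_orthonormality(self):
        rng = np.random.default_rng(1)
        basis = stain_basis_from_od(rng.random((500, 3)))
        V = np.stack([basis.v1, basis.v2, basis.v3])
        assert np.allclose(V @ V.T, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gram_basis_matches_direct_svd(self, seed):
        """Oracle: numpy SVD of the full N x 3 matrix, up to sign, to 1e-8."""
        rng = np.random.default_rng(seed)
        od = rng.random((500, 3))
        basis = stain_basis_from_od(od)
        _, s, vt = np.linalg.svd(od, full_matrices=False)
        assert np.allclose([basis.s1, basis.s2, basis.s3], s, atol=1e-8)
        for v, w in zip((basis.v1, basis.v2, basis.v3), vt):
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_histogram_gram_matches_direct_on_real_slide(self, default_slide, cfg):
        """Whole-slide histogram accumulation equals the explicit OD matrix SVD."""
        wsi = default_slide.as_wsi()
        I0 = estimate_background(wsi, cfg)
        tissue = delineate_tissue(wsi, I0, cfg)
        basis = fit_stain_axes(wsi, tissue, I0, cfg)
        od = to_optical_density(wsi.pixels[tissue].astype(float), I0, cfg.eps_intensity)
        direct = stain_basis_from_od(od, I0, cfg.eps_intensity)
        assert np.allclose([basis.s1, basis.s2, basis.s3],
                           [direct.s1, direct.s2, direct.s3], rtol=1e-8)
        for v, w in zip((basis.v1, basis.v2, basis.v3), (direct.v1, direct.v2, direct.v3)):
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-6

    def test_too_few_tissue_pixels_raises(self, cfg):
        slide = _uniform_slide((100, 100, 100), (16, 16))
        tissue = np.zeros((16, 16), bool)
        tissue[:2, :2] = True
        with pytest.raises(InsufficientTissueError):
            fit_stain_axes(slide, tissue, (245.0, 245.0, 245.0), cfg)


class TestProjectionAndThreshold:
    def test_inplane_od_projects_to_zero(self):
        rng = np.random.default_rng(2)
        basis = stain_basis_from_od(rng.random((500, 3)))
        od = 0.3 * basis.v1 + 1.7 * basis.v2
        assert project_third_axis(od, basis) == pytest.approx(0.0, abs=1e-12)

    def test_v3_projects_to_its_coefficient(self):
        rng = np.random.default_rng(3)
        basis = stain_basis_from_od(rng.random((500, 3)))
        assert project_third_axis(0.5 * basis.v3, basis) == pytest.approx(0.5)

    def test_collagen_projects_above_parenchyma(self, default_slide, default_result, cfg):
        wsi = default_slide.as_wsi()
        I0 = default_result.background_I0
        od = to_optical_density(wsi.pixels.astype(float), I0, cfg.eps_intensity)
        proj = project_third_axis(od, default_result.basis)
        collagen = default_slide.collagen_truth
        parenchyma = default_slide.tissue_truth & ~collagen
        assert proj[collagen].mean() > proj[parenchyma].mean()

    def test_threshold_extremes(self, default_result):
        tissue = default_result.tissue_mask
        proj = np.where(tissue, 0.1, -0.1)
        assert not threshold_collagen(proj, tissue, 1e9).any()
        assert np.array_equal(threshold_collagen(proj, tissue, -1e9), tissue)

    def test_calibrated_threshold_iou(self, default_slide, default_result):
        truth = default_slide.collagen_truth
        mask = default_result.collagen_mask
        iou = np.count_nonzero(mask & truth) / np.count_nonzero(mask | truth)
        assert iou >= 0.80


class TestSegmentSlide:
    def test_five_runs_identical_counts(self, default_slide, cfg):
        wsi = default_slide.as_wsi()
        counts = {segment_slide(wsi, cfg).collagen_px for _ in range(5)}
        assert len(counts) == 1

    def test_tile_size_invariance_bitwise(self, default_slide, cfg):
        wsi = default_slide.as_wsi()
        r_small = segment_slide(wsi, replace(cfg, tile_px=256))
        r_large = segment_slide(wsi, replace(cfg, tile_px=2048))
        assert np.array_equal(r_small.collagen_mask, r_large.collagen_mask)
        assert np.array_equal(r_small.tissue_mask, r_large.tissue_mask)

    def test_blank_slide_yields_empty_masks(self, cfg):
        res = segment_slide(_uniform_slide((245, 245, 245), (256, 256)), cfg)
        assert res.tissue_px == 0 and res.collagen_px == 0

    def test_nesting_invariant(self, default_result):
        assert not np.any(default_result.collagen_mask & ~default_result.tissue_mask)


def test_config_json_roundtrip(tmp_path, cfg):
    path = str(tmp_path / "cfg.json")
    cfg.to_json(path)
    assert SegmentationConfig.from_json(path) == cfg
    import json
    with open(path) as fh:
        data = json.load(fh)
    data["bogus_key"] = 1
    with open(path, "w") as fh:
        json.dump(data, fh)
    with pytest.raises(ValueError, match="unknown config"):
        SegmentationConfig.from_json(path)
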