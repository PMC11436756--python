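"""Enrichment indices, puncta classification, population positivity."""

import numpy as np
import pytest

from acquant import (
    RoiSpec,
    SceneConfig,
    cilia_enrichment,
    count_internal_puncta,
    endosome_mask_from_marker,
    enrichment_index,
    estimate_background,
    fraction_positive,
    simulate_static_scene,
)
from acquant.enrichment import CellClassification
from acquant.segmentation import auto_threshold, max_project_z


def _toy_cell():
    """100-px cell: 20 px compartment at 30, 80 px at 10, background 0."""
    image = np.zeros((10, 12))
    cell = np.zeros((10, 12), dtype=bool)
    cell[:10, :10] = True
    comp = np.zeros((10, 12), dtype=bool)
    comp[:2, :10] = True
    image[cell] = 10.0
    image[comp] = 30.0
    return image, comp, cell


class TestBackground:
    def test_exterior_mean(self):
        image = np.full((8, 8), 10.0)
        cell = np.zeros((8, 8), dtype=bool)
        cell[2:6, 2:6] = True
        image[cell] = 50.0
        assert estimate_background(image, cell) == pytest.approx(10.0)

    def test_background_roi_restricts_estimate(self):
        image = np.full((8, 8), 10.0)
        image[:, 4:] = 99.0  # contaminated exterior region
        cell = np.zeros((8, 8), dtype=bool)
        cell[3:5, 1:3] = True
        roi = np.zeros((8, 8), dtype=bool)
        roi[:, :2] = True
        assert estimate_background(image, cell, background_roi=roi) == pytest.approx(10.0)

    def test_noisy_offset_recovered_within_two_se(self, rng):
        b = 25.0
        image = rng.normal(b, 3.0, size=(64, 64))
        cell = np.zeros((64, 64), dtype=bool)
        cell[20:40, 20:40] = True
        image[cell] += 100.0
        n_ext = (~cell).sum()
        est = estimate_background(image, cell)
        assert abs(est - b) <= 3 * 3.0 / np.sqrt(n_ext)

    def test_full_frame_cell_errors(self):
        with pytest.raises(ValueError, match="exterior"):
            estimate_background(np.ones((4, 4)), np.ones((4, 4), dtype=bool))


class TestEnrichmentIndex:
    def test_uniform_cell_gives_unit_mean_ratio(self):
        image = np.zeros((6, 6))
        cell = np.zeros((6, 6), dtype=bool)
        cell[1:5, 1:5] = True
        image[cell] = 10.0
        comp = np.zeros((6, 6), dtype=bool)
        comp[2, 2:4] = True
        res = enrichment_index(image, comp, cell)
        assert res.index == pytest.approx(1.0)
        assert res.convention == "mean-ratio"

    def test_mean_ratio_matches_pixel_sum_oracle(self):
        image, comp, cell = _toy_cell()
        res = enrichment_index(image, comp, cell)
        # hand oracle: mean(comp)=30 over mean(cell)=(20*30+80*10)/100=14
        assert res.index == pytest.approx(30.0 / 14.0, rel=1e-12)

    def test_integrated_ratio_matches_pixel_sum_oracle(self):
        image, comp, cell = _toy_cell()
        res = enrichment_index(image, comp, cell, convention="integrated-ratio")
        assert res.index == pytest.approx(600.0 / 1400.0, rel=1e-12)

    def test_empty_compartment_flagged_zero(self):
        image, _, cell = _toy_cell()
        res = enrichment_index(image, np.zeros_like(cell), cell)
        assert res.index == 0.0
        assert res.empty_compartment

    def test_zero_cell_fluorescence_errors(self):
        image, comp, cell = _toy_cell()
        with pytest.raises(ValueError, match="zero"):
            enrichment_index(image, comp, cell, background=100.0)

    def test_compartment_clipped_to_cell(self):
        image, comp, cell = _toy_cell()
        outside = comp.copy()
        outside[:, 10:] = True  # extends beyond the cell
        res = enrichment_index(image, outside, cell)
        assert res.index == pytest.approx(30.0 / 14.0, rel=1e-12)

    def test_scale_and_background_invariance(self, rng):
        image, comp, cell = _toy_cell()
        base = enrichment_index(image, comp, cell).index
        scaled = enrichment_index(image * 3.7, comp, cell).index
        offset = enrichment_index(image + 5.0, comp, cell, background=5.0).index
        assert scaled == pytest.approx(base, rel=1e-12)
        assert offset == pytest.approx(base, rel=1e-12)

    def test_area_dependence_by_convention(self):
        # enlarge a uniformly painted compartment: mean-ratio constant,
        # integrated-ratio proportional to the area fraction
        image = np.zeros((20, 20))
        cell = np.ones((20, 20), dtype=bool)
        image[cell] = 10.0
        small = np.zeros_like(cell)
        small[:2] = True
        large = np.zeros_like(cell)
        large[:8] = True
        image[small | large] = 10.0  # uniform cell
        m_small = enrichment_index(image, small, cell).index
        m_large = enrichment_index(image, large, cell).index
        i_small = enrichment_index(image, small, cell, convention="integrated-ratio").index
        i_large = enrichment_index(image, large, cell, convention="integrated-ratio").index
        assert m_small == pytest.approx(m_large)
        assert i_large / i_small == pytest.approx(4.0, rel=1e-12)


class TestEndosomeMask:
    def test_marker_below_threshold_gives_empty_flagged_result(self):
        marker = np.full((8, 8), 5.0)
        cell = np.ones((8, 8), dtype=bool)
        mask = endosome_mask_from_marker(marker, cell, 10.0)
        assert mask.area_px == 0
        res = enrichment_index(np.ones((8, 8)), mask, cell)
        assert res.index == 0.0 and res.empty_compartment

    def test_recovers_true_mask_exactly_noiseless(self, noiseless_scene_cfg):
        stack, truth = simulate_static_scene(noiseless_scene_cfg)
        marker = max_project_z(stack, 0)
        cell = truth.masks["cell"]
        thr = auto_threshold(marker, restrict_to=cell)
        mask = endosome_mask_from_marker(marker, cell, thr)
        np.testing.assert_array_equal(mask.pixels, truth.masks["endosomes"])

    def test_threshold_above_all_values_empty(self):
        marker = np.random.default_rng(0).random((8, 8))
        mask = endosome_mask_from_marker(marker, np.ones((8, 8), dtype=bool), 2.0)
        assert mask.area_px == 0


class TestPunctaClassification:
    def test_counts_painted_puncta_and_calls_positive(self, noiseless_scene_cfg):
        import dataclasses

        # AC9-like cell: endosome-enriched, no ciliary enrichment
        cfg = dataclasses.replace(noiseless_scene_cfg, n_endosomes=12, cilium_factor=1.0)
        stack, truth = simulate_static_scene(cfg)
        ac = max_project_z(stack, 1)
        # threshold between base-cell and endosome levels
        thr = cfg.background + cfg.base_cell * (1 + cfg.endosome_factor) / 2
        cls = count_internal_puncta(ac, truth.masks["cell"], thr)
        assert cls.n_puncta == 12
        assert cls.positive

    def test_no_puncta_is_negative(self):
        image = np.full((16, 16), 10.0)
        cls = count_internal_puncta(image, np.ones_like(image, dtype=bool), 50.0)
        assert cls.n_puncta == 0 and not cls.positive

    def test_exactly_ten_puncta_is_positive_inclusive(self):
        image = np.zeros((25, 25))
        for k in range(10):
            y, x = 2 + 2 * (k // 4) * 2, 2 + (k % 4) * 6
            image[y : y + 2, x : x + 2] = 100.0  # 4-px puncta
        cls = count_internal_puncta(image, np.ones_like(image, dtype=bool), 50.0)
        assert cls.n_puncta == 10
        assert cls.positive

    def test_sub_minimum_puncta_excluded(self):
        image = np.zeros((10, 10))
        image[1, 1] = 100.0  # 1 px
        image[4, 4:6] = 100.0  # 2 px
        image[7, 1:4] = 100.0  # 3 px
        cls = count_internal_puncta(image, np.ones_like(image, dtype=bool), 50.0)
        assert cls.n_puncta == 1


class TestFractionPositive:
    @staticmethod
    def _cls(positive):
        return CellClassification("c", 10 if positive else 0, positive)

    def test_half_positive(self):
        pct, n_pos, n_tot = fraction_positive(
            [self._cls(True), self._cls(False), self._cls(False), self._cls(True)]
        )
        assert (pct, n_pos, n_tot) == (50.0, 2, 4)

    def test_all_negative(self):
        pct, _, _ = fraction_positive([self._cls(False)] * 3)
        assert pct == 0.0

    def test_simulated_population_within_binomial_interval(self, rng):
        p = 0.8
        n = 200
        counts = np.where(rng.random(n) < p, 12, 4)
        classes = [CellClassification(str(i), int(c), bool(c >= 10)) for i, c in enumerate(counts)]
        pct, _, _ = fraction_positive(classes)
        half_width = 100 * 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(pct - 80.0) <= half_width


class TestCiliaEnrichment:
    def test_recovers_ground_truth_with_true_masks(self, noiseless_scene_cfg):
        stack, truth = simulate_static_scene(noiseless_scene_cfg)
        res = cilia_enrichment(
            stack, truth.masks["cilium"], truth.masks["cell"],
            background=noiseless_scene_cfg.background,
        )
        assert res.index == pytest.approx(
            truth.true_enrichment["cilium:mean-ratio"], rel=1e-6
        )

    def test_factor_one_gives_unit_index(self, uniform_scene_cfg):
        stack, truth = simulate_static_scene(uniform_scene_cfg)
        res = cilia_enrichment(
            stack, truth.masks["cilium"], truth.masks["cell"],
            background=uniform_scene_cfg.background,
        )
        assert res.index == pytest.approx(1.0)

    def test_monotone_in_painted_factor(self):
        import dataclasses

        base = SceneConfig(poisson_on=False, gaussian_sd=0.0, seed=7)
        indices = {}
        for factor in (3.0, 8.0):
            cfg = dataclasses.replace(base, cilium_factor=factor)
            stack, truth = simulate_static_scene(cfg)
            indices[factor] = cilia_enrichment(
                stack, truth.masks["cilium"], truth.masks["cell"],
                background=cfg.background,
            ).index
        assert indices[8.0] > indices[3.0]

    def test_accepts_polygon_rois(self, uniform_scene_cfg):
        stack, truth = simulate_static_scene(uniform_scene_cfg)
        ny, nx = uniform_scene_cfg.image_shape
        cell_roi = RoiSpec(
            "cell", vertices=((0.0, 0.0), (0.0, nx - 1.0), (ny - 1.0, nx - 1.0), (ny - 1.0, 0.0))
        )
        ys, xs = np.nonzero(truth.masks["cilium"])
        cil_roi = RoiSpec(
            "cilium",
            vertices=(
                (ys.min() - 0.5, xs.min() - 0.5),
                (ys.min() - 0.5, xs.max() + 0.5),
                (ys.max() + 0.5, xs.max() + 0.5),
                (ys.max() + 0.5, xs.min() - 0.5),
            ),
        )
        res = cilia_enrichment(stack, cil_roi, cell_roi)
        assert res.index > 0
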