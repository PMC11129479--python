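"""Plaque burden, counting, ThioS classification, compaction, circularity."""

import numpy as np
import pytest

from plaquekit.morphometry import (
    classify_thios_positive,
    compute_compaction,
    core_circularity,
    count_deposits,
    global_burden,
    measure_plaques,
    percent_thios_positive,
    summarize_burden,
)
from plaquekit.segmentation import (
    label_components,
    measure_area,
    measure_perimeter,
    nearest_label,
    threshold_channel,
)
from plaquekit.synthetic import SceneParams, generate_scene

from conftest import as_label, as_mask, rasterized_disk


class TestBurden:
    def test_signal_equals_frame(self):
        m = as_mask(np.ones((10, 10), bool))
        assert global_burden(m, m) == 1.0

    def test_empty_signal(self):
        frame = as_mask(np.ones((10, 10), bool))
        assert global_burden(as_mask(np.zeros((10, 10), bool)), frame) == 0.0

    def test_partial_coverage(self):
        frame = as_mask(np.ones((100, 100), bool))
        sig = np.zeros((100, 100), bool)
        sig[:25, :] = True  # 2500 of 10000
        assert global_burden(as_mask(sig), frame) == 0.25

    def test_empty_frame_raises(self):
        with pytest.raises(ValueError):
            global_burden(as_mask(np.ones((5, 5))), as_mask(np.zeros((5, 5))))


class TestCounting:
    def test_empty(self):
        assert count_deposits(as_label(np.zeros((5, 5), int))) == 0

    def test_noise_free_scene_count_matches_truth(self, clean_scene):
        _, img, truth = clean_scene
        lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        assert count_deposits(lab) == len(truth.plaques)

    def test_merged_halos_count_as_one(self):
        m = np.zeros((40, 60), bool)
        m[10:30, 10:30] = True
        m[10:30, 25:45] = True  # overlapping blobs
        lab = label_components(as_mask(m))
        assert count_deposits(lab) == 1


class TestThiosClassification:
    def _setup(self):
        plaques = np.zeros((30, 30), int)
        plaques[5:15, 5:15] = 1
        return as_label(plaques, 1.0)

    def test_zero_overlap_negative(self):
        lab = self._setup()
        assert not classify_thios_positive(1, lab, as_mask(np.zeros((30, 30))), 5.0)

    def test_overlap_above_min_positive(self):
        lab = self._setup()
        thios = np.zeros((30, 30), bool)
        thios[5:7, 5:10] = True  # 10 µm²
        assert classify_thios_positive(1, lab, as_mask(thios), 5.0)

    def test_overlap_exactly_min_positive_tie_rule(self):
        lab = self._setup()
        thios = np.zeros((30, 30), bool)
        thios[5, 5:10] = True  # exactly 5 µm²
        assert classify_thios_positive(1, lab, as_mask(thios), 5.0)


class TestCompaction:
    def test_simple_ratio(self):
        assert compute_compaction(100.0, 50.0) == 0.5

    def test_zero_thios(self):
        assert compute_compaction(100.0, 0.0) == 0.0

    def test_zero_abeta_raises(self):
        with pytest.raises(ValueError):
            compute_compaction(0.0, 10.0)

    def test_end_to_end_quarter_compaction(self):
        """Core r=10 px inside halo r=20 px recovered as C = 0.25 ± 0.03."""
        params = SceneParams(
            image_height_px=256, image_width_px=256, pixel_size_um=0.5,
            n_plaques=1, core_radius_range_um=(5.0, 5.0),
            halo_radius_range_um=(10.0, 10.0), thios_positive_fraction=1.0,
            noise_sigma=0.0, background_microglia_density_per_mm2=0.0, seed=4,
        )
        img, _ = generate_scene(params)
        lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        rec = measure_plaques(lab, threshold_channel(img, "thios"))[0]
        assert rec.compaction == pytest.approx(0.25, abs=0.03)

    def test_parameter_recovery_under_noise(self):
        """MAE of recovered compaction < 0.05 over ≥50 noisy plaques with
        true compaction uniform in [0.1, 0.9] and σ = 10% of foreground."""
        errors = []
        for seed in range(10):
            params = SceneParams(
                image_height_px=512, image_width_px=512, pixel_size_um=0.5,
                n_plaques=5, compaction_range=(0.1, 0.9),
                thios_positive_fraction=1.0, noise_sigma=800.0,
                background_microglia_density_per_mm2=0.0, seed=seed,
            )
            img, truth = generate_scene(params)
            lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
            recs = {r.plaque_id: r for r in
                    measure_plaques(lab, threshold_channel(img, "thios"))}
            for t in truth.plaques:
                rec = recs[nearest_label(lab, t.center)]
                errors.append(abs(rec.compaction - t.true_compaction))
        assert len(errors) >= 50
        assert np.mean(errors) < 0.05

    def test_measured_compaction_monotone_in_halo(self):
        measured = []
        for halo in (10.0, 14.0, 18.0):
            params = SceneParams(
                image_height_px=256, image_width_px=256, pixel_size_um=0.5,
                n_plaques=1, core_radius_range_um=(5.0, 5.0),
                halo_radius_range_um=(halo, halo), thios_positive_fraction=1.0,
                noise_sigma=0.0, background_microglia_density_per_mm2=0.0, seed=9,
            )
            img, _ = generate_scene(params)
            lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
            rec = measure_plaques(lab, threshold_channel(img, "thios"))[0]
            measured.append(rec.compaction)
        assert measured[0] > measured[1] > measured[2]

    def test_identical_masks_give_unit_compaction(self):
        params = SceneParams(
            image_height_px=256, image_width_px=256, pixel_size_um=0.5,
            n_plaques=1, compaction_range=(1.0, 1.0), thios_positive_fraction=1.0,
            noise_sigma=0.0, background_microglia_density_per_mm2=0.0, seed=2,
        )
        img, _ = generate_scene(params)
        lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        rec = measure_plaques(lab, threshold_channel(img, "thios"))[0]
        assert rec.compaction == pytest.approx(1.0, abs=0.02)


class TestCircularity:
    def test_ideal_circle_closed_form(self):
        r = 10.0
        assert core_circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_ideal_square_closed_form(self):
        a = 8.0
        assert core_circularity(a**2, 4 * a) == pytest.approx(np.pi / 4)

    def test_measured_bar_is_elongated(self):
        m = np.zeros((10, 70), bool)
        m[3:6, 5:65] = True
        mask = as_mask(m, 1.0)
        s = core_circularity(measure_area(mask), measure_perimeter(mask))
        assert s < 0.35

    def test_shape_ordering_disk_square_bar(self):
        disk = as_mask(rasterized_disk(30))
        sq = np.zeros((60, 60), bool)
        sq[5:58, 5:58] = True
        square = as_mask(sq)
        bar = np.zeros((10, 120), bool)
        bar[3:6, 5:115] = True
        bar = as_mask(bar)
        values = [
            core_circularity(measure_area(m), measure_perimeter(m))
            for m in (disk, square, bar)
        ]
        assert values[0] > values[1] > values[2]

    def test_zero_perimeter_raises(self):
        with pytest.raises(ValueError):
            core_circularity(10.0, 0.0)


class TestPercentPositiveAndSummary:
    def test_all_positive(self):
        recs = measure_plaques(*self._two_plaques(thios_both=True))
        assert percent_thios_positive(recs) == 100.0

    def test_fraction(self):
        recs = measure_plaques(*self._two_plaques(thios_both=False))
        assert percent_thios_positive(recs) == 50.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            percent_thios_positive([])

    @staticmethod
    def _two_plaques(thios_both):
        plaques = np.zeros((40, 80), int)
        plaques[10:20, 10:20] = 1
        plaques[10:20, 50:60] = 2
        thios = np.zeros((40, 80), bool)
        thios[12:18, 12:18] = True
        if thios_both:
            thios[12:18, 52:58] = True
        return as_label(plaques, 1.0), as_mask(thios, 1.0)

    def test_scene_percentage_matches_generator_truth(self):
        params = SceneParams(
            image_height_px=1024, image_width_px=1024, pixel_size_um=0.5,
            n_plaques=10, thios_positive_fraction=0.4, noise_sigma=0.0,
            background_microglia_density_per_mm2=0.0, seed=77,
        )
        img, truth = generate_scene(params)
        lab = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        recs = measure_plaques(lab, threshold_channel(img, "thios"))
        true_pct = 100.0 * sum(t.thios_positive for t in truth.plaques) / len(truth.plaques)
        # agreement to one-plaque granularity
        assert abs(percent_thios_positive(recs) - true_pct) <= 100.0 / len(truth.plaques)

    def test_global_compaction_modes(self):
        lab, thios = self._two_plaques(thios_both=False)
        abeta = as_mask(lab.pixels > 0, 1.0)
        frame = as_mask(np.ones_like(lab.pixels, bool), 1.0)
        recs = measure_plaques(lab, thios)
        s_all = summarize_burden(abeta, frame, lab, thios, recs, "all")
        s_pos = summarize_burden(abeta, frame, lab, thios, recs, "thios_positive")
        # 36 thios px over 200 abeta px vs 36 over the positive plaque's 100
        assert s_all.global_compaction == pytest.approx(36 / 200)
        assert s_pos.global_compaction == pytest.approx(36 / 100)
        assert s_all.n_deposits == 2
        assert s_all.burden_fraction == pytest.approx(200 / 3200)
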