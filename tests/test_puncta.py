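"""Puncta segmentation, ROI matching, and density bookkeeping."""

import numpy as np
import pytest

from smnd.puncta import (
    Roi,
    intensity_size_profile,
    roi_density,
    sample_negative_rois,
    segment_puncta,
    select_rab5_positive,
    threshold_moments,
)
from smnd.synthetic import simulate_puncta_image


class TestThresholdMoments:
    def test_bimodal_separates_modes(self, rng):
        img = np.concatenate([rng.normal(10, 1, 8000), rng.normal(100, 1, 2000)])
        thr = threshold_moments(img.reshape(100, 100))
        # the moment-preserving threshold must split the two components
        assert img[img <= thr].max() < 50 < img[img > thr].min()
        assert (img > thr).sum() == pytest.approx(2000, abs=20)

    def test_constant_image(self):
        assert threshold_moments(np.full((10, 10), 3.0)) == 3.0


class TestSegmentation:
    def test_blank_image_no_puncta(self):
        assert segment_puncta(np.full((128, 128), 20.0), pixel_size_um=0.1) == []

    def test_disk_count_and_areas_recovered(self):
        img, truth = simulate_puncta_image(10, area_um2=0.2, peak_intensity=200.0,
                                           background=20.0, seed=0)
        puncta = segment_puncta(img, pixel_size_um=0.1)
        assert len(puncta) == 10
        for p in puncta:
            assert p.area_um2 == pytest.approx(0.2, rel=0.2)

    def test_oversized_object_filtered(self):
        img, _ = simulate_puncta_image(3, area_um2=[0.2, 0.2, 5.0], peak_intensity=200.0,
                                       background=20.0, shape=(384, 384), seed=1)
        assert len(segment_puncta(img, pixel_size_um=0.1)) == 2

    def test_thin_line_excluded_by_circularity(self, rng):
        # 1 px x 88 px line: 4πA/P² ≈ 0.039 < 0.04
        img = np.full((128, 128), 20.0) + rng.normal(0, 2, (128, 128))
        img[60, 20:108] += 200.0
        assert segment_puncta(img, pixel_size_um=0.1) == []


class TestIntensityProfile:
    def test_flat_intensity_flat_profile(self):
        img, _ = simulate_puncta_image(12, area_um2=0.2, peak_intensity=200.0,
                                       background=20.0, shape=(384, 384), seed=3)
        puncta = segment_puncta(img, pixel_size_um=0.1)
        prof = intensity_size_profile(puncta, np.arange(0.0, 1.01, 0.1))
        assert np.allclose(prof.normalized_intensity, 1.0, atol=0.02)

    def test_rise_then_fall_peak_bin_recovered(self):
        # intensity law peaking for areas in the 0.3-0.4 bin
        areas = [0.15, 0.15, 0.15, 0.35, 0.35, 0.35, 0.8, 0.8, 0.8]
        peaks = [100.0 if a < 0.3 else (250.0 if a < 0.5 else 80.0) for a in areas]
        img, _ = simulate_puncta_image(9, area_um2=areas, peak_intensity=peaks,
                                       background=20.0, shape=(512, 512),
                                       min_separation_um=2.0, seed=4)
        puncta = segment_puncta(img, pixel_size_um=0.1)
        prof = intensity_size_profile(puncta, np.arange(0.0, 1.01, 0.1))
        best = prof.loc[prof.normalized_intensity.idxmax()]
        assert best.area_lo_um2 == pytest.approx(0.3)

    def test_single_punctum_single_unit_bin(self):
        img, _ = simulate_puncta_image(1, area_um2=0.2, peak_intensity=200.0, seed=5)
        prof = intensity_size_profile(segment_puncta(img, pixel_size_um=0.1),
                                      np.arange(0.0, 1.01, 0.1))
        assert len(prof) == 1
        assert prof.normalized_intensity.iloc[0] == 1.0
        assert prof["low_n"].iloc[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            intensity_size_profile([], [0.0, 1.0])


def _square_roi(r0, c0, side, label=0, kind="+", px=0.1):
    rr, cc = np.mgrid[r0:r0 + side, c0:c0 + side]
    return Roi(label=label, kind=kind, pixels=np.column_stack([rr.ravel(), cc.ravel()]),
               pixel_size_um=px)


class TestRab5Selection:
    def test_area_threshold_strict(self):
        img, _ = simulate_puncta_image(4, area_um2=[0.25, 0.25, 0.35, 0.6],
                                       peak_intensity=200.0, shape=(384, 384),
                                       min_separation_um=2.0, seed=6)
        puncta = segment_puncta(img, pixel_size_um=0.1)
        assert len(puncta) == 4
        selected = select_rab5_positive(puncta, max_area_um2=0.3)
        assert len(selected) == 2


class TestNegativeSampling:
    def test_matched_pair_in_large_mask(self):
        mask = np.ones((200, 200), bool)
        pos = [_square_roi(50, 50, 5)]
        kept, negs = sample_negative_rois(mask, pos, seed=0)
        assert len(kept) == len(negs) == 1
        assert negs[0].area_um2 == kept[0].area_um2
        assert not (set(map(tuple, negs[0].pixels)) & set(map(tuple, kept[0].pixels)))

    def test_impossible_placement_drops_pair_with_warning(self):
        pos = [_square_roi(0, 0, 5)]
        mask = np.zeros((5, 5), bool)
        mask[:, :] = True                       # mask == the positive ROI itself
        with pytest.warns(UserWarning):
            kept, negs = sample_negative_rois(mask, pos, seed=0, max_attempts=50)
        assert kept == [] and negs == []

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        mask = np.ones((300, 300), bool)
        pos = [_square_roi(int(r), int(c), 4, label=i)
               for i, (r, c) in enumerate(rng.integers(10, 280, (50, 2)))]
        _, negs1 = sample_negative_rois(mask, pos, seed=5)
        _, negs2 = sample_negative_rois(mask, pos, seed=5)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(negs1, negs2))

    def test_total_areas_match_exactly(self):
        rng = np.random.default_rng(9)
        mask = np.ones((300, 300), bool)
        pos = [_square_roi(int(r), int(c), int(s), label=i)
               for i, (r, c, s) in enumerate(zip(rng.integers(10, 260, 20),
                                                 rng.integers(10, 260, 20),
                                                 rng.integers(2, 8, 20)))]
        kept, negs = sample_negative_rois(mask, pos, seed=1)
        assert sum(r.area_um2 for r in kept) == sum(r.area_um2 for r in negs)


class TestRoiDensity:
    def test_count_over_area(self):
        roi = _square_roi(0, 0, 5)               # 25 px * (0.1 um)^2 = 0.25 um^2
        locs = np.array([[50.0, 50.0], [100.0, 100.0], [200.0, 200.0],
                         [300.0, 300.0], [400.0, 400.0]])
        assert roi_density(roi, locs) == pytest.approx(5 / 0.25)

    def test_empty_roi_zero(self):
        roi = _square_roi(0, 0, 5)
        assert roi_density(roi, np.zeros((0, 2))) == 0.0

    def test_boundary_localization_counted(self):
        roi = _square_roi(0, 0, 5)               # spans [0, 500) nm
        assert roi_density(roi, np.array([[500.0, 250.0]])) == pytest.approx(1 / 0.25)

    def test_uniform_field_equal_density_in_positives_and_negatives(self, rng):
        mask = np.ones((256, 256), bool)
        pos = [_square_roi(int(r), int(c), 6, label=i)
               for i, (r, c) in enumerate(rng.integers(10, 240, (15, 2)))]
        kept, negs = sample_negative_rois(mask, pos, seed=2)
        locs = np.column_stack([rng.uniform(0, 25600, 60000), rng.uniform(0, 25600, 60000)])
        d_pos = np.array([roi_density(r, locs) for r in kept])
        d_neg = np.array([roi_density(r, locs) for r in negs])
        pooled_se = np.sqrt(np.var(d_pos, ddof=1) / 15 + np.var(d_neg, ddof=1) / 15)
        assert abs(d_pos.mean() - d_neg.mean()) < 3 * pooled_se
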