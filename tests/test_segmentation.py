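import numpy as np
import pytest

from ishscreen.imageops import otsu_threshold
from ishscreen.localization import LocalizationResult
from ishscreen.segmentation import (
    SegmentationError,
    _shifted_localization,
    otsu_segment,
    partition_regions,
    process_series,
    qc_point_features,
    qc_segmentation,
    retry_order,
    segment_from_localization,
    select_areas,
    truth_localization,
)
from ishscreen.synthetic_data import REGION_NAMES, SectionParams, generate_section


def brute_force_otsu(image: np.ndarray) -> int:
    """Independent oracle: maximize between-class variance over all 256 splits."""
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    n = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_matches_brute_force_oracle_on_random_images(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_bimodal_threshold_lies_between_modes(self, rng):
        img = np.where(rng.uniform(size=(40, 40)) < 0.5, 40, 200).astype(np.uint8)
        t = otsu_threshold(img)
        assert 40 <= t < 200

    def test_inverted_image_gives_complementary_foreground(self, rng):
        img = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        fg = otsu_segment(img)
        fg_inv = otsu_segment(255 - img)
        assert np.array_equal(fg, ~fg_inv)

    def test_constant_area_rejected(self):
        with pytest.raises(SegmentationError):
            otsu_segment(np.full((8, 8), 7, dtype=np.uint8))


class TestSelectAreas:
    def test_boxes_overlap_planted_signal(self, default_section):
        _, image, truth = default_section
        boxes = select_areas(truth_localization(truth))
        signal = truth.band_mask | truth.margin_mask
        for name, (r0, c0, r1, c1) in boxes.boxes.items():
            sub = signal[max(r0, 0) : r1, max(c0, 0) : c1]
            assert sub.mean() > 0.2, name

    def test_collinear_chain_falls_back_to_endpoints(self):
        ah = np.column_stack([np.full(8, 50.0), np.linspace(10, 150, 8)])
        dg = np.column_stack([np.full(7, 90.0), np.linspace(30, 130, 7)])
        loc = LocalizationResult(ah, dg, 0.0, (0, 0, 192, 256))
        boxes = select_areas(loc)
        assert boxes.curvature_fallback
        assert boxes.centers["CA1"] == tuple(ah[0])
        assert boxes.centers["CA3"] == tuple(ah[-1])

    def test_scaling_equivariance(self, default_section):
        _, _, truth = default_section
        loc = truth_localization(truth)
        double = LocalizationResult(
            loc.ah_points * 2, loc.dg_points * 2, 0.0, (0, 0, 384, 512)
        )
        b1 = select_areas(loc)
        b2 = select_areas(double)
        for k in b1.centers:
            assert np.allclose(np.array(b2.centers[k]), 2 * np.array(b1.centers[k]))
            assert b2.size[k] == pytest.approx(2 * b1.size[k], abs=1)


class TestPartition:
    def test_thirteen_disjoint_nonempty_regions(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        assert set(rs.regions) == set(REGION_NAMES)
        total = np.zeros(image.shape, dtype=int)
        for mask in rs.regions.values():
            assert mask.any()
            total += mask
        assert total.max() == 1

    def test_band_core_regions_lie_in_true_band(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        for name in ("CA1a", "CA3a", "DGa"):
            mask = rs.regions[name]
            assert (mask & truth.band_mask).sum() / mask.sum() >= 0.8, name

    def test_neuropil_regions_avoid_true_band(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        for name in ("CA1d", "CA3d", "DGd", "DGe"):
            assert (rs.regions[name] & truth.band_mask).sum() == 0, name

    def test_empty_band_mask_raises(self, default_section):
        _, image, truth = default_section
        loc = truth_localization(truth)
        boxes = select_areas(loc)
        masks = {"CA1": np.zeros((10, 10), bool), "CA3": np.ones((10, 10), bool),
                 "DG": np.ones((10, 10), bool)}
        with pytest.raises(SegmentationError):
            partition_regions(boxes, masks, loc, image.shape)


class TestQc:
    def test_samples_twelve_points_per_tested_region(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        feats, labels = qc_point_features(image, rs, seed=0)
        assert feats.shape[0] == 72 == labels.size

    def test_correct_segmentation_accepted(self, qc_forests):
        rf_inside, rf_accept = qc_forests
        params = SectionParams(seed=91, neuropil_enrichment=0.1)
        image, truth = generate_section(params)
        rs = segment_from_localization(image, truth_localization(truth))
        qc = qc_segmentation(image, rs, rf_inside, rf_accept, seed=5)
        assert qc.point_accuracy >= 0.9
        assert qc.accepted

    def test_planted_failures_rejected(self, qc_forests, rng):
        rf_inside, rf_accept = qc_forests
        rejected = 0
        total = 0
        for seed in range(60, 70):
            params = SectionParams(seed=seed, neuropil_enrichment=float(rng.uniform(0, 1.6)))
            image, truth = generate_section(params)
            try:
                rs = segment_from_localization(
                    image, _shifted_localization(truth, rng, 8.0)
                )
            except SegmentationError:
                rejected += 1
                total += 1
                continue
            qc = qc_segmentation(image, rs, rf_inside, rf_accept, seed=int(rng.integers(2**31)))
            rejected += int(not qc.accepted)
            total += 1
        assert rejected / total > 0.9  # false-accept rate < 10%

    def test_untrained_forest_rejected(self, default_section):
        from sklearn.ensemble import RandomForestClassifier

        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        with pytest.raises(ValueError):
            qc_segmentation(image, rs, RandomForestClassifier(), RandomForestClassifier())


class TestSeriesRetry:
    def test_retry_order_alternates_outward_from_default(self):
        order = retry_order(list(range(117, 176)))
        assert order[:5] == [145, 144, 146, 143, 147]
        assert set(order) == set(range(117, 176))

    def _fit_factory(self, truth_by_level):
        def fit(image):
            key = image.tobytes()
            if key in truth_by_level:
                return truth_localization(truth_by_level[key])
            return LocalizationResult(None, None, np.inf, (0, 0) + image.shape,
                                      ok=False, reason="blank")
        return fit

    def test_default_level_tried_first_and_only(self, qc_forests):
        rf_inside, rf_accept = qc_forests
        image, truth = generate_section(SectionParams(seed=7, neuropil_enrichment=0.1))
        fit = self._fit_factory({image.tobytes(): truth})
        series = [(level, image) for level in (143, 144, 145, 146)]
        res = process_series(series, fit, rf_inside, rf_accept, seed=1)
        assert not res.discarded
        assert res.atlas_level == 145
        assert len(res.attempts) == 1

    def test_returns_first_passing_level(self, qc_forests):
        rf_inside, rf_accept = qc_forests
        good_img, good_truth = generate_section(SectionParams(seed=8, neuropil_enrichment=0.1))
        blank = np.full_like(good_img, 230)
        fit = self._fit_factory({good_img.tobytes(): good_truth})
        series = [(131, good_img)] + [(lvl, blank) for lvl in (145, 144, 146)]
        res = process_series(series, fit, rf_inside, rf_accept, seed=1)
        assert res.atlas_level == 131
        assert not res.discarded

    def test_all_blank_series_discarded(self, qc_forests):
        rf_inside, rf_accept = qc_forests
        blank = np.full((192, 256), 230, dtype=np.uint8)
        fit = self._fit_factory({})
        res = process_series([(145, blank), (150, blank)], fit, rf_inside, rf_accept)
        assert res.discarded
        assert len(res.attempts) == 2
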