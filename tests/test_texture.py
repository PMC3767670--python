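import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ishscreen.segmentation import segment_from_localization, truth_localization
from ishscreen.synthetic_data import SectionParams, generate_section
from ishscreen.texture import (
    FEATURE_NAMES,
    OFFSETS,
    WINDOW_MAP,
    assemble_feature_vector,
    canonical_feature_names,
    compute_glcm,
    extract_region_features,
    first_order_features,
    glcm_features,
    place_windows,
    quantize,
    read_feature_table,
    window_features,
    write_feature_table,
)


def oracle_glcm(q: np.ndarray) -> np.ndarray:
    """Exhaustive pair enumeration over the 4 unit offsets, both directions."""
    m = np.zeros((16, 16))
    h, w = q.shape
    for dr, dc in OFFSETS:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    m[q[r, c], q[r2, c2]] += 1
                    m[q[r2, c2], q[r, c]] += 1
    return m / m.sum()


def oracle_first_order(window: np.ndarray) -> tuple:
    """Direct-formula moments and histogram statistics."""
    x = window.astype(float).ravel()
    mean = x.mean()
    sd = np.sqrt(((x - mean) ** 2).mean())
    cv = sd / mean if mean != 0 else 0.0
    skew = ((x - mean) ** 3).mean() / sd**3 if sd > 0 else 0.0
    kurt = ((x - mean) ** 4).mean() / sd**4 if sd > 0 else 0.0
    h = np.bincount(window.ravel() // 16, minlength=16) / x.size
    energy = (h**2).sum()
    entropy = -sum(p * np.log2(p) for p in h if p > 0)
    return mean, sd, cv, skew, kurt, energy, entropy


class TestQuantize:
    @pytest.mark.parametrize("value,level", [(0, 0), (15, 0), (16, 1), (255, 15)])
    def test_bin_edges(self, value, level):
        assert quantize(np.array([[value]]))[0, 0] == level

    def test_constant_window_occupies_one_level(self):
        q = quantize(np.full((5, 5), 100))
        assert len(np.unique(q)) == 1


class TestGLCM:
    def test_two_by_two_example_matches_enumeration(self):
        q = np.array([[0, 0], [1, 1]])
        g = compute_glcm(q)
        assert np.allclose(g.matrix, oracle_glcm(q))
        # directions: horizontal pairs (0,0),(1,1); vertical (0,1)x2; two diagonals
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_matches_oracle_on_random_windows(self, rng):
        for _ in range(30):
            h, w = rng.integers(2, 9, size=2)
            q = rng.integers(0, 16, size=(h, w))
            g = compute_glcm(q)
            assert np.allclose(g.matrix, oracle_glcm(q)), (h, w)

    def test_constant_window_concentrates_mass(self):
        g = compute_glcm(np.full((4, 4), 7))
        assert g.matrix[7, 7] == pytest.approx(1.0)

    def test_symmetric_and_normalized(self, rng):
        q = rng.integers(0, 16, size=(6, 6))
        g = compute_glcm(q)
        assert np.allclose(g.matrix, g.matrix.T)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_transpose_invariance_of_pooled_matrix(self, rng):
        q = rng.integers(0, 16, size=(5, 7))
        assert np.allclose(compute_glcm(q).matrix, compute_glcm(q.T).matrix)

    def test_single_pixel_window_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[3]]))

    def test_agrees_with_skimage_graycomatrix(self, rng):
        # independent cross-check against the reference implementation
        from skimage.feature import graycomatrix

        q = rng.integers(0, 16, size=(8, 8)).astype(np.uint8)
        ref = graycomatrix(q, [1], [np.pi / 2, 0, np.pi / 4, 3 * np.pi / 4],
                           levels=16, symmetric=True, normed=False).astype(float)
        pooled = ref.sum(axis=(2, 3))
        assert np.allclose(compute_glcm(q).matrix, pooled / pooled.sum())


class TestHaralickFeatures:
    def test_constant_window_conventions(self):
        contrast, corr, energy, homog = glcm_features(compute_glcm(np.full((4, 4), 3)))
        assert contrast == 0.0
        assert corr == 0.0  # sigma_i * sigma_j = 0 convention
        assert energy == 1.0
        assert homog == 1.0

    def test_checkerboard_contrast_matches_oracle(self):
        q = np.indices((4, 4)).sum(axis=0) % 2 * 15
        m = oracle_glcm(q)
        expected = sum(
            m[i, j] * (i - j) ** 2 for i in range(16) for j in range(16)
        )
        contrast, _, _, _ = glcm_features(compute_glcm(q))
        assert contrast == pytest.approx(expected)
        assert expected > 0

    def test_energy_and_homogeneity_bounds(self, rng):
        for _ in range(10):
            q = rng.integers(0, 16, size=(6, 6))
            _, _, energy, homog = glcm_features(compute_glcm(q))
            assert 0 < energy <= 1
            assert 0 < homog <= 1


class TestFirstOrder:
    def test_constant_window(self):
        mean, sd, cv, skew, kurt, energy, entropy = first_order_features(
            np.full((6, 6), 42, dtype=np.uint8)
        )
        assert (mean, sd, cv, skew, kurt) == (42.0, 0.0, 0.0, 0.0, 0.0)
        assert energy == 1.0
        assert entropy == 0.0

    def test_two_equal_mass_levels(self):
        w = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        *_, energy, entropy = first_order_features(w)
        assert energy == pytest.approx(0.5)
        assert entropy == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None)
    @given(
        arrays(np.uint8, st.tuples(st.integers(2, 8), st.integers(2, 8)),
               elements=st.integers(0, 255))
    )
    def test_matches_direct_formula_oracle(self, window):
        got = first_order_features(window)
        expected = oracle_first_order(window)
        assert np.allclose(got, expected, atol=1e-10)


class TestRegionExtraction:
    def test_single_window_region_equals_window_features(self, rng):
        image = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        mask = np.zeros((40, 40), bool)
        mask[10:24, 12:26] = True  # exactly 14x14
        feats = extract_region_features(image, mask, (14,))
        direct = window_features(image[10:24, 12:26])
        for name, v in zip(FEATURE_NAMES, direct):
            assert feats[f"14_{name}"] == pytest.approx(v)

    def test_three_window_fixture_is_mean_of_window_oracle(self, rng):
        image = rng.integers(0, 256, size=(20, 70)).astype(np.uint8)
        mask = np.zeros((20, 70), bool)
        mask[2:16, 3:45] = True  # bounding box 14 x 42 -> three 14x14 tiles
        feats = extract_region_features(image, mask, (14,))
        windows = [image[2:16, 3 + 14 * k : 17 + 14 * k] for k in range(3)]
        expected = np.mean([window_features(w) for w in windows], axis=0)
        for name, v in zip(FEATURE_NAMES, expected):
            assert feats[f"14_{name}"] == pytest.approx(v)

    def test_tiny_region_falls_back_to_centered_window(self, rng):
        image = rng.integers(0, 256, size=(60, 60)).astype(np.uint8)
        mask = np.zeros((60, 60), bool)
        mask[30:33, 30:34] = True  # smaller than any window
        placement = place_windows(mask, 18)
        assert placement.fallback
        assert len(placement.boxes) == 1
        r0, c0, r1, c1 = placement.boxes[0]
        assert (r1 - r0, c1 - c0) == (18, 18)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            place_windows(np.zeros((10, 10), bool), 5)


class TestFeatureVector:
    def test_canonical_vector_has_220_named_values(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        fv = assemble_feature_vector(image, rs)
        assert len(fv) == 220
        assert list(fv.index) == canonical_feature_names()
        assert np.isfinite(fv.to_numpy()).all()

    def test_window_map_accounts_for_220(self):
        n_pairs = sum(len(sizes) for sizes in WINDOW_MAP.values())
        assert n_pairs == 20
        assert n_pairs * len(FEATURE_NAMES) == 220

    def test_identical_images_identical_vectors(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        a = assemble_feature_vector(image, rs)
        b = assemble_feature_vector(image.copy(), rs)
        assert a.equals(b)

    def test_missing_region_raises(self, default_section):
        _, image, truth = default_section
        rs = segment_from_localization(image, truth_localization(truth))
        masks = dict(rs.regions)
        del masks["DGe"]
        with pytest.raises(KeyError, match="DGe"):
            assemble_feature_vector(image, masks)

    def test_enriched_neuropil_is_darker_in_d_regions(self):
        vectors = {}
        for e in (1.5, 0.0):
            image, truth = generate_section(
                SectionParams(seed=17, neuropil_enrichment=e, noise_sd=0.0)
            )
            rs = segment_from_localization(image, truth_localization(truth))
            vectors[e] = assemble_feature_vector(image, rs)
        for col in ("CA1d_14_mean", "CA3d_14_mean", "DGd_14_mean"):
            assert vectors[1.5][col] < vectors[0.0][col]


def test_feature_table_roundtrip_and_validation(tmp_path, default_section):
    _, image, truth = default_section
    rs = segment_from_localization(image, truth_localization(truth))
    fv = assemble_feature_vector(image, rs)
    row = {"gene": "g1", "probe": "p1", "level": 145, **fv.to_dict()}
    table = pd.DataFrame([row])
    path = tmp_path / "features.tsv"
    write_feature_table(path, table)
    loaded = read_feature_table(path)
    assert np.allclose(loaded[canonical_feature_names()].to_numpy(),
                       table[canonical_feature_names()].to_numpy())
    # column order is validated
    shuffled = table[list(table.columns[::-1])]
    shuffled.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
    with pytest.raises(ValueError):
        read_feature_table(tmp_path / "bad.tsv")
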