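import numpy as np
import pytest

from tumorherd.features import (FeatureVector, GLCM_STATS, StubExtractor,
                                deep_features, glcm_features, hu_features,
                                stub_extractor)
from tumorherd.phantom import PhantomParams, generate_slice
from tumorherd.segmentation import segment_slice


def _brute_force_glcm_contrast(grid, levels=8):
    """Direct pair enumeration of the symmetric d=1, 0-degree co-occurrence
    contrast on a quantized grid."""
    q = grid.astype(int) * levels // 256
    pairs = []
    h, w = q.shape
    for r in range(h):
        for c in range(w - 1):
            pairs.append((q[r, c], q[r, c + 1]))
            pairs.append((q[r, c + 1], q[r, c]))  # symmetric
    total = len(pairs)
    return sum((i - j) ** 2 for i, j in pairs) / total


class TestGlcm:
    def test_emits_25_named_values(self, class2_slice):
        tm = segment_slice(class2_slice.pixels)
        fv = glcm_features(class2_slice.pixels, tm)
        assert fv.dim == 25
        assert len(set(fv.names)) == 25
        assert fv.source == "GLCM"

    def test_constant_tumor_degenerate_statistics(self):
        pixels = np.full((64, 64), 200, dtype=np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        fv = glcm_features(pixels, mask)
        vals = dict(zip(fv.names, fv.values))
        for name, v in vals.items():
            if "contrast" in name:
                assert v == 0.0
            elif "energy" in name or "homogeneity" in name:
                assert v == pytest.approx(1.0)

    def test_checkerboard_contrast_matches_pair_enumeration(self):
        grid = np.indices((8, 8)).sum(axis=0) % 2 * 255
        grid = grid.astype(np.uint8)
        mask = np.ones((8, 8), bool)
        fv = glcm_features(grid, mask)
        expected = _brute_force_glcm_contrast(grid)
        got = dict(zip(fv.names, fv.values))["glcm_contrast_d1_a0"]
        assert got == pytest.approx(expected)
        assert expected == pytest.approx(49.0)  # levels 0 and 7 alternate

    def test_statistic_bounds(self):
        for seed in range(5):
            s = generate_slice(PhantomParams(class_id=2, seed=seed))
            fv = glcm_features(s.pixels, s.truth_mask)
            for name, v in zip(fv.names, fv.values):
                if "energy" in name or "homogeneity" in name:
                    assert 0 < v <= 1
                elif "entropy" in name:
                    assert v >= 0
                elif "correlation" in name:
                    assert -1 <= v <= 1 + 1e-12

    def test_empty_mask_and_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((8, 8), np.uint8), np.zeros((8, 8), bool))
        with pytest.raises(ValueError):
            glcm_features(np.zeros((8, 8), np.uint8), np.ones((9, 9), bool))


def _brute_force_hu3(mask):
    """Raw-moment summation oracle for the first three Hu invariants."""
    ys, xs = np.nonzero(mask)
    m00 = len(xs)
    cx, cy = xs.mean(), ys.mean()
    def mu(p, q):
        return (((xs - cx) ** p) * ((ys - cy) ** q)).sum()
    def eta(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)
    h1 = eta(2, 0) + eta(0, 2)
    h2 = (eta(2, 0) - eta(0, 2)) ** 2 + 4 * eta(1, 1) ** 2
    h3 = (eta(3, 0) - 3 * eta(1, 2)) ** 2 + (3 * eta(2, 1) - eta(0, 3)) ** 2
    out = np.array([h1, h2, h3])
    signed = np.zeros(3)
    nz = out != 0
    signed[nz] = np.sign(out[nz]) * np.log10(np.abs(out[nz]))
    return signed


class TestHu:
    @staticmethod
    def _disk(r=20, size=64):
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= r * r

    def test_matches_brute_force_moment_oracle(self):
        mask = self._disk()
        fv = hu_features(mask)
        assert fv.dim == 3
        np.testing.assert_allclose(fv.values, _brute_force_hu3(mask), atol=1e-9)

    def test_translation_invariance(self):
        mask = self._disk(12, 96)
        moved = np.roll(np.roll(mask, 13, axis=0), -7, axis=1)
        np.testing.assert_allclose(hu_features(mask).values,
                                   hu_features(moved).values, atol=1e-9)

    def test_rotation_invariance(self, class2_slice):
        m = class2_slice.truth_mask
        np.testing.assert_allclose(hu_features(m).values,
                                   hu_features(np.rot90(m)).values, atol=1e-6)

    def test_scale_invariance_within_discretization(self):
        mask = self._disk(15, 64)
        big = np.kron(mask, np.ones((2, 2), bool))
        np.testing.assert_allclose(hu_features(mask).values,
                                   hu_features(big).values, atol=1e-3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hu_features(np.zeros((8, 8), bool))


class TestDeep:
    def test_stub_is_deterministic_and_reproducible(self, class2_slice):
        a = deep_features(class2_slice, stub_extractor(3))
        b = deep_features(class2_slice, StubExtractor(seed=3))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.dim == 1000

    def test_distinct_slices_embed_differently(self, class1_slice, class2_slice):
        ext = stub_extractor(0)
        assert not np.array_equal(ext.embed(class1_slice).values,
                                  ext.embed(class2_slice).values)

    def test_wrong_output_dim_rejected(self, class2_slice):
        class Bad:
            name = "bad"
            def embed(self, slc):
                return FeatureVector(np.zeros(999), [f"b{i}" for i in range(999)], "bad")
        with pytest.raises(ValueError):
            deep_features(class2_slice, Bad())

    def test_projection_depends_only_on_seed(self):
        assert np.array_equal(StubExtractor(seed=5)._w, StubExtractor(seed=5)._w)
        assert not np.array_equal(StubExtractor(seed=5)._w, StubExtractor(seed=6)._w)

    def test_class_mean_embeddings_separate(self):
        ext = stub_extractor(0)
        m1 = np.mean([ext.embed(generate_slice(PhantomParams(class_id=1, seed=s))).values
                      for s in range(40)], axis=0)
        m2 = np.mean([ext.embed(generate_slice(PhantomParams(class_id=2, seed=s))).values
                      for s in range(40)], axis=0)
        assert np.linalg.norm(m1 - m2) > 0.5

    def test_feature_names_unique_across_full_space(self, class2_slice):
        tm = segment_slice(class2_slice.pixels)
        names = (deep_features(class2_slice, stub_extractor(0)).names
                 + glcm_features(class2_slice.pixels, tm).names
                 + hu_features(tm).names)
        assert len(names) == 1028
        assert len(set(names)) == 1028
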