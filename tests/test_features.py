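"""Descriptor extraction, the three filtering rules, normalization, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from grainpigment.features import (
    DescriptorExtractor,
    FeatureFilter,
    extract_descriptors,
    filter_features,
    normalize,
    pca_reduce,
)


@pytest.fixture(scope="module")
def extractor():
    return DescriptorExtractor()


class TestExtraction:
    def test_default_vector_has_2380_entries(self, extractor, one_render):
        image, mask, _ = one_render
        values = extractor.extract(image, mask)
        assert values.shape == (2380,)
        assert len(extractor.feature_names) == 2380
        assert np.isfinite(values).all()

    def test_histogram_blocks_sum_to_one(self, extractor, one_render):
        image, mask, _ = one_render
        values = extractor.extract(image, mask)
        names = extractor.feature_names
        for space_ch in ("rgb.r", "hsv.s", "lab.l", "ycrcb.cr"):
            block = [v for v, n in zip(values, names) if n.startswith(f"{space_ch}.hist_")]
            assert len(block) == 196
            assert np.isclose(sum(block), 1.0)

    def test_constant_gray_foreground(self, extractor):
        v = 120
        image = np.full((20, 20, 3), 255, dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        image[mask] = v
        values = extractor.extract(image, mask)
        names = extractor.feature_names
        lookup = dict(zip(names, values))
        for ch in ("r", "g", "b"):
            assert np.isclose(lookup[f"rgb.{ch}.mean"], v / 255.0)
            assert lookup[f"rgb.{ch}.sd"] == pytest.approx(0.0, abs=1e-12)
            hist = [lookup[f"rgb.{ch}.hist_{k:03d}"] for k in range(196)]
            assert np.isclose(max(hist), 1.0) and np.isclose(sum(hist), 1.0)

    def test_channel_mean_matches_per_pixel_loop(self, extractor, one_render):
        image, mask, _ = one_render
        values = extractor.extract(image, mask)
        lookup = dict(zip(extractor.feature_names, values))
        # independent oracle: explicit python loop over mask coordinates
        total, count = 0.0, 0
        for r, c in zip(*np.nonzero(mask)):
            total += image[r, c, 1] / 255.0
            count += 1
        assert np.isclose(lookup["rgb.g.mean"], total / count)

    def test_background_pixels_do_not_matter(self, extractor, one_render):
        image, mask, _ = one_render
        ref = extractor.extract(image, mask)
        scrambled = image.copy()
        bg = ~mask.astype(bool)
        scrambled[bg] = np.random.default_rng(0).integers(0, 256, (bg.sum(), 3))
        assert np.array_equal(ref, extractor.extract(scrambled, mask))

    def test_invalid_inputs_rejected(self, extractor, one_render):
        image, mask, _ = one_render
        with pytest.raises(ValueError, match="no foreground"):
            extractor.extract(image, np.zeros_like(mask))
        with pytest.raises(ValueError, match="8-bit"):
            extractor.extract(image.astype(np.float32), mask)
        with pytest.raises(ValueError, match="RGB"):
            extractor.extract(image[..., 0], mask)

    def test_functional_wrapper_returns_names(self, one_render):
        image, mask, _ = one_render
        values, names = extract_descriptors(image, mask)
        assert len(values) == len(names) == 2380


class TestFiltering:
    def _oracle(self, df: pd.DataFrame) -> list[str]:
        """Independent brute-force application of the three rules."""
        cols = list(df.columns)
        # rule 1
        cols = [c for c in cols if df[c].nunique() > 1]
        # rule 2
        cols = [c for c in cols if (df[c] <= 0.01).mean() <= 0.20]
        # rule 3: greedy first-retained-wins
        retained = []
        for c in cols:
            if all(abs(spearmanr(df[c], df[r]).statistic) < 0.97 for r in retained):
                retained.append(c)
        return retained

    def test_constant_column_dropped_by_rule_1(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.2, 0.5, 0.9]})
        fitted = FeatureFilter().fit(df)
        assert list(fitted.transform(df).columns) == ["b"]
        assert fitted.report_.loc[fitted.report_["column"] == "a", "rule"].item() == "constant"

    def test_near_zero_column_dropped_by_rule_2(self):
        # <= 0.01 in 2 of 4 rows (50 % > 20 %)
        df = pd.DataFrame({"a": [0.005, 0.01, 0.5, 0.6], "b": [0.2, 0.3, 0.4, 0.5]})
        fitted = FeatureFilter().fit(df)
        assert list(fitted.transform(df).columns) == ["b"]
        assert (fitted.report_["rule"] == "near_zero").any()

    def test_scaled_copy_dropped_by_rule_3(self):
        rng = np.random.default_rng(0)
        base = rng.random(10) + 0.1
        df = pd.DataFrame({"a": base, "b": 2 * base, "c": rng.random(10) + 0.1})
        fitted = FeatureFilter().fit(df)
        kept = list(fitted.transform(df).columns)
        assert "a" in kept and "b" not in kept  # monotone transform: rho = 1
        row = fitted.report_[fitted.report_["column"] == "b"]
        assert row["rule"].item() == "spearman" and row["statistic"].item() >= 0.97

    def test_toy_matrix_matches_brute_force_oracle(self):
        df = pd.DataFrame(
            {
                "c0": [0.3, 0.3, 0.3, 0.3, 0.3],        # constant
                "c1": [0.0, 0.0, 0.9, 0.8, 0.7],        # >20 % near zero
                "c2": [0.1, 0.2, 0.3, 0.4, 0.5],
                "c3": [0.2, 0.4, 0.6, 0.8, 1.0],        # rank-identical to c2
            }
        )
        fitted = FeatureFilter().fit(df)
        assert list(fitted.transform(df).columns) == self._oracle(df) == ["c2"]

    @pytest.mark.parametrize("seed", [1, 2])
    def test_random_matrix_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.random((8, 6)) + 0.02, columns=list("abcdef"))
        df["e"] = df["a"] ** 3          # rank-redundant with a
        df["f"] = 0.25                  # constant
        fitted = FeatureFilter().fit(df)
        assert list(fitted.transform(df).columns) == self._oracle(df)

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((12, 8)) + 0.02)
        once, _ = filter_features(df)
        twice, second = filter_features(once)
        assert list(twice.columns) == list(once.columns)
        assert second.report_.empty

    def test_single_row_matrix_rejected(self):
        with pytest.raises(ValueError, match="at least 2 rows"):
            FeatureFilter().fit(pd.DataFrame({"a": [1.0]}))


class TestNormalize:
    def test_columns_become_standard(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(3, 2, (30, 5)))
        out, scaler = normalize(df)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.std(axis=0, ddof=0), 1, atol=1e-9)
        # stored transform reproduces the normalized matrix
        assert np.allclose(scaler.transform(df.to_numpy()), out.to_numpy())
        # a new row equal to the column means maps to zero
        assert np.allclose(scaler.transform(df.mean(axis=0).to_numpy()[None]), 0, atol=1e-12)


class TestPCA:
    def test_reduction_dimensionality_and_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 20))
        Z, pca = pca_reduce(X, k=13)
        assert Z.shape == (40, 13)
        evr = pca.explained_variance_ratio_
        assert (np.diff(evr) <= 1e-12).all()

    def test_complete_basis_explains_everything(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (15, 6))
        _, pca = pca_reduce(X, k=6)
        assert np.isclose(pca.explained_variance_ratio_.sum(), 1.0, atol=1e-9)

    def test_component_variances_match_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 6))
        Z, pca = pca_reduce(X, k=6)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(pca.explained_variance_, eig, atol=1e-9)
        assert np.allclose(Z.var(axis=0, ddof=1), eig, atol=1e-9)

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pca_reduce(np.random.default_rng(0).random((5, 3)), k=5)
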