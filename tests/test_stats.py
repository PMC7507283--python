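"""Correlation, regression, ANOVA (raw and summary), PCA, ranking."""

import numpy as np
import pandas as pd
import pytest

from ricevigor import (
    DegenerateStatisticError,
    SignifCode,
    TraitTable,
    ValidationError,
    anova_from_summary,
    anova_oneway,
    linear_regression,
    pca,
    pearson_r,
    rank_genotypes,
)


def table(d, index=None):
    return TraitTable(data=pd.DataFrame(d, index=index))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4])
        res = pearson_r(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10), rng.random(10)
        assert pearson_r(x, y).r == pytest.approx(pearson_r(y, x).r, rel=1e-12)
        assert pearson_r(3 * x + 2, y).r == pytest.approx(pearson_r(x, y).r, rel=1e-12)

    def test_pairwise_complete_na(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        res = pearson_r(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        res = linear_regression(x, 2 * x + 3)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_equals_r_squared_identity(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(20), rng.random(20)
        res = linear_regression(x, y)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)


class TestAnova:
    def test_hand_computed_two_groups(self):
        """Groups {1,2,3},{7,8,9}: SSB=54, SSW=4, df=(1,4) → F=54."""
        res = anova_oneway([[1, 2, 3], [7, 8, 9]])
        assert res.f_stat == pytest.approx(54.0)
        assert res.p_value == pytest.approx(0.0018262, abs=1e-6)
        assert res.code is SignifCode.STAR

    def test_equal_means_nonzero_variance_ns(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [2.0, 1.0, 3.0]])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.code is SignifCode.NS

    def test_summary_matches_raw(self):
        """ANOVA from mean±SE reproduces ANOVA from the raw data exactly."""
        from scipy.stats import f_oneway

        rng = np.random.default_rng(9)
        groups = [rng.normal(loc, 1.0, size=5) for loc in (0.0, 0.4, 1.1, 0.2)]
        raw = anova_oneway(groups)
        summary = anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) / np.sqrt(len(g)) for g in groups],
            5,
        )
        assert summary.f_stat == pytest.approx(raw.f_stat, rel=1e-12)
        sp = f_oneway(*groups)
        assert summary.f_stat == pytest.approx(sp.statistic, rel=1e-10)
        assert summary.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_degenerate_identical_groups(self):
        with pytest.raises(DegenerateStatisticError):
            anova_from_summary([2.0, 2.0], [0.0, 0.0], 5)

    def test_group_size_preconditions(self):
        with pytest.raises(ValidationError):
            anova_oneway([[1.0, 2.0]])


class TestPca:
    def test_single_axis_of_variation(self):
        t = table({"a": [0.0, 1, 2, 3], "b": [5.0, 5, 5, 5.000001]})
        res = pca(t)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-6)

    def test_known_eigenvalues(self):
        """Traits with covariance diag(4, 1) split variance 80/20."""
        rng = np.random.default_rng(12)
        z = rng.normal(size=500)
        w = rng.normal(size=500)
        z = (z - z.mean()) / z.std(ddof=1)
        w = (w - w.mean()) / w.std(ddof=1)
        w = w - z * (w @ z) / (z @ z)  # exact orthogonalization
        w = w / w.std(ddof=1)
        t = table({"a": 2.0 * z, "b": w})
        res = pca(t)
        assert res.variance_fraction == pytest.approx([0.8, 0.2], abs=1e-9)

    def test_fractions_sum_to_one_and_loadings_orthonormal(self):
        rng = np.random.default_rng(13)
        t = table(rng.random((7, 5)), index=list("abcdefg"))
        res = pca(t)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(14)
        frame = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"))
        t1 = TraitTable(data=frame)
        t2 = TraitTable(data=frame.iloc[::-1])
        assert pca(t1).variance_fraction == pytest.approx(
            pca(t2).variance_fraction, rel=1e-9
        )

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(15)
        x = rng.random((9, 4))
        res = pca(table(x, index=[f"g{i}" for i in range(9)]))
        sk = SkPCA().fit(x)
        assert res.variance_fraction[:4] == pytest.approx(
            sk.explained_variance_ratio_, rel=1e-8
        )

    def test_all_na_column_dropped_with_warning(self):
        t = table({"a": [1.0, 2, 3], "b": [np.nan] * 3, "c": [2.0, 1, 4]})
        with pytest.warns(UserWarning, match="b"):
            res = pca(t)
        assert res.trait_names == ("a", "c")

    def test_constant_matrix_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            pca(table({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}))


class TestRanking:
    def test_descending_order(self):
        t = table({"x": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        assert rank_genotypes(t, "x") == ["a", "c", "b"]

    def test_ties_broken_by_label(self):
        t = table({"x": [2.0, 2.0, 1.0]}, index=["z", "a", "m"])
        assert rank_genotypes(t, "x") == ["a", "z", "m"]

    def test_single_row(self):
        t = table({"x": [1.0]}, index=["only"])
        assert rank_genotypes(t, "x") == ["only"]

    def test_unknown_trait(self):
        t = table({"x": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            rank_genotypes(t, "nope")
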