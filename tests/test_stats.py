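"""ANOVA/Tukey, Kaiser PCA, canonical discriminant analysis, jackknife and
allometry — including cross-checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from statomorph import (
    allometry_regression,
    anova_oneway,
    cda_classify,
    cda_fit,
    jackknife_classify,
    pca_select,
    rao_f_approximation,
)
from statomorph.exceptions import (
    InsufficientDataError,
    UndefinedSlopeError,
)
from statomorph.stats import confusion_table

TABLE_N = (12, 20, 20, 11, 9, 17, 20, 12, 20, 20, 4, 20)


def grouped_data(rng, sizes, p=1, spread=1.0, shift=0.0):
    """Gaussian groups; group g is shifted by g*shift along every axis."""
    X, y = [], []
    for g, n in enumerate(sizes):
        X.append(rng.normal(g * shift, spread, size=(n, p)))
        y += [f"g{g:02d}"] * n
    return np.vstack(X), np.array(y)


class TestAnova:
    def test_equal_means_give_f_near_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5.0, 1.0, 300)
        groups = np.repeat(np.arange(6), 50)
        res = anova_oneway(vals, groups)
        assert res.p > 0.01
        assert res.F < 3.0

    def test_study_group_sizes_give_df_11_173(self):
        """Twelve groups with the study's unequal sizes: df = (11, 173)."""
        rng = np.random.default_rng(1)
        vals, groups = [], []
        for g, n in enumerate(TABLE_N):
            vals += list(rng.normal(g, 0.3, n))
            groups += [g] * n
        res = anova_oneway(np.array(vals), np.array(groups))
        assert (res.df1, res.df2) == (11, 173)
        assert res.tukey.shape[0] == 12 * 11 // 2

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 14), rng.normal(0.7, 1, 9)
        res = anova_oneway(np.concatenate([a, b]), np.array([0] * 14 + [1] * 9))
        t, p_t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-10)

    def test_identical_values_give_f_zero(self):
        res = anova_oneway(np.full(30, 2.0), np.repeat([0, 1, 2], 10))
        assert res.F == 0.0

    def test_tukey_matches_statsmodels(self):
        """Tukey-Kramer adjusted p-values agree with the statsmodels
        implementation on unbalanced groups."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(3)
        vals, groups = [], []
        for g, (n, mu) in enumerate(zip((8, 15, 11), (0.0, 0.8, 0.3))):
            vals += list(rng.normal(mu, 1.0, n))
            groups += [f"g{g}"] * n
        vals, groups = np.array(vals), np.array(groups)
        res = anova_oneway(vals, groups)
        ref = sm.pairwise_tukeyhsd(vals, groups)
        np.testing.assert_allclose(
            res.tukey["adjusted_p"].to_numpy(), ref.pvalues, atol=1e-8
        )
        np.testing.assert_allclose(
            -res.tukey["mean_diff"].to_numpy(), ref.meandiffs, atol=1e-12
        )


class TestPCASelect:
    def test_eigenvalues_sum_to_p(self):
        rng = np.random.default_rng(4)
        sel = pca_select(rng.normal(size=(120, 9)))
        assert sel.eigenvalues.sum() == pytest.approx(9.0, abs=1e-6)
        assert np.all(np.diff(sel.eigenvalues) <= 1e-12)

    def test_correlated_block_retention(self):
        """Two perfectly correlated columns plus one independent: spectrum
        (2, 1, 0); strict 'eigenvalue > 1' retains exactly one component."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        sel = pca_select(np.column_stack([a, a, b]))
        assert sel.eigenvalues[0] == pytest.approx(2.0, abs=0.1)
        assert sel.eigenvalues[2] == pytest.approx(0.0, abs=1e-9)
        assert sel.retained_count == 1

    def test_scores_centred(self):
        rng = np.random.default_rng(6)
        sel = pca_select(rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5)))
        assert np.abs(sel.scores.mean(axis=0)).max() < 1e-9

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.normal(size=50), np.full(50, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = pca_select(X)
        assert len(sel.columns) == 1

    def test_single_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            pca_select(np.ones((1, 4)))


class TestCDAFit:
    @pytest.mark.parametrize(
        "p,k,expected",
        [(3, 12, (33, 504)), (83, 12, (913, 1033)), (83, 6, (415, 489))],
        ids=["lw-3faces", "nef-species", "nef-family"],
    )
    def test_rao_degrees_of_freedom(self, p, k, expected):
        """Rao's F degrees of freedom for the study's three model shapes
        (N = 185 with the default study's unequal group sizes)."""
        rng = np.random.default_rng(8)
        sizes = TABLE_N if k == 12 else (12, 51, 26, 52, 20, 24)
        X, y = grouped_data(rng, sizes, p=p, shift=0.5)
        model = cda_fit(X, y)
        assert (model.df1, model.df2) == expected

    def test_wilks_lambda_one_when_means_equal(self):
        """Wilks' lambda is exactly 1 when every group mean is identical,
        and strictly decreases when one centroid is translated away."""
        rng = np.random.default_rng(9)
        base = rng.normal(size=(30, 4))
        # three copies of the same centred cloud -> identical group means
        X = np.vstack([base - base.mean(0)] * 3)
        y = np.repeat([0, 1, 2], 30)
        m0 = cda_fit(X, y)
        assert m0.wilks_lambda == pytest.approx(1.0, abs=1e-10)
        X2 = X.copy()
        X2[y == 2] += 1.0
        assert cda_fit(X2, y).wilks_lambda < m0.wilks_lambda - 0.1

    def test_wilks_and_f_match_statsmodels_manova(self):
        """Wilks' lambda, Rao's F and both dfs agree with the MANOVA
        implementation in statsmodels."""
        manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(10)
        X, y = grouped_data(rng, (15, 20, 12, 18), p=5, shift=0.6)
        model = cda_fit(X, y)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        df["g"] = y
        mv = manova.MANOVA.from_formula(
            "x0 + x1 + x2 + x3 + x4 ~ g", data=df
        ).mv_test()
        ref = mv.results["g"]["stat"].loc["Wilks' lambda"]
        assert model.wilks_lambda == pytest.approx(ref["Value"], rel=1e-8)
        assert model.rao_F == pytest.approx(ref["F Value"], rel=1e-6)
        assert model.df1 == int(ref["Num DF"])
        assert model.df2 == int(ref["Den DF"])

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            cda_fit(np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10))

    def test_rao_t_degenerates_to_one_for_two_groups_one_variable(self):
        F, df1, df2, _ = rao_f_approximation(0.5, 1, 2, 30)
        assert df1 == 1
        assert df2 == pytest.approx(28.0)


class TestClassification:
    def test_well_separated_clusters_fully_correct(self):
        rng = np.random.default_rng(11)
        X, y = grouped_data(rng, (25, 25, 25), p=4, shift=10.0)
        model = cda_fit(X, y)
        pred, table = cda_classify(model, X, true_labels=y)
        assert table.overall_percent_correct == 100.0
        assert np.trace(table.counts) == 75

    def test_training_set_of_singletons_self_classifies(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(4, 3))
        y = np.array(["a", "b", "c", "d"])
        with pytest.warns(UserWarning, match="singular"):
            model = cda_fit(X, y)
        pred = cda_classify(model, X)
        assert list(pred) == list(y)

    def test_priors_shift_borderline_point(self):
        """A point equidistant between two centroids goes to the larger
        group under proportional priors and ties under equal priors by
        label order; the decision values differ exactly by ln(prior)."""
        rng = np.random.default_rng(13)
        X, y = grouped_data(rng, (40, 10), p=2, shift=4.0)
        eq = cda_fit(X, y, priors="equal")
        prop = cda_fit(X, y, priors="proportional")
        # construct the exact midpoint in canonical space
        mid_c = eq.group_centroids.mean(axis=0)
        V = eq.canonical_coefficients
        mid = np.linalg.lstsq(V.T, mid_c, rcond=None)[0]
        d_eq = ((mid @ V - eq.group_centroids) ** 2).sum(axis=1)
        assert d_eq[0] == pytest.approx(d_eq[1], abs=1e-9)
        assert cda_classify(prop, mid[None, :])[0] == "g00"

    def test_affine_invariance_of_confusion_tables(self):
        """CDA classification is a Mahalanobis rule, so any invertible
        affine map of feature space leaves the confusion table unchanged."""
        rng = np.random.default_rng(14)
        X, y = grouped_data(rng, (20, 15, 25), p=6, shift=1.0)
        A = rng.normal(size=(6, 6)) + 6 * np.eye(6)
        b = rng.normal(size=6)
        _, t1 = cda_classify(cda_fit(X, y), X, true_labels=y)
        XA = X @ A + b
        _, t2 = cda_classify(cda_fit(XA, y), XA, true_labels=y)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_matches_sklearn_lda_predictions(self):
        """With proportional priors the Mahalanobis-to-centroid rule equals
        linear discriminant analysis; predictions match scikit-learn."""
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(15)
        X, y = grouped_data(rng, (30, 22, 17, 26), p=5, shift=0.8)
        model = cda_fit(X, y, priors="proportional")
        mine = cda_classify(model, X)
        ref = sk.LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (mine == ref).mean() > 0.99


class TestJackknife:
    def test_refit_count_equals_n(self):
        rng = np.random.default_rng(16)
        X, y = grouped_data(rng, (10, 10), p=2, shift=5.0)
        table = jackknife_classify(X, y)
        assert table.n_refits == 20
        assert table.counts.sum() == 20

    def test_well_separated_clusters_perfect(self):
        rng = np.random.default_rng(17)
        X, y = grouped_data(rng, (20, 20, 20), p=3, shift=10.0)
        table = jackknife_classify(X, y)
        assert table.overall_percent_correct == 100.0

    def test_permuted_labels_give_chance_level(self):
        """Random labels: leave-one-out accuracy is 100/k within three
        binomial standard errors."""
        rng = np.random.default_rng(18)
        k, n = 4, 40
        X = rng.normal(size=(k * n, 5))
        y = rng.permutation(np.repeat(np.arange(k), n))
        table = jackknife_classify(X, y)
        se = 100 * np.sqrt((1 / k) * (1 - 1 / k) / (k * n))
        assert abs(table.overall_percent_correct - 100 / k) <= 3 * se

    def test_not_above_resubstitution_on_standard_fixture(self, full_study):
        sp = full_study["species"]
        assert (
            sp.jackknife.overall_percent_correct
            <= sp.resubstitution.overall_percent_correct
        )

    def test_singleton_group_warns_and_never_self_classifies(self):
        """A group of size one still allows every fold to be fitted (the
        remaining groups carry the fold), but its own member can never be
        classified correctly; a warning says so."""
        rng = np.random.default_rng(19)
        X = np.vstack(
            [
                rng.normal(0, 1, size=(6, 2)),
                rng.normal(8, 1, size=(6, 2)),
                rng.normal((0, 8), 1, size=(1, 2)),
            ]
        )
        y = np.array(["a"] * 6 + ["b"] * 6 + ["c"])
        with pytest.warns(UserWarning, match="size 1"):
            table = jackknife_classify(X, y)
        c_row = table.labels.index("c")
        assert table.counts[c_row, c_row] == 0


class TestConfusionTable:
    def test_rows_sum_to_group_sizes(self):
        t = confusion_table(
            ["a", "a", "b", "b", "b"], ["a", "b", "b", "b", "a"], ["a", "b"], "resubstitution"
        )
        assert t.counts.sum(axis=1).tolist() == [2, 3]
        assert t.overall_percent_correct == pytest.approx(60.0)
        assert t.percent_correct_per_group[0] == pytest.approx(50.0)


class TestAllometry:
    def test_null_slopes_not_significant(self):
        """Shape independent of size by construction: at the fixed seed no
        species shows a significant slope."""
        rng = np.random.default_rng(20)
        species = np.repeat([f"s{i}" for i in range(4)], 20)
        length = rng.normal(300, 25, 80)
        mean_nef = rng.normal(0.01, 0.001, 80)  # independent of length
        res = allometry_regression(mean_nef, length, species)
        assert res["p"].min() > 0.01

    def test_drifting_species_detected(self):
        rng = np.random.default_rng(21)
        length = rng.normal(300, 25, 20)
        mean_nef = 0.01 + 1e-4 * (length - 300) + rng.normal(0, 5e-4, 20)
        res = allometry_regression(
            mean_nef, length, np.array(["drifter"] * 20)
        )
        assert res.loc["drifter", "p"] < 0.01
        assert res.loc["drifter", "r_squared"] > 0.8

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            allometry_regression(
                np.array([1.0, 2.0]), np.array([10.0, 20.0]), np.array(["a", "a"])
            )

    def test_constant_length_rejected(self):
        with pytest.raises(UndefinedSlopeError):
            allometry_regression(
                np.array([1.0, 2.0, 3.0]),
                np.array([10.0, 10.0, 10.0]),
                np.array(["a"] * 3),
            )
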