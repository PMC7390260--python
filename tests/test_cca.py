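import numpy as np
import pytest
from scipy import stats

from omicslink import Namespace, bartlett_test, fit_cca, helio_data
from omicslink.cca import SingularCorrelationError
from helpers import bruteforce_cca, make_matrix, standardize


def random_pair(rng, n, p, q, coupled=True):
    Xv = rng.standard_normal((n, p))
    Yv = rng.standard_normal((n, q))
    if coupled:
        Yv[:, 0] += 0.7 * Xv[:, 0]
    X = make_matrix(Xv, Namespace.HGNC, "g")
    Y = make_matrix(Yv, Namespace.CHEBI, "m")
    return X, Y


class TestFitCCA:
    def test_univariate_case_equals_absolute_pearson(self, rng):
        for _ in range(20):
            x = rng.standard_normal(30)
            y = 0.5 * x + rng.standard_normal(30)
            X = make_matrix(x[:, None], prefix="g")
            Y = make_matrix(y[:, None], Namespace.CHEBI, "m")
            r = fit_cca(X, Y).correlations[0]
            assert r == pytest.approx(abs(stats.pearsonr(x, y)[0]), abs=1e-12)

    def test_linear_image_of_x_gives_perfect_correlations(self, rng):
        Xv = rng.standard_normal((50, 3))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)  # invertible mixing
        Yv = (Xv @ A)[:, [2, 0, 1]] * np.array([3.0, -0.5, 10.0])
        X = make_matrix(Xv, prefix="g")
        Y = make_matrix(Yv, Namespace.CHEBI, "m")
        assert fit_cca(X, Y).correlations == pytest.approx(np.ones(3), abs=1e-8)

    def test_affine_invariance_of_correlations(self, rng):
        X, Y = random_pair(rng, 100, 3, 3)
        base = fit_cca(X, Y).correlations
        Ax = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        Ay = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        X2 = make_matrix(X.values @ Ax + 5.0, prefix="g")
        Y2 = make_matrix(Y.values @ Ay - 2.0, Namespace.CHEBI, "m")
        assert fit_cca(X2, Y2).correlations == pytest.approx(base, abs=1e-8)

    def test_matches_bruteforce_maximization(self, rng):
        X, Y = random_pair(rng, 200, 3, 3)
        mine = fit_cca(X, Y).correlations
        oracle = bruteforce_cca(X.values, Y.values)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_variates_mutually_uncorrelated(self, rng):
        X, Y = random_pair(rng, 120, 4, 3)
        res = fit_cca(X, Y)
        for block in (res.x_variates, res.y_variates):
            C = np.corrcoef(block, rowvar=False)
            assert np.abs(C[~np.eye(res.k, dtype=bool)]).max() < 1e-8
        cross = np.corrcoef(res.x_variates.T, res.y_variates.T)[: res.k, res.k :]
        off = cross[~np.eye(res.k, dtype=bool)]
        assert np.abs(off).max() < 1e-8
        assert np.diag(cross) == pytest.approx(res.correlations, abs=1e-8)

    def test_loadings_are_variable_variate_correlations(self, rng):
        X, Y = random_pair(rng, 80, 3, 4)
        res = fit_cca(X, Y)
        for values, loadings, variates in (
            (X.values, res.x_loadings, res.x_variates),
            (Y.values, res.y_loadings, res.y_variates),
        ):
            for j in range(values.shape[1]):
                for i in range(res.k):
                    direct = stats.pearsonr(values[:, j], variates[:, i])[0]
                    assert loadings[j, i] == pytest.approx(direct, abs=1e-8)

    def test_squared_loading_equals_simple_regression_r2(self, rng):
        X, Y = random_pair(rng, 90, 3, 3)
        res = fit_cca(X, Y)
        Zx = standardize(X.values)
        for j in range(3):
            slope, intercept = np.polyfit(res.x_variates[:, 0], Zx[:, j], 1)
            fitted = slope * res.x_variates[:, 0] + intercept
            ss_res = ((Zx[:, j] - fitted) ** 2).sum()
            ss_tot = (standardize(Zx[:, [j]]) ** 2).sum()
            r2 = 1 - ss_res / ss_tot
            assert res.x_loadings[j, 0] ** 2 == pytest.approx(r2, abs=1e-8)

    def test_diagnostic_ranges_and_redundancy_identity(self, rng):
        X, Y = random_pair(rng, 150, 4, 4)
        res = fit_cca(X, Y)
        assert np.all(np.diff(res.correlations) <= 1e-12)
        assert np.all((res.correlations >= 0) & (res.correlations <= 1))
        for adeq in (res.x_adequacies, res.y_adequacies):
            assert np.all((adeq >= 0) & (adeq <= 1))
        for comm in (res.x_communalities, res.y_communalities):
            assert np.all((comm >= -1e-12) & (comm <= 1 + 1e-12))
        assert res.y_redundancies == pytest.approx(
            res.correlations**2 * res.y_adequacies, abs=1e-10
        )
        assert res.x_redundancies == pytest.approx(
            res.correlations**2 * res.x_adequacies, abs=1e-10
        )

    def test_sign_convention_largest_loading_positive(self, rng):
        X, Y = random_pair(rng, 100, 4, 3)
        res = fit_cca(X, Y)
        for i in range(res.k):
            stacked = np.concatenate([res.x_loadings[:, i], res.y_loadings[:, i]])
            assert stacked[np.argmax(np.abs(stacked))] > 0

    def test_singular_within_set_matrix_advises_prune(self, rng):
        x = rng.standard_normal(30)
        Xv = np.column_stack([x, x, rng.standard_normal(30)])
        X = make_matrix(Xv, prefix="g")
        Y = make_matrix(rng.standard_normal((30, 2)), Namespace.CHEBI, "m")
        with pytest.raises(SingularCorrelationError, match="prune"):
            fit_cca(X, Y)

    def test_too_few_samples_is_hard_error(self, rng):
        X = make_matrix(rng.standard_normal((4, 3)), prefix="g")
        Y = make_matrix(rng.standard_normal((4, 3)), Namespace.CHEBI, "m")
        with pytest.raises(ValueError, match="cannot support"):
            fit_cca(X, Y)

    def test_sample_size_guideline_warns_not_errors(self, rng):
        X = make_matrix(rng.standard_normal((40, 12)), prefix="g")
        Y = make_matrix(rng.standard_normal((40, 12)), Namespace.CHEBI, "m")
        with pytest.warns(UserWarning, match="guideline"):
            res = fit_cca(X, Y)
        # study-shaped run: 12 canonical pairs, 12-row Bartlett table
        assert res.k == 12 and len(res.bartlett) == 12

    def test_sample_order_mismatch_rejected(self, rng):
        X = make_matrix(rng.standard_normal((10, 2)), prefix="g")
        Y = make_matrix(rng.standard_normal((10, 2)), Namespace.CHEBI, "m")
        Y.sample_ids = list(reversed(Y.sample_ids))
        with pytest.raises(ValueError, match="same samples"):
            fit_cca(X, Y)


class TestBartlett:
    def test_null_gives_zero_statistic_and_unit_pvalue(self):
        table = bartlett_test(np.zeros(3), n=50, p=3, q=3)
        assert table["chi_squared"].to_numpy() == pytest.approx(np.zeros(3))
        assert table["p_value"].to_numpy() == pytest.approx(np.ones(3))

    def test_closed_form_worked_example(self):
        # n = 20, p = q = 1, r = 0.5: chi2 = -17.5 ln(0.75), df = 1
        table = bartlett_test(np.array([0.5]), n=20, p=1, q=1)
        expected_chi2 = -17.5 * np.log(0.75)
        assert table["chi_squared"].iloc[0] == pytest.approx(expected_chi2, abs=1e-10)
        assert expected_chi2 == pytest.approx(5.034, abs=1e-3)
        assert table["df"].iloc[0] == 1
        assert table["p_value"].iloc[0] == pytest.approx(
            stats.chi2.sf(expected_chi2, 1), abs=1e-12
        )
        assert table["p_value"].iloc[0] == pytest.approx(0.0248, abs=1e-3)

    def test_degrees_of_freedom_rule(self):
        table = bartlett_test(np.array([0.9, 0.5, 0.1]), n=100, p=5, q=3)
        assert list(table["df"]) == [15, 8, 3]

    def test_correlation_domain_enforced(self):
        with pytest.raises(ValueError):
            bartlett_test(np.array([1.0]), n=20, p=1, q=1)
        with pytest.raises(ValueError):
            bartlett_test(np.array([-0.2]), n=20, p=1, q=1)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError, match="too small"):
            bartlett_test(np.array([0.5]), n=3, p=2, q=2)


class TestHelioData:
    def test_row_count_and_content_match_loadings(self, rng):
        X, Y = random_pair(rng, 60, 3, 2)
        res = fit_cca(X, Y)
        table = helio_data(res, 1)
        assert len(table) == 5
        assert list(table["set"]) == ["X"] * 3 + ["Y"] * 2
        for _, row in table.iterrows():
            values = X.values if row["set"] == "X" else Y.values
            features = X.feature_ids if row["set"] == "X" else Y.feature_ids
            variates = res.x_variates if row["set"] == "X" else res.y_variates
            j = features.index(row["variable"])
            direct = stats.pearsonr(values[:, j], variates[:, 0])[0]
            assert row["loading"] == pytest.approx(direct, abs=1e-8)

    def test_collinear_variable_loads_at_one(self, rng):
        x = rng.standard_normal(50)
        X = make_matrix(x[:, None], prefix="g")
        Y = make_matrix(
            np.column_stack([0.8 * x + 0.1 * rng.standard_normal(50)]),
            Namespace.CHEBI, "m",
        )
        res = fit_cca(X, Y)
        table = helio_data(res, 1)
        # the lone X variable IS the first variate up to scale
        assert table.loc[table["set"] == "X", "loading"].iloc[0] == pytest.approx(
            1.0, abs=1e-10
        )

    def test_out_of_range_index_rejected(self, rng):
        X, Y = random_pair(rng, 60, 2, 2)
        res = fit_cca(X, Y)
        for bad in (0, 3):
            with pytest.raises(ValueError, match="cv_index"):
                helio_data(res, bad)
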