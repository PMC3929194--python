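import math

import numpy as np
import pytest
from scipy import stats

from coexnet.simulate import generate_trait_regression_fixture, reference_cohort
from coexnet.validation import (
    ValidationFixture,
    candidate_pca,
    expression_trait_correlation,
    fold_change,
    group_stats,
    normalize_delta_ct,
    trait_regression,
)
from oracles import pca_eigh_oracle


def fixture_from(imf_by_group, expression=None):
    out = []
    for group, values in imf_by_group.items():
        for i, v in enumerate(values):
            out.append(
                ValidationFixture(
                    animal_id=f"{group}{i}", group=group, age_months=28.0,
                    imf_percent=v, expression=dict(expression or {}),
                )
            )
    return out


class TestGroupStats:
    def test_published_low_group(self, cohort):
        s = group_stats(cohort)["low"]
        assert round(s.mean, 2) == 9.54
        assert round(s.sem, 2) == 1.35

    def test_published_high_group(self, cohort):
        s = group_stats(cohort)["high"]
        # printed mean is 20.84; the mean of the printed individual values
        # is 20.8467, agreeing to one unit in the last printed digit
        assert abs(s.mean - 20.84) <= 0.01
        assert round(s.sem, 2) == 1.52

    def test_constant_group(self):
        s = group_stats(fixture_from({"low": [5.0, 5.0, 5.0], "high": [7.0, 8.0]}))
        assert s["low"].mean == 5.0
        assert s["low"].sem == 0.0

    def test_sem_is_sd_over_sqrt_n(self, cohort):
        for s in group_stats(cohort).values():
            assert s.sem == pytest.approx(s.sd / math.sqrt(s.n))

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            group_stats(fixture_from({"low": [5.0], "high": [7.0, 8.0]}))


class TestFoldChange:
    def test_published_dpyd_ratio(self, cohort):
        assert round(fold_change(cohort, "DPYD"), 1) == 3.2

    def test_published_tmem60_ratio(self, cohort):
        assert round(fold_change(cohort, "TMEM60"), 2) == 2.24

    def test_identical_means_unity(self):
        fixture = fixture_from({"low": [5.0, 6.0], "high": [7.0, 8.0]},
                               expression={"G": 0.4})
        assert fold_change(fixture, "G") == pytest.approx(1.0)

    def test_nonpositive_low_mean_rejected(self):
        fixture = fixture_from({"low": [5.0, 6.0], "high": [7.0, 8.0]})
        for f in fixture:
            f.expression["G"] = -0.1 if f.group == "low" else 0.5
        with pytest.raises(ValueError, match="fold change undefined"):
            fold_change(fixture, "G")


class TestTraitRegression:
    def test_slope_recovery(self):
        fixture = generate_trait_regression_fixture(
            n=200, expression_slope=2.0, noise_sd=0.1, seed=3,
        )
        report = trait_regression(fixture, "G0001")
        assert 1.9 <= report.coefficients["expression"] <= 2.1

    def test_constant_expression_rank_deficient(self):
        fixture = fixture_from({"low": [5.0, 6.0, 7.0], "high": [8.0, 9.0, 10.0]},
                               expression={"G": 0.5})
        with pytest.raises(ValueError, match="rank deficient.*expression"):
            trait_regression(fixture, "G", covariates=())

    def test_zero_noise_exact_recovery(self):
        fixture = generate_trait_regression_fixture(
            n=100, expression_slope=1.5, age_slope=0.2, noise_sd=1e-300, seed=5,
        )
        report = trait_regression(fixture, "G0001", covariates=("age",))
        assert report.coefficients["expression"] == pytest.approx(1.5, abs=1e-8)
        assert report.coefficients["age_months"] == pytest.approx(0.2, abs=1e-8)
        assert report.expression_p < 1e-15

    def test_matches_normal_equations(self):
        fixture = generate_trait_regression_fixture(
            n=60, expression_slope=1.0, noise_sd=0.5, seed=9,
        )
        report = trait_regression(fixture, "G0001", covariates=("age", "housekeeping"))
        y = np.array([f.imf_percent for f in fixture])
        x = np.column_stack([
            np.ones(60),
            [f.expression["G0001"] for f in fixture],
            [f.age_months for f in fixture],
            [f.housekeeping for f in fixture],
        ])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        got = [report.coefficients[k] for k in
               ("intercept", "expression", "age_months", "housekeeping")]
        np.testing.assert_allclose(got, beta, atol=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        fixture = generate_trait_regression_fixture(
            n=40, expression_slope=0.8, noise_sd=0.4, seed=13,
        )
        report = trait_regression(fixture, "G0001", covariates=("age",))
        y = [f.imf_percent for f in fixture]
        x = sm.add_constant(np.column_stack([
            [f.expression["G0001"] for f in fixture],
            [f.age_months for f in fixture],
        ]))
        fit = sm.OLS(y, x).fit()
        assert report.coefficients["expression"] == pytest.approx(fit.params[1])
        assert report.expression_p == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_insufficient_samples_rejected(self):
        fixture = generate_trait_regression_fixture(
            n=5, expression_slope=1.0, seed=1
        )[:3]
        with pytest.raises(ValueError, match="cannot identify"):
            trait_regression(fixture, "G0001", covariates=("age", "housekeeping"))

    def test_mean_bias_over_seeds(self):
        true_slope = 2.0
        estimates = []
        for seed in range(50):
            fixture = generate_trait_regression_fixture(
                n=100, expression_slope=true_slope, noise_sd=0.5, seed=seed,
            )
            report = trait_regression(fixture, "G0001")
            estimates.append(report.coefficients["expression"])
        bias = abs(np.mean(estimates) - true_slope) / true_slope
        assert bias < 0.02


class TestExpressionTraitCorrelation:
    def test_perfect_correlation(self):
        fixture = fixture_from({"low": [1.0, 2.0], "high": [3.0, 4.0]})
        for f in fixture:
            f.expression["G"] = f.imf_percent
        r, p = expression_trait_correlation(fixture, "G")
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_anticorrelated(self):
        fixture = fixture_from({"low": [1.0, 2.0], "high": [3.0, 4.0]})
        for f in fixture:
            f.expression["G"] = -f.imf_percent
        r, _ = expression_trait_correlation(fixture, "G")
        assert r == pytest.approx(-1.0)

    def test_t_transform_p_value_at_r085_n12(self):
        # closed form: t = r sqrt((n-2)/(1-r^2)), two-sided tail
        r, n = 0.85, 12
        t = r * math.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(t, n - 2)
        assert expected == pytest.approx(0.0004, abs=2e-4)
        rng = np.random.default_rng(0)
        # construct a 12-sample fixture with correlation exactly 0.85
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        y = (y - np.polyval(np.polyfit(x, y, 1), x))  # residualize
        y = r * (x - x.mean()) / x.std() + math.sqrt(1 - r**2) * y / y.std()
        fixture = []
        for i in range(n):
            fixture.append(ValidationFixture(
                animal_id=str(i), group="low" if i < 6 else "high",
                age_months=28.0, imf_percent=float(y[i] - y.min()),
                expression={"G": float(x[i])},
            ))
        got_r, got_p = expression_trait_correlation(fixture, "G")
        assert got_r == pytest.approx(0.85, abs=1e-9)
        assert got_p == pytest.approx(expected, rel=1e-6)

    def test_zero_variance_rejected(self):
        fixture = fixture_from({"low": [1.0, 2.0], "high": [3.0, 4.0]},
                               expression={"G": 0.5})
        with pytest.raises(ValueError, match="zero variance"):
            expression_trait_correlation(fixture, "G")


class TestCandidatePCA:
    def make_fixture(self, x, genes):
        return [
            ValidationFixture(
                animal_id=f"a{i}", group="low" if i % 2 else "high",
                age_months=28.0, imf_percent=10.0,
                expression={g: float(x[i, j]) for j, g in enumerate(genes)},
            )
            for i in range(x.shape[0])
        ]

    def test_collinear_data_single_component(self, rng):
        base = rng.standard_normal(6)
        x = np.column_stack([base, 2 * base + 1.0])
        report = candidate_pca(self.make_fixture(x, ["A", "B"]), ["A", "B"])
        assert report.variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratios_sum_to_one(self, rng):
        x = rng.standard_normal((8, 4))
        genes = ["A", "B", "C", "D"]
        report = candidate_pca(self.make_fixture(x, genes), genes)
        assert report.variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(report.variance_ratio >= 0)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.standard_normal((4, 3))
        genes = ["A", "B", "C"]
        report = candidate_pca(self.make_fixture(x, genes), genes, scale=False)
        vals, vecs = pca_eigh_oracle(x)
        n_comp = min(4 - 1, 3)
        total = vals.sum()
        np.testing.assert_allclose(
            report.variance_ratio[:n_comp], vals[:n_comp] / total, atol=1e-10
        )
        for c in range(2):
            got = report.loadings[:, c]
            expected = vecs[:, c]
            if np.dot(got, expected) < 0:
                expected = -expected
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_scores_centered(self, rng):
        x = rng.standard_normal((10, 5))
        genes = list("ABCDE")
        report = candidate_pca(self.make_fixture(x, genes), genes)
        np.testing.assert_allclose(report.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_components_orthogonal(self, rng):
        x = rng.standard_normal((10, 4))
        genes = list("ABCD")
        report = candidate_pca(self.make_fixture(x, genes), genes)
        gram = report.loadings.T @ report.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_pc2_relationship_signs(self, rng):
        x = rng.standard_normal((12, 3))
        genes = ["A", "B", "C"]
        report = candidate_pca(self.make_fixture(x, genes), genes)
        for i, g in enumerate(genes):
            expected = "positive" if report.loadings[i, 1] >= 0 else "negative"
            assert report.pc2_relationship[g] == expected

    def test_constant_gene_named(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        fixture = self.make_fixture(x, ["A", "B"])
        with pytest.raises(ValueError, match="B"):
            candidate_pca(fixture, ["A", "B"])


class TestDeltaCt:
    def test_known_value(self):
        # Ct difference of -1 doubles abundance
        out = normalize_delta_ct(np.array([20.0]), np.array([21.0]))
        assert out[0] == pytest.approx(2.0)
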