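import numpy as np
import pandas as pd
import pytest

from fentonflux.association import (
    LassoFit,
    contribution_summary,
    lasso_fit,
    metastasis_regression,
    pearson,
    r_squared,
)
from fentonflux.synthetic import generate_rm_cohort

RM_NAMES = [f"RM{i}" for i in range(1, 41)]


@pytest.fixture(scope="module")
def planted_cohort():
    es, fenton = generate_rm_cohort(
        200, RM_NAMES, support={"RM1", "RM2"}, beta={"RM1": 2.0, "RM2": 1.0},
        noise_sd=0.01, seed=5,
    )
    return es, fenton


class TestLassoFit:
    def test_support_recovery(self, planted_cohort):
        es, fenton = planted_cohort
        fit = lasso_fit(fenton, es, seed=0)
        assert {"RM1", "RM2"} <= set(fit.selected)
        assert fit.coefficients.drop(["RM1", "RM2"]).abs().max() <= 0.1
        # cross-check against least squares on the true support
        X = es.loc[["RM1", "RM2"]].T.to_numpy()
        Xc = np.column_stack([np.ones(len(fenton)), X])
        beta = np.linalg.lstsq(Xc, fenton.to_numpy(), rcond=None)[0]
        # lasso works on z-scored predictors; compare on the raw scale
        raw = fit.coefficients[["RM1", "RM2"]].to_numpy() / es.loc[
            ["RM1", "RM2"]
        ].std(axis=1, ddof=0).to_numpy()
        assert raw == pytest.approx(beta[1:], rel=0.05)

    def test_huge_penalty_zeroes_everything(self, planted_cohort):
        es, fenton = planted_cohort
        fit = lasso_fit(fenton, es, lam=1e6)
        assert fit.selected == []

    def test_zero_penalty_equals_least_squares(self, planted_cohort):
        es, fenton = planted_cohort
        fit = lasso_fit(fenton, es, lam=0.0, standardize=False)
        X = np.column_stack([np.ones(len(fenton)), es.T.to_numpy()])
        beta = np.linalg.lstsq(X, fenton.to_numpy(), rcond=None)[0]
        assert fit.coefficients.to_numpy() == pytest.approx(beta[1:], abs=1e-6)

    def test_deterministic_given_seed(self, planted_cohort):
        es, fenton = planted_cohort
        f1 = lasso_fit(fenton, es, seed=3)
        f2 = lasso_fit(fenton, es, seed=3)
        pd.testing.assert_series_equal(f1.coefficients, f2.coefficients)

    def test_constant_response_rejected(self, planted_cohort):
        es, _ = planted_cohort
        with pytest.raises(ValueError):
            lasso_fit(pd.Series(1.0, index=es.columns), es)

    def test_selected_set_shrinks_along_penalty_path(self, planted_cohort):
        es, fenton = planted_cohort
        sizes = [
            len(lasso_fit(fenton, es, lam=lam).selected)
            for lam in (0.001, 0.01, 0.1, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


def _fit_with(coefs: dict[str, float]) -> LassoFit:
    all_rms = ["X", "Y", "Z"]
    series = pd.Series({rm: coefs.get(rm, 0.0) for rm in all_rms})
    return LassoFit(
        coefficients=series, intercept=0.0, lambda_chosen=0.1, r2=0.9,
        n=100, p=3, standardized=False,
    )


class TestContributionSummary:
    def test_nine_of_eleven_rate(self):
        fits = [_fit_with({"X": 0.3}) for _ in range(9)] + [_fit_with({}) for _ in range(2)]
        summary = contribution_summary(fits, min_rate=0.4)
        assert summary.rates["X"] == pytest.approx(0.818, abs=5e-4)
        assert summary.n_types == 11

    def test_never_selected_excluded(self):
        fits = [_fit_with({"X": 0.5}), _fit_with({"X": 0.5})]
        summary = contribution_summary(fits, min_rate=0.1)
        assert "Y" not in summary.rates.index

    def test_single_type(self):
        summary = contribution_summary([_fit_with({"X": 0.5})], min_rate=0.4)
        assert summary.scores["X"] == 0.5
        assert summary.rates["X"] == 1.0

    def test_score_averages_only_selecting_types(self):
        fits = [_fit_with({"X": 0.4}), _fit_with({"X": 0.2}), _fit_with({})]
        summary = contribution_summary(fits, min_rate=0.4)
        assert summary.scores["X"] == pytest.approx(0.3)

    def test_negative_coefficients_ignored_by_default(self):
        fits = [_fit_with({"X": -0.5}), _fit_with({"X": 0.5})]
        summary = contribution_summary(fits, min_rate=0.0)
        assert summary.rates.get("X", 0.0) == 0.5
        assert summary.scores["X"] == 0.5


class TestRSquared:
    def test_perfect_fit(self, planted_cohort):
        es, _ = planted_cohort
        fenton = 2.0 * es.loc["RM1"] + 1.0
        fit = lasso_fit(fenton, es, lam=0.0)
        assert r_squared(fit, fenton, es) == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only_fit_is_zero(self, planted_cohort):
        es, fenton = planted_cohort
        fit = lasso_fit(fenton, es, lam=1e6)
        assert r_squared(fit, fenton, es) == pytest.approx(0.0, abs=1e-9)

    def test_matches_planted_signal_fraction(self):
        # var(signal) = 1, var(noise) = 1/9 -> R^2 = 0.9
        es, fenton = generate_rm_cohort(
            500, RM_NAMES, support={"RM1"}, beta={"RM1": 1.0},
            noise_sd=1.0 / 3.0, seed=11,
        )
        fit = lasso_fit(fenton, es, lam=0.0)
        assert r_squared(fit, fenton, es) == pytest.approx(0.9, abs=0.05)


class TestMetastasisRegression:
    @pytest.fixture()
    def predictors(self):
        rng = np.random.default_rng(2)
        synth = pd.Series(rng.uniform(0.5, 2.0, 11))
        neu1 = pd.Series(rng.uniform(1.0, 10.0, 11))
        return synth, neu1

    def test_exact_noiseless_recovery(self, predictors):
        synth, neu1 = predictors
        rates = 1.91 * synth - 0.039 * neu1
        coef, pvals = metastasis_regression(rates, synth, neu1)
        assert coef["sialic_synthesis"] == pytest.approx(1.91)
        assert coef["degradation_expr"] == pytest.approx(-0.039)
        assert (pvals < 0.05).all()

    def test_zero_degradation_reduces_to_one_term(self, predictors):
        synth, _ = predictors
        zeros = pd.Series(0.0, index=synth.index)
        rates = 1.91 * synth
        with pytest.warns(UserWarning, match="collinear"):
            coef, _ = metastasis_regression(rates, synth, zeros)
        assert coef["sialic_synthesis"] == pytest.approx(1.91)
        assert coef["degradation_expr"] == pytest.approx(0.0, abs=1e-12)

    def test_type_order_invariance(self, predictors):
        synth, neu1 = predictors
        rates = 1.91 * synth - 0.039 * neu1 + 0.05
        coef1, _ = metastasis_regression(rates, synth, neu1)
        perm = np.random.default_rng(0).permutation(len(rates))
        coef2, _ = metastasis_regression(
            rates.iloc[perm], synth.iloc[perm], neu1.iloc[perm]
        )
        assert coef1.to_numpy() == pytest.approx(coef2.to_numpy())

    def test_too_few_types_rejected(self):
        s = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            metastasis_regression(s, s, s)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, p = pearson([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.98198, abs=1e-4)
        assert 0 < p < 1

    @pytest.mark.parametrize("a,b", [(2.0, 1.0), (-3.0, 0.5)])
    def test_affine_invariance_up_to_sign(self, a, b):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        r, _ = pearson(x, a * x + b)
        assert r == pytest.approx(np.sign(a), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
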