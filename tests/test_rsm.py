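"""Quadratic response-surface fit, ANOVA and fit metrics."""

import dataclasses

import numpy as np
import pytest

import extraopt as eo
from extraopt.rsm import (SingularDesignError, UndefinedRSquaredError,
                          model_matrix, term_names)
from extraopt.simulate import DEFAULT_TRUTH

# the study's published coded-factor coefficients, in package term order
PUBLISHED = dict(zip(term_names(4), DEFAULT_TRUTH))


class TestFitReference:
    """The packaged 29-run experiment reproduces the published regression."""

    def test_all_published_coefficients(self, table1_fit):
        for name, expected in PUBLISHED.items():
            assert table1_fit.coefficients()[name] == pytest.approx(
                expected, abs=0.02), name

    def test_intercept_is_center_mean(self, table1, table1_fit):
        """BBD orthogonality pins the intercept to the mean of the five
        center replicates."""
        center = table1.response[np.all(table1.coded == 0, axis=1)]
        assert len(center) == 5
        assert table1_fit.intercept == pytest.approx(center.mean(), abs=1e-6)

    @pytest.mark.parametrize("point, expected, tol", [
        ((0, 0, 0, 0), 121.52, 0.01),
        ((-1, -1, 0, 0), 80.12, 0.05),
    ])
    def test_published_predictions(self, table1_fit, point, expected, tol):
        assert table1_fit.predict(np.array(point, dtype=float)) == pytest.approx(
            expected, abs=tol)

    def test_predictions_match_published_column(self, table1, table1_fit,
                                                table1_extra_columns):
        pred = table1_fit.predict(table1.coded)
        np.testing.assert_allclose(pred, table1_extra_columns["rsm_predicted"],
                                   atol=0.05)


def test_constant_fit_predicts_intercept(factors):
    fit = eo.QuadraticFit(factors=factors, beta=np.r_[7.5, np.zeros(14)],
                          xtx_inv=np.eye(15), ms_residual=0.0, n_obs=29)
    rng = np.random.default_rng(0)
    assert np.allclose(fit.predict(rng.uniform(-1, 1, (10, 4))), 7.5)


def test_noise_free_recovery(factors):
    """Responses generated exactly from a known quadratic are interpolated."""
    spec = eo.SyntheticSpec(noise_sd=0.0, seed=7)
    fit = eo.fit_quadratic(eo.generate(spec, factors))
    np.testing.assert_allclose(fit.beta, spec.coefficients, rtol=1e-9, atol=1e-9)


def test_too_few_runs(factors):
    d = eo.generate_bbd(factors, n_center=5)
    short = eo.DesignTable.from_actual(factors, d.actual[:12],
                                       np.ones(12), d.run_ids[:12])
    with pytest.raises(ValueError, match="more than"):
        eo.fit_quadratic(short)


def test_singular_design_names_columns(factors):
    """A design that never moves factor 4 has collinear x4 columns."""
    coded = eo.generate_bbd(factors[:3], n_center=5).coded
    coded4 = np.column_stack([coded, np.zeros(len(coded))])
    d = eo.DesignTable.from_coded(factors, coded4,
                                  response=np.arange(len(coded4), dtype=float))
    with pytest.raises(SingularDesignError) as err:
        eo.fit_quadratic(d)
    assert any("4" in c for c in err.value.columns)


@pytest.fixture(scope="module")
def tab(table1, table1_fit):
    return eo.anova(table1, table1_fit)


class TestAnovaReference:
    """Published ANOVA of the quadratic model."""

    def test_model_f(self, tab):
        assert tab["Model"].f == pytest.approx(16.54, rel=0.005)

    def test_r_squared(self, tab):
        assert tab.r_squared == pytest.approx(0.9430, abs=0.001)

    def test_pure_error(self, tab):
        assert tab["Pure Error"].ss == pytest.approx(57.15, abs=0.01)
        assert tab["Pure Error"].df == 4

    def test_lack_of_fit(self, tab):
        assert tab["Lack of Fit"].f == pytest.approx(4.45, rel=0.01)
        assert tab["Lack of Fit"].df == 10
        assert tab["Lack of Fit"].p == pytest.approx(0.0816, abs=0.002)

    @pytest.mark.parametrize("source, ss, f", [
        ("X1", 38.7, 0.7817), ("X2", 106.68, 2.15), ("X3", 2032.16, 41.05),
        ("X4", 551.49, 11.14), ("X1X2", 4.73, 0.0956), ("X1X3", 0.2704, 0.0055),
        ("X1X4", 101.81, 2.06), ("X2X3", 5.78, 0.1168), ("X2X4", 0.0529, 0.0011),
        ("X3X4", 1085.37, 21.92), ("X1^2", 4128.66, 83.39),
        ("X2^2", 2205.09, 44.54), ("X3^2", 3517.75, 71.05),
        ("X4^2", 1620.11, 32.72),
    ])
    def test_published_term_rows(self, tab, source, ss, f):
        assert tab[source].ss == pytest.approx(ss, rel=0.01, abs=5e-4)
        # small F values are printed at 2 significant figures only
        assert tab[source].f == pytest.approx(f, rel=0.015, abs=1e-4)

    def test_model_p_rendered_below_threshold(self, tab):
        assert tab["Model"].p < 1e-4
        assert "<0.0001" in tab.to_text()

    def test_df_bookkeeping(self, tab):
        assert tab["Model"].df + tab["Residual"].df == tab["Cor Total"].df
        assert tab["Lack of Fit"].ss + tab["Pure Error"].ss == pytest.approx(
            tab["Residual"].ss, rel=1e-8)

    def test_ss_additivity(self, tab):
        assert tab["Model"].ss + tab["Residual"].ss == pytest.approx(
            tab["Cor Total"].ss, rel=1e-8)


def test_noise_free_anova(factors):
    d = eo.generate(eo.SyntheticSpec(noise_sd=0.0, seed=3), factors)
    fit = eo.fit_quadratic(d)
    tab = eo.anova(d, fit)
    assert tab["Residual"].ss == pytest.approx(0.0, abs=1e-12)
    assert tab.r_squared == pytest.approx(1.0, abs=1e-12)


def test_residual_orthogonality(table1, table1_fit):
    """OLS residuals are orthogonal to every model column."""
    X = model_matrix(table1.coded)
    resid = table1.response - table1_fit.predict(table1.coded)
    assert np.max(np.abs(X.T @ resid)) < 1e-6


def test_linear_partial_ss_equals_12_bsq(table1, table1_fit):
    """On the orthogonal BBD the partial SS of a linear term is 12 b_j^2."""
    tab = eo.anova(table1, table1_fit)
    for j, src in enumerate(["X1", "X2", "X3", "X4"]):
        expected = 12.0 * table1_fit.beta[1 + j] ** 2
        assert tab[src].ss == pytest.approx(expected, rel=1e-6)


def test_sequential_ss_sums_to_model_ss(table1, table1_fit):
    seq = eo.anova(table1, table1_fit, ss_type="sequential")
    term_total = sum(seq[s].ss for s in
                     ["X1", "X2", "X3", "X4", "X1X2", "X1X3", "X1X4", "X2X3",
                      "X2X4", "X3X4", "X1^2", "X2^2", "X3^2", "X4^2"])
    assert term_total == pytest.approx(seq["Model"].ss, rel=1e-8)


def test_no_replicates_omits_lack_of_fit(factors, caplog):
    d = eo.generate(eo.SyntheticSpec(noise_sd=1.0, n_center=1, seed=5), factors)
    tab = eo.anova(d, eo.fit_quadratic(d))
    with pytest.raises(KeyError):
        tab["Pure Error"]


def test_ols_matches_statsmodels_oracle(rng):
    """Normal-equations solution vs an independent generic LS fit on random
    (non-orthogonal) designs."""
    sm = pytest.importorskip("statsmodels.api")
    factors = eo.default_factors()
    for _ in range(50):
        coded = rng.uniform(-1, 1, size=(25, 4))
        y = rng.normal(size=25) * 10 + 100
        d = eo.DesignTable.from_coded(factors, coded, y)
        fit = eo.fit_quadratic(d)
        oracle = sm.OLS(y, model_matrix(coded)).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, rtol=1e-8, atol=1e-8)


def test_coefficient_interval_coverage(factors):
    """95% t-intervals cover the true coefficients at close to nominal rate."""
    from scipy import stats
    truth = DEFAULT_TRUTH
    covered = total = 0
    for seed in range(500):
        d = eo.generate(eo.SyntheticSpec(noise_sd=3.78, seed=seed), factors)
        fit = eo.fit_quadratic(d)
        half = stats.t.ppf(0.975, fit.df_residual) * fit.coefficient_se()
        covered += int(np.sum(np.abs(fit.beta - truth) <= half))
        total += len(truth)
    assert covered / total >= 0.90


class TestFitMetrics:
    def test_perfect_predictions(self, table1):
        m = eo.fit_metrics(table1, table1.response)
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["rmse"] == 0.0

    def test_published_rsm_column(self, table1, table1_extra_columns):
        m = eo.fit_metrics(table1, table1_extra_columns["rsm_predicted"].to_numpy())
        assert m["r_squared"] == pytest.approx(0.943, abs=0.002)

    def test_published_ann_column(self, table1, table1_extra_columns):
        # fit quality of the published network predictions; computed, not
        # asserted against any reported headline value
        m = eo.fit_metrics(table1, table1_extra_columns["ann_predicted"].to_numpy())
        assert 0.9 < m["r_squared"] < 1.0

    def test_zero_variance_response(self, factors):
        d = eo.generate_bbd(factors, n_center=5).with_response(np.full(29, 3.0))
        with pytest.raises(UndefinedRSquaredError):
            eo.fit_metrics(d, np.zeros(29))


def test_fit_json_round_trip(table1_fit):
    fit2 = eo.QuadraticFit.from_dict(table1_fit.to_dict())
    np.testing.assert_allclose(fit2.beta, table1_fit.beta, rtol=0, atol=0)
    point = np.array([0.3, -0.2, 0.5, 0.1])
    assert fit2.predict(point) == table1_fit.predict(point)
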