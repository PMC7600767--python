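"""Trend ratio, relative growth, yearly counts and polynomial trend."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from termspace.corpus import Corpus, Document
from termspace.trends import (
    PolynomialTrend,
    fit_trend_polynomial,
    relative_growth,
    trend_ratio,
    trend_series,
    trend_table,
    yearly_counts,
)

counts = st.integers(min_value=0, max_value=10_000)


def hand_trend(nw2, nt2, nw1, nt1):
    # direct transcription of the smoothed frequency-ratio formula
    return ((nw2 + 0.1) / (nt2 + 0.1)) / ((nw1 + 0.1) / (nt1 + 0.1))


class TestTrendRatio:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0, 100, 0, 100), 1.0),
            ((5, 100, 5, 100), 1.0),
            ((9, 100, 0, 100), 91.0),  # (9.1/100.1)/(0.1/100.1)
        ],
    )
    def test_worked_examples(self, args, expected):
        assert trend_ratio(*args) == pytest.approx(expected, rel=1e-12)

    def test_rejects_word_count_above_total(self):
        with pytest.raises(ValueError):
            trend_ratio(5, 3, 0, 10)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            trend_ratio(-1, 10, 0, 10)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=300, derandomize=True)
    def test_reciprocity(self, a, b, c, d):
        nw2, nt2 = min(a, b), max(a, b)
        nw1, nt1 = min(c, d), max(c, d)
        product = trend_ratio(nw2, nt2, nw1, nt1) * trend_ratio(nw1, nt1, nw2, nt2)
        assert product == pytest.approx(1.0, rel=1e-12)

    def test_strictly_monotone_in_word_counts(self):
        for n in range(0, 99):
            assert trend_ratio(n + 1, 100, 10, 100) > trend_ratio(n, 100, 10, 100)
            assert trend_ratio(10, 100, n + 1, 100) < trend_ratio(10, 100, n, 100)

    def test_always_finite_and_positive(self):
        assert trend_ratio(0, 0, 0, 0) == 1.0
        assert 0 < trend_ratio(0, 10_000, 10_000, 10_000) < 1


class TestRelativeGrowth:
    @pytest.mark.parametrize(
        "baseline, final, expected",
        [
            (0, 44, 100.0),   # absent at baseline
            (7, 7, 0.0),      # no change
            (2, 3, 33.33),    # hand evaluation: 100*(3-2)/3
        ],
    )
    def test_worked_examples(self, baseline, final, expected):
        assert relative_growth(baseline, final) == pytest.approx(expected, abs=0.005)

    def test_zero_final_is_an_error(self):
        with pytest.raises(ValueError, match="no final-period usage"):
            relative_growth(5, 0)

    def test_negative_when_usage_declined(self):
        assert relative_growth(10, 5) == -100.0

    def test_bounded_above_by_100(self):
        for b in range(0, 50):
            for f in range(1, 50):
                assert relative_growth(b, f) <= 100.0

    def test_scale_invariance_grid(self):
        # a ratio of differences: the common factor cancels, so scaling
        # both counts by the same positive integer never changes the value
        for b in range(0, 12):
            for f in range(1, 12):
                for k in (2, 3, 7):
                    assert relative_growth(k * b, k * f) == pytest.approx(
                        relative_growth(b, f), rel=1e-12
                    )


class TestYearlyCounts:
    def test_document_counts_once_per_term_year(self):
        doc = Document("d", 2018, title="predictive", abstract="predictive predictive")
        table = yearly_counts(Corpus([doc]), ["predictive"])
        assert table.count("predictive", 2018) == 1

    def test_empty_corpus(self):
        table = yearly_counts(Corpus(), ["predict"])
        assert table.totals == {} and table.term_counts == {"predict": {}}

    def test_totals_cover_unmatched_documents(self):
        docs = [
            Document("a", 2010, title="x", abstract="predictive model"),
            Document("b", 2010, title="y", abstract="cohort study"),
        ]
        table = yearly_counts(Corpus(docs), ["predictive"])
        assert table.totals == {2010: 2}
        assert table.count("predictive", 2010) == 1

    def test_root_matching_counts_derivatives(self):
        doc = Document("d", 2012, title="", abstract="unpredictability rules")
        table = yearly_counts(Corpus([doc]), ["predict"], match="root")
        assert table.count("predict", 2012) == 1

    def test_year_range_filter(self):
        docs = [Document(str(y), y, title="t", abstract="predictive") for y in (2005, 2010)]
        table = yearly_counts(Corpus(docs), ["predictive"], years=(2007, 2019))
        assert 2005 not in table.totals and table.count("predictive", 2010) == 1

    def test_trend_series_and_table_export(self):
        docs = [
            Document("a", 2010, title="", abstract="predictive"),
            Document("b", 2011, title="", abstract="predictive model"),
            Document("c", 2011, title="", abstract="cohort"),
        ]
        table = yearly_counts(Corpus(docs), ["predictive"])
        series = trend_series(table, "predictive")
        assert series.by_year_pair[(2010, 2011)] == pytest.approx(
            hand_trend(1, 2, 1, 1), rel=1e-12
        )
        frame = trend_table(table, baseline_year=2010, final_year=2011)
        assert set(frame.columns) >= {"term", "year", "count", "total"}
        assert len(frame) == 2


class TestPolynomialTrend:
    def test_exact_cubic_perfect_fit(self):
        years = np.arange(1975, 2019)
        y = 2.0 + 0.5 * (years - 1995) + 0.03 * (years - 1995) ** 2 + 0.001 * (years - 1995) ** 3
        fit = fit_trend_polynomial(dict(zip(years, y)), degree=3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_linear_data_nested_in_cubic(self):
        years = np.arange(2000, 2010)
        fit = fit_trend_polynomial(dict(zip(years, 3.0 * years - 5000)), degree=3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self):
        # independent closed-form least squares: solve V'V b = V'y on the
        # raw Vandermonde (small x keeps it well conditioned)
        rng = np.random.default_rng(42)
        x = np.arange(0, 25, dtype=float)
        true = np.array([5.0, -2.0, 0.7, -0.01])
        y = true[0] + true[1] * x + true[2] * x**2 + true[3] * x**3
        y = y + rng.normal(scale=0.5, size=x.size)
        V = np.vander(x, 4, increasing=True)
        oracle = np.linalg.solve(V.T @ V, V.T @ y)
        fit = fit_trend_polynomial(dict(zip(x, y)), degree=3)
        assert np.allclose(fit.coefficients, oracle, rtol=1e-8)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fit_trend_polynomial({y: 7.0 for y in range(2000, 2010)})

    def test_too_few_distinct_years_rejected(self):
        with pytest.raises(ValueError, match="distinct years"):
            fit_trend_polynomial({2000: 1.0, 2001: 2.0, 2002: 4.0}, degree=3)

    def test_shift_invariance_of_fit_quality(self):
        rng = np.random.default_rng(3)
        x = np.arange(1975, 2019, dtype=float)
        y = 100 + 3 * (x - 1990) + 0.2 * (x - 1990) ** 2 + rng.normal(scale=5, size=x.size)
        f1 = fit_trend_polynomial(dict(zip(x, y)), degree=3)
        f2 = fit_trend_polynomial(dict(zip(x + 57, y)), degree=3)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-9)
        assert f1.residual_sd == pytest.approx(f2.residual_sd, rel=1e-9)
        assert f1.predict(2019) == pytest.approx(f2.predict(2019 + 57), rel=1e-9)

    def test_predict_extrapolates(self):
        years = np.arange(2000, 2018)
        y = (years - 2000.0) ** 2
        est = PolynomialTrend(degree=2).fit(years, y)
        assert est.predict([2020])[0] == pytest.approx(400.0, rel=1e-8)

    def test_estimator_params(self):
        est = PolynomialTrend(degree=4)
        assert est.get_params() == {"degree": 4}
        est.set_params(degree=2)
        assert est.degree == 2
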