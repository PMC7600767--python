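"""Trend statistics on per-year publication counts.

Three statistics drive the analysis:

* the *trend ratio*: the smoothed year-over-year ratio of a term's relative
  document frequency,

  ``Trend = ((n_w,y2 + 0.1)/(N_y2 + 0.1)) / ((n_w,y1 + 0.1)/(N_y1 + 0.1))``

  where ``n_w,y`` is the number of articles containing the word in year y
  and ``N_y`` the total articles that year.  The 0.1 smoothing constant is
  part of the published statistic and is not configurable; it keeps the
  ratio finite and positive even for absent terms.

* *relative growth*, the headline percentage comparing a final year to a
  baseline year: ``100 * (n_final - n_baseline) / n_final``.  A term absent
  at baseline scores exactly 100.00; equal counts score 0; decline is
  negative.

* an ordinary least-squares polynomial trend (default cubic) on yearly
  counts, fitted on internally centered/scaled years for conditioning and
  reported in the original year basis, used to extrapolate publication
  activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .corpus import Corpus, tokenize
from .grouping import match_derivative

__all__ = [
    "SMOOTHING",
    "YearlyCountTable",
    "TrendSeries",
    "PolynomialFit",
    "PolynomialTrend",
    "trend_ratio",
    "relative_growth",
    "yearly_counts",
    "trend_series",
    "fit_trend_polynomial",
]

#: Formula smoothing constant; part of the published statistic, never change.
SMOOTHING = 0.1

DEFAULT_BASELINE_YEAR = 2007
DEFAULT_FINAL_YEAR = 2019


def trend_ratio(
    n_word_y2: float, n_total_y2: float, n_word_y1: float, n_total_y1: float
) -> float:
    """Smoothed ratio of relative document frequencies between two years.

    Always finite and positive thanks to the 0.1 smoothing; equals 1.0 when
    the relative frequency is unchanged (including absent-in-both).
    """
    for n_word, n_total in ((n_word_y2, n_total_y2), (n_word_y1, n_total_y1)):
        if n_total < 0 or n_word < 0:
            raise ValueError("counts must be non-negative")
        if n_word > n_total:
            raise ValueError("word count exceeds the year's total articles")
    return ((n_word_y2 + SMOOTHING) / (n_total_y2 + SMOOTHING)) / (
        (n_word_y1 + SMOOTHING) / (n_total_y1 + SMOOTHING)
    )


def relative_growth(n_baseline: float, n_final: float) -> float:
    """Percent growth of usage from a baseline year to a final year.

    ``100 * (n_final - n_baseline) / n_final``: exactly 100.0 when the term
    was absent at baseline, 0 at no change, negative on decline.
    """
    if n_final == 0:
        raise ValueError("no final-period usage")
    return 100.0 * (n_final - n_baseline) / n_final


@dataclass
class YearlyCountTable:
    """Per-term article counts by year plus per-year corpus totals."""

    term_counts: dict[str, dict[int, int]] = field(default_factory=dict)
    totals: dict[int, int] = field(default_factory=dict)

    def count(self, term: str, year: int) -> int:
        return self.term_counts.get(term, {}).get(year, 0)

    def window_total(self, term: str, years: Iterable[int] | None = None) -> int:
        counts = self.term_counts.get(term, {})
        if years is None:
            return sum(counts.values())
        return sum(counts.get(y, 0) for y in years)

    def relative_growth(
        self,
        term: str,
        baseline_year: int = DEFAULT_BASELINE_YEAR,
        final_year: int = DEFAULT_FINAL_YEAR,
    ) -> float:
        return relative_growth(
            self.count(term, baseline_year), self.count(term, final_year)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": term, "year": year, "count": n, "total": self.totals.get(year, 0)}
            for term, by_year in sorted(self.term_counts.items())
            for year, n in sorted(by_year.items())
        ]
        return pd.DataFrame(rows, columns=["term", "year", "count", "total"])


@dataclass
class TrendSeries:
    """Year-over-year smoothed trend values for one term."""

    term: str
    by_year_pair: dict[tuple[int, int], float] = field(default_factory=dict)


def _term_matcher(term: str, match: str):
    if match == "exact":
        return lambda tokens: term in tokens
    if match == "root":
        return lambda tokens: any(match_derivative(t, term) for t in tokens)
    raise ValueError(f"unknown match mode {match!r}")


def yearly_counts(
    corpus: Corpus,
    terms: Iterable[str],
    years: tuple[int, int] | None = None,
    match: str = "exact",
) -> YearlyCountTable:
    """Count, per term and year, the number of documents containing the term.

    A document contributes at most once per term per year no matter how
    often the term repeats inside it.  ``match="root"`` applies the
    derivative rule instead of exact token equality.  Totals cover every
    document in the year range, matched or not.
    """
    terms = list(dict.fromkeys(terms))
    matchers = {t: _term_matcher(t, match) for t in terms}
    table = YearlyCountTable(term_counts={t: {} for t in terms})
    for doc in corpus:
        if years is not None and not (years[0] <= doc.year <= years[1]):
            continue
        table.totals[doc.year] = table.totals.get(doc.year, 0) + 1
        token_set = set()
        for fld in doc.fields():
            token_set.update(tokenize(fld, doc.language))
        for term in terms:
            if matchers[term](token_set):
                by_year = table.term_counts[term]
                by_year[doc.year] = by_year.get(doc.year, 0) + 1
    return table


def trend_series(table: YearlyCountTable, term: str) -> TrendSeries:
    """All consecutive-year trend ratios available for a term."""
    years = sorted(table.totals)
    out = TrendSeries(term=term)
    for y1, y2 in zip(years, years[1:]):
        out.by_year_pair[(y1, y2)] = trend_ratio(
            table.count(term, y2), table.totals[y2],
            table.count(term, y1), table.totals[y1],
        )
    return out


class PolynomialTrend(RegressorMixin, BaseEstimator):
    """Least-squares polynomial trend of publication counts over years.

    Parameters
    ----------
    degree:
        Polynomial degree, default 3 (cubic), the standard choice for
        long-run publication-activity curves.

    Attributes
    ----------
    coefficients_:
        Ascending-power coefficients in the original year basis.
    r_squared_:
        ``1 - SS_res / SS_tot`` on the fitted data.
    residual_sd_:
        Standard deviation (population, ddof=0) of fit residuals, the
        ``+-`` band quoted alongside extrapolations.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("years and counts must have the same length")
        if np.unique(x).size <= self.degree:
            raise ValueError(
                f"need more than {self.degree} distinct years, got {np.unique(x).size}"
            )
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("R² undefined: constant series (SS_tot = 0)")
        # Polynomial.fit maps years onto [-1, 1] internally (centering and
        # scaling for conditioning); convert() reports the original basis.
        self._poly = np.polynomial.Polynomial.fit(x, y, deg=self.degree)
        residuals = y - self._poly(x)
        self.coefficients_ = self._poly.convert().coef
        self.r_squared_ = 1.0 - float(np.sum(residuals**2)) / ss_tot
        self.residual_sd_ = float(np.std(residuals))
        return self

    def predict(self, X):
        if not hasattr(self, "_poly"):
            raise ValueError("PolynomialTrend is not fitted")
        x = np.asarray(X, dtype=float)
        return self._poly(x)


@dataclass
class PolynomialFit:
    """Plain-data view of a fitted polynomial trend."""

    degree: int
    coefficients: np.ndarray  # ascending powers, original year basis
    r_squared: float
    residual_sd: float
    _estimator: PolynomialTrend = field(repr=False, default=None)

    def predict(self, year):
        return self._estimator.predict(year)


def fit_trend_polynomial(
    series: Mapping[int, float] | Sequence[tuple[int, float]],
    degree: int = 3,
) -> PolynomialFit:
    """Fit a polynomial trend to a year -> count series."""
    items = sorted(dict(series).items())
    years = [y for y, _ in items]
    counts = [c for _, c in items]
    est = PolynomialTrend(degree=degree).fit(years, counts)
    return PolynomialFit(
        degree=degree,
        coefficients=est.coefficients_,
        r_squared=est.r_squared_,
        residual_sd=est.residual_sd_,
        _estimator=est,
    )


def trend_table(
    table: YearlyCountTable,
    baseline_year: int = DEFAULT_BASELINE_YEAR,
    final_year: int = DEFAULT_FINAL_YEAR,
) -> pd.DataFrame:
    """Long-format export: term, year, count, total, trend vs previous
    year, relative growth vs baseline (NaN where undefined)."""
    rows = []
    years = sorted(table.totals)
    prev = {y2: y1 for y1, y2 in zip(years, years[1:])}
    for term in sorted(table.term_counts):
        try:
            growth = table.relative_growth(term, baseline_year, final_year)
        except ValueError:
            growth = float("nan")
        for year in years:
            n = table.count(term, year)
            trend = (
                trend_ratio(n, table.totals[year],
                            table.count(term, prev[year]), table.totals[prev[year]])
                if year in prev
                else float("nan")
            )
            rows.append(
                {
                    "term": term,
                    "year": year,
                    "count": n,
                    "total": table.totals[year],
                    "trend_vs_previous_year": trend,
                    "relative_growth_vs_baseline": growth,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "year", "count", "total",
            "trend_vs_previous_year", "relative_growth_vs_baseline",
        ],
    )
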