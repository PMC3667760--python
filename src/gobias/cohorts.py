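"""Throughput cohorts, the proteins-per-article distribution and its fit.

Articles are binned by the number of distinct proteins they annotate:
single (1), low (2-9), moderate (10-99) and high throughput (>= 100).
The proteins-per-article histogram is heavy-tailed; its shape is
summarized, as in the source analysis, by ordinary least squares of
log10(article count) on log10(throughput k) — a plain log-log linear fit,
not a maximum-likelihood power-law estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .gaf import ArticleGroup

COHORTS = ("SINGLE", "LOW", "MODERATE", "HIGH")

#: lower bounds of the LOW, MODERATE and HIGH cohorts
DEFAULT_BOUNDARIES = (2, 10, 100)


def assign_cohort(n_proteins: int,
                  boundaries: tuple[int, int, int] = DEFAULT_BOUNDARIES) -> str:
    """Cohort label for an article annotating *n_proteins* distinct proteins."""
    if n_proteins < 1:
        raise ValueError(f"throughput must be >= 1, got {n_proteins}")
    low, moderate, high = boundaries
    if n_proteins >= high:
        return "HIGH"
    if n_proteins >= moderate:
        return "MODERATE"
    if n_proteins >= low:
        return "LOW"
    return "SINGLE"


def cohort_percentages(counts: Sequence[int]) -> list[float]:
    """Each count as a percent of the sequence's own sum, rounded to 2 dp."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return [round(100.0 * c / total, 2) for c in counts]


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort article and distinct-protein tallies with percentages.

    A protein annotated by articles in two cohorts counts once in each, so
    ``total_proteins`` is the sum of the per-cohort counts (protein-cohort
    pairs), not a global distinct-protein count.
    """

    articles: dict[str, int]
    proteins: dict[str, int]
    percent_articles: dict[str, float]
    percent_proteins: dict[str, float]

    @property
    def total_articles(self) -> int:
        return sum(self.articles.values())

    @property
    def total_proteins(self) -> int:
        return sum(self.proteins.values())


def cohort_summary(article_groups: Mapping[int, ArticleGroup],
                   boundaries: tuple[int, int, int] = DEFAULT_BOUNDARIES,
                   ) -> CohortSummary:
    """Tabulate articles and distinct proteins per throughput cohort."""
    if not article_groups:
        raise InsufficientDataError("no article groups to summarize")
    articles = {c: 0 for c in COHORTS}
    protein_sets: dict[str, set[str]] = {c: set() for c in COHORTS}
    for group in article_groups.values():
        cohort = assign_cohort(group.throughput, boundaries)
        articles[cohort] += 1
        protein_sets[cohort].update(group.distinct_proteins)
    proteins = {c: len(protein_sets[c]) for c in COHORTS}
    pa = cohort_percentages([articles[c] for c in COHORTS])
    pp = cohort_percentages([proteins[c] for c in COHORTS])
    return CohortSummary(
        articles=articles,
        proteins=proteins,
        percent_articles=dict(zip(COHORTS, pa)),
        percent_proteins=dict(zip(COHORTS, pp)),
    )


def proteins_per_article_histogram(article_groups: Mapping[int, ArticleGroup],
                                   ) -> dict[int, int]:
    """Number of articles at each observed throughput k (no zero bins)."""
    hist: dict[int, int] = {}
    for group in article_groups.values():
        hist[group.throughput] = hist.get(group.throughput, 0) + 1
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(count) on log10(k)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def fit_loglog(histogram: Mapping[int, int]) -> PowerLawFit:
    """Fit log10(article count) against log10(throughput) by least squares.

    Requires at least three distinct throughput values with positive counts;
    zero-count bins never appear in the histogram, so no value reaches the
    logarithm at zero.
    """
    ks = np.array(sorted(histogram), dtype=float)
    counts = np.array([histogram[int(k)] for k in ks], dtype=float)
    if np.any(ks <= 0) or np.any(counts <= 0):
        raise ValueError("histogram keys and counts must be positive")
    if len(ks) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct throughput values, got {len(ks)}")
    res = stats.linregress(np.log10(ks), np.log10(counts))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_points=len(ks),
    )
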