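"""Top-K article dominance: term contributions, aspect mix, exclusive-HT.

The articles that annotate the most proteins ("top-K", K = 50 by default)
dominate the experimental corpus of several model organisms. This module
measures that dominance per species: the *contribution* of the top set to
each GO term's annotations, the most frequent terms inside the top set,
the ontology-aspect mix of each throughput cohort, and the fraction of a
species' proteins whose every experimental annotation comes from a
high-throughput article (exclusive-HT, "XHT").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .gaf import AnnotationRecord, ArticleGroup


def top_articles(article_groups: Mapping[int, ArticleGroup], k: int,
                 ) -> list[ArticleGroup]:
    """The k highest-throughput articles; ties broken by ascending PMID."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(article_groups.values(),
                    key=lambda g: (-g.throughput, g.pmid))
    return ranked[:k]


@dataclass(frozen=True)
class ContributionRecord:
    """Share of one (taxon, term)'s annotations supplied by the top set."""

    taxon: int
    term: str
    topk_count: int
    corpus_count: int

    @property
    def contribution(self) -> float:
        return self.topk_count / self.corpus_count


def term_contribution(corpus: Sequence[AnnotationRecord],
                      top_pmids: Iterable[int],
                      taxon: int, term_id: str) -> ContributionRecord:
    """Fraction of a term's annotations, within one taxon, from top articles.

    Both numerator and denominator are restricted to annotations of the
    given taxon.
    """
    top = set(top_pmids)
    corpus_count = topk_count = 0
    for rec in corpus:
        if rec.taxon == taxon and rec.go_term == term_id:
            corpus_count += 1
            if rec.pmid in top:
                topk_count += 1
    if corpus_count == 0:
        raise LookupError(
            f"term {term_id} has no annotations for taxon {taxon}")
    return ContributionRecord(taxon=taxon, term=term_id,
                              topk_count=topk_count, corpus_count=corpus_count)


def top_terms(corpus: Sequence[AnnotationRecord], top_pmids: Iterable[int],
              taxon: int, n: int = 5) -> list[str]:
    """The n most frequent terms in the taxon's top-set annotations.

    Ties are broken by ascending term id. Empty when the taxon has no
    annotations in the top set.
    """
    top = set(top_pmids)
    counts = Counter(rec.go_term for rec in corpus
                     if rec.taxon == taxon and rec.pmid in top)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [term for term, _ in ranked[:n]]


def aspect_fraction_by_cohort(corpus: Sequence[AnnotationRecord],
                              cohort_of_pmid: Mapping[int, str],
                              ) -> dict[str, dict[str, float]]:
    """Per cohort, the fraction of annotations in each aspect (F, P, C).

    Cohorts with no annotations are absent from the result; fractions of a
    present cohort sum to 1.
    """
    counts: dict[str, Counter[str]] = {}
    for rec in corpus:
        cohort = cohort_of_pmid[rec.pmid]
        counts.setdefault(cohort, Counter())[rec.aspect] += 1
    out: dict[str, dict[str, float]] = {}
    for cohort, aspect_counts in counts.items():
        total = sum(aspect_counts.values())
        out[cohort] = {a: aspect_counts.get(a, 0) / total for a in "FPC"}
    return out


def xht_percent(xht: int, total: int) -> float:
    """Percent of a taxon's proteins that are exclusively HT-annotated."""
    if not 0 <= xht <= total or total == 0:
        raise ValueError(f"need 0 <= xht <= total > 0, got {xht}/{total}")
    return round(100.0 * xht / total, 4)


@dataclass(frozen=True)
class ExclusiveHTRow:
    taxon: int
    xht: int
    total: int

    @property
    def percent_xht(self) -> float:
        return xht_percent(self.xht, self.total)


def exclusive_ht_table(corpus: Sequence[AnnotationRecord],
                       article_groups: Mapping[int, ArticleGroup],
                       ht_threshold: int = 100,
                       min_proteins: int = 200) -> list[ExclusiveHTRow]:
    """Per well-annotated taxon, count exclusively HT-annotated proteins.

    A protein is XHT iff every one of its experimental annotations comes
    from an article of throughput >= *ht_threshold*. Only taxa with more
    than *min_proteins* experimentally annotated proteins are reported
    (the rest are omitted, not zeroed). Rows are ordered by descending
    percent, ties by ascending taxon id.
    """
    throughput = {pmid: g.throughput for pmid, g in article_groups.items()}
    proteins: dict[int, dict[str, bool]] = {}  # taxon -> protein -> all-HT?
    for rec in corpus:
        ht = throughput[rec.pmid] >= ht_threshold
        taxon_map = proteins.setdefault(rec.taxon, {})
        taxon_map[rec.protein_id] = taxon_map.get(rec.protein_id, True) and ht
    rows = []
    for taxon, flags in proteins.items():
        total = len(flags)
        if total <= min_proteins:
            continue
        rows.append(ExclusiveHTRow(taxon=taxon,
                                   xht=sum(flags.values()), total=total))
    rows.sort(key=lambda r: (-r.percent_xht, r.taxon))
    return rows
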