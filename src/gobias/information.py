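"""Annotation informativeness: edge-count depth and information content.

Two complementary specificity measures per annotation: (1) the term's
minimal edge depth in its ontology namespace, and (2) corpus information
content, IC = log2(1/f) bits, where f is the term's frequency among the
corpus's direct annotations within the same namespace. Frequencies use
direct annotations only — no true-path propagation up the DAG — mirroring
how term usage is tallied in the corpus itself (propagation is available
via a flag). Aggregating either measure per throughput cohort shows
whether high-throughput articles assign shallower, more generic terms
than single-protein studies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import pandas as pd

from .gaf import AnnotationRecord
from .ontology import OntologyGraph


def term_frequency(corpus: Sequence[AnnotationRecord], term_id: str,
                   ontology: OntologyGraph | None = None,
                   propagate: bool = False) -> float:
    """Frequency of *term_id* among same-namespace direct annotations.

    With ``propagate=True`` a term's occurrences include annotations to any
    of its descendants (true-path propagation); the denominator is unchanged.
    No smoothing: a term absent from the corpus raises ``LookupError``.
    """
    counts, totals, aspect_of = _frequency_tables(corpus, ontology, propagate)
    if term_id not in counts or counts[term_id] == 0:
        raise LookupError(f"term {term_id} does not occur in the corpus")
    return counts[term_id] / totals[aspect_of[term_id]]


def _frequency_tables(corpus, ontology, propagate):
    counts: Counter[str] = Counter()
    totals: Counter[str] = Counter()
    aspect_of: dict[str, str] = {}
    for rec in corpus:
        tid = rec.go_term
        if ontology is not None:
            try:
                tid = ontology.resolve(tid)
            except LookupError:
                pass  # counted under its raw id; profile callers tally skips
        counts[tid] += 1
        totals[rec.aspect] += 1
        aspect_of[tid] = rec.aspect
        if propagate and ontology is not None:
            for anc in ontology.ancestors(tid):
                counts[anc] += 1
                aspect_of.setdefault(anc, rec.aspect)
    return counts, totals, aspect_of


def information_content(frequency: float, base: float = 2.0) -> float:
    """IC of a term frequency: log(1/f); base 2 gives bits."""
    if not 0.0 < frequency <= 1.0:
        raise ValueError(f"frequency must be in (0, 1], got {frequency}")
    return -math.log(frequency, base)


@dataclass
class InfoProfile:
    """Per (cohort, namespace) depth and IC aggregates plus skip tally."""

    table: pd.DataFrame  # columns: cohort, namespace, metric, mean, sd, n
    skipped_terms: Counter = field(default_factory=Counter)


def cohort_information_profile(corpus: Sequence[AnnotationRecord],
                               ontology: OntologyGraph,
                               cohort_of_pmid: Mapping[int, str],
                               ic_base: float = 2.0) -> InfoProfile:
    """Aggregate depth and IC of every annotation per (cohort, namespace).

    Each annotation contributes its term's minimal depth and its IC to the
    cohort of its source article. Annotations whose term cannot be resolved
    in the ontology are counted in ``skipped_terms``, never silently lost.
    Cohort/namespace pairs with no annotations are reported with n = 0.
    """
    counts, totals, _ = _frequency_tables(corpus, ontology, propagate=False)
    samples: dict[tuple[str, str], dict[str, list[float]]] = {}
    skipped: Counter[str] = Counter()
    for rec in corpus:
        try:
            tid = ontology.resolve(rec.go_term)
            depth = ontology.min_depth(tid)
        except LookupError:
            skipped[rec.go_term] += 1
            continue
        ic = information_content(counts[tid] / totals[rec.aspect], ic_base)
        ns = ontology.namespace(tid)
        cohort = cohort_of_pmid[rec.pmid]
        cell = samples.setdefault((cohort, ns), {"depth": [], "ic": []})
        cell["depth"].append(float(depth))
        cell["ic"].append(ic)

    from .cohorts import COHORTS
    from .ontology import NAMESPACES

    rows = []
    for cohort in COHORTS:
        for ns in NAMESPACES:
            cell = samples.get((cohort, ns))
            for metric in ("depth", "ic"):
                vals = pd.Series(cell[metric]) if cell else pd.Series(dtype=float)
                rows.append({
                    "cohort": cohort,
                    "namespace": ns,
                    "metric": metric,
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else
                          (0.0 if len(vals) == 1 else float("nan")),
                    "n": int(len(vals)),
                })
    return InfoProfile(table=pd.DataFrame(rows), skipped_terms=skipped)
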