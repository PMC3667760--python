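"""Repetition and consistency of annotations across high-throughput articles.

Different large-scale studies often re-annotate the same proteins. Two
statistics quantify this. *Redundancy* clusters the protein entries of the
top-K articles (one entry per protein-article pair) at 100% sequence
identity and reports 100·(1 − clusters/entries), so 0 means every entry is
unique. *Repetition* is simply the fraction of proteins annotated by two or
more articles. They answer related but distinct questions and are reported
separately.

*Maximum annotation consistency* asks whether the studies that re-annotate
a protein agree: for one protein and one ontology namespace, C_max is the
most frequent term's count divided by the total annotation count. Four
annotations of which two say "mitochondrion" give C_max = 2/4 = 0.5;
C_max = 1 means all sources used a single term.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .gaf import AnnotationRecord, ArticleGroup
from .ontology import ASPECT_TO_NAMESPACE, OntologyGraph


# -- sequence redundancy ------------------------------------------------

def cluster_identical(entries: Sequence[tuple[str, str]],
                      ) -> list[set[str]]:
    """Partition ``(entry_id, sequence)`` pairs by byte-identical sequence.

    Full-length 100% identity, no alignment. Deterministic: clusters are
    ordered by first appearance of their sequence.
    """
    by_seq: dict[str, set[str]] = {}
    for entry_id, seq in entries:
        if not seq:
            raise ValueError(f"entry {entry_id} has an empty sequence")
        by_seq.setdefault(seq, set()).add(entry_id)
    return list(by_seq.values())


def redundancy_percent(n_entries: int, n_clusters: int) -> int:
    """100·(1 − clusters/entries), rounded to nearest (half away from zero)."""
    if not 1 <= n_clusters <= n_entries:
        raise ValueError(
            f"need 1 <= n_clusters <= n_entries, got {n_clusters}/{n_entries}")
    value = 100.0 * (1.0 - n_clusters / n_entries)
    return int(math.floor(value + 0.5))


def repetition_fraction(article_counts: Mapping[str, int]) -> float:
    """Fraction of proteins annotated by two or more articles."""
    if not article_counts:
        raise ValueError("empty protein -> article-count mapping")
    if any(c < 1 for c in article_counts.values()):
        raise ValueError("article counts must be >= 1")
    multi = sum(1 for c in article_counts.values() if c >= 2)
    return multi / len(article_counts)


def read_fasta(fasta_content: str) -> dict[str, str]:
    """Accession → residue string; accession per db|acc|name or raw header."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(fasta_content), "fasta"):
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 3 else rec.id
        seqs[acc] = str(rec.seq).upper()
    return seqs


@dataclass(frozen=True)
class RedundancySummary:
    """Per-taxon sequence redundancy over top-set protein-article entries."""

    taxon: int
    n_articles: int
    n_entries: int
    n_clusters: int
    skipped_accessions: int = 0
    mean_multi_cluster_size: float = float("nan")

    @property
    def redundancy(self) -> int:
        return redundancy_percent(self.n_entries, self.n_clusters)


def redundancy_summary(top_set: Sequence[ArticleGroup],
                       sequences: Mapping[str, str],
                       ) -> list[RedundancySummary]:
    """Cluster each taxon's top-set protein-article entries at 100% identity.

    Entries carry article multiplicity: a protein annotated by three top
    articles contributes three entries. Accessions missing from the FASTA
    go to a per-taxon skip tally. The mean cluster size is computed over
    clusters with two or more entries only.
    """
    per_taxon: dict[int, list[tuple[str, str]]] = {}
    articles: dict[int, set[int]] = {}
    skipped: Counter[int] = Counter()
    for group in top_set:
        for taxon in group.taxa:
            prots = {r.protein_id for r in group.records if r.taxon == taxon}
            articles.setdefault(taxon, set()).add(group.pmid)
            for acc in sorted(prots):
                seq = sequences.get(acc)
                if seq is None:
                    skipped[taxon] += 1
                    continue
                per_taxon.setdefault(taxon, []).append(
                    (f"{acc}@{group.pmid}", seq))
    out = []
    for taxon in sorted(per_taxon):
        clusters = cluster_identical(per_taxon[taxon])
        multi = [len(c) for c in clusters if len(c) >= 2]
        out.append(RedundancySummary(
            taxon=taxon,
            n_articles=len(articles[taxon]),
            n_entries=len(per_taxon[taxon]),
            n_clusters=len(clusters),
            skipped_accessions=skipped[taxon],
            mean_multi_cluster_size=(sum(multi) / len(multi)) if multi
                                    else float("nan"),
        ))
    return out


# -- annotation consistency ----------------------------------------------

def consistency_max(term_counts: Mapping[str, int]) -> float:
    """Most frequent term's count over the total annotation count."""
    if not term_counts:
        raise ValueError("empty term-count mapping")
    if any(c < 1 for c in term_counts.values()):
        raise ValueError("term counts must be >= 1")
    total = sum(term_counts.values())
    return max(term_counts.values()) / total


def mean_consistency(corpus: Sequence[AnnotationRecord],
                     top_pmids: Iterable[int],
                     min_articles: int = 2,
                     min_terms: int = 2,
                     ontology: OntologyGraph | None = None,
                     prune_ancestors: bool = False) -> pd.DataFrame:
    """Mean C_max per (taxon, namespace) over multiply-annotated proteins.

    For each taxon and namespace, proteins annotated by more than one
    top-set article get a C_max from their term counts across those
    articles; the row reports mean, sd (n−1 denominator), standard error,
    and the filter counts (proteins, distinct articles, distinct terms —
    both counted after the >1-article restriction). Rows with fewer than
    *min_articles* articles or *min_terms* terms are omitted.

    With ``prune_ancestors=True`` (requires *ontology*) a term assigned to
    a protein is dropped when another assigned term of the same protein is
    its descendant, so only the most specific assigned terms are compared.
    """
    top = set(top_pmids)
    # (taxon, namespace, protein) -> {article pmids}, Counter over terms
    cell_articles: dict[tuple, set[int]] = {}
    cell_terms: dict[tuple, Counter[str]] = {}
    for rec in corpus:
        if rec.pmid not in top:
            continue
        ns = ASPECT_TO_NAMESPACE.get(rec.aspect, rec.aspect)
        key = (rec.taxon, ns, rec.protein_id)
        cell_articles.setdefault(key, set()).add(rec.pmid)
        cell_terms.setdefault(key, Counter())[rec.go_term] += 1

    rows: dict[tuple[int, str], dict] = {}
    for key in sorted(cell_terms):
        taxon, ns, protein = key
        if len(cell_articles[key]) < 2:
            continue
        counts = cell_terms[key]
        if prune_ancestors and ontology is not None:
            counts = _prune_ancestor_terms(counts, ontology)
        row = rows.setdefault((taxon, ns), {
            "cmax": [], "articles": set(), "terms": set()})
        row["cmax"].append(consistency_max(counts))
        row["articles"].update(cell_articles[key])
        row["terms"].update(counts)

    records = []
    for (taxon, ns), row in sorted(rows.items()):
        if len(row["articles"]) < min_articles or len(row["terms"]) < min_terms:
            continue
        vals = pd.Series(row["cmax"])
        n = len(vals)
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        records.append({
            "taxon": taxon,
            "namespace": ns,
            "n_proteins": n,
            "mean_cmax": float(vals.mean()),
            "sd": sd,
            "stderr": sd / math.sqrt(n),
            "n_articles": len(row["articles"]),
            "n_terms": len(row["terms"]),
        })
    return pd.DataFrame(records, columns=[
        "taxon", "namespace", "n_proteins", "mean_cmax", "sd", "stderr",
        "n_articles", "n_terms"])


def _prune_ancestor_terms(counts: Counter, ontology: OntologyGraph) -> Counter:
    keep = Counter()
    terms = list(counts)
    for t in terms:
        t_primary = ontology.resolve(t)
        if any(t_primary in ontology.ancestors(o) for o in terms
               if ontology.resolve(o) != t_primary):
            continue
        keep[t] = counts[t]
    return keep if keep else counts
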