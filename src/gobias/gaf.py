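"""GAF ingestion: experimental-evidence filtering and grouping by article.

A GAF 2.x file carries one annotation per row. This module keeps only rows
whose evidence code is experimental (EXP, IDA, IPI, IMP, IGI, IEP by
default), drops NOT-qualified rows (they assert absence of function), and
expands rows that cite several PubMed ids into one record per cited article
— each cited study independently supports the annotation. Rows with no
PMID-type reference cannot be attributed to an article; they are excluded
from article analyses but counted in a side tally so the loss is auditable.

The unit conventions used downstream: a "protein annotated by an article"
is a distinct accession (isoform suffixes kept verbatim), and an
"annotation" is a (protein, term, article) triple.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import GafFormatError

#: GO experimental evidence codes.
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

_GO_ID = re.compile(r"^GO:\d{7}$")

# 0-based GAF column indices (GAF 2.0/2.1, 17 columns; 15 required here)
_COL_DB = 0
_COL_ID = 1
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_GOID = 4
_COL_REFERENCE = 5
_COL_EVIDENCE = 6
_COL_ASPECT = 8
_COL_TAXON = 12
_MIN_COLUMNS = 15


@dataclass(frozen=True)
class AnnotationRecord:
    """One experimental GO annotation attributed to one article."""

    protein_id: str
    go_term: str
    aspect: str  # F, P or C
    evidence: str
    pmid: int | None
    taxon: int
    qualifiers: tuple[str, ...] = ()
    symbol: str = ""


@dataclass
class GafStats:
    """Side tallies from a parse: nothing is dropped silently."""

    rows: int = 0
    kept_records: int = 0
    excluded_evidence: int = 0
    excluded_not: int = 0
    no_pmid: int = 0
    multi_pmid_rows: int = 0


@dataclass(frozen=True)
class ArticleGroup:
    """All records sharing one PMID; throughput = distinct proteins."""

    pmid: int
    records: tuple[AnnotationRecord, ...]
    distinct_proteins: frozenset[str] = field(default_factory=frozenset)
    taxa: frozenset[int] = field(default_factory=frozenset)

    @property
    def throughput(self) -> int:
        return len(self.distinct_proteins)


def parse_gaf(gaf_content: str,
              evidence_filter: Iterable[str] = EXPERIMENTAL_CODES,
              *,
              ontology=None,
              stats: GafStats | None = None) -> list[AnnotationRecord]:
    """Parse GAF content into experimentally evidenced annotation records.

    Parameters
    ----------
    gaf_content:
        Tab-separated GAF 2.x text; comment lines begin with ``!``.
    evidence_filter:
        Evidence codes to keep.
    ontology:
        Optional :class:`~gobias.ontology.OntologyGraph`; when supplied,
        rows whose aspect column disagrees with the term's namespace are
        rejected.
    stats:
        Optional :class:`GafStats` mutated in place with side tallies.

    Raises
    ------
    GafFormatError
        On rows with fewer than 15 columns, a malformed GO id, or an
        aspect/namespace mismatch; the message carries the 1-based line
        number.
    """
    from .ontology import NAMESPACE_TO_ASPECT  # cycle-free late import
    keep = set(evidence_filter)
    tally = stats if stats is not None else GafStats()
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(gaf_content.splitlines(), start=1):
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_COLUMNS:
            raise GafFormatError(
                f"line {lineno}: expected >= {_MIN_COLUMNS} columns, "
                f"got {len(cols)}")
        tally.rows += 1
        go_id = cols[_COL_GOID].strip()
        if not _GO_ID.match(go_id):
            raise GafFormatError(f"line {lineno}: malformed GO id {go_id!r}")
        qualifiers = tuple(q for q in cols[_COL_QUALIFIER].split("|") if q)
        if any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
            tally.excluded_not += 1
            continue
        evidence = cols[_COL_EVIDENCE].strip()
        if evidence not in keep:
            tally.excluded_evidence += 1
            continue
        pmids = _pmids(cols[_COL_REFERENCE])
        if not pmids:
            tally.no_pmid += 1
            continue
        if len(pmids) > 1:
            tally.multi_pmid_rows += 1
        taxon = _taxon(cols[_COL_TAXON], lineno)
        aspect = cols[_COL_ASPECT].strip()
        if ontology is not None and go_id in ontology:
            expected = NAMESPACE_TO_ASPECT[ontology.namespace(go_id)]
            if aspect != expected:
                raise GafFormatError(
                    f"line {lineno}: aspect {aspect!r} disagrees with the "
                    f"{ontology.namespace(go_id)} namespace of {go_id}")
        for pmid in pmids:
            records.append(AnnotationRecord(
                protein_id=cols[_COL_ID].strip(),
                go_term=go_id,
                aspect=aspect,
                evidence=evidence,
                pmid=pmid,
                taxon=taxon,
                qualifiers=qualifiers,
                symbol=cols[_COL_SYMBOL].strip(),
            ))
            tally.kept_records += 1
    return records


def _pmids(reference_field: str) -> list[int]:
    out = []
    for ref in reference_field.split("|"):
        ref = ref.strip()
        if ref.upper().startswith("PMID:"):
            digits = ref.split(":", 1)[1]
            if digits.isdigit():
                out.append(int(digits))
    return out


def _taxon(taxon_field: str, lineno: int) -> int:
    # multi-organism rows list interacting taxa pipe-separated; the first is
    # the annotated gene product's taxon
    first = taxon_field.split("|")[0].strip()
    if ":" in first:
        first = first.split(":", 1)[1]
    if not first.isdigit():
        raise GafFormatError(f"line {lineno}: malformed taxon {taxon_field!r}")
    return int(first)


def group_by_article(records: Sequence[AnnotationRecord],
                     ) -> dict[int, ArticleGroup]:
    """Partition records by PMID, ascending; throughput is distinct proteins."""
    buckets: dict[int, list[AnnotationRecord]] = {}
    for rec in records:
        if rec.pmid is None:
            raise ValueError("record without a pmid cannot be grouped")
        buckets.setdefault(rec.pmid, []).append(rec)
    groups: dict[int, ArticleGroup] = {}
    for pmid in sorted(buckets):
        recs = tuple(buckets[pmid])
        groups[pmid] = ArticleGroup(
            pmid=pmid,
            records=recs,
            distinct_proteins=frozenset(r.protein_id for r in recs),
            taxa=frozenset(r.taxon for r in recs),
        )
    return groups


def records_to_tsv(records: Sequence[AnnotationRecord]) -> str:
    """Serialize normalized records as TSV with a fixed header."""
    lines = ["protein_id\tgo_term\taspect\tevidence\tpmid\ttaxon\tqualifiers\tsymbol"]
    for r in records:
        lines.append("\t".join([
            r.protein_id, r.go_term, r.aspect, r.evidence,
            "" if r.pmid is None else str(r.pmid), str(r.taxon),
            "|".join(r.qualifiers), r.symbol,
        ]))
    return "\n".join(lines) + "\n"
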