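"""Sequence redundancy clustering and annotation-consistency statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gobias import (
    cluster_identical,
    consistency_max,
    gen_sequences,
    group_by_article,
    mean_consistency,
    parse_gaf,
    read_fasta,
    redundancy_percent,
    redundancy_summary,
    repetition_fraction,
    top_articles,
)
from test_gaf import gaf_row


def test_distinct_sequences_form_singletons():
    entries = [(f"e{i}", seq) for i, seq in
               enumerate(["MAAA", "MCCC", "MDDD", "MEEE"])]
    clusters = cluster_identical(entries)
    assert sorted(len(c) for c in clusters) == [1, 1, 1, 1]


def test_copies_cluster_together():
    entries = [("a", "MKV"), ("b", "MKV"), ("c", "MKV"), ("d", "MW")]
    sizes = sorted(len(c) for c in cluster_identical(entries))
    assert sizes == [1, 3]


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        cluster_identical([("a", "")])


def test_cluster_partition_matches_quadratic_oracle():
    rng = np.random.default_rng(5)
    pool = ["".join(rng.choice(list("ACDEFGHIK"), size=30)) for _ in range(60)]
    entries = [(f"e{i}", pool[int(rng.integers(60))]) for i in range(200)]
    clusters = cluster_identical(entries)
    # partition property
    ids = [e for c in clusters for e in c]
    assert sorted(ids) == sorted(e for e, _ in entries)
    # all-pairs equality oracle
    seq_of = dict(entries)
    cluster_of = {e: i for i, c in enumerate(clusters) for e in c}
    for a, _ in entries:
        for b, _ in entries:
            assert (cluster_of[a] == cluster_of[b]) == (seq_of[a] == seq_of[b])


@pytest.mark.parametrize("entries,clusters,expected", [
    (10, 10, 0),
    (4, 1, 75),
    (8, 5, 38),  # 37.5 rounds half away from zero
])
def test_redundancy_percent_rounding(entries, clusters, expected):
    assert redundancy_percent(entries, clusters) == expected


def test_redundancy_percent_domain():
    with pytest.raises(ValueError):
        redundancy_percent(5, 6)
    with pytest.raises(ValueError):
        redundancy_percent(5, 0)


def test_repetition_fraction_cases():
    assert repetition_fraction({"a": 1, "b": 1}) == 0.0
    assert repetition_fraction({"a": 2, "b": 3}) == 1.0
    assert repetition_fraction({"p1": 1, "p2": 2, "p3": 3, "p4": 1}) == 0.5
    with pytest.raises(ValueError):
        repetition_fraction({})


def test_consistency_max_worked_example():
    counts = {"nucleus": 1, "cytoplasm": 1, "mitochondrion": 2}
    assert consistency_max(counts) == 0.5


def test_consistency_max_degenerate_cases():
    assert consistency_max({"X": 7}) == 1.0
    assert consistency_max({c: 1 for c in "abcde"}) == pytest.approx(1 / 5)
    with pytest.raises(ValueError):
        consistency_max({})


@settings(derandomize=True, max_examples=100)
@given(st.dictionaries(st.text(min_size=1, max_size=4),
                       st.integers(min_value=1, max_value=50),
                       min_size=1, max_size=8))
def test_consistency_max_invariances(counts):
    value = consistency_max(counts)
    assert 1 / len(counts) <= value <= 1
    doubled = {t: 2 * c for t, c in counts.items()}
    assert consistency_max(doubled) == pytest.approx(value)
    assert (value == 1) == (len(counts) == 1)


def _consistency_corpus():
    # two articles annotate P1 with the same C term; two articles annotate
    # P2 with two different C terms (two counts each)
    rows = [
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:1"),
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:2"),
        gaf_row("P2", go="GO:0000102", aspect="C", ref="PMID:1"),
        gaf_row("P2", go="GO:0000102", aspect="C", ref="PMID:2"),
        gaf_row("P2", go="GO:0000103", aspect="C", ref="PMID:1"),
        gaf_row("P2", go="GO:0000103", aspect="C", ref="PMID:2"),
    ]
    return parse_gaf("\n".join(rows))


def test_mean_consistency_perfect_agreement():
    recs = parse_gaf("\n".join([
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:1"),
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:2"),
        gaf_row("P2", go="GO:0000102", aspect="C", ref="PMID:1"),
        gaf_row("P2", go="GO:0000102", aspect="C", ref="PMID:2"),
    ]))
    table = mean_consistency(recs, [1, 2])
    assert len(table) == 1
    row = table.iloc[0]
    assert row.mean_cmax == 1.0
    assert row.sd == 0.0
    assert row.n_proteins == 2
    assert row.n_articles == 2


def test_mean_consistency_split_terms_give_half():
    table = mean_consistency(_consistency_corpus(), [1, 2])
    row = table.iloc[0]
    # P1 -> cmax 1.0; P2 -> counts {102:2, 103:2} -> 0.5
    assert row.mean_cmax == pytest.approx(0.75)
    assert row.n_terms == 3


def test_mean_consistency_filters_omit_rows():
    # single shared term fails the min_terms=2 filter
    recs = parse_gaf("\n".join([
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:1"),
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:2"),
    ]))
    assert mean_consistency(recs, [1, 2]).empty
    assert not mean_consistency(recs, [1, 2], min_terms=1).empty
    # proteins seen by a single article never enter
    solo = parse_gaf("\n".join([
        gaf_row("P1", go="GO:0000101", aspect="C", ref="PMID:1"),
        gaf_row("P1", go="GO:0000102", aspect="C", ref="PMID:1"),
    ]))
    assert mean_consistency(solo, [1]).empty


def test_read_fasta_extracts_accession_from_uniprot_header():
    fasta = ">sp|P12345|NAME_HUMAN some protein\nMKVA\n>RAW1\nmwce\n"
    seqs = read_fasta(fasta)
    assert seqs == {"P12345": "MKVA", "RAW1": "MWCE"}


def test_redundancy_summary_counts_entries_with_article_multiplicity():
    # P1 annotated by two articles -> two entries sharing one sequence
    recs = parse_gaf("\n".join([
        gaf_row("P1", ref="PMID:1"),
        gaf_row("P1", ref="PMID:2"),
        gaf_row("P2", ref="PMID:1"),
    ]))
    groups = group_by_article(recs)
    top = top_articles(groups, 2)
    seqs = {"P1": "MAAA", "P2": "MCCC"}
    (summary,) = redundancy_summary(top, seqs)
    assert summary.n_entries == 3
    assert summary.n_clusters == 2
    assert summary.redundancy == 33
    assert summary.mean_multi_cluster_size == 2.0
    assert summary.skipped_accessions == 0


def test_redundancy_summary_tallies_missing_accessions():
    recs = parse_gaf("\n".join([gaf_row("P1"), gaf_row("P2")]))
    top = top_articles(group_by_article(recs), 1)
    (summary,) = redundancy_summary(top, {"P1": "MAAA"})
    assert summary.skipped_accessions == 1
    assert summary.n_entries == 1
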