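"""Term frequency, information content and per-cohort info profiles."""

import math
import random

import pytest

from gobias import (
    cohort_information_profile,
    information_content,
    parse_gaf,
    term_frequency,
)
from test_gaf import gaf_row


def _records(rows):
    return parse_gaf("\n".join(rows))


def test_single_term_corpus_has_frequency_one():
    recs = _records([gaf_row(f"P{i:05d}", go="GO:0000002") for i in range(5)])
    assert term_frequency(recs, "GO:0000002") == 1.0


def test_frequency_is_per_namespace_hand_count():
    # one F-aspect occurrence of GO:0000009 among 8 F-aspect annotations;
    # a C-aspect annotation must not enter the denominator
    rows = [gaf_row(f"P{i:05d}", go="GO:0000002", aspect="F") for i in range(7)]
    rows.append(gaf_row("P00008", go="GO:0000009", aspect="F"))
    rows.append(gaf_row("P00009", go="GO:0000030", aspect="C"))
    recs = _records(rows)
    assert term_frequency(recs, "GO:0000009") == pytest.approx(0.125)
    assert term_frequency(recs, "GO:0000030") == 1.0


def test_frequency_invariant_to_record_order():
    rows = [gaf_row(f"P{i:05d}", go=f"GO:{(i % 3) + 1:07d}") for i in range(9)]
    recs = _records(rows)
    shuffled = recs[:]
    random.Random(0).shuffle(shuffled)
    for term in {r.go_term for r in recs}:
        assert term_frequency(recs, term) == term_frequency(shuffled, term)


def test_unseen_term_raises():
    recs = _records([gaf_row()])
    with pytest.raises(LookupError):
        term_frequency(recs, "GO:0999999")


@pytest.mark.parametrize("freq,bits", [(1.0, 0.0), (0.25, 2.0), (0.125, 3.0)])
def test_information_content_closed_form(freq, bits):
    assert information_content(freq) == pytest.approx(bits)


@pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
def test_information_content_domain(bad):
    with pytest.raises(ValueError):
        information_content(bad)


def test_ic_strictly_decreasing_in_frequency():
    freqs = [0.01, 0.1, 0.5, 0.9, 1.0]
    ics = [information_content(f) for f in freqs]
    assert all(a > b for a, b in zip(ics, ics[1:]))
    assert all(ic >= 0 for ic in ics)


def test_pooled_frequency_between_per_corpus_frequencies():
    a = _records([gaf_row(f"P{i:05d}", go="GO:0000002") for i in range(3)]
                 + [gaf_row("P00010", go="GO:0000003")])
    b = _records([gaf_row(f"Q{i:05d}", go="GO:0000002") for i in range(1)]
                 + [gaf_row(f"Q{i + 1:05d}", go="GO:0000003") for i in range(3)])
    for term in ("GO:0000002", "GO:0000003"):
        fa, fb = term_frequency(a, term), term_frequency(b, term)
        pooled = term_frequency(a + b, term)
        assert min(fa, fb) <= pooled <= max(fa, fb)


def test_profile_single_depth3_term(ontology, ontology_pair):
    _, otruth = ontology_pair
    term = otruth.terms_at("molecular_function", 3)[0]
    recs = _records([gaf_row(f"P{i:05d}", go=term, aspect="F",
                             ref=f"PMID:{100 + i}") for i in range(4)])
    cohort_of = {r.pmid: "SINGLE" for r in recs}
    profile = cohort_information_profile(recs, ontology, cohort_of)
    row = profile.table.query(
        "cohort == 'SINGLE' and namespace == 'molecular_function'")
    depth = row[row.metric == "depth"].iloc[0]
    ic = row[row.metric == "ic"].iloc[0]
    assert depth["mean"] == pytest.approx(3.0)
    assert depth["sd"] == pytest.approx(0.0)
    assert ic["mean"] == pytest.approx(0.0)
    assert depth["n"] == 4


def test_profile_reports_empty_cohorts_with_zero_count(ontology, ontology_pair):
    _, otruth = ontology_pair
    term = otruth.terms_at("biological_process", 2)[0]
    recs = _records([gaf_row("P00001", go=term, aspect="P"),
                     gaf_row("P00002", go=term, aspect="P")])
    cohort_of = {100: "LOW"}
    profile = cohort_information_profile(recs, ontology, cohort_of)
    high = profile.table.query("cohort == 'HIGH'")
    assert (high["n"] == 0).all()
    assert high["mean"].isna().all()


def test_profile_tallies_unresolvable_terms(ontology):
    recs = _records([gaf_row(go="GO:0999999")])
    profile = cohort_information_profile(recs, ontology, {100: "SINGLE"})
    assert profile.skipped_terms == {"GO:0999999": 1}


def test_constructed_depth_bias_orders_cohorts(ontology, ontology_pair):
    # articles built so SINGLE uses depth-5 terms and HIGH depth-1 terms:
    # the aggregate means must preserve the construction ordering
    _, otruth = ontology_pair
    deep = otruth.terms_at("biological_process", 5)
    shallow = otruth.terms_at("biological_process", 1)
    rows, cohort_of = [], {}
    for i in range(20):
        pmid = 500 + i
        rows.append(gaf_row(f"S{i:04d}", go=deep[i % len(deep)], aspect="P",
                            ref=f"PMID:{pmid}"))
        cohort_of[pmid] = "SINGLE"
    for i in range(200):
        pmid = 900
        rows.append(gaf_row(f"H{i:04d}", go=shallow[i % len(shallow)],
                            aspect="P", ref=f"PMID:{pmid}"))
        cohort_of[pmid] = "HIGH"
    profile = cohort_information_profile(_records(rows), ontology, cohort_of)
    t = profile.table.query("namespace == 'biological_process'")

    def mean(cohort, metric):
        return t[(t.cohort == cohort) & (t.metric == metric)].iloc[0]["mean"]

    assert mean("SINGLE", "depth") > mean("HIGH", "depth")
    assert mean("SINGLE", "ic") > mean("HIGH", "ic")
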