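import pytest

from gobias import (
    SyntheticTruth,
    gen_corpus,
    gen_ontology,
    gen_sequences,
    group_by_article,
    parse_gaf,
    parse_obo,
)


@pytest.fixture(scope="session")
def ontology_pair():
    return gen_ontology(seed=11)


@pytest.fixture(scope="session")
def ontology(ontology_pair):
    obo, _ = ontology_pair
    return parse_obo(obo)


@pytest.fixture(scope="session")
def corpus_pair(ontology_pair):
    _, otruth = ontology_pair
    config = SyntheticTruth(n_articles=400, k_max=300, pool_size=1000, seed=7)
    return gen_corpus(config, otruth)


@pytest.fixture(scope="session")
def records(corpus_pair):
    gaf, _ = corpus_pair
    return parse_gaf(gaf)


@pytest.fixture(scope="session")
def groups(records):
    return group_by_article(records)


@pytest.fixture(scope="session")
def synthetic_dir(tmp_path_factory, ontology_pair, corpus_pair):
    """Synthetic OBO + GAF + FASTA written to disk for pipeline runs."""
    obo, _ = ontology_pair
    gaf, truth = corpus_pair
    accessions = sorted({line.split("\t")[1] for line in gaf.splitlines()
                         if line and not line.startswith("!")})
    fasta, _ = gen_sequences(accessions, duplication=0.4, seed=truth.seed)
    root = tmp_path_factory.mktemp("synthetic")
    (root / "corpus.obo").write_text(obo)
    (root / "corpus.gaf").write_text(gaf)
    (root / "corpus.fasta").write_text(fasta)
    return root
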