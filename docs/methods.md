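# Methods

## The question the pipeline answers

Experimental GO annotations enter databases article by article, and articles
differ enormously in throughput: most annotate a single protein, while a
genome-wide screen can annotate thousands in one shot with one assay. Because
one assay can only see one kind of function (a fractionation/MS study sees
subcellular location; an RNAi screen sees developmental phenotypes), a corpus
dominated by a few such studies is biased in which terms, which ontology
aspects and which organisms it covers. `gobias` turns that concern into a set
of reproducible measurements over a GAF corpus.

## Corpus model and filtering

An annotation is a (protein accession, GO term, aspect, evidence code, PMID,
taxon) tuple. Only rows with experimental evidence (EXP, IDA, IPI, IMP, IGI,
IEP) are kept; IEA and other computational codes are out of scope.
NOT-qualified rows assert absence of function and are dropped. A row citing
several PubMed ids yields one record per PMID — each cited study
independently supports the annotation — and the inflation is tallied so it
is auditable. Rows with no PMID-type reference cannot be attributed to an
article; they are excluded from article analyses and counted in a side
tally. Counting units: a "protein annotated by an article" is a distinct
accession (isoform suffixes kept verbatim); an "annotation" is a
(protein, term, article) triple; species identity is the GAF taxon id.

## Ontology structure and term depth

Each GO namespace is a rooted DAG of child→parent edges. The traversed edge
set is `is_a` plus `part_of` by default (the GO convention for
localization-style reasoning); a flag restricts traversal to `is_a`. The
`regulates` family is never traversed because it can cross namespaces. Term
depth is the number of edges on the *shortest* root→term path — root 0, its
direct children 1 — computed by breadth-first search from each root;
depth counts edges, not nodes. Obsolete terms carry no edges and raise on
query; alternate ids resolve silently to their primary id. Cycles among
traversed edges, ambiguous roots and unreachable terms are structural
errors, reported with an offending term.

## Information content

IC(t) = log₂(1/f(t)) bits, where f(t) is the number of direct annotations of
t divided by all annotations in t's namespace. Direct counting (no true-path
propagation up the DAG) is the default because term frequency in the corpus
is itself the quantity of interest — the same corpus whose biases are being
measured — and propagation would mix the structural and usage signals; a
`propagate` flag enables the true-path variant. The log base only rescales,
never reorders; base 2 is used so values read as bits. Depth and IC are
deliberately reported side by side: depth is sensitive to uneven DAG
connectivity, IC is circular in a corpus dominated by few articles, and
agreement between the two is the robust signal.

## Cohorts and the throughput distribution

Cohort bounds are 1 / 2–9 / 10–99 / ≥ 100 proteins per article
(configurable). The proteins-per-article histogram uses observed k only (no
zero bins). Its tail is summarized by ordinary least squares of
log₁₀(article count) on log₁₀(k) with the slope's two-sided t-test — the
plain log-log regression practitioners report, chosen over
maximum-likelihood power-law estimation for comparability. Note this
estimator is biased on sparse histograms: singleton bins at large k
(log count = 0) flatten the slope, so a corpus sampled at exponent α = 2.0
fits around −1.2 at 5 000 articles. The slope-recovery test therefore
calibrates its tolerance from 20 independent replicate draws of the same
sampling procedure rather than assuming the fit is unbiased. Cohort
percentage denominators are the pipeline's own totals; the per-cohort
protein counts are protein–cohort pairs (a protein annotated by articles in
two cohorts counts once in each).

## Top-K dominance and exclusive-HT

Articles are ranked by distinct-protein count, ties broken by ascending
PMID; K defaults to 50. A term's *contribution* is top-set count over corpus
count with both sides restricted to one taxon. A protein is exclusive-HT
when every one of its experimental annotations comes from an article of
throughput ≥ 100 (configurable); only taxa with more than 200 experimentally
annotated proteins are reported — the computable reading of "species with
more than 200 genes", with the threshold configurable.

## Redundancy and consistency

Redundancy clusters the top-set's protein–article entries (so article
multiplicity counts) at 100 % sequence identity — byte-identical residue
strings, no alignment; approximate clustering is a non-goal. Redundancy
percent is round(100·(1 − clusters/entries)), half away from zero. The mean
cluster size is taken over clusters of two or more entries. Accessions
missing from the FASTA go to a skip tally. Repetition — the fraction of
proteins annotated by ≥ 2 articles — is a distinct statistic and is exposed
separately rather than reconciled with redundancy.

Consistency: per protein and namespace, restricted to proteins annotated by
more than one top-set article, C_max = (max term count)/(total count) over
the terms assigned across those articles. Per (taxon, namespace) the table
reports mean, sd (n−1), standard error, and the filter counts; rows with
fewer than 2 articles or 2 distinct terms are omitted (both thresholds
configurable; distinct terms are counted after the >1-article restriction).
Terms are compared as assigned; an optional `prune_ancestors` flag drops an
assigned term when a more specific assigned term of the same protein
subsumes it (default off — identity among assigned terms is the simple,
interpretable measure, and the worked example is unchanged either way).

## Synthetic corpus generator

The generator emulates exactly the structure the statistics assume:

* **Ontology** — each namespace built level by level (default 6 levels,
  40/60/40 terms); a term at level i links only to level i−1, so its true
  minimal depth is its construction level, recorded in the truth ledger.
  Occasional extra parents (same level−1, sometimes `part_of`) create
  multiple root paths without changing the minimum.
* **Articles** — throughputs drawn from the truncated power law
  P(k) ∝ k^(−α), k ≤ k_max (defaults α = 2.0, k_max = 500): the truncation
  mirrors the genome-size ceiling on real throughput. One PMID per article;
  a separate fixture exercises multi-PMID rows.
* **Cohort habits** — aspect mixes default to the observed corpus fractions
  (≈ 24/54/22 F/P/C for single-to-moderate cohorts, 5/38/57 for the high
  cohort); term-depth weights favor deep terms for single/low cohorts and
  shallow ones for the high cohort, and each high-throughput article limits
  itself to a 5-term vocabulary, as single-assay studies do. These defaults
  make the depth/IC cohort ordering a designed property of the data, which
  the tests then verify the pipeline recovers.
* **Proteins and sequences** — accessions drawn from a shared pool (default
  2 000), so articles re-annotate the same proteins; a planted fraction
  (default 0.3) of FASTA sequences duplicate a representative's residue
  string, giving an exactly known cluster partition.

What the generator does *not* emulate: real GO term identifiers or
semantics, curation noise, per-species annotation depth differences,
isoform-specific accession structure, or correlations between a protein's
annotations across articles beyond pool reuse. Passing tests therefore show
the pipeline recovers planted structure faithfully, not that any particular
real corpus exhibits that structure.

## Problem sizes and numerical choices

Tests run the generator at 400–5 000 articles and 50-term oracle DAGs; the
slope-recovery check uses 5 000 articles at α = 2.0 with a tolerance
calibrated from 20 replicate draws, depth is verified against brute-force
all-paths enumeration on 100 random 50-term DAGs, and clustering against the
O(n²) all-pairs oracle at 200 entries. Percentages print to 2 decimals,
redundancy as integer percent, consistency to 3 decimals, exclusive-HT
percentages to 4 — matching the reporting conventions of the tables the
pipeline mirrors. All randomness flows through `numpy.random.default_rng`
seeds; identical seed and configuration give byte-identical artefacts and
reports.

## Known limitations

* The GAF parser targets GAF 2.0/2.1 TSV; GPAD/GPI dialects are out of
  scope.
* Aspect/namespace agreement is taken from the GAF aspect column; records
  whose term is unresolvable in the supplied ontology are tallied and
  skipped in ontology-dependent stages rather than failing the run.
* The log-log slope is a descriptive summary, not an exponent estimate (see
  above); an MLE fit would be a labeled extension.
* Taxon ids are reported as-is; no NCBI name resolution.
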