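# gobias

Audit annotation-throughput biases in Gene Ontology (GO) annotation corpora.

Experimental GO annotations are curated from published articles, and a handful
of high-throughput studies (mass-spectrometry surveys, genome-wide RNAi
screens, localization atlases) each annotate hundreds or thousands of
proteins, while most articles annotate one. `gobias` quantifies what that
skew does to our picture of protein function. Given a GAF 2.x annotation
file, the matching OBO ontology and (optionally) a FASTA of protein
sequences, it reports:

* **Cohorts** — articles binned by throughput *k* (distinct proteins
  annotated): single (*k* = 1), low (2–9), moderate (10–99), high (≥ 100);
  plus the proteins-per-article histogram and an OLS fit of
  log₁₀ *n*(*k*) on log₁₀ *k* summarizing its heavy tail.
* **Information** — per cohort and namespace, the mean minimal edge depth of
  the assigned terms (root = 0) and their information content
  IC(*t*) = log₂ 1/*f*(*t*) in bits, where *f*(*t*) is the term's frequency
  among same-namespace direct annotations.
* **Top-K dominance** — per species: the *contribution* of the top-K
  highest-throughput articles to each term's annotations
  (count in top-K / count in corpus), the top-K's most frequent terms, the
  ontology-aspect mix of each cohort, and the fraction of proteins whose
  every experimental annotation comes from a high-throughput article
  (exclusive-HT, "XHT").
* **Redundancy & consistency** — how often top-K articles re-annotate
  sequence-identical proteins (100 % identity clustering of protein–article
  entries; redundancy = 100·(1 − clusters/entries)), and whether they agree:
  the maximum annotation consistency of a protein in one namespace is
  C\_max = max₉ c₉ / Σ₉ c₉, the most frequent term's share of its annotation
  counts.

Only experimentally evidenced rows (EXP, IDA, IPI, IMP, IGI, IEP) enter the
analysis; NOT-qualified rows are dropped, and rows citing several PubMed ids
count once per citing article.

A synthetic-corpus generator (`gobias.simulate`) produces OBO + GAF + FASTA
triples with known ground truth — power-law article sizes, cohort-biased
term depths and aspect mixes, planted sequence duplication — so the whole
pipeline is testable without the multi-gigabyte real corpus.

## Worked example

Generate a synthetic corpus of 1000 articles and audit it:

```sh
gobias simulate --out sim --n-articles 1000 --seed 7
gobias all --gaf sim/synthetic.gaf --obo sim/synthetic.obo \
           --fasta sim/synthetic.fasta --out report --seed 7
```

`report/cohort_summary.tsv`:

```text
cohort	articles	proteins	percent_articles	percent_proteins
SINGLE	613	539	61.30	18.06
LOW	326	839	32.60	28.11
MODERATE	56	930	5.60	31.16
HIGH	5	677	0.50	22.68
SUM	1000	2985	100.00	100.00
```

Five articles — 0.5 % of the corpus — supply 22.7 % of the protein
annotations: the "few articles, many proteins" skew the audit is built to
expose. `report/powerlaw_fit.tsv` summarizes the histogram's tail
(slope −1.14, r² = 0.74 here; the raw-histogram OLS slope is a biased
estimate of the sampling exponent, see `docs/methods.md`), and
`report/info_profile.tsv` shows single-throughput annotations are deeper and
carry more bits than high-throughput ones (e.g. biological_process mean
depth 3.75 vs 1.39, mean IC 6.03 vs 4.12 in this run). The exclusive-HT
table reports, per taxon, how many proteins are known *only* through
high-throughput work:

```text
taxon	xht	total	percent_xht
6239	233	956	24.3724
559292	107	735	14.5578
9606	124	1093	11.3449
```

Identical inputs, configuration and seed give byte-identical TSVs; each file
starts with a provenance header (tool version, config hash, input
checksums).

As a library:

```python
from gobias import parse_gaf, group_by_article, cohort_summary

records = parse_gaf(open("sim/synthetic.gaf").read())
summary = cohort_summary(group_by_article(records))
print(summary.percent_proteins)  # {'SINGLE': 18.06, 'LOW': 28.11, ...}
```

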