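"""Synthetic OBO + GAF + FASTA corpora with known ground truth.

The generator reproduces the statistical structure the analysis assumes,
so every stage can be exercised and verified offline:

* an ontology per namespace built level by level, so each term's minimal
  depth is its construction level by construction;
* article throughputs drawn from a truncated discrete power law
  P(k) ∝ k^(−α) on k ∈ [1, k_max] — the truncation mirrors the genome-size
  ceiling on real throughput;
* per-cohort annotation habits: high-throughput articles draw shallow
  terms from a small per-article vocabulary and skew toward the cellular
  component aspect, while single/low-throughput articles draw deep terms
  across many vocabularies (the aspect mixtures default to the fractions
  observed in the real corpus: roughly 24/54/22 for low-throughput
  cohorts and 5/38/57 for the high cohort);
* proteins drawn from a shared pool, so articles re-annotate the same
  accessions and repetition statistics are non-trivial;
* sequence duplication planted at the sequence level (distinct accessions
  sharing one residue string), exercising the identity-clustering path.

Each generator returns the artefact text plus a truth ledger; recovery
tests compare pipeline output against the ledger. Identical seed and
configuration give byte-identical artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohorts import assign_cohort
from .errors import ConfigError
from .ontology import NAMESPACES, NAMESPACE_TO_ASPECT

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_EVIDENCE_CYCLE = ("IDA", "IMP", "IPI", "IGI", "IEP", "EXP")

DEFAULT_NAMESPACE_SIZES = {
    "molecular_function": 40,
    "biological_process": 60,
    "cellular_component": 40,
}

#: aspect mixture per cohort (F/P/C), defaulting to the observed corpus mix
DEFAULT_ASPECT_MIX = {
    "SINGLE": {"F": 0.24, "P": 0.54, "C": 0.22},
    "LOW": {"F": 0.24, "P": 0.54, "C": 0.22},
    "MODERATE": {"F": 0.24, "P": 0.54, "C": 0.22},
    "HIGH": {"F": 0.05, "P": 0.38, "C": 0.57},
}

#: term-depth weights per cohort: low-throughput studies report specific
#: (deep) terms, high-throughput assays generic (shallow) ones
DEFAULT_DEPTH_WEIGHTS = {
    "SINGLE": {1: 0.05, 2: 0.10, 3: 0.20, 4: 0.30, 5: 0.35},
    "LOW": {1: 0.05, 2: 0.15, 3: 0.25, 4: 0.30, 5: 0.25},
    "MODERATE": {1: 0.15, 2: 0.25, 3: 0.25, 4: 0.20, 5: 0.15},
    "HIGH": {1: 0.45, 2: 0.35, 3: 0.15, 4: 0.04, 5: 0.01},
}

#: distinct terms a high-throughput article uses (assay reports few terms)
HIGH_COHORT_VOCABULARY = 5

DEFAULT_TAXA = (6239, 9606, 559292)


@dataclass(frozen=True)
class OntologyTruth:
    """Construction ledger for a generated ontology."""

    depth: dict[str, int]
    namespace_of: dict[str, str]
    roots: dict[str, str]

    @property
    def n_terms(self) -> int:
        return len(self.depth)

    def terms_at(self, namespace: str, depth: int) -> list[str]:
        return sorted(t for t, d in self.depth.items()
                      if d == depth and self.namespace_of[t] == namespace)


def gen_ontology(namespace_sizes: Mapping[str, int] | None = None,
                 depth_levels: int = 6,
                 branching: int = 3,
                 seed: int = 0) -> tuple[str, OntologyTruth]:
    """Generate an OBO 1.2 ontology with known minimal depths.

    Every term at level *i* links (``is_a``, occasionally ``part_of``) only
    to terms at level *i − 1*, so its minimal depth is exactly *i*. Extra
    parents within the previous level create multiple root paths without
    changing the minimum. Requires at least one term per level.
    """
    sizes = dict(namespace_sizes or DEFAULT_NAMESPACE_SIZES)
    if depth_levels < 1 or branching < 1:
        raise ConfigError("depth_levels and branching must be >= 1")
    for ns, size in sizes.items():
        if ns not in NAMESPACES:
            raise ConfigError(f"unknown namespace {ns}")
        if size < depth_levels:
            raise ConfigError(
                f"namespace {ns}: {size} terms cannot fill {depth_levels} levels")
    rng = np.random.default_rng(seed)

    stanzas: list[str] = []
    depth: dict[str, int] = {}
    namespace_of: dict[str, str] = {}
    roots: dict[str, str] = {}
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        tid = f"GO:{next_id:07d}"
        next_id += 1
        return tid

    for ns in NAMESPACES:
        if ns not in sizes:
            continue
        size = sizes[ns]
        levels: list[list[str]] = [[] for _ in range(depth_levels)]
        root = new_id()
        levels[0].append(root)
        roots[ns] = root
        # one term per level first, then round-robin the remainder bounded
        # by branching growth
        remaining = size - 1
        level_quota = [0] * depth_levels
        for lvl in range(1, depth_levels):
            if remaining > 0:
                level_quota[lvl] = 1
                remaining -= 1
        lvl = 1
        while remaining > 0:
            cap = max(1, len(levels[0]) * branching ** lvl)
            if level_quota[lvl] < cap:
                level_quota[lvl] += 1
                remaining -= 1
            lvl = lvl + 1 if lvl + 1 < depth_levels else 1

        for tid in levels[0]:
            depth[tid] = 0
            namespace_of[tid] = ns
            stanzas.append(_stanza(tid, f"{ns} root", ns, []))
        for lvl in range(1, depth_levels):
            for _ in range(level_quota[lvl]):
                tid = new_id()
                levels[lvl].append(tid)
                depth[tid] = lvl
                namespace_of[tid] = ns
                parents = [str(rng.choice(levels[lvl - 1]))]
                if len(levels[lvl - 1]) > 1 and rng.random() < 0.3:
                    extra = str(rng.choice(
                        [p for p in levels[lvl - 1] if p != parents[0]]))
                    parents.append(extra)
                rels = ["is_a"] + [
                    "part_of" if rng.random() < 0.25 else "is_a"
                    for _ in parents[1:]]
                stanzas.append(_stanza(
                    tid, f"{ns} term level {lvl}", ns,
                    list(zip(parents, rels))))

    header = "format-version: 1.2\nontology: synthetic-go\n"
    content = header + "\n" + "\n".join(stanzas)
    return content, OntologyTruth(depth=depth, namespace_of=namespace_of,
                                  roots=roots)


def _stanza(tid: str, name: str, ns: str,
            parents: list[tuple[str, str]]) -> str:
    lines = ["[Term]", f"id: {tid}", f"name: {name}", f"namespace: {ns}"]
    for parent, rel in parents:
        if rel == "is_a":
            lines.append(f"is_a: {parent}")
        else:
            lines.append(f"relationship: {rel} {parent}")
    return "\n".join(lines) + "\n"


# -- corpus --------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generator configuration plus the per-article ledger it produced."""

    alpha: float = 2.0
    k_max: int = 500
    n_articles: int = 1000
    pool_size: int = 2000
    taxa: tuple[int, ...] = DEFAULT_TAXA
    aspect_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_ASPECT_MIX.items()})
    depth_weights: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(w) for c, w in DEFAULT_DEPTH_WEIGHTS.items()})
    high_vocabulary: int = HIGH_COHORT_VOCABULARY
    duplication: float = 0.3
    seed: int = 0
    # ledgers, filled by gen_corpus
    article_sizes: dict[int, int] = field(default_factory=dict)
    article_cohorts: dict[int, str] = field(default_factory=dict)
    article_taxa: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ConfigError(f"alpha must exceed 1, got {self.alpha}")
        if self.k_max < 1:
            raise ConfigError("k_max must be >= 1")
        if not 0 <= self.duplication < 1:
            raise ConfigError("duplication must be in [0, 1)")
        if self.pool_size < self.k_max:
            raise ConfigError(
                f"protein pool ({self.pool_size}) smaller than the largest "
                f"possible article ({self.k_max})")


def sample_article_sizes(alpha: float, k_max: int, n_articles: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw throughputs from the truncated power law P(k) ∝ k^(−α)."""
    ks = np.arange(1, k_max + 1, dtype=float)
    pmf = ks ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n_articles, p=pmf)


def gen_corpus(config: SyntheticTruth, ontology_truth: OntologyTruth,
               seed: int | None = None) -> tuple[str, SyntheticTruth]:
    """Generate a GAF 2.0 corpus following *config*; fills its ledgers.

    One PMID per article; each protein in an article receives one
    annotation whose aspect and term depth follow the article cohort's
    profiles. High-cohort articles restrict themselves to a small term
    vocabulary, mirroring single-assay studies.
    """
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    pool = np.array([f"PROT{i:05d}" for i in range(config.pool_size)])
    sizes = sample_article_sizes(config.alpha, config.k_max,
                                 config.n_articles, rng)
    aspect_names = {a: ns for ns, a in NAMESPACE_TO_ASPECT.items()}

    rows: list[str] = []
    config.article_sizes.clear()
    config.article_cohorts.clear()
    config.article_taxa.clear()
    for i, k in enumerate(sizes):
        pmid = 1_000_000 + i
        k = int(k)
        cohort = assign_cohort(k)
        taxon = int(rng.choice(np.asarray(config.taxa)))
        proteins = rng.choice(pool, size=k, replace=False)
        config.article_sizes[pmid] = k
        config.article_cohorts[pmid] = cohort
        config.article_taxa[pmid] = taxon

        mix = config.aspect_mix[cohort]
        weights = config.depth_weights[cohort]
        if cohort == "HIGH" and config.high_vocabulary:
            vocab = [_draw_term(rng, ontology_truth, mix, weights,
                                aspect_names)
                     for _ in range(config.high_vocabulary)]
            terms = [vocab[int(rng.integers(len(vocab)))] for _ in range(k)]
        else:
            terms = [_draw_term(rng, ontology_truth, mix, weights,
                                aspect_names) for _ in range(k)]
        for acc, (term, aspect) in zip(proteins, terms):
            evidence = _EVIDENCE_CYCLE[int(rng.integers(len(_EVIDENCE_CYCLE)))]
            rows.append("\t".join([
                "UniProtKB", acc, acc, "", term, f"PMID:{pmid}", evidence,
                "", aspect, f"{acc} protein", "", "protein",
                f"taxon:{taxon}", "20111201", "SynDB", "", ""]))
    content = "!gaf-version: 2.0\n" + "\n".join(rows) + "\n"
    return content, config


def _draw_term(rng, truth: OntologyTruth, mix: Mapping[str, float],
               weights: Mapping[int, float],
               aspect_names: Mapping[str, str]) -> tuple[str, str]:
    aspects = sorted(mix)
    probs = np.array([mix[a] for a in aspects], dtype=float)
    aspect = aspects[int(rng.choice(len(aspects), p=probs / probs.sum()))]
    ns = aspect_names[aspect]
    depths = sorted(weights)
    dprobs = np.array([weights[d] for d in depths], dtype=float)
    want = depths[int(rng.choice(len(depths), p=dprobs / dprobs.sum()))]
    candidates = truth.terms_at(ns, want)
    while not candidates and want > 0:
        want -= 1  # namespace shallower than the profile: take nearest level
        candidates = truth.terms_at(ns, want)
    if not candidates:
        raise ConfigError(f"namespace {ns} has no terms below the root")
    return str(candidates[int(rng.integers(len(candidates)))]), aspect


# -- sequences -----------------------------------------------------------

def gen_sequences(accessions: Sequence[str], length: int = 60,
                  duplication: float = 0.3, seed: int = 0,
                  ) -> tuple[str, dict[str, str]]:
    """Generate FASTA with a planted fraction of duplicated sequences.

    A fraction *duplication* of accessions copy the residue string of a
    randomly chosen representative; the rest are independent uniform
    strings (collisions negligible at length >= 30). Returns the FASTA
    text and the planted map accession → cluster representative
    (representatives map to themselves).
    """
    if length < 1:
        raise ConfigError("length must be >= 1")
    if not 0 <= duplication < 1:
        raise ConfigError("duplication must be in [0, 1)")
    rng = np.random.default_rng(seed)
    accs = list(accessions)
    n = len(accs)
    n_dup = min(int(round(duplication * n)), max(n - 1, 0))
    dup_idx = set(map(int, rng.choice(n, size=n_dup, replace=False))) if n_dup else set()
    originals = [i for i in range(n) if i not in dup_idx]

    seqs: dict[str, str] = {}
    rep_of: dict[str, str] = {}
    for i in originals:
        seqs[accs[i]] = "".join(rng.choice(_AMINO_ACIDS, size=length))
        rep_of[accs[i]] = accs[i]
    for i in sorted(dup_idx):
        rep = accs[originals[int(rng.integers(len(originals)))]]
        seqs[accs[i]] = seqs[rep]
        rep_of[accs[i]] = rep

    lines = []
    for acc in accs:
        lines.append(f">sp|{acc}|{acc}_SYN synthetic protein")
        lines.append(seqs[acc])
    return "\n".join(lines) + "\n", rep_of
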