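"""End-to-end pipeline: configuration, stage orchestration, TSV emission.

``run_pipeline`` ties the stages together: parse the ontology and the GAF,
bin articles into throughput cohorts, and emit the eight report tables as
TSV files, each with a provenance header (config hash, input checksums,
tool version) so identical inputs and configuration yield byte-identical
outputs. Numeric formatting follows the reporting conventions used
throughout: percentages to 2 decimals, redundancy as an integer percent,
consistency statistics to 3 decimals, exclusive-HT percentages to 4.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .errors import GobiasError
from . import cohorts as _cohorts
from . import consistency as _consistency
from . import gaf as _gaf
from . import information as _information
from . import ontology as _ontology
from . import topk as _topk

log = logging.getLogger("gobias")

STAGES = ("cohorts", "info", "topk", "redundancy", "consistency")

#: stage → report files it owns
STAGE_OUTPUTS = {
    "cohorts": ("cohort_summary.tsv", "histogram.tsv", "powerlaw_fit.tsv"),
    "info": ("info_profile.tsv",),
    "topk": ("contribution.tsv", "exclusive_ht.tsv"),
    "redundancy": ("redundancy.tsv",),
    "consistency": ("consistency.tsv",),
}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for a full audit run."""

    gaf: Path
    obo: Path
    fasta: Path | None = None
    out_dir: Path = Path("gobias-out")
    evidence: tuple[str, ...] = tuple(sorted(_gaf.EXPERIMENTAL_CODES))
    cohort_boundaries: tuple[int, int, int] = _cohorts.DEFAULT_BOUNDARIES
    k: int = 50
    ht_threshold: int = 100
    min_proteins: int = 200
    min_articles: int = 2
    min_terms: int = 2
    ic_base: float = 2.0
    relationships: tuple[str, ...] = _ontology.DEFAULT_RELATIONSHIPS
    top_terms_n: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        # analysis parameters only: file locations are recorded separately
        # as content checksums, so moving files never changes the hash
        payload = {k: str(v) for k, v in asdict(self).items()
                   if k not in ("gaf", "obo", "fasta", "out_dir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StageError(GobiasError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict[str, Path]:
    """Run the requested stages and write their TSV reports.

    Returns a mapping report-name → written path. On a stage failure the
    stage's partial outputs are removed and :class:`StageError` names the
    failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)

    ontology = _ontology.parse_obo(Path(config.obo).read_text(),
                                   relationships=config.relationships)
    stats = _gaf.GafStats()
    records = _gaf.parse_gaf(Path(config.gaf).read_text(),
                             evidence_filter=config.evidence, stats=stats)
    groups = _gaf.group_by_article(records)
    log.info("parsed %d records from %d rows (%d articles); "
             "dropped: %d evidence, %d NOT, %d no-PMID",
             stats.kept_records, stats.rows, len(groups),
             stats.excluded_evidence, stats.excluded_not, stats.no_pmid)
    cohort_of = {pmid: _cohorts.assign_cohort(g.throughput,
                                              config.cohort_boundaries)
                 for pmid, g in groups.items()}
    top = _topk.top_articles(groups, config.k)
    top_pmids = [g.pmid for g in top]

    written: dict[str, Path] = {}

    def emit(name: str, lines: list[str]) -> None:
        path = out / name
        path.write_text(header + "\n".join(lines) + "\n")
        written[name] = path

    for stage in stages:
        try:
            if stage == "cohorts":
                _stage_cohorts(emit, groups, config)
            elif stage == "info":
                _stage_info(emit, records, ontology, cohort_of, config)
            elif stage == "topk":
                _stage_topk(emit, records, groups, top_pmids, config)
            elif stage == "redundancy":
                _stage_redundancy(emit, top, config)
            elif stage == "consistency":
                _stage_consistency(emit, records, top_pmids, config)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            for name in STAGE_OUTPUTS.get(stage, ()):
                (out / name).unlink(missing_ok=True)
                written.pop(name, None)
            raise StageError(stage, exc) from exc
    return written


def _provenance(config: PipelineConfig) -> str:
    lines = [f"! gobias {__version__}",
             f"! config-hash {config.config_hash()}"]
    for label in ("gaf", "obo", "fasta"):
        path = getattr(config, label)
        if path is not None:
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
            lines.append(f"! input {label} sha256:{digest}")
    return "\n".join(lines) + "\n"


def _stage_cohorts(emit, groups, config: PipelineConfig) -> None:
    summary = _cohorts.cohort_summary(groups, config.cohort_boundaries)
    lines = ["cohort\tarticles\tproteins\tpercent_articles\tpercent_proteins"]
    for c in _cohorts.COHORTS:
        lines.append(f"{c}\t{summary.articles[c]}\t{summary.proteins[c]}"
                     f"\t{summary.percent_articles[c]:.2f}"
                     f"\t{summary.percent_proteins[c]:.2f}")
    lines.append(f"SUM\t{summary.total_articles}\t{summary.total_proteins}"
                 f"\t100.00\t100.00")
    emit("cohort_summary.tsv", lines)

    hist = _cohorts.proteins_per_article_histogram(groups)
    emit("histogram.tsv", ["k\tarticles"] +
         [f"{k}\t{v}" for k, v in hist.items()])

    fit = _cohorts.fit_loglog(hist)
    emit("powerlaw_fit.tsv", [
        "slope\tintercept\tr_squared\tp_value\tn_points",
        f"{fit.slope:.6f}\t{fit.intercept:.6f}\t{fit.r_squared:.6f}"
        f"\t{fit.p_value:.3e}\t{fit.n_points}"])


def _stage_info(emit, records, ontology, cohort_of,
                config: PipelineConfig) -> None:
    profile = _information.cohort_information_profile(
        records, ontology, cohort_of, ic_base=config.ic_base)
    lines = ["cohort\tnamespace\tmetric\tmean\tsd\tn"]
    for row in profile.table.itertuples(index=False):
        mean = "" if row.n == 0 else f"{row.mean:.3f}"
        sd = "" if row.n == 0 else f"{row.sd:.3f}"
        lines.append(f"{row.cohort}\t{row.namespace}\t{row.metric}"
                     f"\t{mean}\t{sd}\t{row.n}")
    emit("info_profile.tsv", lines)
    if profile.skipped_terms:
        log.warning("info stage skipped %d annotations with unresolvable terms",
                    sum(profile.skipped_terms.values()))


def _stage_topk(emit, records, groups, top_pmids,
                config: PipelineConfig) -> None:
    taxa = sorted({t for pmid in top_pmids for t in groups[pmid].taxa})
    lines = [f"taxon\tterm\trank\ttopk_count\tcorpus_count\tcontribution"]
    for taxon in taxa:
        terms = _topk.top_terms(records, top_pmids, taxon,
                                n=config.top_terms_n)
        for rank, term in enumerate(terms, start=1):
            contrib = _topk.term_contribution(records, top_pmids, taxon, term)
            lines.append(f"{taxon}\t{term}\t{rank}\t{contrib.topk_count}"
                         f"\t{contrib.corpus_count}"
                         f"\t{contrib.contribution:.4f}")
    emit("contribution.tsv", lines)

    rows = _topk.exclusive_ht_table(records, groups,
                                    ht_threshold=config.ht_threshold,
                                    min_proteins=config.min_proteins)
    emit("exclusive_ht.tsv", ["taxon\txht\ttotal\tpercent_xht"] +
         [f"{r.taxon}\t{r.xht}\t{r.total}\t{r.percent_xht:.4f}" for r in rows])


def _stage_redundancy(emit, top, config: PipelineConfig) -> None:
    if config.fasta is None:
        emit("redundancy.tsv",
             ["taxon\tn_articles\tn_entries\tn_clusters\tredundancy_percent"
              "\tmean_multi_cluster_size\tskipped"])
        return
    sequences = _consistency.read_fasta(Path(config.fasta).read_text())
    lines = ["taxon\tn_articles\tn_entries\tn_clusters\tredundancy_percent"
             "\tmean_multi_cluster_size\tskipped"]
    for row in _consistency.redundancy_summary(top, sequences):
        mean = ("" if row.mean_multi_cluster_size != row.mean_multi_cluster_size
                else f"{row.mean_multi_cluster_size:.2f}")
        lines.append(f"{row.taxon}\t{row.n_articles}\t{row.n_entries}"
                     f"\t{row.n_clusters}\t{row.redundancy}\t{mean}"
                     f"\t{row.skipped_accessions}")
    emit("redundancy.tsv", lines)


def _stage_consistency(emit, records, top_pmids,
                       config: PipelineConfig) -> None:
    table = _consistency.mean_consistency(
        records, top_pmids,
        min_articles=config.min_articles, min_terms=config.min_terms)
    lines = ["taxon\tnamespace\tn_proteins\tmean_cmax\tsd\tstderr"
             "\tn_articles\tn_terms"]
    for row in table.itertuples(index=False):
        lines.append(f"{row.taxon}\t{row.namespace}\t{row.n_proteins}"
                     f"\t{row.mean_cmax:.3f}\t{row.sd:.3f}\t{row.stderr:.3f}"
                     f"\t{row.n_articles}\t{row.n_terms}")
    emit("consistency.tsv", lines)
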