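"""End-to-end orchestration: one config in, a run report and TSVs out.

Stage order: call-dmrs → overlap → region-meth → select-dmes → screen →
annotate → validate (when validation inputs are present).  Execution is
single-process and deterministic: identical config and inputs produce
byte-identical outputs.  Each stage logs one structured line with counts
and wall time; log content is excluded from the determinism guarantee.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import DEFAULT_PROMOTER_BP, classify_location
from .capture_meth import profiles_from_reads, validate_pairs
from .corr_screen import DEFAULT_Q_MAX, DEFAULT_R_MIN, screen_pairs
from .dme_filter import DEFAULT_ALPHA, select_dmes
from .dmr_caller import (
    DEFAULT_DIFF_THRESHOLD,
    DEFAULT_Q_THRESHOLD,
    DEFAULT_WINDOW,
    call_dmrs,
)
from .io_formats import (
    DEFAULT_MIN_COVERAGE,
    GenomicInterval,
    SampleSheet,
    calls_to_frame,
    read_cpg_calls,
    read_gene_models,
    read_intervals,
    read_sample_sheet,
    write_records,
)
from .methlevels import DEFAULT_MIN_CPGS, region_methylation_matrix
from .overlap import dmrs_in_enhancers

__all__ = ["PipelineConfig", "RunReport", "StageOutputs", "run_pipeline", "run_stages"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All paths, thresholds and method switches of one run."""

    sample_sheet: str
    enhancers: str
    enhancer_format: str = "bed"
    genes: str | None = None
    validation_sheet: str | None = None

    window: int = DEFAULT_WINDOW
    diff: float = DEFAULT_DIFF_THRESHOLD
    q_dmr: float = DEFAULT_Q_THRESHOLD
    alpha_dme: float = DEFAULT_ALPHA
    r_min: float = DEFAULT_R_MIN
    q_corr: float = DEFAULT_Q_MAX
    promoter_bp: int = DEFAULT_PROMOTER_BP
    min_coverage: int = DEFAULT_MIN_COVERAGE
    min_cpgs: int = DEFAULT_MIN_CPGS

    qmethod: str = "slim_pi0"
    ttest: str = "welch"
    fdr_family: str = "per-enhancer"
    tss_anchor: str = "nearest_edge"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_coverage < 0 or self.min_cpgs < 0:
            raise ValueError("window/min_coverage/min_cpgs out of range")
        if not (0 <= self.q_dmr <= 1 and 0 <= self.alpha_dme <= 1 and 0 <= self.q_corr <= 1):
            raise ValueError("q/alpha thresholds must lie in [0, 1]")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        if not 0 <= self.diff <= 100:
            raise ValueError("diff threshold is a percent in [0, 100]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def semantic_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage counts of the filter funnel, plus provenance."""

    counts: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__

    def as_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "config_hash": self.config_hash, "version": self.version},
            indent=2,
            sort_keys=True,
        )


@dataclass
class StageOutputs:
    """In-memory results of every stage, for tests and downstream use."""

    dmrs: list
    pairs: list
    matrix: object
    dmes: list
    correlations: list
    annotations: list
    validations: list
    report: RunReport


def _log_stage(name: str, t0: float, **counts) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
                " ".join(f"{k}={v}" for k, v in counts.items()))


def run_stages(
    cohort: Mapping[str, pd.DataFrame],
    sheet: SampleSheet,
    enhancers: Sequence[GenomicInterval],
    config: PipelineConfig,
    genes: Sequence | None = None,
    capture_reads: Mapping[str, pd.DataFrame] | None = None,
    capture_totals: Mapping[str, int] | None = None,
) -> StageOutputs:
    """Run all stages on in-memory inputs; see :func:`run_pipeline` for files."""
    report = RunReport(config_hash=config.semantic_hash())

    t0 = time.time()
    dmrs = call_dmrs(
        cohort, sheet, window=config.window, diff_threshold=config.diff,
        q_threshold=config.q_dmr, qmethod=config.qmethod,
    )
    n_pass = sum(d.passes for d in dmrs)
    report.counts["windows_tested"] = len(dmrs)
    report.counts["dmrs_passing"] = n_pass
    _log_stage("call-dmrs", t0, tested=len(dmrs), passing=n_pass)

    t0 = time.time()
    pairs = dmrs_in_enhancers(dmrs, enhancers)
    candidate_enh = {p.enhancer.key() for p in pairs}
    report.counts["enhancers_with_contained_dmrs"] = len(candidate_enh)
    report.counts["containment_pairs"] = len(pairs)
    _log_stage("overlap", t0, pairs=len(pairs), enhancers=len(candidate_enh))

    t0 = time.time()
    regions = [p.enhancer for p in pairs]
    seen = set()
    regions = [e for e in regions if not (e.key() in seen or seen.add(e.key()))]
    passing_windows = [d.window for d in dmrs if d.passes]
    matrix = region_methylation_matrix(
        regions + passing_windows, cohort, min_cpgs=config.min_cpgs
    )
    _log_stage("region-meth", t0, regions=len(matrix.regions))

    t0 = time.time()
    dmes = select_dmes(pairs, matrix, sheet, alpha=config.alpha_dme, variant=config.ttest)
    n_sel = sum(d.selected for d in dmes)
    report.counts["dmes_selected"] = n_sel
    _log_stage("select-dmes", t0, candidates=len(dmes), selected=n_sel)

    t0 = time.time()
    correlations = screen_pairs(
        dmes, dmrs, matrix, r_min=config.r_min, q_max=config.q_corr,
        fdr_family=config.fdr_family,
    )
    n_cpass = sum(c.passes for c in correlations)
    report.counts["pairs_screened"] = len(correlations)
    report.counts["pairs_passing"] = n_cpass
    _log_stage("screen", t0, screened=len(correlations), passing=n_cpass)

    annotations = []
    if genes:
        t0 = time.time()
        seen_regions: set = set()
        for c in correlations:
            if not c.passes:
                continue
            for region in (c.enhancer, c.partner):
                if region.key() in seen_regions:
                    continue
                seen_regions.add(region.key())
                annotations.append(
                    classify_location(region, genes, promoter_bp=config.promoter_bp)
                )
        report.counts["regions_annotated"] = len(annotations)
        _log_stage("annotate", t0, regions=len(annotations))

    validations = []
    if capture_reads is not None:
        t0 = time.time()
        passing_pairs = [c for c in correlations if c.passes]
        if passing_pairs:
            region_set = []
            seen_v: set = set()
            for c in passing_pairs:
                for region in (c.enhancer, c.partner):
                    if region.key() not in seen_v:
                        seen_v.add(region.key())
                        region_set.append(region)
            profiles = profiles_from_reads(capture_reads, region_set, capture_totals)
            validations = validate_pairs(passing_pairs, profiles)
        report.counts["pairs_validated"] = len(validations)
        _log_stage("validate", t0, validated=len(validations))

    return StageOutputs(dmrs, pairs, matrix, dmes, correlations, annotations,
                        validations, report)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute the pipeline from files per ``config``, writing every
    intermediate TSV plus a JSON run report into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config.sample_sheet).parent

    sheet = read_sample_sheet(config.sample_sheet)
    cohort = {}
    for info in sheet.samples:
        if info.path is None:
            raise ValueError(f"sample {info.sample_id} has no call-file path")
        p = Path(info.path)
        if not p.is_absolute():
            p = base / p
        cohort[info.sample_id] = calls_to_frame(
            read_cpg_calls(p, min_coverage=config.min_coverage)
        )
    enhancers = read_intervals(config.enhancers, format=config.enhancer_format)
    genes = read_gene_models(config.genes) if config.genes else None

    capture_reads = capture_totals = None
    if config.validation_sheet:
        vdf = pd.read_csv(config.validation_sheet, sep="\t")
        vbase = Path(config.validation_sheet).parent
        capture_reads, capture_totals = {}, {}
        for _, row in vdf.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = vbase / p
            ivs = read_intervals(p, format="bed")
            capture_reads[row["sample_id"]] = pd.DataFrame(
                {"chrom": [i.chrom for i in ivs],
                 "start": [i.start for i in ivs],
                 "end": [i.end for i in ivs]}
            )
            capture_totals[row["sample_id"]] = (
                int(row["total_reads"]) if "total_reads" in vdf.columns else len(ivs)
            )

    try:
        out = run_stages(cohort, sheet, enhancers, config, genes=genes,
                         capture_reads=capture_reads, capture_totals=capture_totals)
    except Exception:
        (outdir / "FAILED").write_text("pipeline aborted; partial outputs retained\n")
        raise

    write_records(out.dmrs, outdir / "dmrs.tsv",
                  columns=["chrom", "start", "end", "meth_diff", "p_value", "q_value", "passes"])
    write_records(out.pairs, outdir / "containment_pairs.tsv",
                  columns=["enhancer_chrom", "enhancer_start", "enhancer_end", "enhancer_name",
                           "dmr_chrom", "dmr_start", "dmr_end", "meth_diff", "q_value"])
    out.matrix.to_frame().to_csv(outdir / "region_methylation.tsv", sep="\t",
                                 index=False, float_format="%.6g", na_rep="NA")
    write_records(out.dmes, outdir / "dmes.tsv",
                  columns=["chrom", "start", "end", "name", "mean_group1", "mean_group2",
                           "t_statistic", "p_value", "direction", "selected"])
    corr_cols = ["enhancer_chrom", "enhancer_start", "enhancer_end", "enhancer_name",
                 "partner_chrom", "partner_start", "partner_end", "n", "r",
                 "p_value", "q_value", "strength", "passes"]
    write_records(out.correlations, outdir / "correlations.tsv", columns=corr_cols)
    if out.annotations:
        write_records(out.annotations, outdir / "annotations.tsv")
    if out.validations:
        write_records(out.validations, outdir / "validations.tsv", columns=corr_cols)
    (outdir / "run_report.json").write_text(out.report.as_json() + "\n")
    config.to_yaml(outdir / "config_used.yaml")
    return out.report
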