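"""Capture-seq validation: region methylation as rpkm, re-tested correlations.

Capture (enrichment) cohorts measure methylation as read density rather
than base-level beta-values: a region's level is rpkm — reads overlapping
the region (by >= 1 bp) per kilobase of region per million mapped reads.
Nominated enhancer–partner pairs are then re-tested by Pearson correlation
of rpkm vectors across the validation cohort; no |r| threshold is applied
at this stage, the validation simply reports r, p and the strength label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corr_screen import (
    CorrelationRecord,
    UndefinedCorrelation,
    classify_strength,
    pearson_pvalue,
    pearson_r,
)
from .io_formats import GenomicInterval

__all__ = ["READ_LENGTH", "CaptureProfile", "region_rpkm", "count_overlapping_reads", "validate_pairs"]

READ_LENGTH = 36  # bp, the sequenced read length emulated by the simulator


@dataclass(frozen=True)
class CaptureProfile:
    """One validation sample: total mapped reads and per-region rpkm."""

    sample_id: str
    total_reads: int
    region_rpkm: dict[tuple, float]  # keyed by GenomicInterval.key()

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")

    def rpkm_of(self, region: GenomicInterval) -> float:
        try:
            return self.region_rpkm[region.key()]
        except KeyError:
            raise KeyError(f"region {region} absent from profile {self.sample_id}")


def count_overlapping_reads(
    reads, region: GenomicInterval, min_overlap: int = 1
) -> int:
    """Number of reads overlapping ``region`` by at least ``min_overlap`` bp.

    ``reads`` is either a sequence of GenomicInterval or a DataFrame with
    chrom/start/end columns (1-based inclusive).
    """
    import pandas as pd

    if isinstance(reads, pd.DataFrame):
        sub = reads.loc[reads["chrom"] == region.chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
    else:
        starts = np.array([r.start for r in reads if r.chrom == region.chrom])
        ends = np.array([r.end for r in reads if r.chrom == region.chrom])
    if starts.size == 0:
        return 0
    ov = np.minimum(ends, region.end) - np.maximum(starts, region.start) + 1
    return int((ov >= min_overlap).sum())


def region_rpkm(
    reads: Sequence[GenomicInterval],
    region: GenomicInterval,
    total_reads: int,
    min_overlap: int = 1,
) -> float:
    """rpkm = overlapping reads / (region kb × total mapped reads in millions)."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    c = count_overlapping_reads(reads, region, min_overlap=min_overlap)
    return c / ((region.length / 1000.0) * (total_reads / 1e6))


def profiles_from_reads(
    cohort_reads: Mapping[str, Sequence[GenomicInterval]],
    regions: Sequence[GenomicInterval],
    total_reads: Mapping[str, int] | None = None,
    min_overlap: int = 1,
) -> list[CaptureProfile]:
    """Build per-sample CaptureProfiles for a fixed region set.

    ``total_reads`` defaults to each sample's full read count (the whole
    BED line count, not per-chromosome totals).
    """
    profiles = []
    for sid, reads in cohort_reads.items():
        total = total_reads[sid] if total_reads is not None else len(reads)
        rpkm = {
            reg.key(): region_rpkm(reads, reg, total, min_overlap=min_overlap)
            for reg in regions
        }
        profiles.append(CaptureProfile(sid, total, rpkm))
    return profiles


def validate_pairs(
    pairs: Sequence[CorrelationRecord],
    cohort: Sequence[CaptureProfile],
) -> list[CorrelationRecord]:
    """Re-test nominated pairs on rpkm vectors across the validation cohort.

    Every region of every pair must be present in every profile; needs at
    least three samples.  Returned records carry the validation r, raw
    two-tailed p (q mirrors p: no multiplicity family is claimed here) and
    strength label; ``passes`` is not re-thresholded and is left False.
    """
    if len(cohort) < 3:
        raise ValueError("validation cohort needs >= 3 samples")
    out: list[CorrelationRecord] = []
    for pair in pairs:
        x = np.array([prof.rpkm_of(pair.enhancer) for prof in cohort])
        y = np.array([prof.rpkm_of(pair.partner) for prof in cohort])
        try:
            r = pearson_r(x, y)
        except UndefinedCorrelation:
            r = float("nan")
        if np.isnan(r):
            p = float("nan")
            strength = "undefined"
        else:
            p = pearson_pvalue(r, len(cohort))
            strength = classify_strength(r)
        out.append(
            CorrelationRecord(
                enhancer=pair.enhancer,
                partner=pair.partner,
                n=len(cohort),
                r=r,
                p_value=p,
                q_value=p,
                strength=strength,
                passes=False,
            )
        )
    return out
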