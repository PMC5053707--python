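"""Per-CpG beta-values, region-level methylation and coverage QC.

A CpG's beta-value is its methylated-read count divided by total coverage.
Region methylation is the *unweighted* mean of the beta-values of the CpGs
falling inside the region (1-based inclusive bounds): the per-CpG values,
not the pooled counts, are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CpGRecord, GenomicInterval, calls_to_frame

__all__ = [
    "DEFAULT_MIN_CPGS",
    "cpg_beta",
    "region_methylation",
    "coverage_histogram",
    "RegionMethylationMatrix",
    "region_methylation_matrix",
    "plot_coverage_histograms",
]

DEFAULT_MIN_CPGS = 3


def cpg_beta(n_meth: int, n_total: int) -> float:
    """Beta-value of one CpG: methylated count over total coverage."""
    if n_total < 1:
        raise ValueError("beta-value undefined at zero coverage")
    if not 0 <= n_meth <= n_total:
        raise ValueError(f"n_meth {n_meth} outside [0, {n_total}]")
    return n_meth / n_total


def region_methylation(
    region: GenomicInterval,
    calls: Sequence[CpGRecord] | pd.DataFrame,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> float:
    """Unweighted mean beta-value over CpGs inside ``region``.

    CpGs at region.start and region.end are inside (inclusive bounds).
    Returns NaN (missing) when fewer than ``min_cpgs`` CpGs contribute.
    """
    df = calls_to_frame(calls)
    mask = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] <= region.end)
    )
    sub = df.loc[mask]
    if len(sub) < min_cpgs:
        return float("nan")
    return float((sub["n_meth"] / sub["n_total"]).mean())


def coverage_histogram(
    calls: Sequence[CpGRecord] | pd.DataFrame, max_bin: int = 100
) -> np.ndarray:
    """Histogram of per-CpG total coverage.

    Bins are the integer coverages 0..max_bin; the last bin is open-ended
    (coverage >= max_bin).  The counts sum to the number of records, which
    makes the histogram a conservation check as well as a PCR-duplication
    QC plot (duplication bias shows as a secondary right-hand peak).
    """
    df = calls_to_frame(calls)
    counts = np.zeros(max_bin + 1, dtype=int)
    if len(df) == 0:
        return counts
    cov = np.minimum(df["n_total"].to_numpy(), max_bin)
    np.add.at(counts, cov, 1)
    return counts


@dataclass(frozen=True)
class RegionMethylationMatrix:
    """Region × sample methylation levels with per-cell CpG counts.

    ``values[i, j]`` is the mean beta-value of region i in sample j, NaN
    where fewer than ``min_cpgs`` CpGs had calls; ``n_cpgs[i, j]`` is the
    number of CpGs that contributed.
    """

    regions: tuple[GenomicInterval, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    n_cpgs: np.ndarray
    min_cpgs: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("values shape does not match regions × samples")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation values must lie in [0, 1]")

    def row(self, region: GenomicInterval) -> np.ndarray:
        """Per-sample values for a region, matched on (chrom, start, end)."""
        for i, r in enumerate(self.regions):
            if r.key() == region.key():
                return self.values[i]
        raise KeyError(f"region {region} not in matrix")

    def __contains__(self, region: GenomicInterval) -> bool:
        return any(r.key() == region.key() for r in self.regions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.samples))
        df.insert(0, "chrom", [r.chrom for r in self.regions])
        df.insert(1, "start", [r.start for r in self.regions])
        df.insert(2, "end", [r.end for r in self.regions])
        df.insert(3, "name", [r.name for r in self.regions])
        return df


def region_methylation_matrix(
    regions: Sequence[GenomicInterval],
    cohort: Mapping[str, Sequence[CpGRecord] | pd.DataFrame],
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> RegionMethylationMatrix:
    """Compute the region × sample methylation matrix for a cohort.

    ``cohort`` maps sample id → CpG calls.  Uses sorted positions per
    chromosome for O(log n) region lookups.
    """
    samples = tuple(cohort.keys())
    values = np.full((len(regions), len(samples)), np.nan)
    n_cpgs = np.zeros((len(regions), len(samples)), dtype=int)
    for j, sid in enumerate(samples):
        df = calls_to_frame(cohort[sid])
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            pos = sub["pos"].to_numpy()
            beta = (sub["n_meth"] / sub["n_total"]).to_numpy()
            for i, region in enumerate(regions):
                if region.chrom != chrom:
                    continue
                lo = np.searchsorted(pos, region.start, side="left")
                hi = np.searchsorted(pos, region.end, side="right")
                n = hi - lo
                n_cpgs[i, j] = n
                if n >= min_cpgs:
                    values[i, j] = beta[lo:hi].mean()
    return RegionMethylationMatrix(tuple(regions), samples, values, n_cpgs, min_cpgs)


def plot_coverage_histograms(
    cohort: Mapping[str, Sequence[CpGRecord] | pd.DataFrame],
    path: str,
    max_bin: int = 100,
) -> None:
    """Per-sample coverage-per-base histograms on one figure (QC plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(cohort)
    ncols = min(4, max(n, 1))
    nrows = -(-n // ncols) if n else 1
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, (sid, calls) in zip(axes.flat, cohort.items()):
        ax.set_visible(True)
        counts = coverage_histogram(calls, max_bin=max_bin)
        ax.bar(np.arange(len(counts)), counts, width=1.0, color="steelblue")
        ax.set_title(sid, fontsize=8)
        ax.set_xlabel("coverage per base", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
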