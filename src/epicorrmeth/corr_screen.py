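"""Intrachromosomal enhancer–DMR methylation-correlation screen.

Each selected DME is paired with every passing DMR on its chromosome
(excluding DMRs contained in the enhancer itself, which would correlate
trivially); per pair the sample Pearson r and its two-tailed p-value are
computed across samples, p-values are BH-adjusted within each enhancer's
candidate family (a pooled family is available), and pairs pass at
|r| >= 0.85 with q <= 0.05.

Correlation strength is labelled on the conventional scale: |r| >= 0.5 is
"good to excellent", below that "moderate to nil".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dme_filter import DmeRecord
from .dmr_caller import DmrRecord
from .io_formats import GenomicInterval, interval_sort_key
from .methlevels import RegionMethylationMatrix
from .overlap import contains

__all__ = [
    "DEFAULT_R_MIN",
    "DEFAULT_Q_MAX",
    "CorrelationRecord",
    "UndefinedCorrelation",
    "pearson_r",
    "pearson_pvalue",
    "classify_strength",
    "screen_pairs",
]

DEFAULT_R_MIN = 0.85
DEFAULT_Q_MAX = 0.05


class UndefinedCorrelation(ValueError):
    """Raised when a vector has zero variance or too few complete pairs."""


@dataclass(frozen=True)
class CorrelationRecord:
    enhancer: GenomicInterval
    partner: GenomicInterval
    n: int
    r: float
    p_value: float
    q_value: float
    strength: str
    passes: bool

    def as_row(self) -> dict:
        return {
            "enhancer_chrom": self.enhancer.chrom,
            "enhancer_start": self.enhancer.start,
            "enhancer_end": self.enhancer.end,
            "enhancer_name": self.enhancer.name,
            "partner_chrom": self.partner.chrom,
            "partner_start": self.partner.start,
            "partner_end": self.partner.end,
            "n": self.n,
            "r": self.r,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "strength": self.strength,
            "passes": self.passes,
        }


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation on pairwise-complete values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise UndefinedCorrelation(f"need >= 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("zero variance in one vector")
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson coefficient.

    t = r·sqrt(n−2)/sqrt(1−r²) referred to Student's t with n−2 df;
    |r| = 1 gives p = 0 exactly.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def classify_strength(r: float) -> str:
    """|r| >= 0.5 → "good to excellent"; otherwise "moderate to nil"."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return "good to excellent" if abs(r) >= 0.5 else "moderate to nil"


def screen_pairs(
    dmes: Sequence[DmeRecord],
    dmrs: Sequence[DmrRecord],
    matrix: RegionMethylationMatrix,
    r_min: float = DEFAULT_R_MIN,
    q_max: float = DEFAULT_Q_MAX,
    fdr_family: str = "per-enhancer",
) -> list[CorrelationRecord]:
    """Correlation screen over all (selected DME, passing DMR) candidate pairs.

    Candidates are restricted to the enhancer's chromosome and exclude DMRs
    contained in the enhancer.  Pairs with undefined correlation (constant
    vector, < 3 complete samples) are skipped.  BH adjustment runs within
    each enhancer's candidate family by default (``fdr_family='pooled'``
    adjusts across all enhancers jointly).  A pair passes when |r| >= r_min
    and q <= q_max and n >= 3.  Output is sorted by q then |r| descending.
    """
    if fdr_family not in ("per-enhancer", "pooled"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    selected = [d for d in dmes if d.selected]
    passing = [d for d in dmrs if d.passes]
    raw: list[tuple[DmeRecord, DmrRecord, int, float, float]] = []
    for dme in selected:
        evals = matrix.row(dme.enhancer)
        for dmr in passing:
            if dmr.window.chrom != dme.enhancer.chrom:
                continue
            if contains(dme.enhancer, dmr.window):
                continue
            pvals = matrix.row(dmr.window)
            mask = np.isfinite(evals) & np.isfinite(pvals)
            try:
                r = pearson_r(evals, pvals)
            except UndefinedCorrelation:
                continue
            n = int(mask.sum())
            raw.append((dme, dmr, n, r, pearson_pvalue(r, n)))

    if not raw:
        return []
    q = np.full(len(raw), np.nan)
    if fdr_family == "pooled":
        q[:] = multipletests([t[4] for t in raw], method="fdr_bh")[1]
    else:
        by_enh: dict[tuple, list[int]] = {}
        for i, (dme, *_rest) in enumerate(raw):
            by_enh.setdefault(dme.enhancer.key(), []).append(i)
        for idxs in by_enh.values():
            q[idxs] = multipletests([raw[i][4] for i in idxs], method="fdr_bh")[1]

    records = [
        CorrelationRecord(
            enhancer=dme.enhancer,
            partner=dmr.window,
            n=n,
            r=r,
            p_value=p,
            q_value=float(qv),
            strength=classify_strength(r),
            passes=bool(abs(r) >= r_min and qv <= q_max and n >= 3),
        )
        for (dme, dmr, n, r, p), qv in zip(raw, q)
    ]
    records.sort(key=lambda c: (c.q_value, -abs(c.r),
                                interval_sort_key(c.enhancer), interval_sort_key(c.partner)))
    return records
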