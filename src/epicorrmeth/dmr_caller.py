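"""Windowed differential-methylation calling between two groups.

The genome is tiled into fixed 1000-bp windows; per window, per-sample
methylated/total counts are aggregated over the CpGs inside it and a
binomial logistic regression of methylated proportion on a group indicator
(observations weighted by total coverage) is tested against the
intercept-only model by a 1-df likelihood-ratio chi-square.  Windows pass
when the pooled percent methylation difference exceeds the effect threshold
(default >50%) and the FDR-adjusted q-value is below the cut (default
<0.01).

q-values come either from plain Benjamini–Hochberg (``bh``) or from a
π0-weighted BH (``slim_pi0``) in which the null proportion π0 is estimated
from the upper tail of the p-value distribution, in the spirit of
sliding-linear-model q-value estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CpGRecord, GenomicInterval, SampleSheet, calls_to_frame

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_DIFF_THRESHOLD",
    "DEFAULT_Q_THRESHOLD",
    "DmrRecord",
    "UntestableWindow",
    "tile_windows",
    "aggregate_window_counts",
    "test_window",
    "estimate_pi0",
    "adjust_qvalues",
    "call_dmrs",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_DIFF_THRESHOLD = 50.0
DEFAULT_Q_THRESHOLD = 0.01


class UntestableWindow(ValueError):
    """Raised when a window has zero total coverage in at least one group."""


@dataclass(frozen=True)
class DmrRecord:
    """One tested window with its effect size, p/q-values and pass flag.

    ``meth_diff`` is the pooled percent difference, group1 − group2, where
    pooled means sum(n_meth)/sum(n_total) over the group's samples.
    """

    window: GenomicInterval
    meth_diff: float
    p_value: float
    q_value: float
    per_sample_counts: tuple[tuple[int, int], ...]
    passes: bool

    def as_row(self) -> dict:
        return {
            "chrom": self.window.chrom,
            "start": self.window.start,
            "end": self.window.end,
            "meth_diff": self.meth_diff,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "passes": self.passes,
        }


def tile_windows(
    chrom: str, chrom_length: int, window: int = DEFAULT_WINDOW
) -> list[GenomicInterval]:
    """Non-overlapping tiles [k·w+1, (k+1)·w], last tile truncated.

    The tiles partition 1..chrom_length: every position falls in exactly
    one tile.
    """
    if window < 1:
        raise ValueError(f"window size must be >= 1, got {window}")
    if chrom_length < 1:
        raise ValueError(f"chromosome length must be >= 1, got {chrom_length}")
    tiles = []
    start = 1
    while start <= chrom_length:
        end = min(start + window - 1, chrom_length)
        tiles.append(GenomicInterval(chrom, start, end))
        start = end + 1
    return tiles


def aggregate_window_counts(
    window: GenomicInterval,
    cohort: Mapping[str, Sequence[CpGRecord] | pd.DataFrame],
) -> dict[str, tuple[int, int]]:
    """Per-sample (n_meth, n_total) sums over CpGs inside ``window`` (inclusive)."""
    out: dict[str, tuple[int, int]] = {}
    for sid, calls in cohort.items():
        df = calls_to_frame(calls)
        mask = (
            (df["chrom"] == window.chrom)
            & (df["pos"] >= window.start)
            & (df["pos"] <= window.end)
        )
        sub = df.loc[mask]
        out[sid] = (int(sub["n_meth"].sum()), int(sub["n_total"].sum()))
    return out


def _pooled_props(counts: np.ndarray, g1_mask: np.ndarray) -> tuple[float, float]:
    m1, t1 = counts[g1_mask, 0].sum(), counts[g1_mask, 1].sum()
    m2, t2 = counts[~g1_mask, 0].sum(), counts[~g1_mask, 1].sum()
    return m1 / t1, m2 / t2


def test_window(
    counts: Sequence[tuple[int, int]],
    groups: Sequence[str],
) -> tuple[float, float]:
    """Binomial logistic-regression LRT of one window.

    ``counts`` holds per-sample (n_meth, n_total); ``groups`` the matching
    group labels (exactly two distinct).  The full model regresses the
    methylated proportion on an intercept plus group indicator with
    binomial (success, failure) outcomes — so each observation is weighted
    by its total coverage — and is compared with the intercept-only model
    by a likelihood-ratio chi-square with 1 df.

    Returns ``(meth_diff, p_value)`` with meth_diff in percent (group1 −
    group2, pooled counts).  Group order follows first appearance in
    ``groups``.  Raises :class:`UntestableWindow` when a group has zero
    total coverage.
    """
    counts = np.asarray(counts, dtype=float)
    groups = list(groups)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] != len(groups):
        raise ValueError("counts must be (n_samples, 2) matching groups")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    g1_mask = np.array([g == labels[0] for g in groups])
    if counts[g1_mask, 1].sum() == 0 or counts[~g1_mask, 1].sum() == 0:
        raise UntestableWindow("a group has zero total coverage in this window")

    p1, p2 = _pooled_props(counts, g1_mask)
    meth_diff = 100.0 * (p1 - p2)

    pooled = counts[:, 0].sum() / counts[:, 1].sum()
    if pooled in (0.0, 1.0):
        # all observations at the same boundary: the group model cannot
        # improve on the intercept-only fit
        return meth_diff, 1.0

    keep = counts[:, 1] > 0
    endog = np.column_stack([counts[keep, 0], counts[keep, 1] - counts[keep, 0]])
    exog_full = sm.add_constant(g1_mask[keep].astype(float), has_constant="add")
    exog_null = np.ones((keep.sum(), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(endog, exog_full, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, exog_null, family=sm.families.Binomial()).fit()
        lrt = 2.0 * (full.llf - null.llf)
    except Exception:  # IRLS failure at extreme separation: exact deviance fallback
        lrt = _pooled_g_statistic(counts, g1_mask)
    lrt = max(lrt, 0.0)
    p_value = float(stats.chi2.sf(lrt, df=1))
    return float(meth_diff), p_value


def _pooled_g_statistic(counts: np.ndarray, g1_mask: np.ndarray) -> float:
    """2·Σ obs·ln(obs/exp) on the pooled 2×2 table (boundary-safe)."""
    m1, t1 = counts[g1_mask, 0].sum(), counts[g1_mask, 1].sum()
    m2, t2 = counts[~g1_mask, 0].sum(), counts[~g1_mask, 1].sum()
    obs = np.array([[m1, t1 - m1], [m2, t2 - m2]], dtype=float)
    pooled = (m1 + m2) / (t1 + t2)
    exp = np.array([[t1 * pooled, t1 * (1 - pooled)], [t2 * pooled, t2 * (1 - pooled)]])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion π0 from the upper p-value distribution.

    For each λ on a 0.1…0.9 grid, π0(λ) = #{p > λ} / (n·(1−λ)).  The grid
    point where the finite-difference slope of π0(λ) is smallest in
    magnitude marks the plateau of the estimate; π0 is the mean of π0(λ)
    from that point on, clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.1, 0.95, 0.1)
    n = len(p)
    if n == 0:
        return 1.0
    pi0_lam = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in lambdas])
    if len(lambdas) < 2:
        est = pi0_lam[-1]
    else:
        slopes = np.abs(np.diff(pi0_lam) / np.diff(lambdas))
        k = int(np.argmin(slopes))
        est = float(pi0_lam[k:].mean())
    return float(np.clip(est, 1.0 / n, 1.0))


def adjust_qvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values.

    ``bh``: Benjamini–Hochberg step-up with monotonicity enforcement.
    ``slim_pi0``: π0-weighted BH — q = π0 × BH q, with π0 estimated by
    :func:`estimate_pi0`; q ≤ BH q always when π0 ≤ 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "slim_pi0"):
        raise ValueError(f"unknown q-value method {method!r}")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "slim_pi0":
        q = np.clip(estimate_pi0(p) * q, 0.0, 1.0)
    return q


def call_dmrs(
    cohort: Mapping[str, Sequence[CpGRecord] | pd.DataFrame],
    sheet: SampleSheet,
    window: int = DEFAULT_WINDOW,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    qmethod: str = "slim_pi0",
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[DmrRecord]:
    """Tile, aggregate, test, adjust and filter all windows of a cohort.

    Both passing and non-passing records are retained (``passes`` flags the
    windows with |meth_diff| > diff_threshold and q < q_threshold), sorted
    by (chrom, start).  Windows without CpG coverage in both groups are
    skipped and logged, not assigned p = 1.  Chromosome lengths default to
    the largest observed CpG position per chromosome.
    """
    if not cohort or all(len(calls_to_frame(c)) == 0 for c in cohort.values()):
        raise ValueError("empty cohort")
    sample_ids = list(sheet.sample_ids)
    missing = [s for s in sample_ids if s not in cohort]
    if missing:
        raise ValueError(f"samples missing from cohort: {missing}")
    groups = [sheet.group_of(s) for s in sample_ids]
    labels = sheet.group_labels
    g1_mask = np.array([g == labels[0] for g in groups])

    frames = {s: calls_to_frame(cohort[s]) for s in sample_ids}
    chroms = sorted({c for df in frames.values() for c in df["chrom"].unique()})
    if chrom_lengths is None:
        chrom_lengths = {
            c: max(int(df.loc[df["chrom"] == c, "pos"].max())
                   for df in frames.values()
                   if (df["chrom"] == c).any())
            for c in chroms
        }

    tested: list[tuple[GenomicInterval, float, float, tuple[tuple[int, int], ...]]] = []
    n_skipped = 0
    for chrom in chroms:
        n_tiles = -(-chrom_lengths[chrom] // window)
        meth = np.zeros((len(sample_ids), n_tiles), dtype=np.int64)
        total = np.zeros((len(sample_ids), n_tiles), dtype=np.int64)
        for i, sid in enumerate(sample_ids):
            df = frames[sid]
            sub = df.loc[df["chrom"] == chrom]
            if len(sub) == 0:
                continue
            idx = (sub["pos"].to_numpy() - 1) // window
            idx = np.clip(idx, 0, n_tiles - 1)
            meth[i] = np.bincount(idx, weights=sub["n_meth"].to_numpy(),
                                  minlength=n_tiles).astype(np.int64)
            total[i] = np.bincount(idx, weights=sub["n_total"].to_numpy(),
                                   minlength=n_tiles).astype(np.int64)
        any_cov = total.sum(axis=0) > 0
        for k in np.nonzero(any_cov)[0]:
            win = GenomicInterval(
                chrom, int(k) * window + 1,
                min((int(k) + 1) * window, chrom_lengths[chrom]),
            )
            counts = tuple(zip(meth[:, k].tolist(), total[:, k].tolist()))
            try:
                meth_diff, p = test_window(counts, groups)
            except UntestableWindow:
                n_skipped += 1
                continue
            tested.append((win, meth_diff, p, counts))
    if n_skipped:
        logger.info("skipped %d windows with zero coverage in one group", n_skipped)

    if not tested:
        return []
    q = adjust_qvalues([t[2] for t in tested], method=qmethod)
    records = [
        DmrRecord(
            window=win,
            meth_diff=meth_diff,
            p_value=p,
            q_value=float(qv),
            per_sample_counts=counts,
            passes=bool(abs(meth_diff) > diff_threshold and qv < q_threshold),
        )
        for (win, meth_diff, p, counts), qv in zip(tested, q)
    ]
    records.sort(key=lambda r: (r.window.chrom, r.window.start))
    return records
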