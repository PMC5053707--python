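"""Interval containment between called DMRs and an enhancer catalog.

The pairing criterion is full containment ("completely within"): a DMR
window pairs with an enhancer only when the enhancer spans it entirely on
the same chromosome.  An ``any``-overlap escape hatch exists but is off by
default.  One DMR may sit in several overlapping enhancers; all pairs are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .dmr_caller import DmrRecord
from .io_formats import GenomicInterval, interval_sort_key

__all__ = ["ContainmentPair", "contains", "overlaps", "dmrs_in_enhancers"]


@dataclass(frozen=True)
class ContainmentPair:
    enhancer: GenomicInterval
    dmr: DmrRecord

    def as_row(self) -> dict:
        return {
            "enhancer_chrom": self.enhancer.chrom,
            "enhancer_start": self.enhancer.start,
            "enhancer_end": self.enhancer.end,
            "enhancer_name": self.enhancer.name,
            "dmr_chrom": self.dmr.window.chrom,
            "dmr_start": self.dmr.window.start,
            "dmr_end": self.dmr.window.end,
            "meth_diff": self.dmr.meth_diff,
            "q_value": self.dmr.q_value,
        }


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies completely within ``outer`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base."""
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def dmrs_in_enhancers(
    dmrs: Sequence[DmrRecord],
    enhancers: Sequence[GenomicInterval],
    mode: str = "within",
) -> list[ContainmentPair]:
    """All (enhancer, passing DMR) containment pairs.

    Only DMRs with ``passes`` set enter the comparison.  Implemented with a
    per-chromosome interval index; equivalent to the brute-force all-pairs
    check.  Output order is (enhancer, dmr) coordinate-sorted and
    independent of input order.
    """
    if mode not in ("within", "any"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for enh in enhancers:
        # interval tree is half-open: store [start, end+1)
        trees.setdefault(enh.chrom, IntervalTree()).addi(enh.start, enh.end + 1, enh)
    pairs: list[ContainmentPair] = []
    for dmr in dmrs:
        if not dmr.passes:
            continue
        tree = trees.get(dmr.window.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(dmr.window.start, dmr.window.end + 1):
            enh = hit.data
            if mode == "any" or contains(enh, dmr.window):
                pairs.append(ContainmentPair(enh, dmr))
    pairs.sort(key=lambda p: (interval_sort_key(p.enhancer), interval_sort_key(p.dmr.window)))
    return pairs
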