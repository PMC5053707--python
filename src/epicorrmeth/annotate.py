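"""Region annotation against gene models.

Regions are classified with priority promoter > gene body > intergenic.
The promoter is the fixed stretch (default 1500 bp) immediately upstream of
the TSS in gene orientation; gene-body hits report the exons/introns
overlapped, numbered in transcription order (exon 1 nearest the TSS);
intergenic regions report the nearest gene, the boundary gap and whether
the region lies upstream or downstream of that gene.

Because published enhancer–gene distance columns mix anchor conventions
(sometimes the region's start, sometimes its end), TSS distance takes an
explicit anchor argument and the pipeline reports all three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import GeneModel, GenomicInterval
from .overlap import overlaps

__all__ = [
    "DEFAULT_PROMOTER_BP",
    "AnnotationRecord",
    "promoter_of",
    "gene_gap_distance",
    "tss_distance",
    "classify_location",
]

DEFAULT_PROMOTER_BP = 1500

TSS_ANCHORS = ("region_start", "region_end", "nearest_edge")


@dataclass(frozen=True)
class AnnotationRecord:
    region: GenomicInterval
    category: str  # promoter | gene_body | intergenic
    gene: GeneModel | None
    sub_features: tuple[str, ...] = ()
    gap_bp: int | None = None
    relative_position: str | None = None  # upstream | downstream
    tss_distances: dict | None = None

    def as_row(self) -> dict:
        return {
            "chrom": self.region.chrom,
            "start": self.region.start,
            "end": self.region.end,
            "name": self.region.name,
            "category": self.category,
            "gene_symbol": self.gene.symbol if self.gene else None,
            "gene_accession": self.gene.accession if self.gene else None,
            "sub_features": ";".join(self.sub_features) if self.sub_features else None,
            "gap_bp": self.gap_bp,
            "relative_position": self.relative_position,
            "tss_dist_region_start": (self.tss_distances or {}).get("region_start"),
            "tss_dist_region_end": (self.tss_distances or {}).get("region_end"),
            "tss_dist_nearest_edge": (self.tss_distances or {}).get("nearest_edge"),
        }


def promoter_of(gene: GeneModel, length: int = DEFAULT_PROMOTER_BP) -> GenomicInterval:
    """The ``length`` bp immediately upstream of the TSS in gene orientation.

    + strand: [TSS−length, TSS−1]; − strand: [TSS+1, TSS+length]; clipped
    at position 1.  Never overlaps the gene body on the TSS side.
    """
    if gene.strand == "+":
        start = max(1, gene.tss - length)
        end = gene.tss - 1
        if end < start:  # TSS at the very chromosome start
            end = start
    else:
        start = gene.tss + 1
        end = gene.tss + length
    return GenomicInterval(gene.chrom, start, end,
                           name=f"promoter:{gene.symbol}", strand=gene.strand)


def gene_gap_distance(region: GenomicInterval, gene: GeneModel) -> tuple[int, str]:
    """Boundary gap and orientation-aware position of a non-overlapping region.

    1-based inclusive arithmetic: a region starting at ``tx_end + 1`` is
    1 bp downstream of a + strand gene.  Downstream/upstream follows the
    gene's transcription direction.
    """
    if region.chrom != gene.chrom:
        raise ValueError("region and gene must share a chromosome")
    if overlaps(region, gene.span):
        raise ValueError("region overlaps the gene; gap distance undefined")
    if region.start > gene.tx_end:  # region to the right of the gene
        gap = region.start - gene.tx_end
        position = "downstream" if gene.strand == "+" else "upstream"
    else:  # region to the left
        gap = gene.tx_start - region.end
        position = "upstream" if gene.strand == "+" else "downstream"
    return gap, position


def tss_distance(region: GenomicInterval, gene: GeneModel, anchor: str = "nearest_edge") -> int:
    """|TSS − anchor position| with the TSS per strand rule.

    ``region_start``/``region_end`` anchor on the region's boundaries;
    ``nearest_edge`` uses whichever boundary is closer to the TSS.
    """
    if region.chrom != gene.chrom:
        raise ValueError("region and gene must share a chromosome")
    if anchor not in TSS_ANCHORS:
        raise ValueError(f"unknown TSS anchor {anchor!r}")
    tss = gene.tss
    if anchor == "region_start":
        return abs(tss - region.start)
    if anchor == "region_end":
        return abs(tss - region.end)
    return min(abs(tss - region.start), abs(tss - region.end))


def _exon_labels(gene: GeneModel, region: GenomicInterval) -> tuple[str, ...]:
    """Exon/intron labels overlapped by region, numbered in transcription order."""
    if not gene.exons:
        return ()
    n = len(gene.exons)
    features: list[tuple[int, str, GenomicInterval]] = []  # (transcription rank, label, span)
    for i, ex in enumerate(gene.exons):  # genomic order
        k = i + 1 if gene.strand == "+" else n - i
        features.append((2 * k - 1, f"exon {k}", ex))
    for i in range(n - 1):
        left, right = gene.exons[i], gene.exons[i + 1]
        if right.start - left.end < 2:
            continue
        intron = GenomicInterval(gene.chrom, left.end + 1, right.start - 1)
        k = i + 1 if gene.strand == "+" else n - i - 1  # intron k follows exon k
        features.append((2 * k, f"intron {k}", intron))
    hits = [(rank, label) for rank, label, span in features if overlaps(region, span)]
    hits.sort()
    return tuple(label for _, label in hits)


def classify_location(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> AnnotationRecord:
    """Classify a region as promoter, gene body, or intergenic.

    Ties for nearest gene break on the smaller accession string.  When no
    gene shares the region's chromosome, the record is intergenic with no
    gene and an undefined gap.
    """
    same_chrom = sorted(
        (g for g in genes if g.chrom == region.chrom),
        key=lambda g: (g.tx_start, g.tx_end, g.accession),
    )
    if not same_chrom:
        return AnnotationRecord(region, "intergenic", None)

    def tss_map(gene: GeneModel) -> dict:
        return {a: tss_distance(region, gene, a) for a in TSS_ANCHORS}

    promoter_hits = [g for g in same_chrom if overlaps(region, promoter_of(g, promoter_bp))]
    if promoter_hits:
        gene = min(promoter_hits, key=lambda g: (tss_distance(region, g), g.accession))
        return AnnotationRecord(region, "promoter", gene, tss_distances=tss_map(gene))

    body_hits = [g for g in same_chrom if overlaps(region, g.span)]
    if body_hits:
        gene = min(body_hits, key=lambda g: (tss_distance(region, g), g.accession))
        return AnnotationRecord(
            region, "gene_body", gene,
            sub_features=_exon_labels(gene, region),
            tss_distances=tss_map(gene),
        )

    def boundary_gap(gene: GeneModel) -> int:
        return gene_gap_distance(region, gene)[0]

    gene = min(same_chrom, key=lambda g: (boundary_gap(g), g.accession))
    gap, position = gene_gap_distance(region, gene)
    return AnnotationRecord(
        region, "intergenic", gene,
        gap_bp=gap, relative_position=position, tss_distances=tss_map(gene),
    )
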