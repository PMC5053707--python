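"""Domain types and file I/O with explicit coordinate conventions.

All in-memory coordinates are 1-based inclusive, matching UCSC browser
display and the coordinate style used in enhancer/gene tables.  BED input
and output (0-based, half-open) is converted only at the I/O boundary.
No statistics live in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CpGRecord",
    "SampleInfo",
    "SampleSheet",
    "FormatError",
    "read_cpg_calls",
    "read_intervals",
    "read_gene_models",
    "read_sample_sheet",
    "write_records",
    "write_intervals_bed",
    "calls_to_frame",
    "interval_sort_key",
]

DEFAULT_MIN_COVERAGE = 10


class FormatError(ValueError):
    """A file violated its documented dialect or a record its invariants."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval; ``length = end - start + 1``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise FormatError(
                f"interval end {self.end} precedes start {self.start} on {self.chrom}"
            )
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple[str, int, int]:
        """Coordinate identity, ignoring name/strand decoration."""
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # chr1:100-200 style
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    """Total sort order: chromosome lexicographic, then start, then end."""
    return (iv.chrom, iv.start, iv.end)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A transcript model with strand-aware TSS.

    TSS is ``tx_start`` on the + strand and ``tx_end`` on the − strand.
    Exons, when present, are sorted, non-overlapping and contained in the
    transcript span; ``exons`` are stored in genomic order.
    """

    accession: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tx_start < 1 or self.tx_end < self.tx_start:
            raise FormatError(
                f"bad transcript span {self.tx_start}-{self.tx_end} for {self.accession}"
            )
        if self.exons is not None:
            prev_end = 0
            for ex in self.exons:
                if ex.chrom != self.chrom:
                    raise FormatError("exon on wrong chromosome")
                if ex.start <= prev_end:
                    raise FormatError("exons must be sorted and non-overlapping")
                if ex.start < self.tx_start or ex.end > self.tx_end:
                    raise FormatError("exon outside transcript span")
                prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end,
                               name=self.symbol, strand=self.strand)


@dataclass(frozen=True, slots=True)
class CpGRecord:
    """One CpG methylation observation: methylated / total read counts."""

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"CpG position must be >= 1, got {self.pos}")
        if self.n_total < 1:
            raise FormatError(f"CpG total coverage must be >= 1, got {self.n_total}")
        if not 0 <= self.n_meth <= self.n_total:
            raise FormatError(
                f"methylated count {self.n_meth} outside [0, {self.n_total}] "
                f"at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True, slots=True)
class SampleInfo:
    sample_id: str
    group: str
    path: str | None = None


@dataclass(frozen=True)
class SampleSheet:
    """Cohort design: unique sample ids, each assigned to one of two groups.

    ``group1`` is the first group label encountered in sheet order (by
    convention the phenotype of interest, e.g. CIMP); all group differences
    downstream are reported as group1 − group2.
    """

    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("sample ids must be unique")
        if len(self.group_labels) != 2:
            raise FormatError(
                f"sample sheet must define exactly two groups, got {self.group_labels}"
            )
        for g in self.group_labels:
            if not self.group_ids(g):
                raise FormatError(f"group {g!r} is empty")

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return tuple(seen)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    def group_ids(self, group: str) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.group == group)

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.group
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# readers


def _open_lines(path: str | Path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return fh.read().splitlines()


def read_cpg_calls(
    path: str | Path,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[CpGRecord]:
    """Read a tab-delimited per-CpG call file.

    Two dialects are recognised from the header:

    * ``chrom pos strand n_meth n_total`` — counts directly;
    * ``chrom pos strand coverage freqC`` — methylKit-style, converted via
      ``n_meth = round(coverage * freqC / 100)``, ``n_total = coverage``.

    Records with ``n_total < min_coverage`` are dropped.  Output is sorted
    by (chrom, pos).  A duplicated (chrom, pos, strand) is an error.
    """
    lines = _open_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty call file")
    header = lines[0].rstrip("\n").split("\t")
    cols = {c: i for i, c in enumerate(header)}
    count_dialect = {"chrom", "pos", "strand", "n_meth", "n_total"} <= cols.keys()
    freq_dialect = {"chrom", "pos", "strand", "coverage", "freqC"} <= cols.keys()
    if not (count_dialect or freq_dialect):
        raise FormatError(f"{path}: unrecognised call-file header {header}")

    records: list[CpGRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            chrom = parts[cols["chrom"]]
            pos = int(parts[cols["pos"]])
            strand = parts[cols["strand"]]
            if count_dialect:
                n_meth = int(parts[cols["n_meth"]])
                n_total = int(parts[cols["n_total"]])
            else:
                n_total = int(parts[cols["coverage"]])
                n_meth = int(round(n_total * float(parts[cols["freqC"]]) / 100.0))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc
        key = (chrom, pos, strand)
        if key in seen:
            raise FormatError(f"{path}:{lineno}: duplicate call at {chrom}:{pos} ({strand})")
        seen.add(key)
        try:
            rec = CpGRecord(chrom, pos, strand, n_meth, n_total)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if rec.n_total >= min_coverage:
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read an interval catalog.

    ``format='bed'``: 0-based half-open BED3/BED4(+strand); converted to
    1-based inclusive via (start+1, end).  ``format='table1'``: tab-delimited
    with header ``chrom start end [name] [strand]`` already 1-based
    inclusive.  Output is sorted.
    """
    if format not in ("bed", "table1"):
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    lines = _open_lines(path)
    start_line = 1
    if format == "table1":
        if not lines:
            raise FormatError(f"{path}: empty interval table")
        header = lines[0].split("\t")
        cols = {c: i for i, c in enumerate(header)}
        if not {"chrom", "start", "end"} <= cols.keys():
            raise FormatError(f"{path}: table1 format requires chrom/start/end header")
        body = lines[1:]
        start_line = 2
    else:
        body = lines
    for lineno, line in enumerate(body, start=start_line):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        try:
            if format == "bed":
                chrom, s, e = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 and parts[3] else None
                strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
                iv = GenomicInterval(chrom, s + 1, e, name=name, strand=strand)
            else:
                chrom = parts[cols["chrom"]]
                s = int(parts[cols["start"]])
                e = int(parts[cols["end"]])
                name = parts[cols["name"]] if "name" in cols and parts[cols["name"]] else None
                strand = (
                    parts[cols["strand"]]
                    if "strand" in cols and parts[cols["strand"]] in ("+", "-")
                    else None
                )
                iv = GenomicInterval(chrom, s, e, name=name, strand=strand)
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed interval line: {exc}") from exc
        out.append(iv)
    out.sort(key=interval_sort_key)
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like gene table.

    Required header columns: ``symbol accession chrom strand tx_start
    tx_end``; optional ``exon_starts``/``exon_ends`` as comma-separated
    1-based inclusive lists.
    """
    lines = _open_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty gene table")
    cols = {c: i for i, c in enumerate(lines[0].split("\t"))}
    required = {"symbol", "accession", "chrom", "strand", "tx_start", "tx_end"}
    if not required <= cols.keys():
        raise FormatError(f"{path}: gene table missing columns {required - cols.keys()}")
    genes: list[GeneModel] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            chrom = parts[cols["chrom"]]
            exons = None
            if "exon_starts" in cols and "exon_ends" in cols:
                raw_s = parts[cols["exon_starts"]].strip().rstrip(",")
                raw_e = parts[cols["exon_ends"]].strip().rstrip(",")
                if raw_s and raw_e:
                    starts = [int(x) for x in raw_s.split(",")]
                    ends = [int(x) for x in raw_e.split(",")]
                    if len(starts) != len(ends):
                        raise FormatError("exon start/end lists differ in length")
                    exons = tuple(
                        GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
                    )
            gene = GeneModel(
                accession=parts[cols["accession"]],
                symbol=parts[cols["symbol"]],
                chrom=chrom,
                strand=parts[cols["strand"]],
                tx_start=int(parts[cols["tx_start"]]),
                tx_end=int(parts[cols["tx_end"]]),
                exons=exons,
            )
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed gene line: {exc}") from exc
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.tx_end, g.accession))
    return genes


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab-delimited sample sheet with columns sample_id, group[, path]."""
    lines = _open_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty sample sheet")
    cols = {c: i for i, c in enumerate(lines[0].split("\t"))}
    if not {"sample_id", "group"} <= cols.keys():
        raise FormatError(f"{path}: sample sheet requires sample_id and group columns")
    samples = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        samples.append(
            SampleInfo(
                sample_id=parts[cols["sample_id"]],
                group=parts[cols["group"]],
                path=parts[cols["path"]] if "path" in cols and len(parts) > cols["path"] else None,
            )
        )
    return SampleSheet(tuple(samples))


# ---------------------------------------------------------------------------
# writers


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def _record_row(rec) -> dict:
    """Flatten a domain record into a writable row (1-based coordinates)."""
    if isinstance(rec, GenomicInterval):
        return {
            "chrom": rec.chrom, "start": rec.start, "end": rec.end,
            "name": rec.name, "strand": rec.strand,
        }
    if isinstance(rec, CpGRecord):
        return {
            "chrom": rec.chrom, "pos": rec.pos, "strand": rec.strand,
            "n_meth": rec.n_meth, "n_total": rec.n_total,
        }
    if isinstance(rec, GeneModel):
        return {
            "symbol": rec.symbol, "accession": rec.accession, "chrom": rec.chrom,
            "strand": rec.strand, "tx_start": rec.tx_start, "tx_end": rec.tx_end,
            "exon_starts": ",".join(str(e.start) for e in rec.exons) if rec.exons else "",
            "exon_ends": ",".join(str(e.end) for e in rec.exons) if rec.exons else "",
        }
    if hasattr(rec, "as_row"):
        return rec.as_row()
    raise TypeError(f"do not know how to write records of type {type(rec).__name__}")


def write_records(records: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a tab-delimited table with a header.

    Column order is deterministic (the record type's natural order); floats
    are rendered at 6 significant digits; re-reading a written interval file
    reproduces the input.  An empty list with no declared columns produces a
    header-only file for intervals.
    """
    rows = [_record_row(r) for r in records]
    if rows:
        types = {type(r).__name__ for r in records}
        if len(types) > 1:
            raise TypeError(f"records must be homogeneous, got {sorted(types)}")
        header = list(rows[0].keys())
    elif columns is not None:
        header = list(columns)
    else:
        header = ["chrom", "start", "end", "name", "strand"]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in header) + "\n")


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based, half-open): internal (s, e) → (s-1, e)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields.append(iv.name or ".")
            if iv.strand is not None:
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def calls_to_frame(calls: Sequence[CpGRecord] | pd.DataFrame) -> pd.DataFrame:
    """Canonical DataFrame view of CpG calls (columns chrom,pos,strand,n_meth,n_total)."""
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "strand": [c.strand for c in calls],
            "n_meth": [c.n_meth for c in calls],
            "n_total": [c.n_total for c in calls],
        }
    )
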