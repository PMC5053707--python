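"""Synthetic two-group bisulfite cohorts with planted ground truth.

The generator emulates the study design the pipeline is built for: a
6-vs-5 two-group cohort of per-CpG methylated/total counts in which

* background CpG methylation is bimodal — low (~0.1) inside simulated
  CpG-dense segments, high (~0.8) elsewhere — and identical in both groups;
* planted DMR windows sit on the 1000-bp tiling grid and separate the
  groups by exactly ``dmr_delta`` in true mean methylation;
* coupled enhancer/partner pairs share a per-sample latent factor: the
  enhancer's regional mean moves by ``a·u_s`` and the partner's by
  ``sign·b·u_s``, producing the strong intrachromosomal methylation
  correlation the screen must recover.  Each coupled enhancer is itself
  group-differential and contains one planted "anchor" DMR window, so the
  full funnel (DMR → containment → DME → screen) can find it;
* counts are beta-binomial: per CpG and sample the methylation level is
  Beta-distributed around its regional mean (precision ``beta_precision``)
  and the methylated count is binomial at negative-binomial coverage.

The latent factor is drawn per sample from a standard normal and centered
within each group before use, so coupling adds within-group covariation
without perturbing the planted between-group difference.

A separate capture-seq cohort (default 24 samples) emulates
enrichment-based validation: fixed-length 36-bp reads are placed with
intensity proportional to regional methylation driven by a fresh latent
factor, so coupled pairs exhibit correlated rpkm across samples.

Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    SampleInfo,
    SampleSheet,
    write_intervals_bed,
    write_records,
)

__all__ = [
    "SimConfig",
    "PlantedDmr",
    "PlantedEnhancer",
    "CoupledPair",
    "TruthSet",
    "plant_truth",
    "simulate_cohort_counts",
    "simulate_capture_cohort",
    "place_reads",
    "write_cohort",
]

GRID = 1000  # bp; planted DMR windows align to this tiling grid

# background methylation mixture (identical across groups)
BG_LOW = 0.1     # inside CpG-dense segments
BG_HIGH = 0.8    # elsewhere
ISLAND_CELL_FRACTION = 0.08   # fraction of grid cells that are CpG-dense
ISLAND_DENSITY_WEIGHT = 5.0   # CpG sampling weight of dense cells
MEAN_CLAMP = (0.02, 0.98)     # keeps Beta parameters and Pearson r defined
MIN_CPGS_PER_PLANTED = 6      # planted windows are topped up to this CpG count

CAPTURE_READ_LENGTH = 36
CAPTURE_BASE_INTENSITY = 0.5
CAPTURE_BACKGROUND_INTENSITY = 0.3
CAPTURE_JITTER_SD = 0.03


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohorts."""

    n_group1: int = 6
    n_group2: int = 5
    group_labels: tuple[str, str] = ("CIMP", "nonCIMP")
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    n_cpgs: int = 20_000
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0   # negative-binomial size parameter
    beta_precision: float = 50.0
    n_planted_dmrs: int = 50
    dmr_delta: float = 0.6
    n_enhancers: int = 20
    enhancer_length_range: tuple[int, int] = (1000, 4000)
    n_coupled_pairs: int = 10
    coupling_strengths: tuple[float, float] = (0.12, 0.12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one sample")
        if not 0.0 <= self.dmr_delta <= 1.0:
            raise ValueError("dmr_delta must lie in [0, 1]")
        if self.chrom_length < 2 * GRID:
            raise ValueError("chromosome too short for the tiling grid")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be positive")
        if self.n_coupled_pairs > self.n_enhancers:
            raise ValueError("coupled pairs cannot exceed enhancers")
        if self.n_coupled_pairs > 0 and self.n_planted_dmrs < 2 * self.n_coupled_pairs:
            raise ValueError(
                "need n_planted_dmrs >= 2*n_coupled_pairs (anchor + partner windows)"
            )
        if self.enhancer_length_range[0] < GRID:
            raise ValueError(f"enhancers must span at least one {GRID}-bp grid window")
        if self.enhancer_length_range[1] < self.enhancer_length_range[0]:
            raise ValueError("bad enhancer length range")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        g1, g2 = self.group_labels
        return tuple(
            [f"{g1}_{i+1:02d}" for i in range(self.n_group1)]
            + [f"{g2}_{i+1:02d}" for i in range(self.n_group2)]
        )

    def sample_sheet(self) -> SampleSheet:
        g1, g2 = self.group_labels
        return SampleSheet(
            tuple(
                SampleInfo(sid, g1 if i < self.n_group1 else g2)
                for i, sid in enumerate(self.sample_ids)
            )
        )


@dataclass(frozen=True)
class PlantedDmr:
    window: GenomicInterval
    mean_group1: float
    mean_group2: float
    role: str            # plain | anchor | partner
    pair_index: int | None = None


@dataclass(frozen=True)
class PlantedEnhancer:
    interval: GenomicInterval
    mean_group1: float | None   # None: background (non-differential) enhancer
    mean_group2: float | None
    pair_index: int | None = None


@dataclass(frozen=True)
class CoupledPair:
    enhancer: GenomicInterval
    partner: GenomicInterval
    sign: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("coupling sign must be +1 or -1")
        if self.enhancer.chrom != self.partner.chrom:
            raise ValueError("coupled partner must share the enhancer's chromosome")


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth: what the pipeline should recover."""

    dmr_windows: tuple[PlantedDmr, ...]
    enhancers: tuple[PlantedEnhancer, ...]
    coupled_pairs: tuple[CoupledPair, ...]
    latent_factors: dict  # sample_id -> float
    island_cells: frozenset  # grid-cell indices of CpG-dense segments

    @property
    def dmr_intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(d.window for d in self.dmr_windows)

    @property
    def enhancer_intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(e.interval for e in self.enhancers)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _grid_window(config: SimConfig, cell: int) -> GenomicInterval:
    return GenomicInterval(
        config.chrom, cell * GRID + 1, min((cell + 1) * GRID, config.chrom_length)
    )


def _cells_of(iv: GenomicInterval) -> range:
    return range((iv.start - 1) // GRID, (iv.end - 1) // GRID + 1)


def plant_truth(config: SimConfig) -> TruthSet:
    """Place non-overlapping planted elements and draw latent factors.

    Planted DMR windows align to the 1000-bp grid.  The first
    ``n_coupled_pairs`` DMRs are anchors inside coupled enhancers, the
    next ``n_coupled_pairs`` are the coupled partners, the rest are plain.
    Raises a configuration error if elements cannot be placed without
    overlap after bounded retries.
    """
    rng = _rng(config, 1)
    n_cells = config.chrom_length // GRID
    occupied: set[int] = set()

    def claim_cells(cells: Sequence[int]) -> bool:
        cs = set(cells)
        if cs & occupied or min(cs) < 1 or max(cs) >= n_cells - 1:
            return False
        occupied.update(cs)
        return True

    def draw_cell() -> int:
        for _ in range(10_000):
            cell = int(rng.integers(1, n_cells - 1))
            if claim_cells([cell]):
                return cell
        raise ValueError("could not place elements without overlap; chromosome too crowded")

    hi = 0.5 + config.dmr_delta / 2.0
    lo = 0.5 - config.dmr_delta / 2.0

    def group_means(direction: int) -> tuple[float, float]:
        return (hi, lo) if direction > 0 else (lo, hi)

    n_pairs = config.n_coupled_pairs
    enhancers: list[PlantedEnhancer] = []
    dmrs: list[PlantedDmr] = []
    pairs: list[CoupledPair] = []

    # coupled enhancers, each built around one grid cell (the anchor DMR)
    pad_max = (config.enhancer_length_range[1] - GRID) // 2
    for j in range(n_pairs):
        placed = False
        for _ in range(10_000):
            cell = int(rng.integers(1, n_cells - 1))
            left = int(rng.integers(0, pad_max + 1)) if pad_max else 0
            right = int(rng.integers(0, pad_max + 1)) if pad_max else 0
            anchor = _grid_window(config, cell)
            enh = GenomicInterval(
                config.chrom,
                max(1, anchor.start - left),
                min(config.chrom_length, anchor.end + right),
                name=f"enh_{j+1:03d}",
            )
            if claim_cells(list(_cells_of(enh))):
                placed = True
                break
        if not placed:
            raise ValueError("could not place coupled enhancers without overlap")
        direction = 1 if rng.random() < 0.5 else -1
        m1, m2 = group_means(direction)
        enhancers.append(PlantedEnhancer(enh, m1, m2, pair_index=j))
        dmrs.append(PlantedDmr(anchor, m1, m2, role="anchor", pair_index=j))

    # coupled partner windows (distal, same chromosome)
    for j in range(n_pairs):
        sign = 1 if rng.random() < 0.5 else -1
        cell = draw_cell()
        window = _grid_window(config, cell)
        e_dir = 1 if enhancers[j].mean_group1 > enhancers[j].mean_group2 else -1
        m1, m2 = group_means(e_dir * sign)
        dmrs.append(PlantedDmr(window, m1, m2, role="partner", pair_index=j))
        pairs.append(CoupledPair(enhancers[j].interval, window, sign))

    # plain DMRs
    for _ in range(config.n_planted_dmrs - 2 * n_pairs):
        cell = draw_cell()
        direction = 1 if rng.random() < 0.5 else -1
        m1, m2 = group_means(direction)
        dmrs.append(PlantedDmr(_grid_window(config, cell), m1, m2, role="plain"))

    # background (non-differential) enhancers
    for j in range(config.n_enhancers - n_pairs):
        placed = False
        for _ in range(10_000):
            cell = int(rng.integers(1, n_cells - 1))
            left = int(rng.integers(0, pad_max + 1)) if pad_max else 0
            right = int(rng.integers(0, pad_max + 1)) if pad_max else 0
            base = _grid_window(config, cell)
            enh = GenomicInterval(
                config.chrom,
                max(1, base.start - left),
                min(config.chrom_length, base.end + right),
                name=f"enh_bg_{j+1:03d}",
            )
            if claim_cells(list(_cells_of(enh))):
                placed = True
                break
        if not placed:
            raise ValueError("could not place background enhancers without overlap")
        enhancers.append(PlantedEnhancer(enh, None, None))

    # CpG-dense segments among the remaining cells
    free = np.array(sorted(set(range(n_cells)) - occupied))
    n_islands = int(round(ISLAND_CELL_FRACTION * n_cells))
    island_cells = frozenset(
        int(c) for c in rng.choice(free, size=min(n_islands, len(free)), replace=False)
    )

    latent = rng.standard_normal(config.n_group1 + config.n_group2)
    latent_factors = dict(zip(config.sample_ids, latent.tolist()))

    dmrs.sort(key=lambda d: d.window.start)
    return TruthSet(
        dmr_windows=tuple(dmrs),
        enhancers=tuple(enhancers),
        coupled_pairs=tuple(pairs),
        latent_factors=latent_factors,
        island_cells=island_cells,
    )


def _centered_latent(truth: TruthSet, config: SimConfig) -> np.ndarray:
    """Latent factors centered within each group (per-sample, sheet order)."""
    u = np.array([truth.latent_factors[s] for s in config.sample_ids])
    n1 = config.n_group1
    u = u.copy()
    u[:n1] -= u[:n1].mean()
    u[n1:] -= u[n1:].mean()
    return u


def _cpg_positions(truth: TruthSet, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample CpG positions: dense segments carry extra weight; planted
    windows are topped up to a minimum CpG count."""
    n_cells = config.chrom_length // GRID
    weights = np.ones(n_cells)
    weights[list(truth.island_cells)] = ISLAND_DENSITY_WEIGHT
    weights /= weights.sum()
    cells = rng.choice(n_cells, size=config.n_cpgs, p=weights)
    offsets = rng.integers(0, GRID, size=config.n_cpgs)
    pos = cells * GRID + 1 + offsets
    pos = np.unique(pos[pos <= config.chrom_length])
    extra: list[int] = []
    for d in truth.dmr_windows:
        mask = (pos >= d.window.start) & (pos <= d.window.end)
        have = {int(p) for p in pos[mask]}
        while len(have) < MIN_CPGS_PER_PLANTED:
            cand = int(rng.integers(d.window.start, d.window.end + 1))
            if cand not in have:
                extra.append(cand)
                have.add(cand)
    if extra:
        pos = np.unique(np.concatenate([pos, np.array(extra, dtype=pos.dtype)]))
    return pos


def _per_sample_means(
    truth: TruthSet, config: SimConfig, pos: np.ndarray
) -> np.ndarray:
    """True per-CpG methylation mean for every (sample, CpG)."""
    n_samples = config.n_group1 + config.n_group2
    cells = (pos - 1) // GRID
    base = np.where(np.isin(cells, list(truth.island_cells)), BG_LOW, BG_HIGH)
    means = np.tile(base, (n_samples, 1)).astype(float)
    u = _centered_latent(truth, config)
    a, b = config.coupling_strengths
    group1 = np.arange(n_samples) < config.n_group1

    def region_mask(iv: GenomicInterval) -> np.ndarray:
        return (pos >= iv.start) & (pos <= iv.end)

    # coupled enhancers (their whole span, anchor windows included)
    for enh in truth.enhancers:
        if enh.pair_index is None:
            continue
        mask = region_mask(enh.interval)
        mu_g = np.where(group1, enh.mean_group1, enh.mean_group2)
        means[:, mask] = (mu_g + a * u)[:, None]

    for d in truth.dmr_windows:
        if d.role == "anchor":
            continue  # covered by its enhancer
        mask = region_mask(d.window)
        mu_g = np.where(group1, d.mean_group1, d.mean_group2)
        if d.role == "partner":
            sign = truth.coupled_pairs[d.pair_index].sign
            means[:, mask] = (mu_g + sign * b * u)[:, None]
        else:
            means[:, mask] = mu_g[:, None]

    return np.clip(means, *MEAN_CLAMP)


def simulate_cohort_counts(
    truth: TruthSet, config: SimConfig
) -> tuple[dict[str, pd.DataFrame], SampleSheet]:
    """Draw the per-sample per-CpG count cohort.

    Coverage ~ negative binomial(coverage_mean, coverage_dispersion)
    truncated at 1; methylation level per CpG and sample ~ Beta with the
    planted mean and precision ``beta_precision``; methylated count ~
    Binomial(coverage, level).  Returns {sample_id: DataFrame with columns
    chrom,pos,strand,n_meth,n_total} plus the matching SampleSheet.
    """
    rng = _rng(config, 2)
    pos = _cpg_positions(truth, config, rng)
    means = _per_sample_means(truth, config, pos)
    phi = config.beta_precision
    size = config.coverage_dispersion
    p_nb = size / (size + config.coverage_mean)
    cohort: dict[str, pd.DataFrame] = {}
    for i, sid in enumerate(config.sample_ids):
        cov = rng.negative_binomial(size, p_nb, size=len(pos))
        cov = np.maximum(cov, 1)
        mu = means[i]
        theta = rng.beta(mu * phi, (1.0 - mu) * phi)
        n_meth = rng.binomial(cov, theta)
        cohort[sid] = pd.DataFrame(
            {
                "chrom": config.chrom,
                "pos": pos.astype(int),
                "strand": "+",
                "n_meth": n_meth.astype(int),
                "n_total": cov.astype(int),
            }
        )
    return cohort, config.sample_sheet()


def place_reads(
    rng: np.random.Generator,
    regions: Sequence[GenomicInterval],
    intensities: Sequence[float],
    n_reads: int,
    chrom: str,
    chrom_length: int,
    read_length: int = CAPTURE_READ_LENGTH,
    background_intensity: float = CAPTURE_BACKGROUND_INTENSITY,
) -> pd.DataFrame:
    """Place fixed-length reads with intensity-proportional region weights.

    Each region's expected dedicated read count is proportional to
    ``intensity × length``; the remaining reads scatter uniformly over the
    chromosome with weight ``background_intensity × chrom_length``.  A
    region with zero intensity receives no dedicated reads.
    """
    if n_reads < 1:
        raise ValueError("reads_per_sample must be >= 1")
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    weights = np.array([iv.length for iv in regions], dtype=float) * intensities
    weights = np.concatenate([weights, [background_intensity * chrom_length]])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all placement weights are zero")
    alloc = rng.multinomial(n_reads, weights / total)
    starts: list[np.ndarray] = []
    for iv, k in zip(regions, alloc[:-1]):
        if k == 0:
            continue
        lo = max(1, iv.start - read_length + 1)  # any start overlapping iv
        starts.append(rng.integers(lo, iv.end + 1, size=k))
    if alloc[-1]:
        starts.append(rng.integers(1, max(2, chrom_length - read_length + 1), size=alloc[-1]))
    s = np.sort(np.concatenate(starts)) if starts else np.array([], dtype=int)
    return pd.DataFrame(
        {"chrom": chrom, "start": s.astype(int), "end": (s + read_length - 1).astype(int)}
    )


def simulate_capture_cohort(
    truth: TruthSet,
    config: SimConfig,
    n_samples: int = 24,
    reads_per_sample: int = 50_000,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Simulate the enrichment-based validation cohort.

    Reads are 36-bp intervals placed with intensity proportional to
    regional methylation driven by a fresh per-sample latent factor, so
    coupled pairs show correlated rpkm across samples.  Returns per-sample
    read tables (1-based inclusive coordinates) and total read counts.
    """
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    rng = _rng(config, 3)
    u = rng.standard_normal(n_samples)
    a, b = config.coupling_strengths
    regions = list(truth.enhancer_intervals) + [
        d.window for d in truth.dmr_windows if d.role != "anchor"
    ]
    pair_of_enh = {e.interval.key(): e.pair_index for e in truth.enhancers}
    partner_sign = {
        d.window.key(): truth.coupled_pairs[d.pair_index].sign
        for d in truth.dmr_windows
        if d.role == "partner"
    }
    reads: dict[str, pd.DataFrame] = {}
    totals: dict[str, int] = {}
    for s in range(n_samples):
        sid = f"tissue_{s+1:02d}"
        intens = []
        for iv in regions:
            mu = CAPTURE_BASE_INTENSITY
            if pair_of_enh.get(iv.key()) is not None:
                mu = mu + a * u[s]
            elif iv.key() in partner_sign:
                mu = mu + partner_sign[iv.key()] * b * u[s]
            mu += rng.normal(0.0, CAPTURE_JITTER_SD)
            intens.append(float(np.clip(mu, 0.05, 0.95)))
        df = place_reads(
            rng, regions, intens, reads_per_sample, config.chrom, config.chrom_length
        )
        reads[sid] = df
        totals[sid] = len(df)
    return reads, totals


def write_cohort(
    truth: TruthSet,
    cohort: Mapping[str, pd.DataFrame],
    sheet: SampleSheet,
    outdir: str | Path,
) -> None:
    """Emit the cohort in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for info in sheet.samples:
        path = outdir / f"{info.sample_id}.calls.tsv"
        cohort[info.sample_id].to_csv(path, sep="\t", index=False)
        rows.append(f"{info.sample_id}\t{info.group}\t{path.name}")
    (outdir / "samples.tsv").write_text(
        "sample_id\tgroup\tpath\n" + "\n".join(rows) + "\n"
    )
    write_intervals_bed(truth.enhancer_intervals, outdir / "enhancers.bed")
    write_records(list(truth.dmr_intervals), outdir / "planted_dmrs.tsv")
    with open(outdir / "coupled_pairs.tsv", "wt") as fh:
        fh.write("enhancer\tpartner\tsign\n")
        for p in truth.coupled_pairs:
            fh.write(f"{p.enhancer}\t{p.partner}\t{p.sign:+d}\n")
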