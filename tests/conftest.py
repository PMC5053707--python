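"""Shared fixtures: published worked-example coordinates and synthetic cohorts.

The heavyweight synthetic cohorts are session-scoped so the recovery,
calibration and acceptance tests share one simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from epicorrmeth.io_formats import GeneModel, GenomicInterval
from epicorrmeth.pipeline import PipelineConfig, run_stages
from epicorrmeth.synthetic_data import (
    SimConfig,
    plant_truth,
    simulate_capture_cohort,
    simulate_cohort_counts,
)

# --- published worked-example coordinates (GRCh37/hg19) --------------------

ENHANCER_1702 = GenomicInterval("chr1", 18958671, 18960284, name="1702")
ENHANCER_1944 = GenomicInterval("chr15", 65377669, 65381418, name="1944")
DC1A = GenomicInterval("chr1", 228194001, 228195000, name="DC1A")
DC1B = GenomicInterval("chr1", 240118001, 240119000, name="DC1B")
DC15A = GenomicInterval("chr15", 65628001, 65629000, name="DC15A")
WNT3A = GeneModel("NM_033131", "WNT3A", "chr1", "+", 228194722, 228248972)
CHRM3 = GeneModel("NM_000740", "CHRM3", "chr1", "+", 239549876, 240078750)
IGDCC3 = GeneModel("NM_004884", "IGDCC3", "chr15", "-", 65619464, 65670378)


@pytest.fixture(scope="session")
def table1():
    """Coordinates of the published enhancer–DMR–gene triples."""
    return {
        "enh_1702": ENHANCER_1702, "enh_1944": ENHANCER_1944,
        "DC1A": DC1A, "DC1B": DC1B, "DC15A": DC15A,
        "WNT3A": WNT3A, "CHRM3": CHRM3, "IGDCC3": IGDCC3,
    }


# --- synthetic cohorts -----------------------------------------------------


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition cohort: 6 vs 5 samples, 50 planted DMRs, 10 coupled pairs."""
    cfg = SimConfig(seed=1)
    truth = plant_truth(cfg)
    cohort, sheet = simulate_cohort_counts(truth, cfg)
    return cfg, truth, cohort, sheet


@pytest.fixture(scope="session")
def recovery_run(default_sim):
    """Full pipeline stages (incl. capture validation) on the default cohort."""
    cfg, truth, cohort, sheet = default_sim
    reads, totals = simulate_capture_cohort(truth, cfg)
    pc = PipelineConfig(sample_sheet="-", enhancers="-")
    out = run_stages(cohort, sheet, truth.enhancer_intervals, pc,
                     capture_reads=reads, capture_totals=totals)
    return cfg, truth, out


@pytest.fixture(scope="session")
def null_sim():
    """Null cohort: no planted effects; ~2,000 testable windows."""
    cfg = SimConfig(seed=11, n_planted_dmrs=0, n_coupled_pairs=0, n_enhancers=0)
    truth = plant_truth(cfg)
    cohort, sheet = simulate_cohort_counts(truth, cfg)
    return cfg, truth, cohort, sheet


@pytest.fixture(scope="session")
def null_dmrs(null_sim):
    """Window-test results on the null cohort (~2,000 windows)."""
    from epicorrmeth.dmr_caller import call_dmrs

    cfg, truth, cohort, sheet = null_sim
    return call_dmrs(cohort, sheet)


@pytest.fixture(scope="session")
def dme3_run():
    """Funnel with exactly 3 differential enhancers among 20 (the published shape)."""
    cfg = SimConfig(seed=5, n_coupled_pairs=3)
    truth = plant_truth(cfg)
    cohort, sheet = simulate_cohort_counts(truth, cfg)
    pc = PipelineConfig(sample_sheet="-", enhancers="-")
    out = run_stages(cohort, sheet, truth.enhancer_intervals, pc)
    return cfg, truth, out


def pooled_g_statistic(table: np.ndarray) -> float:
    """Independent oracle: G = 2·Σ obs·ln(obs/exp) on a 2×2 (meth, unmeth) table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row @ col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return float(2.0 * terms.sum())
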