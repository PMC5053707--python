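"""Generator contracts: planted truth, count model, capture cohort, determinism."""

import numpy as np
import pandas as pd
import pytest

from epicorrmeth.io_formats import GenomicInterval
from epicorrmeth.methlevels import region_methylation_matrix
from epicorrmeth.synthetic_data import (
    GRID,
    SimConfig,
    place_reads,
    plant_truth,
    simulate_capture_cohort,
    simulate_cohort_counts,
)


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = SimConfig()
        assert (cfg.n_group1, cfg.n_group2) == (6, 5)
        assert cfg.n_planted_dmrs == 50 and cfg.n_coupled_pairs == 10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dmr_delta=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_coupled_pairs=30, n_enhancers=20)
        with pytest.raises(ValueError):
            SimConfig(n_planted_dmrs=5, n_coupled_pairs=10)
        with pytest.raises(ValueError):
            SimConfig(enhancer_length_range=(500, 4000))


class TestPlantTruth:
    def test_counts_match_config(self, default_sim):
        cfg, truth, _, _ = default_sim
        assert len(truth.dmr_windows) == cfg.n_planted_dmrs
        assert len(truth.enhancers) == cfg.n_enhancers
        assert len(truth.coupled_pairs) == cfg.n_coupled_pairs

    def test_no_planted_elements_when_zeroed(self):
        cfg = SimConfig(n_planted_dmrs=0, n_coupled_pairs=0, n_enhancers=0, seed=3)
        truth = plant_truth(cfg)
        assert truth.dmr_windows == () and truth.coupled_pairs == ()

    def test_dmr_windows_grid_aligned(self, default_sim):
        _, truth, _, _ = default_sim
        for d in truth.dmr_windows:
            assert (d.window.start - 1) % GRID == 0 and d.window.length == GRID

    def test_planted_elements_do_not_overlap(self, default_sim):
        _, truth, _, _ = default_sim
        spans = [d.window for d in truth.dmr_windows if d.role != "anchor"]
        spans += list(truth.enhancer_intervals)
        spans.sort(key=lambda iv: iv.start)
        for a, b in zip(spans, spans[1:]):
            assert a.end < b.start

    def test_group_means_differ_by_delta(self, default_sim):
        cfg, truth, _, _ = default_sim
        for d in truth.dmr_windows:
            assert abs(d.mean_group1 - d.mean_group2) == pytest.approx(cfg.dmr_delta)

    def test_partners_share_enhancer_chromosome(self, default_sim):
        _, truth, _, _ = default_sim
        for p in truth.coupled_pairs:
            assert p.enhancer.chrom == p.partner.chrom

    def test_anchor_windows_inside_their_enhancers(self, default_sim):
        from epicorrmeth.overlap import contains

        _, truth, _, _ = default_sim
        enh = {e.pair_index: e.interval for e in truth.enhancers if e.pair_index is not None}
        for d in truth.dmr_windows:
            if d.role == "anchor":
                assert contains(enh[d.pair_index], d.window)

    def test_negative_sign_pairs_have_opposing_group_direction(self, default_sim):
        _, truth, _, _ = default_sim
        enh_dir = {e.pair_index: np.sign(e.mean_group1 - e.mean_group2)
                   for e in truth.enhancers if e.pair_index is not None}
        partners = {d.pair_index: d for d in truth.dmr_windows if d.role == "partner"}
        for j, pair in enumerate(truth.coupled_pairs):
            p_dir = np.sign(partners[j].mean_group1 - partners[j].mean_group2)
            assert p_dir == pair.sign * enh_dir[j]


class TestCohortCounts:
    def test_identical_seed_gives_identical_cohort(self):
        cfg = SimConfig(seed=4, chrom_length=300_000, n_cpgs=3000,
                        n_planted_dmrs=6, n_coupled_pairs=2, n_enhancers=4)
        a, _ = simulate_cohort_counts(plant_truth(cfg), cfg)
        b, _ = simulate_cohort_counts(plant_truth(cfg), cfg)
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])

    def test_different_seed_differs(self):
        base = dict(chrom_length=300_000, n_cpgs=3000, n_planted_dmrs=6,
                    n_coupled_pairs=2, n_enhancers=4)
        a, _ = simulate_cohort_counts(plant_truth(SimConfig(seed=4, **base)),
                                      SimConfig(seed=4, **base))
        b, _ = simulate_cohort_counts(plant_truth(SimConfig(seed=5, **base)),
                                      SimConfig(seed=5, **base))
        assert any(not a[s].equals(b2) for (s, b2) in b.items())

    def test_counts_respect_invariants(self, default_sim):
        _, _, cohort, _ = default_sim
        for df in cohort.values():
            assert (df["n_total"] >= 1).all()
            assert ((df["n_meth"] >= 0) & (df["n_meth"] <= df["n_total"])).all()

    def test_planted_pooled_difference_near_delta(self, default_sim):
        """Pooled beta difference across planted windows ≈ dmr_delta."""
        cfg, truth, cohort, sheet = default_sim
        g1 = sheet.group_ids(sheet.group_labels[0])
        g2 = sheet.group_ids(sheet.group_labels[1])
        diffs = []
        for d in truth.dmr_windows:
            def pooled(ids):
                m = t = 0
                for sid in ids:
                    df = cohort[sid]
                    sub = df[(df["pos"] >= d.window.start) & (df["pos"] <= d.window.end)]
                    m += sub["n_meth"].sum(); t += sub["n_total"].sum()
                return m / t
            sign = 1 if d.mean_group1 >= d.mean_group2 else -1
            diffs.append(sign * (pooled(g1) - pooled(g2)))
        assert np.mean(diffs) == pytest.approx(cfg.dmr_delta, abs=0.05)

    def test_coupled_pair_region_means_strongly_correlated(self, default_sim):
        cfg, truth, cohort, _ = default_sim
        regions = []
        for p in truth.coupled_pairs:
            regions += [p.enhancer, p.partner]
        matrix = region_methylation_matrix(regions, cohort, min_cpgs=1)
        for k, p in enumerate(truth.coupled_pairs):
            x, y = matrix.values[2 * k], matrix.values[2 * k + 1]
            r = np.corrcoef(x, y)[0, 1]
            assert p.sign * r > 0.85

    def test_null_cohort_background_identical_across_groups(self, null_sim):
        """With nothing planted, group pooled levels agree closely."""
        cfg, _, cohort, sheet = null_sim
        def pooled(ids):
            m = sum(cohort[s]["n_meth"].sum() for s in ids)
            t = sum(cohort[s]["n_total"].sum() for s in ids)
            return m / t
        p1 = pooled(sheet.group_ids(sheet.group_labels[0]))
        p2 = pooled(sheet.group_ids(sheet.group_labels[1]))
        assert abs(p1 - p2) < 0.01


class TestCaptureCohort:
    def test_zero_reads_rejected(self, default_sim):
        cfg, truth, _, _ = default_sim
        with pytest.raises(ValueError):
            simulate_capture_cohort(truth, cfg, reads_per_sample=0)

    def test_zero_intensity_region_gets_no_dedicated_reads(self):
        rng = np.random.default_rng(0)
        dead = GenomicInterval("chr1", 10_001, 12_000)
        live = GenomicInterval("chr1", 50_001, 52_000)
        df = place_reads(rng, [dead, live], [0.0, 1.0], 5000, "chr1", 100_000,
                         background_intensity=0.0)
        from epicorrmeth.capture_meth import count_overlapping_reads

        assert count_overlapping_reads(df, dead) == 0
        assert count_overlapping_reads(df, live) == 5000

    def test_doubling_intensity_doubles_expected_reads(self):
        rng = np.random.default_rng(1)
        a = GenomicInterval("chr1", 10_001, 12_000)
        b = GenomicInterval("chr1", 50_001, 52_000)
        df = place_reads(rng, [a, b], [1.0, 2.0], 60_000, "chr1", 100_000,
                         background_intensity=0.0)
        from epicorrmeth.capture_meth import count_overlapping_reads

        ratio = count_overlapping_reads(df, b) / count_overlapping_reads(df, a)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_coupled_pair_rpkm_correlation_matches_sign(self, recovery_run):
        from epicorrmeth.capture_meth import profiles_from_reads

        cfg, truth, _ = recovery_run
        reads, totals = simulate_capture_cohort(truth, cfg)
        regions = [iv for p in truth.coupled_pairs for iv in (p.enhancer, p.partner)]
        profiles = profiles_from_reads(reads, regions, totals)
        rs = []
        for p in truth.coupled_pairs:
            x = [prof.rpkm_of(p.enhancer) for prof in profiles]
            y = [prof.rpkm_of(p.partner) for prof in profiles]
            rs.append(p.sign * np.corrcoef(x, y)[0, 1])
        # positive in expectation per pair; strongly positive on average
        assert all(r > 0 for r in rs)
        assert np.mean(rs) > 0.4

    def test_capture_determinism(self):
        cfg = SimConfig(seed=4, chrom_length=300_000, n_cpgs=3000,
                        n_planted_dmrs=6, n_coupled_pairs=2, n_enhancers=4)
        truth = plant_truth(cfg)
        a, ta = simulate_capture_cohort(truth, cfg, n_samples=4, reads_per_sample=2000)
        b, tb = simulate_capture_cohort(truth, cfg, n_samples=4, reads_per_sample=2000)
        assert ta == tb
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])
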