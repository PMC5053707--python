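"""Pearson screen: coefficient, p-value transform, thresholds, FDR families."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epicorrmeth.corr_screen import (
    UndefinedCorrelation,
    classify_strength,
    pearson_pvalue,
    pearson_r,
    screen_pairs,
)
from epicorrmeth.dme_filter import DmeRecord
from epicorrmeth.dmr_caller import DmrRecord
from epicorrmeth.io_formats import GenomicInterval
from epicorrmeth.methlevels import RegionMethylationMatrix


class TestPearsonR:
    def test_identity_is_one(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_affine_anticorrelation_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov = 1.1667, sd_x = sd_y = 1.2910 → r = 0.8 exactly
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_symmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=11), rng.normal(size=11)
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete_filtering(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 8.0, 10.0]
        assert pearson_r(x, y) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-10, 10),
           flip=st.sampled_from([1.0, -1.0]))
    def test_affine_invariance(self, scale, shift, flip):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0 = pearson_r(x, y)
        r1 = pearson_r(x, flip * scale * np.asarray(y) + shift)
        assert r1 == pytest.approx(flip * r0, abs=1e-9)


class TestPearsonPvalue:
    @pytest.mark.parametrize(
        "r,n,printed",
        [(0.634, 24, "0.00088"), (0.493, 24, "0.014"), (0.089, 24, "0.68")],
    )
    def test_published_validation_pvalues(self, r, n, printed):
        assert f"{pearson_pvalue(r, n):.2g}" == printed

    def test_zero_r_gives_p_one(self):
        assert pearson_pvalue(0.0, 24) == pytest.approx(1.0)

    def test_perfect_correlation_gives_p_zero(self):
        assert pearson_pvalue(1.0, 5) == 0.0
        assert pearson_pvalue(-1.0, 5) == 0.0

    def test_monotone_in_abs_r_and_in_n(self):
        ps = [pearson_pvalue(r, 12) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps == sorted(ps, reverse=True)
        pn = [pearson_pvalue(0.5, n) for n in (5, 10, 20, 40)]
        assert pn == sorted(pn, reverse=True)

    def test_matches_scipy_exact_test(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=24), rng.normal(size=24)
        res = stats.pearsonr(x, y)
        assert pearson_pvalue(res.statistic, 24) == pytest.approx(res.pvalue, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)


class TestStrength:
    @pytest.mark.parametrize(
        "r,label",
        [(0.634, "good to excellent"), (0.493, "moderate to nil"),
         (-1.0, "good to excellent"), (0.5, "good to excellent"),
         (-0.49, "moderate to nil")],
    )
    def test_conventional_scale(self, r, label):
        assert classify_strength(r) == label


def _screen_setup(values_by_region, samples=6):
    """Build DMEs/DMRs/matrix from {(chrom,start,end,name,kind): values}."""
    regions, rows = [], []
    dmes, dmrs = [], []
    for (chrom, start, end, name, kind), vals in values_by_region.items():
        iv = GenomicInterval(chrom, start, end, name=name)
        regions.append(iv)
        rows.append(vals)
        if kind == "dme":
            dmes.append(DmeRecord(iv, (0.8, 0.2), 5.0, 0.001, "hyper_in_group1", True))
        else:
            dmrs.append(DmrRecord(iv, 60.0, 1e-8, 1e-6, (), True))
    matrix = RegionMethylationMatrix(
        tuple(regions), tuple(f"s{i}" for i in range(samples)),
        np.array(rows, dtype=float), np.full((len(regions), samples), 5), 3,
    )
    return dmes, dmrs, matrix


class TestScreenPairs:
    def test_contained_dmr_excluded_from_candidates(self):
        vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        dmes, dmrs, matrix = _screen_setup({
            ("chr1", 1000, 5000, "E", "dme"): vals,
            ("chr1", 2001, 3000, "inside", "dmr"): vals,
            ("chr1", 9001, 10000, "distal", "dmr"): vals,
        })
        out = screen_pairs(dmes, dmrs, matrix)
        assert [c.partner.name for c in out] == ["distal"]
        assert out[0].passes and out[0].r == pytest.approx(1.0)

    def test_intrachromosomal_rule_excludes_other_chromosomes(self):
        vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        dmes, dmrs, matrix = _screen_setup({
            ("chr1", 1000, 5000, "E", "dme"): vals,
            ("chr2", 9001, 10000, "far", "dmr"): vals,
        })
        assert screen_pairs(dmes, dmrs, matrix) == []

    def test_anticorrelated_pair_passes_with_negative_r(self):
        x = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        dmes, dmrs, matrix = _screen_setup({
            ("chr1", 1000, 5000, "E", "dme"): x,
            ("chr1", 9001, 10000, "anti", "dmr"): [1 - v for v in x],
        })
        (rec,) = screen_pairs(dmes, dmrs, matrix)
        assert rec.passes and rec.r == pytest.approx(-1.0)

    def test_unselected_dmes_and_failing_dmrs_ignored(self):
        vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        dmes, dmrs, matrix = _screen_setup({
            ("chr1", 1000, 5000, "E", "dme"): vals,
            ("chr1", 9001, 10000, "d", "dmr"): vals,
        })
        dmes = [DmeRecord(d.enhancer, d.group_means, d.t_statistic, d.p_value,
                          d.direction, False) for d in dmes]
        assert screen_pairs(dmes, dmrs, matrix) == []

    def test_matches_brute_force_recomputation(self):
        """Screen results equal a direct all-pairs recomputation."""
        rng = np.random.default_rng(6)
        spec = {}
        for i in range(3):
            spec[("chr1", 1 + 20_000 * i, 5000 + 20_000 * i, f"E{i}", "dme")] = rng.uniform(0.1, 0.9, 6)
        for j in range(6):
            spec[("chr1", 200_000 + 10_000 * j, 200_999 + 10_000 * j, f"D{j}", "dmr")] = rng.uniform(0.1, 0.9, 6)
        dmes, dmrs, matrix = _screen_setup(spec)
        out = screen_pairs(dmes, dmrs, matrix, fdr_family="pooled")
        assert len(out) == 18
        from statsmodels.stats.multitest import multipletests

        expected = {}
        ps = []
        keys = []
        for d in dmes:
            for m in dmrs:
                r = pearson_r(matrix.row(d.enhancer), matrix.row(m.window))
                keys.append((d.enhancer.key(), m.window.key()))
                expected[keys[-1]] = r
                ps.append(pearson_pvalue(r, 6))
        qmap = dict(zip(keys, multipletests(ps, method="fdr_bh")[1]))
        for rec in out:
            k = (rec.enhancer.key(), rec.partner.key())
            assert rec.r == pytest.approx(expected[k])
            assert rec.q_value == pytest.approx(qmap[k])

    def test_per_enhancer_q_monotone_and_bounded(self):
        rng = np.random.default_rng(13)
        spec = {("chr1", 1000, 5000, "E", "dme"): rng.uniform(0.1, 0.9, 6)}
        for j in range(8):
            spec[("chr1", 100_000 + 5_000 * j, 100_999 + 5_000 * j, f"D{j}", "dmr")] = (
                rng.uniform(0.1, 0.9, 6)
            )
        dmes, dmrs, matrix = _screen_setup(spec)
        out = screen_pairs(dmes, dmrs, matrix)
        by_p = sorted(out, key=lambda c: c.p_value)
        assert all(a.q_value <= b.q_value + 1e-12 for a, b in zip(by_p, by_p[1:]))
        assert all(c.q_value <= 1.0 for c in out)
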