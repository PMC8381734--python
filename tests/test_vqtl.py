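from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vqtlkit import (InsufficientGroupsError, empirical_type1,
                     genomic_lambda, levene_median_test,
                     qq_manhattan_tables, simulate_genotypes,
                     simulate_phenotype, vqtl_scan)
from vqtlkit.simulate import Block, SimConfig

from conftest import make_genotypes


class TestLeveneMedian:
    def test_hand_computed_example(self):
        """g0: (0,0,4,4), g1: (1,2,3) gives W = 160/7 on (1, 5) df."""
        y = np.array([0, 0, 4, 4, 1, 2, 3], dtype=float)
        g = np.array([0, 0, 0, 0, 1, 1, 1], dtype=float)
        rec = levene_median_test(y, g, min_group=3)
        assert rec.w == pytest.approx(float(Fraction(160, 7)), abs=1e-12)
        assert (rec.df1, rec.df2) == (1, 5)
        assert rec.group_medians == {0: 2.0, 1: 2.0}

    def test_location_shift_gives_zero_statistic(self):
        y = np.array([1, 3, 5, 7], dtype=float)
        g = np.array([0, 0, 1, 1], dtype=float)
        rec = levene_median_test(y, g, min_group=2)
        assert rec.w == 0.0 and rec.p == 1.0

    def test_matches_scipy_on_random_instances(self, rng):
        """Brown-Forsythe statistic equals the independent reference
        implementation to relative 1e-10."""
        for _ in range(1000):
            n = int(rng.integers(15, 120))
            g = rng.integers(0, 3, n)
            y = rng.standard_normal(n)
            groups = [y[g == v] for v in np.unique(g) if (g == v).sum() >= 2]
            if len(groups) < 2:
                continue
            w_ref, p_ref = stats.levene(*groups, center="median")
            rec = levene_median_test(y, g, min_group=2)
            assert rec.w == pytest.approx(w_ref, rel=1e-10)
            assert rec.p == pytest.approx(p_ref, rel=1e-8)

    def test_sparse_group_excluded_not_merged(self):
        y = np.concatenate([np.arange(10.0), np.arange(10.0) * 2, [5.0]])
        g = np.array([0] * 10 + [1] * 10 + [2])
        rec = levene_median_test(y, g, min_group=5)
        assert rec.k == 2 and rec.n == 20
        assert rec.size_of(2) == 0

    def test_too_few_groups_raises(self):
        with pytest.raises(InsufficientGroupsError):
            levene_median_test(np.arange(10.0), np.zeros(10), min_group=5)

    def test_degenerate_zero_within_flagged(self):
        y = np.array([1, 1, 1, 1, 0, 2, 0, 2], dtype=float)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        rec = levene_median_test(y, g, min_group=2)
        assert rec.degenerate and rec.p == 0.0

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_and_scale_invariance(self, shift, scale):
        """W is invariant to per-group location shifts and overall
        rescaling of the trait."""
        rng = np.random.default_rng(99)
        y = rng.standard_normal(60)
        g = rng.integers(0, 3, 60).astype(float)
        base = levene_median_test(y, g, min_group=2).w
        shifted = y + shift * (g == 1)
        assert levene_median_test(shifted * scale, g, min_group=2).w \
            == pytest.approx(base, rel=1e-9)


class TestScan:
    def _null_data(self, n=400, m=300, seed=0):
        cfg = SimConfig(n_samples=n, blocks=[Block(m, maf=(0.2, 0.5))],
                        anchor=0, partner=1, seed=seed)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        return G, y

    def test_null_pvalues_uniform(self):
        G, y = self._null_data(n=500, m=2000, seed=4)
        res = vqtl_scan(G, y)
        ks = stats.kstest(res.table["P"], "uniform")
        assert ks.pvalue > 0.001

    def test_interaction_anchor_top_of_block(self):
        """With beta_ab = 1 the anchor is the best vQTL in its LD block
        in most seeds at the study sample size."""
        from vqtlkit.simulate import config_interaction
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = config_interaction(m_partners=2, beta_ab=1.0, seed=seed)
            G = simulate_genotypes(cfg)
            y = simulate_phenotype(G, cfg).trait_values()
            res = vqtl_scan(G.take_variants(np.arange(10)), y)
            best = res.table.sort_values("P").iloc[0]["ID"]
            hits += best == "snp00004"
        assert hits >= 0.8 * n_seeds

    def test_direct_variance_effect_reaches_suggestive(self):
        """kappa = 1.3 at n = 2447 crosses the suggestive threshold in
        at least half the seeds."""
        from vqtlkit.simulate import config_pure_vqtl
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = config_pure_vqtl(m_partners=2, seed=seed)
            G = simulate_genotypes(cfg)
            y = simulate_phenotype(G, cfg).trait_values()
            rec = levene_median_test(y, G.dosage(cfg.anchor))
            hits += rec.p < 5e-7
        assert hits >= 0.5 * n_seeds

    def test_scan_order_invariance(self, rng):
        G, y = self._null_data(n=200, m=50, seed=6)
        perm = rng.permutation(G.n_variants)
        a = vqtl_scan(G, y).table.set_index("ID")
        b = vqtl_scan(G.take_variants(perm), y).table.set_index("ID")
        for vid in a.index:
            assert a.at[vid, "W"] == b.at[vid, "W"]

    def test_no_overlapping_samples_raises(self):
        G, y = self._null_data(n=50, m=5)
        import pandas as pd
        bad = pd.Series(y, index=[f"zz{i}" for i in range(50)])
        with pytest.raises(ValueError, match="overlap"):
            vqtl_scan(G, bad)


class TestGenomicLambda:
    def test_all_half_is_one(self):
        assert genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_uniform_pvalues_calibrated(self, rng):
        p = rng.uniform(size=1_000_000)
        assert 0.99 < genomic_lambda(p) < 1.01

    def test_halving_pvalues_inflates(self, rng):
        p = rng.uniform(0.2, 1.0, 500)
        assert genomic_lambda(p / 2) > genomic_lambda(p)

    def test_domain_checks(self):
        with pytest.raises(ValueError, match="p-values"):
            genomic_lambda(np.linspace(0.0, 1.0, 200))
        with pytest.raises(ValueError, match="need"):
            genomic_lambda(np.full(10, 0.5))


class TestEmpiricalType1:
    def _data(self):
        cfg = SimConfig(n_samples=300, blocks=[Block(500, maf=(0.2, 0.5))],
                        anchor=0, partner=1, seed=8)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        return G, y

    def test_threshold_one_counts_all_testable(self):
        G, y = self._data()
        counts = empirical_type1(G, y, threshold=1.01, n_perm=1, seed=0)
        assert counts[0] == len(vqtl_scan(G, y).table)

    def test_mean_count_within_binomial_ci(self):
        """Permutation counts at alpha = 0.05 agree with the binomial
        expectation across replicates."""
        G, y = self._data()
        m = len(vqtl_scan(G, y).table)
        n_perm, alpha = 20, 0.05
        counts = empirical_type1(G, y, threshold=alpha, n_perm=n_perm,
                                 seed=3)
        se = np.sqrt(alpha * (1 - alpha) * m / n_perm)
        assert abs(counts.mean() - alpha * m) < 2.58 * se

    def test_same_seed_same_counts(self):
        G, y = self._data()
        a = empirical_type1(G, y, 0.05, n_perm=3, seed=7)
        b = empirical_type1(G, y, 0.05, n_perm=3, seed=7)
        assert np.array_equal(a, b)


class TestQqManhattan:
    def test_tables_shapes_and_conventions(self):
        cfg = SimConfig(n_samples=200, blocks=[Block(40, maf=0.3)],
                        anchor=0, partner=1, seed=9)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        table = vqtl_scan(G, y).table
        qq, man = qq_manhattan_tables(table)
        n = len(table)
        assert len(qq) == n and len(man) == n
        np.testing.assert_allclose(
            qq["EXPECTED"], -np.log10((np.arange(1, n + 1) - 0.5) / n))
        assert (np.diff(qq["OBSERVED"]) <= 1e-12).all()
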