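import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from vqtlkit import (colocalize_table, gxe_tests, interaction_test,
                     levene_median_test, scan_partner,
                     sensitivity_drop_extreme, simulate_genotypes,
                     simulate_phenotype, stratified_effects,
                     stratified_vqtl, vqtl_scan)
from vqtlkit.epistasis import _cov_beta, _ols_core
from vqtlkit.preprocess import residualize
from vqtlkit.simulate import Block, SimConfig, config_interaction


def _random_instance(rng, n=200):
    gA = rng.integers(0, 3, n).astype(float)
    gB = rng.integers(0, 3, n).astype(float)
    y = (0.2 * gA - 0.1 * gB + 0.3 * gA * gB
         + rng.standard_normal(n) * rng.uniform(0.5, 2))
    return y, gA, gB


class TestInteractionTest:
    def test_exact_interpolation_degenerate(self, rng):
        gA = rng.integers(0, 3, 100).astype(float)
        gB = rng.integers(0, 3, 100).astype(float)
        y = 1.0 + 0.5 * gA * gB
        rec = interaction_test(y, gA, gB)
        assert rec.beta_ab == pytest.approx(0.5, abs=1e-10)
        assert rec.degenerate and rec.p == 0.0

    @pytest.mark.parametrize("cov_type", ["model", "HC0", "HC1", "HC2",
                                          "HC3"])
    def test_matches_statsmodels_oracle(self, rng, cov_type):
        """Coefficients and every HC-type standard error agree with the
        independent statsmodels fit to relative 1e-8."""
        sm_type = {"model": "nonrobust"}.get(cov_type, cov_type)
        for _ in range(200):
            y, gA, gB = _random_instance(rng)
            rec = interaction_test(y, gA, gB, cov_type=cov_type)
            X = sm.add_constant(np.column_stack([gA, gB, gA * gB]))
            fit = sm.OLS(y, X).fit(cov_type=sm_type)
            assert rec.beta_ab == pytest.approx(fit.params[3], rel=1e-8)
            assert rec.se_ab == pytest.approx(fit.bse[3], rel=1e-8)

    def test_robust_se_close_to_model_when_homoscedastic(self, rng):
        n = 5000
        gA = rng.binomial(2, 0.3, n).astype(float)
        gB = rng.binomial(2, 0.4, n).astype(float)
        y = 0.1 * gA + 0.1 * gB + rng.standard_normal(n)
        r_model = interaction_test(y, gA, gB, cov_type="model")
        r_hc3 = interaction_test(y, gA, gB, cov_type="HC3")
        assert 0.97 < r_hc3.se_ab / r_model.se_ab < 1.03

    def test_symmetric_in_arguments(self, rng):
        y, gA, gB = _random_instance(rng)
        a = interaction_test(y, gA, gB)
        b = interaction_test(y, gB, gA)
        assert a.beta_ab == pytest.approx(b.beta_ab, rel=1e-12)
        assert a.se_ab == pytest.approx(b.se_ab, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_collinear_pair_raises(self, rng):
        gA = rng.integers(0, 3, 100).astype(float)
        y = rng.standard_normal(100)
        with pytest.raises(np.linalg.LinAlgError):
            interaction_test(y, gA, 2 - gA)

    def test_hc0_equals_model_for_constant_squared_residuals(self, rng):
        """With equal e_i^2 the sandwich collapses onto sigma^2 (X'X)^-1
        up to the df weight."""
        n = 50
        gA = rng.integers(0, 3, n).astype(float)
        gB = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), gA, gB, gA * gB])
        _, resid, xtx_inv, _ = _ols_core(X, y)
        e = np.where(resid >= 0, 1.0, -1.0)  # |e_i| identical
        hc0 = _cov_beta(X, e, xtx_inv, float(e @ e), "HC0")
        model = _cov_beta(X, e, xtx_inv, float(e @ e), "model")
        np.testing.assert_allclose(hc0, model * (n - 4) / n, atol=1e-10)


class TestScanPartner:
    def test_true_partner_ranks_first(self):
        for seed in (0, 1):
            cfg = config_interaction(m_partners=200, seed=seed)
            G = simulate_genotypes(cfg)
            res = residualize(simulate_phenotype(G, cfg))
            table, _ = scan_partner(G, res, "snp00004")
            assert table.sort_values("P").iloc[0]["ID_B"] == "snp00010"

    def test_null_phenotype_calibrated(self):
        cfg = SimConfig(n_samples=1000, blocks=[Block(1, maf=0.3),
                                                Block(400, maf=(0.2, 0.5))],
                        anchor=0, partner=1, seed=12)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        table, _ = scan_partner(G, y, "snp00000", robust_policy="never")
        frac = float((table["P"] < 0.05).mean())
        m = len(table)
        assert abs(frac - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / m)

    def test_high_ld_partners_excluded(self):
        cfg = SimConfig(n_samples=800,
                        blocks=[Block(3, maf=0.3, rho=1 - 1e-12),
                                Block(5, maf=0.3)],
                        anchor=0, partner=3, seed=13)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        table, diag = scan_partner(G, y, "snp00000")
        assert len(diag["excluded"]) >= 2
        assert not set(diag["excluded"]["ID"]) & set(table["ID_B"])

    def test_monomorphic_anchor_raises(self):
        cfg = SimConfig(n_samples=50, blocks=[Block(3, maf=0.3)],
                        anchor=0, partner=1, seed=14)
        G = simulate_genotypes(cfg)
        G.calls[:, 0] = 1
        y = simulate_phenotype(G, cfg).trait_values()
        with pytest.raises(ValueError, match="monomorphic"):
            scan_partner(G, y, "snp00000")


class TestStratifiedEffects:
    def test_opposite_slopes_cancel_in_combined_sample(self):
        """beta_b=-1, beta_ab=1: stratum slopes -1, 0, +1; the combined
        slope is beta_b + beta_ab * E[gA] ~ 0 at p_A = 0.5."""
        cfg = SimConfig(n_samples=20_000,
                        blocks=[Block(1, maf=0.5), Block(1, maf=0.5)],
                        anchor=0, partner=1, beta_b=-1.0, beta_ab=1.0,
                        seed=15)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        gA, gB = G.dosage(0), G.dosage(1)
        table = stratified_effects(y, gA, gB)
        for a, expect in zip((0, 1, 2), (-1.0, 0.0, 1.0)):
            row = table[table["STRATUM_GENO"] == a].iloc[0]
            assert abs(row["BETA_B"] - expect) < 3 * row["SE"]
        combined = table[table["STRATUM_GENO"] == "all"].iloc[0]
        assert abs(combined["BETA_B"]) < 3 * combined["SE"]

    def test_no_interaction_slopes_homogeneous(self):
        cfg = SimConfig(n_samples=5000,
                        blocks=[Block(1, maf=0.4), Block(1, maf=0.4)],
                        anchor=0, partner=1, beta_b=0.3, seed=16)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        table = stratified_effects(y, G.dosage(0), G.dosage(1))
        strata = table[table["STRATUM_GENO"] != "all"].dropna()
        w = 1 / strata["SE"] ** 2
        pooled = np.sum(w * strata["BETA_B"]) / np.sum(w)
        chi2 = float(np.sum(w * (strata["BETA_B"] - pooled) ** 2))
        assert stats.chi2.sf(chi2, len(strata) - 1) > 0.001

    def test_stratum_sizes_partition_sample(self, rng):
        y, gA, gB = _random_instance(rng, n=500)
        table = stratified_effects(y, gA, gB)
        strata = table[table["STRATUM_GENO"] != "all"]
        assert strata["N"].sum() == 500


class TestStratifiedVqtl:
    def test_downsampling_deterministic_and_balanced(self):
        cfg = config_interaction(m_partners=2, seed=17)
        G = simulate_genotypes(cfg)
        res = residualize(simulate_phenotype(G, cfg))
        gB = G.dosage("snp00010")
        Gl = G.take_variants(np.arange(10))
        a = stratified_vqtl(Gl, res, gB, downsample=True, seed=5)
        b = stratified_vqtl(Gl, res, gB, downsample=True, seed=5)
        sizes = {k: int(v.table["N"].iloc[0]) for k, v in a.items()}
        assert len(set(sizes.values())) == 1
        for k in a:
            pd.testing.assert_frame_equal(a[k].table, b[k].table)

    def test_small_stratum_skipped(self, rng):
        cfg = SimConfig(n_samples=300, blocks=[Block(3, maf=0.3)],
                        anchor=0, partner=1, seed=18)
        G = simulate_genotypes(cfg)
        y = simulate_phenotype(G, cfg).trait_values()
        gB = np.zeros(300)
        gB[:5] = 2  # a stratum far below 3 * min_group
        out = stratified_vqtl(G, y, gB, min_group=5)
        assert 2 not in out and 0 in out


class TestGxe:
    def test_joint_test_detects_main_effect(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 2447
            g = rng.binomial(2, 0.3, n).astype(float)
            E = rng.standard_normal(n)
            y = 0.3 * g + rng.standard_normal(n)
            _, rec2 = gxe_tests(y, g, E)
            hits += rec2["p"] < 0.01
        assert hits >= 9

    def test_null_calibration_of_both_tests(self):
        p1, p2 = [], []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            g = rng.binomial(2, 0.3, n).astype(float)
            E = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rec1, rec2 = gxe_tests(y, g, E, cov_type="model")
            p1.append(rec1.p)
            p2.append(rec2["p"])
        for p in (p1, p2):
            frac = np.mean(np.array(p) < 0.05)
            assert abs(frac - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / 200)

    def test_constant_exposure_raises(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        with pytest.raises(np.linalg.LinAlgError):
            gxe_tests(rng.standard_normal(100), g, np.ones(100))


class TestColocalize:
    def _records(self, seed=0):
        cfg = config_interaction(m_partners=50, seed=seed)
        G = simulate_genotypes(cfg)
        res = residualize(simulate_phenotype(G, cfg))
        scan = vqtl_scan(G, res, min_group=5)
        epi, _ = scan_partner(G, res, "snp00010")  # anchor at the partner
        return G, scan.table, epi

    def test_lead_row_has_unit_r2(self):
        G, vtab, etab = self._records()
        table = colocalize_table(vtab, etab, "snp00004", G)
        assert table.set_index("ID").at["snp00004", "R2_LEAD"] == 1.0

    def test_disjoint_sets_give_empty_table(self):
        G, vtab, etab = self._records()
        empty = colocalize_table(vtab.iloc[:0], etab, "snp00004", G)
        assert len(empty) == 0

    def test_signals_colocalize_under_interaction(self):
        """Variance and interaction -log10 p co-vary across the anchor
        LD block when the interaction drives the variance signal."""
        rhos = []
        for seed in range(20):
            G, vtab, etab = self._records(seed)
            table = colocalize_table(vtab, etab, "snp00004", G,
                                     window_bp=100_000)
            block = table[table["ID"].str.match("snp0000")]
            rho = stats.spearmanr(block["NEGLOG10P_VQTL"],
                                  block["NEGLOG10P_INT"]).statistic
            rhos.append(rho)
        assert np.median(rhos) > 0.5

    def test_absent_lead_raises(self):
        G, vtab, etab = self._records()
        with pytest.raises(ValueError, match="absent"):
            colocalize_table(vtab, etab, "nope", G)


class TestSensitivity:
    def test_n_decreases_by_one_and_stability(self):
        cfg = config_interaction(m_partners=2, seed=19)
        G = simulate_genotypes(cfg)
        res = residualize(simulate_phenotype(G, cfg))
        y = res.series().reindex(G.samples).to_numpy()
        gA = G.dosage("snp00004")
        out = sensitivity_drop_extreme(y, {
            "levene": lambda idx: levene_median_test(y[idx], gA[idx]).p})
        row = out.iloc[0]
        assert row["N_AFTER"] == row["N_BEFORE"] - 1
        # stability: the log-p shift is small relative to the signal depth
        shift = abs(np.log10(row["P_AFTER"]) - np.log10(row["P_BEFORE"]))
        assert shift < max(0.5, 0.15 * abs(np.log10(row["P_BEFORE"])))

    def test_outlier_drives_spurious_signal(self, rng):
        """An 8 SD outlier in the minor-homozygote group creates a Levene
        signal that vanishes when the observation is removed."""
        n = 500
        g = rng.binomial(2, 0.25, n).astype(float)
        y = rng.standard_normal(n)
        j = int(np.flatnonzero(g == 2)[0])
        y[j] = 8.0
        out = sensitivity_drop_extreme(y, {
            "levene": lambda idx: levene_median_test(y[idx], g[idx]).p})
        row = out.iloc[0]
        assert row["DROPPED_INDEX"] == j
        assert row["P_AFTER"] > row["P_BEFORE"]
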