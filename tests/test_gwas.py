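"""Mixed-model association machinery against analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hapcross as hc
from conftest import make_geno
from hapcross.datatypes import MISSING, HaplotypeBlock
from hapcross.gwas import (
    block_design,
    empirical_threshold,
    fit_null_mlm,
    genomic_inflation,
    kinship,
    pca_covariates,
    qq_deviation,
    select_pcs_bic,
    snp_design,
)
from hapcross.gwas import test_feature as feature_test


def random_inbred_panel(n_lines, n_markers, seed):
    rng = np.random.default_rng(seed)
    return make_geno(rng.choice([0, 2], size=(n_lines, n_markers))
                     .astype(np.int8))


class TestKinship:
    def test_duplicated_line_off_diagonal_equals_diagonal(self):
        G0 = random_inbred_panel(10, 200, 0)
        calls = np.vstack([G0.calls, G0.calls[:1]])
        G = make_geno(calls)
        K = kinship(G)
        assert K[0, 10] == pytest.approx(K[0, 0])

    def test_unrelated_founders_near_zero_off_diagonal(self):
        G = random_inbred_panel(30, 2000, 1)
        K = kinship(G)
        off = K[np.triu_indices_from(K, k=1)]
        # centering on estimated frequencies forces row sums to ~0, so
        # unrelated off-diagonals center on -mean(diag)/(n-1), not 0
        bias = -np.diag(K).mean() / (G.n_lines - 1)
        se = 2.0 / np.sqrt(2000)  # inbred dosages: var of mean product
        assert abs(off.mean() - bias) < 3 * se / np.sqrt(len(off))
        assert np.abs(off - bias).max() < 6 * se

    def test_psd_and_marker_order_invariance(self):
        G = random_inbred_panel(15, 100, 2)
        K = kinship(G)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        perm = np.random.default_rng(0).permutation(G.n_markers)
        G2 = make_geno(G.calls[:, perm])
        np.testing.assert_allclose(kinship(G2), K, atol=1e-10)

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            kinship(make_geno([[0], [2]]))


class TestPCA:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        a = rng.choice([0, 2], size=(25, 300), p=[0.8, 0.2])
        b = rng.choice([0, 2], size=(25, 300), p=[0.2, 0.8])
        G = make_geno(np.vstack([a, b]).astype(np.int8))
        pcs = pca_covariates(G, 2)
        from sklearn.metrics import silhouette_score

        labels = np.array([0] * 25 + [1] * 25)
        assert silhouette_score(pcs[:, :1], labels) > 0.8

    def test_k_zero_gives_empty_design(self):
        G = random_inbred_panel(10, 20, 4)
        assert pca_covariates(G, 0).shape == (10, 0)

    def test_variance_explained_non_increasing(self):
        G = random_inbred_panel(20, 50, 5)
        pcs = pca_covariates(G, 5)
        v = pcs.var(axis=0)
        assert np.all(np.diff(v) <= 1e-9)

    def test_k_at_least_n_rejected(self):
        G = random_inbred_panel(5, 20, 6)
        with pytest.raises(ValueError):
            pca_covariates(G, 5)

    def test_deterministic_sign(self):
        G = random_inbred_panel(12, 40, 7)
        np.testing.assert_allclose(pca_covariates(G, 3),
                                   pca_covariates(G, 3))


class TestNullMLM:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(8)
        n = 60
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = fit_null_mlm(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        resid = y - X @ beta_ols
        reml_var = resid @ resid / (n - 2)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(reml_var,
                                                            rel=1e-4)

    def test_heritability_recovery_on_polygenic_trait(self):
        rng = np.random.default_rng(9)
        G = random_inbred_panel(300, 800, 10)
        K = kinship(G)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(300))
        hits = 0
        for rep in range(10):
            u = L @ rng.normal(size=300)
            u = u / u.std() * np.sqrt(0.5)
            y = u + rng.normal(scale=np.sqrt(0.5), size=300)
            fit = fit_null_mlm(y, np.ones((300, 1)), K)
            h2 = fit.sigma_g2 * np.diag(K).mean() / (
                fit.sigma_g2 * np.diag(K).mean() + fit.sigma_e2)
            hits += 0.3 <= h2 <= 0.7
        assert hits >= 8

    def test_constant_trait_handled(self):
        fit = fit_null_mlm(np.ones(30), np.ones((30, 1)), np.eye(30))
        assert fit.sigma_g2 == 0.0 and fit.sigma_e2 == 0.0


class TestSelectPCs:
    def test_kmax_zero_returns_zero(self):
        G = random_inbred_panel(40, 60, 11)
        y = np.random.default_rng(0).normal(size=40)
        assert select_pcs_bic(y, G, kinship(G), k_max=0) == 0

    def test_unstructured_trait_prefers_zero_pcs(self):
        G = random_inbred_panel(100, 300, 12)
        K = kinship(G)
        rng = np.random.default_rng(13)
        zeros = sum(select_pcs_bic(rng.normal(size=100), G, K, k_max=3) == 0
                    for _ in range(20))
        assert zeros >= 18

    def test_pc_driven_trait_selects_at_least_one(self):
        rng = np.random.default_rng(14)
        a = rng.choice([0, 2], size=(50, 300), p=[0.85, 0.15])
        b = rng.choice([0, 2], size=(50, 300), p=[0.15, 0.85])
        G = make_geno(np.vstack([a, b]).astype(np.int8))
        pcs = pca_covariates(G, 1)
        y = pcs[:, 0] / pcs[:, 0].std() + rng.normal(scale=0.1, size=100)
        assert select_pcs_bic(y, G, kinship(G), k_max=3) >= 1

    def test_nonfinite_trait_rejected(self):
        G = random_inbred_panel(30, 50, 15)
        y = np.full(30, np.nan)
        with pytest.raises(ValueError):
            select_pcs_bic(y, G, kinship(G))


def _three_class_block(n, seed):
    rng = np.random.default_rng(seed)
    labels = rng.choice(["AA", "AT", "TT"], size=n, p=[0.5, 0.3, 0.2])
    blk = HaplotypeBlock("HB1.1", "1A", ["m1", "m2"], 0.0, 1.0,
                         assignments={f"L{i + 1}": c
                                      for i, c in enumerate(labels)})
    return blk, labels


class TestFeatureTest:
    def test_equals_one_way_anova_under_identity_kinship(self):
        n = 90
        blk, labels = _three_class_block(n, 16)
        rng = np.random.default_rng(17)
        y = rng.normal(size=n) + (labels == "TT") * 0.8
        line_ids = [f"L{i + 1}" for i in range(n)]
        X = np.ones((n, 1))
        K = np.eye(n)
        fit = fit_null_mlm(y, X, K)
        design, classes, ref = block_design(blk, line_ids)
        res = feature_test(y, X, K, fit, design, "HB1.1",
                           class_labels=classes)
        groups = [y[labels == g] for g in ("AA", "AT", "TT")]
        f_oracle, p_oracle = stats.f_oneway(*groups)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)
        assert res.df == 2

    def test_single_class_feature_degenerate(self):
        n = 40
        blk = HaplotypeBlock("HB1.1", "1A", ["m1"], 0.0, 0.0,
                             assignments={f"L{i + 1}": "A" for i in range(n)})
        y = np.random.default_rng(0).normal(size=n)
        design, classes, _ = block_design(blk, [f"L{i + 1}" for i in range(n)])
        res = feature_test(y, np.ones((n, 1)), np.eye(n),
                           fit_null_mlm(y, np.ones((n, 1)), np.eye(n)),
                           design, class_labels=classes)
        assert res.p_value == 1.0 and res.df == 0

    def test_missing_lines_dropped_per_feature(self):
        n = 50
        blk, labels = _three_class_block(n, 18)
        # unassign 10 lines
        for i in range(10):
            blk.assignments.pop(f"L{i + 1}", None)
        y = np.random.default_rng(1).normal(size=n)
        design, classes, _ = block_design(blk, [f"L{i + 1}" for i in range(n)])
        res = feature_test(y, np.ones((n, 1)), np.eye(n),
                           fit_null_mlm(y, np.ones((n, 1)), np.eye(n)),
                           design, class_labels=classes)
        assert res.n == n - 10

    def test_rare_classes_pooled(self):
        labels = ["AA"] * 95 + ["AT"] * 3 + ["TT"] * 1 + ["GG"] * 1
        blk = HaplotypeBlock("HB1.1", "1A", ["m1"], 0.0, 0.0,
                             assignments={f"L{i + 1}": c
                                          for i, c in enumerate(labels)})
        design, classes, ref = block_design(
            blk, [f"L{i + 1}" for i in range(100)], pool_threshold=0.02)
        assert ref == "AA"
        assert set(classes) == {"AT", "rare-other"}

    def test_snp_design_missing_to_nan(self):
        G = make_geno([[0], [2], [MISSING]])
        d = snp_design(G, "m1", G.line_ids)
        assert d[0, 0] == 0 and d[1, 0] == 2 and np.isnan(d[2, 0])


class TestThresholdAndQQ:
    def test_empirical_threshold_is_bottom_order_statistic(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=1000)
        assert empirical_threshold(p, 0.1) == pytest.approx(p.min())

    def test_fixed_threshold_semantics(self, scenario_scan):
        res = scenario_scan.results_
        sig = res[res["significant"]]
        assert (sig["p_value"] <= sig["threshold"]).all()
        assert sig["qq_deviates"].all()

    def test_degenerate_all_ones(self):
        p = np.ones(2000)
        assert empirical_threshold(p) == 1.0
        with pytest.raises(ValueError):
            empirical_threshold([])

    def test_qq_uniform_flags_about_five_percent(self):
        rng = np.random.default_rng(20)
        rates = [qq_deviation(rng.uniform(size=500)).mean()
                 for _ in range(20)]
        assert np.mean(rates) == pytest.approx(0.05, abs=0.04)

    def test_qq_planted_signal_flagged(self):
        rng = np.random.default_rng(21)
        p = np.concatenate([[1e-8], rng.uniform(size=499)])
        assert qq_deviation(p)[0]

    def test_qq_needs_twenty_tests(self):
        with pytest.raises(ValueError):
            qq_deviation(np.full(10, 0.5))

    def test_genomic_inflation_near_one_under_corrected_null(self, scenario,
                                                             scenario_filtered):
        """Structured polygenic null trait: kinship-corrected scan keeps
        lambda close to 1."""
        sc = scenario
        Gf = scenario_filtered[0]
        spec = hc.QTLSpec(trait="null_trait", qtls=(),
                          environment_means={"e1": 0.0},
                          polygenic_var=1.0, residual_var=1.0)
        tab = hc.simulate_phenotypes(Gf, spec, seed=77)
        scan = hc.MixedModelScan(k_max=0, include_snps=True)
        scan.fit([], Gf, tab, trait_names=["null_trait"])
        lam = genomic_inflation(scan.results_["p_value"])
        assert 0.9 <= lam <= 1.1


class TestScanProperties:
    def test_scan_invariant_to_line_order(self, scenario, scenario_filtered,
                                          scenario_blocks, scenario_scan):
        sc = scenario
        Gf = scenario_filtered[0]
        rng = np.random.default_rng(4)
        order = rng.permutation(Gf.n_lines)
        G2 = hc.GenotypeMatrix([Gf.line_ids[i] for i in order],
                               Gf.marker_ids, Gf.calls[order], Gf.alleles)
        scan2 = hc.MixedModelScan(k_max=2).fit(
            scenario_blocks, G2, sc.phenotypes)
        a = scenario_scan.results_.sort_values(
            ["feature", "trait", "environment"]).reset_index(drop=True)
        b = scan2.results_.sort_values(
            ["feature", "trait", "environment"]).reset_index(drop=True)
        # eigendecomposition and the 1-D variance-ratio optimizer introduce
        # order-dependent floating-point noise; the scan is invariant up to
        # that, and the significance calls must match exactly
        pd.testing.assert_series_equal(a["p_value"], b["p_value"],
                                       atol=1e-6, rtol=1e-4)
        assert (a["significant"] == b["significant"]).all()

    def test_power_rises_with_effect_size(self):
        """Detection p-value of the planted haplotype falls monotonically
        as its effect grows (paired seeds)."""
        pvals = []
        for effect in (0.4, 0.8, 1.6):
            ps = []
            for seed in (101, 102, 103):
                sc = hc.planted_scenario(seed, effect_sd=effect)
                blk = hc.assign_classes(
                    hc.HaplotypeBlock("P", "1B",
                                      list(sc.planted_markers), 0, 1),
                    sc.genotypes)
                y = sc.phenotypes.vector("grain_yield", "heat")
                lines = [l for l in sc.genotypes.line_ids if l in y.index]
                yv = y.loc[lines].to_numpy()
                K = hc.kinship(sc.genotypes)
                idx = [sc.genotypes.line_index(l) for l in lines]
                Ksub = K[np.ix_(idx, idx)]
                X = np.ones((len(lines), 1))
                fit = fit_null_mlm(yv, X, Ksub)
                design, classes, _ = block_design(blk, lines)
                res = feature_test(yv, X, Ksub, fit, design,
                                   class_labels=classes)
                ps.append(res.p_value)
            pvals.append(np.median(ps))
        assert pvals[0] > pvals[1] > pvals[2]

    def test_ols_oracle_with_zero_genetic_variance(self, scenario,
                                                   scenario_filtered,
                                                   scenario_blocks):
        """With sigma_g^2 forced to 0 the GLS scan equals plain OLS."""
        Gf = scenario_filtered[0]
        blk = scenario_blocks[0]
        y = scenario.phenotypes.vector("grain_yield", "heat")
        lines = [l for l in Gf.line_ids if l in y.index]
        yv = y.loc[lines].to_numpy()
        K = hc.kinship(Gf)
        idx = [Gf.line_index(l) for l in lines]
        Ksub = K[np.ix_(idx, idx)]
        X = np.ones((len(lines), 1))
        from hapcross.gwas import MLMFit

        s, U = np.linalg.eigh(Ksub)
        forced = MLMFit(0.0, 1.0, 0.0, 0.0, 0, np.zeros(1),
                        np.clip(s, 0, None), U)
        design, classes, _ = block_design(blk, lines)
        res = feature_test(yv, X, Ksub, forced, design, class_labels=classes)
        keep = ~np.isnan(design).any(axis=1)
        groups = {}
        for lab, val in zip(np.array(lines)[keep], yv[keep]):
            groups.setdefault(blk.assignments[lab], []).append(val)
        f_oracle, p_oracle = stats.f_oneway(*groups.values())
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)
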