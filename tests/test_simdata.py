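"""Tests of the synthetic-data generator: LD structure, null calibration,
factor-mediated signal propagation, overlap-induced error correlation."""

import numpy as np
import pytest

from polyfactor.simdata import (LDPanel, TrueGenerativeModel, make_ld_panel,
                                null_model, polygenic_model,
                                simulate_multitrait_sumstats,
                                simulate_qtl_sumstats)


class TestMakeLDPanel:
    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            make_ld_panel(10, 5, 5, 0.5, seed=0)       # n_ref too small
        with pytest.raises(ValueError):
            make_ld_panel(100, 0, 5, 0.5, seed=0)
        with pytest.raises(ValueError):
            make_ld_panel(100, 5, 5, 1.0, seed=0)      # rho outside [0,1)
        with pytest.raises(ValueError):
            make_ld_panel(100, 5, 5, -0.1, seed=0)

    def test_determinism(self):
        a = make_ld_panel(100, 5, 10, 0.5, seed=42)
        b = make_ld_panel(100, 5, 10, 0.5, seed=42)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_independent_variants_uncorrelated(self):
        panel = make_ld_panel(1000, 4, 10, 0.0, seed=1)
        R = panel.empirical_corr(np.arange(panel.m))
        off = R[~np.eye(panel.m, dtype=bool)]
        assert np.max(np.abs(off)) < 4.0 / np.sqrt(panel.n_ref)

    def test_ar1_adjacent_correlation(self):
        # oracle: the generating haplotype copy-chain has corr rho at lag 1
        rho = 0.9
        panel = make_ld_panel(1000, 10, 20, rho, seed=2)
        rs = []
        for b in range(panel.n_blocks):
            idx = panel.block_indices(b)
            R = panel.empirical_corr(idx)
            rs.extend(R[i, i + 1] for i in range(idx.size - 1))
        assert abs(np.mean(rs) - rho) < 0.02

    def test_ar1_lag_profile_matches_power_law(self):
        rho = 0.7
        panel = make_ld_panel(2000, 10, 15, rho, seed=3)
        for lag in (2, 4):
            rs = []
            for b in range(panel.n_blocks):
                idx = panel.block_indices(b)
                R = panel.empirical_corr(idx)
                rs.extend(R[i, i + lag] for i in range(idx.size - lag))
            assert abs(np.mean(rs) - rho ** lag) < 0.03

    def test_freqs_match_genotype_means(self, small_panel):
        emp = small_panel.genotypes.mean(axis=0) / 2.0
        assert np.max(np.abs(emp - small_panel.freqs)) < \
            4.0 / np.sqrt(small_panel.n_ref)

    def test_positions_strictly_increasing_within_chromosome(self, small_panel):
        for c in np.unique(small_panel.chrom):
            pos = small_panel.positions[small_panel.chrom == c]
            assert np.all(np.diff(pos) > 0)

    def test_cross_block_independence(self):
        panel = make_ld_panel(2000, 6, 10, 0.8, seed=4)
        g = panel.genotypes.astype(float)
        R = np.corrcoef(g, rowvar=False)
        cross = np.abs(R[panel.block_map[:, None] != panel.block_map[None, :]])
        assert cross.mean() < 0.03


class TestGenerativeModel:
    def test_rejects_non_psd_implied_covariance(self):
        with pytest.raises(ValueError):
            TrueGenerativeModel(
                loadings=np.array([[1.0], [1.0]]), factor_cov=np.eye(1),
                residual_var=np.array([-2.0, 0.1]),
                snp_factor_effects=np.zeros((5, 1)),
                snp_direct_effects=np.zeros((5, 2)),
                trait_neff=np.array([1e4, 1e4]),
                trait_names=["A", "B"], factor_names=["F"])

    def test_dimension_mismatch_rejected(self, small_panel):
        model = null_model(small_panel, 2, [1e4, 1e4])
        model.snp_factor_effects = model.snp_factor_effects[:-1]
        with pytest.raises(ValueError):
            simulate_multitrait_sumstats(small_panel, model, seed=0)

    def test_plant_variant_labels(self, small_panel):
        model = polygenic_model(small_panel, [[0.5], [0.5]], [[1.0]],
                                [0.1, 0.1], [1e4, 1e4], ["A", "B"], ["F"],
                                seed=0)
        model.plant_variant(3, gamma=[0.1])
        model.plant_variant(5, gamma=[0.0], delta=[0.1, 0.0])
        assert model.labels[3] == "specific"
        assert model.labels[5] == "heterogeneous"
        # factor-consistent variants carry no direct effects
        consistent = model.labels != "heterogeneous"
        assert np.allclose(model.snp_direct_effects[3], 0)
        assert consistent[3]


class TestSimulateMultitrait:
    def test_null_traits_standard_normal(self):
        panel = make_ld_panel(200, 600, 20, 0.3, seed=5)
        model = null_model(panel, 3, [5e4] * 3)
        tables, _ = simulate_multitrait_sumstats(panel, model, seed=6)
        for tab in tables.values():
            chi2 = (tab["BETA"] / tab["SE"]) ** 2
            assert 0.95 < chi2.mean() < 1.05

    def test_factor_signal_propagates_to_loading_traits_only(self):
        # oracle: E[z] = Lambda @ gamma * sqrt(N)
        panel = make_ld_panel(200, 50, 1, 0.0, seed=7)
        k, q = 9, 3
        Lam = np.zeros((k, q))
        Lam[:3, 0] = 0.6       # three gut traits on factor 1
        Lam[3:7, 1] = 0.6
        Lam[7:, 2] = 0.6
        gamma = np.zeros((panel.m, q))
        gamma[10, 0] = 0.08
        model = TrueGenerativeModel(
            loadings=Lam, factor_cov=np.eye(q),
            residual_var=np.full(k, 0.05),
            snp_factor_effects=gamma, snp_direct_effects=np.zeros((panel.m, k)),
            trait_neff=np.full(k, 5e4),
            trait_names=[f"T{i}" for i in range(k)],
            factor_names=["F1", "F2", "F3"])
        zs = np.zeros((20, k))
        for r in range(20):
            tables, _ = simulate_multitrait_sumstats(panel, model, seed=100 + r)
            zs[r] = [tables[f"T{i}"]["BETA"][10] / tables[f"T{i}"]["SE"][10]
                     for i in range(k)]
        expected = Lam @ gamma[10] * np.sqrt(5e4)
        assert np.allclose(zs.mean(axis=0), expected, atol=1.5)
        assert np.all(np.abs(zs.mean(axis=0)[3:]) < 1.5)   # other traits null

    def test_full_overlap_duplicated_traits_correlate(self):
        panel = make_ld_panel(200, 2000, 1, 0.0, seed=8)
        model = null_model(panel, 2, [2e4, 2e4],
                           overlap_frac=np.array([[1, 1.0], [1.0, 1]]),
                           overlap_pheno_corr=np.array([[1, 1.0], [1.0, 1]]))
        tables, _ = simulate_multitrait_sumstats(panel, model, seed=9)
        za = tables["T1"]["BETA"] / tables["T1"]["SE"]
        zb = tables["T2"]["BETA"] / tables["T2"]["SE"]
        assert np.corrcoef(za, zb)[0, 1] > 0.999

    def test_partial_overlap_error_correlation(self):
        panel = make_ld_panel(200, 5000, 1, 0.0, seed=10)
        c = 0.3
        model = null_model(panel, 2, [2e4, 2e4],
                           overlap_frac=np.array([[1, 0.5], [0.5, 1]]),
                           overlap_pheno_corr=np.array([[1, 0.6], [0.6, 1]]))
        tables, _ = simulate_multitrait_sumstats(panel, model, seed=11)
        za = tables["T1"]["BETA"] / tables["T1"]["SE"]
        zb = tables["T2"]["BETA"] / tables["T2"]["SE"]
        assert abs(np.corrcoef(za, zb)[0, 1] - c) < 0.05

    def test_causal_covariance_converges_to_target(self):
        panel = make_ld_panel(60, 1000, 20, 0.2, seed=12)
        _, Lam, Phi, Theta = _immune_like_structure()
        model = polygenic_model(panel, Lam, Phi, Theta, np.full(9, 5e4),
                                [f"T{i}" for i in range(9)],
                                ["F1", "F2", "F3"], seed=13)
        b = model.joint_effects()
        emp = b.T @ b     # summed per-variant causal covariance
        target = model.implied_cov()
        assert np.max(np.abs(emp - target)) < 0.1 * np.max(np.abs(target))


def _immune_like_structure():
    Lam = np.zeros((9, 3))
    Lam[:3, 0] = 0.45
    Lam[3:7, 1] = 0.42
    Lam[7:, 2] = 0.44
    Phi = np.full((3, 3), 0.25)
    np.fill_diagonal(Phi, 1.0)
    return None, Lam, Phi, np.full(9, 0.10)


class TestSimulateQTL:
    def test_unknown_variant_rejected(self, small_panel):
        with pytest.raises(KeyError):
            simulate_qtl_sumstats(small_panel, "rs999999", 0.3, 1000, seed=0)

    def test_none_is_pure_noise(self, small_panel):
        tab = simulate_qtl_sumstats(small_panel, "none", 0.3, 1000, seed=1)
        chi2 = (tab["BETA"] / tab["SE"]) ** 2
        assert 0.8 < chi2.mean() < 1.2

    def test_zero_effect_matches_none_distribution(self, small_panel):
        tab = simulate_qtl_sumstats(small_panel, "rs5", 0.0, 1000, seed=2)
        chi2 = (tab["BETA"] / tab["SE"]) ** 2
        assert 0.8 < chi2.mean() < 1.2

    def test_causal_variant_carries_signal(self, small_panel):
        tab = simulate_qtl_sumstats(small_panel, "rs10", 0.35, 1000, seed=3)
        z = (tab["BETA"] / tab["SE"]).to_numpy()
        j = small_panel.index_of("rs10")
        assert abs(z[j]) > 6
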