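"""Factor-level GWAS tests: covariance augmentation, SNP-effect estimation,
Q_SNP calibration and invariances."""

import numpy as np
import pytest
from scipy import stats

from polyfactor import factor_model as fm
from polyfactor.factor_gwas import (expand_covariance, estimate_snp_effects,
                                    q_snp, run_factor_gwas)
from polyfactor.ldsc import GeneticCovarianceEstimate
from polyfactor.simdata import (TrueGenerativeModel, make_ld_panel,
                                simulate_multitrait_sumstats)


@pytest.fixture(scope="module")
def fitted_truth(nine_trait_structure):
    """A fitted model object constructed from the true architecture."""
    traits, Lam, Phi, Theta = nine_trait_structure
    S = Lam @ Phi @ Lam.T + np.diag(Theta)
    est = GeneticCovarianceEstimate(S=S, V=np.eye(45) * 1e-4,
                                    intercepts=np.eye(9),
                                    trait_names=traits, n_blocks=200)
    spec = fm.ModelSpec(factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                                 "F_alrg": traits[7:]}, trait_names=traits)
    return est, fm.fit_wls(est, spec)


class TestExpandCovariance:
    def test_null_variant_zero_snp_trait_covariance(self, fitted_truth):
        est, _ = fitted_truth
        aug = expand_covariance(est, np.zeros(9), np.full(9, 0.01), 0.3)
        assert np.allclose(aug.snp_trait_cov, 0.0)

    def test_covariance_is_beta_times_snp_variance(self, fitted_truth):
        est, _ = fitted_truth
        beta = np.zeros(9)
        beta[0] = 0.1
        aug = expand_covariance(est, beta, np.full(9, 0.01), 0.5)
        # 0.1 * 2 * 0.5 * 0.5 = 0.05
        assert aug.snp_trait_cov[0] == pytest.approx(0.05)
        assert aug.var_snp == pytest.approx(0.5)

    def test_augmented_matrix_contains_original_as_leading_block(
            self, fitted_truth):
        est, _ = fitted_truth
        aug = expand_covariance(est, np.full(9, 0.02), np.full(9, 0.01), 0.3)
        assert np.allclose(aug.S_star[:9, :9], est.S)
        assert np.allclose(aug.S_star, aug.S_star.T)

    def test_missing_statistics_rejected(self, fitted_truth):
        est, _ = fitted_truth
        beta = np.full(9, 0.02)
        beta[3] = np.nan
        with pytest.raises(ValueError):
            expand_covariance(est, beta, np.full(9, 0.01), 0.3)


def _simulate_snp_tables(Lam, Phi, Theta, gamma, delta, n, m, seed,
                         error_corr=None):
    """m independent variants under the given per-variant architecture."""
    panel = make_ld_panel(200, m, 1, 0.0, seed=seed)
    k, q = Lam.shape
    frac = np.eye(k) if error_corr is None else (error_corr != 0) * 1.0
    pc = np.eye(k) if error_corr is None else error_corr
    model = TrueGenerativeModel(
        loadings=Lam, factor_cov=Phi, residual_var=Theta,
        snp_factor_effects=np.tile(gamma, (panel.m, 1)),
        snp_direct_effects=np.tile(delta, (panel.m, 1)),
        trait_neff=np.full(k, n),
        trait_names=[f"T{i}" for i in range(k)],
        factor_names=[f"F{j}" for j in range(q)],
        overlap_frac=frac, overlap_pheno_corr=pc)
    tables, _ = simulate_multitrait_sumstats(panel, model, seed=seed + 1)
    beta = np.column_stack([tables[f"T{i}"]["BETA"] for i in range(k)])
    se = np.column_stack([tables[f"T{i}"]["SE"] for i in range(k)])
    freq = tables["T0"]["FREQ"].to_numpy()
    return beta, se, freq


class TestEstimateSnpEffects:
    def test_factor_one_effect_recovered_others_null(self, fitted_truth,
                                                     nine_trait_structure):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        gamma_std = 0.05
        n = 5e4
        hits = np.zeros(3)
        within = 0
        reps = 200
        beta, se, freq = _simulate_snp_tables(
            Lam, Phi, Theta, np.array([gamma_std, 0, 0]), np.zeros(9),
            n, reps, seed=31)
        for j in range(reps):
            aug = expand_covariance(est, beta[j], se[j], freq[j])
            g, g_se = estimate_snp_effects(aug, fit)
            vg = 2 * freq[j] * (1 - freq[j])
            truth = gamma_std / np.sqrt(vg)     # dosage scale
            within += abs(g[0] - truth) < 2 * g_se[0]
            hits += np.abs(g / g_se) > 1.96
        assert within / reps >= 0.90
        assert hits[0] == reps                   # factor 1 always detected
        assert hits[1] / reps < 0.30             # others mostly null
        assert hits[2] / reps < 0.30

    def test_null_variant_z_scores_standard_normal(self, fitted_truth,
                                                   nine_trait_structure):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        reps = 1000
        beta, se, freq = _simulate_snp_tables(
            Lam, Phi, Theta, np.zeros(3), np.zeros(9), 5e4, reps, seed=32)
        zs = np.empty((reps, 3))
        for j in range(reps):
            aug = expand_covariance(est, beta[j], se[j], freq[j])
            g, g_se = estimate_snp_effects(aug, fit)
            zs[j] = g / g_se
        for f in range(3):
            assert abs(zs[:, f].mean()) < 0.05 + 3 / np.sqrt(reps)
            assert 0.9 < zs[:, f].var() < 1.1
            assert stats.kstest(zs[:, f], "norm").pvalue > 0.01

    def test_duplicated_traits_collapse_to_single_trait_gwas(self):
        # one factor, four identical indicators: factor beta equals trait beta
        k = 4
        Lam = np.full((k, 1), np.sqrt(0.3))
        est = GeneticCovarianceEstimate(
            S=Lam @ Lam.T + np.eye(k) * 1e-9,
            V=np.eye(k * (k + 1) // 2) * 1e-6,
            intercepts=np.ones((k, k)),
            trait_names=[f"T{i}" for i in range(k)], n_blocks=50)
        spec = fm.ModelSpec(factors={"F": est.trait_names},
                            trait_names=est.trait_names)
        fit = fm.fit_wls(est, spec)
        beta = np.full(k, 0.04)
        aug = expand_covariance(est, beta, np.full(k, 0.01), 0.4)
        g, g_se = estimate_snp_effects(aug, fit)
        # loading ~ sqrt(0.3): SNP -> factor path scaled by 1/loading
        assert g[0] * fit.loadings[0, 0] == pytest.approx(0.04, rel=1e-4)


class TestQSnp:
    def test_calibrated_under_factor_consistent_variants(self, fitted_truth,
                                                         nine_trait_structure):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        reps = 1000
        rng = np.random.default_rng(5)
        # nonzero factor effects, zero direct effects (the Q_SNP null)
        panel = make_ld_panel(200, reps, 1, 0.0, seed=33)
        gamma = rng.multivariate_normal(np.zeros(3), Phi * 1e-3, size=reps)
        model = TrueGenerativeModel(
            loadings=Lam, factor_cov=Phi, residual_var=Theta,
            snp_factor_effects=gamma,
            snp_direct_effects=np.zeros((reps, 9)),
            trait_neff=np.full(9, 5e4), trait_names=traits,
            factor_names=["F_gut", "F_aid", "F_alrg"])
        tables, _ = simulate_multitrait_sumstats(panel, model, seed=34)
        beta = np.column_stack([tables[t]["BETA"] for t in traits])
        se = np.column_stack([tables[t]["SE"] for t in traits])
        freq = tables[traits[0]]["FREQ"].to_numpy()
        rej = 0
        for j in range(reps):
            aug = expand_covariance(est, beta[j], se[j], freq[j])
            chi2, df, p = q_snp(aug, fit)
            rej += p < 0.05
        assert df == 6
        lo, hi = stats.binom.interval(0.95, reps, 0.05)
        assert lo <= rej <= hi

    def test_power_against_trait_specific_effect(self, fitted_truth,
                                                 nine_trait_structure):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        delta = np.zeros(9)
        delta[0] = 0.05
        reps = 200
        beta, se, freq = _simulate_snp_tables(
            Lam, Phi, Theta, np.zeros(3), delta, 5e4, reps, seed=35)
        det = 0
        for j in range(reps):
            aug = expand_covariance(est, beta[j], se[j], freq[j])
            chi2, df, p = q_snp(aug, fit)
            det += p < 5e-8
        assert det / reps > 0.5

    def test_invariant_to_trait_ordering(self, fitted_truth,
                                         nine_trait_structure):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.01, 9)
        se = np.full(9, 0.008)
        aug = expand_covariance(est, beta, se, 0.3)
        chi2_a, _, _ = q_snp(aug, fit)

        perm = rng.permutation(9)
        traits_p = [traits[i] for i in perm]
        S_p = est.S[np.ix_(perm, perm)]
        est_p = GeneticCovarianceEstimate(
            S=S_p, V=np.eye(45) * 1e-4, intercepts=np.eye(9),
            trait_names=traits_p, n_blocks=200)
        spec_p = fm.ModelSpec(
            factors={"F_gut": [t for t in traits_p if t in traits[:3]],
                     "F_aid": [t for t in traits_p if t in traits[3:7]],
                     "F_alrg": [t for t in traits_p if t in traits[7:]]},
            trait_names=traits_p)
        fit_p = fm.fit_wls(est_p, spec_p)
        aug_p = expand_covariance(est_p, beta[perm], se[perm], 0.3)
        chi2_b, _, _ = q_snp(aug_p, fit_p)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-6)


class TestRunFactorGwas:
    def test_output_schema_and_order(self, fitted_truth,
                                     nine_trait_structure, small_panel):
        est, fit = fitted_truth
        traits, Lam, Phi, Theta = nine_trait_structure
        model = TrueGenerativeModel(
            loadings=Lam, factor_cov=Phi, residual_var=Theta,
            snp_factor_effects=np.zeros((small_panel.m, 3)),
            snp_direct_effects=np.zeros((small_panel.m, 9)),
            trait_neff=np.full(9, 5e4), trait_names=traits,
            factor_names=["F_gut", "F_aid", "F_alrg"])
        tables, _ = simulate_multitrait_sumstats(small_panel, model, seed=36)
        out = run_factor_gwas(tables, est, fit)
        assert set(out) == {"F_gut", "F_aid", "F_alrg"}
        for tab in out.values():
            assert {"SNP", "CHR", "BP", "BETA", "SE", "Z", "P",
                    "QSNP_CHI2", "QSNP_DF", "QSNP_P"} <= set(tab.columns)
            key = tab[["CHR", "BP"]].to_numpy()
            assert (np.lexsort((key[:, 1], key[:, 0])) == np.arange(len(tab))).all()
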