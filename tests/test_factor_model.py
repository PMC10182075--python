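"""Confirmatory factor model tests: grouping, WLS recovery, fit indices,
selection."""

import numpy as np
import pytest

from polyfactor import factor_model as fm
from polyfactor.ldsc import GeneticCovarianceEstimate, lower_tri_order


class TestProposeGroups:
    def test_reproduces_three_disease_groups(self, nine_trait_structure,
                                             exact_estimate):
        traits, *_ = nine_trait_structure
        groups = fm.propose_groups(exact_estimate.rg(), threshold=0.4,
                                   trait_names=traits)
        as_sets = [set(g) for g in groups]
        assert {"CD", "UC", "PSC"} in as_sets
        assert {"T1D", "SLE", "JIA", "RA"} in as_sets
        assert {"AST", "ECZ"} in as_sets

    def test_all_below_threshold_gives_singletons(self):
        rg = np.eye(4) + 0.1 - 0.1 * np.eye(4)
        groups = fm.propose_groups(rg, threshold=0.4)
        assert len(groups) == 4

    def test_chain_merges_transitively(self):
        rg = np.eye(3)
        rg[0, 1] = rg[1, 0] = 0.5
        rg[1, 2] = rg[2, 1] = 0.5
        rg[0, 2] = rg[2, 0] = 0.1
        groups = fm.propose_groups(rg, threshold=0.4, trait_names=list("ABC"))
        assert groups == [["A", "B", "C"]]

    def test_rejects_asymmetric_input(self):
        rg = np.eye(3)
        rg[0, 1] = 0.5
        with pytest.raises(ValueError):
            fm.propose_groups(rg)


class TestModelSpec:
    def test_unloaded_trait_rejected(self):
        with pytest.raises(ValueError):
            fm.ModelSpec(factors={"F": ["A"]}, trait_names=["A", "B"])

    def test_overparameterized_model_rejected(self):
        with pytest.raises(ValueError):
            fm.ModelSpec(factors={"F1": ["A", "B"], "F2": ["A", "B"],
                                  "F3": ["A", "B"]},
                         trait_names=["A", "B"])

    def test_cross_loading_supported(self):
        spec = fm.ModelSpec(factors={"F1": ["A", "B"], "F2": ["B", "C", "D"]},
                            trait_names=["A", "B", "C", "D"])
        assert (1, 0) in spec.loading_entries
        assert (1, 1) in spec.loading_entries


class TestFitWLS:
    def test_exact_recovery_of_generating_model(self, nine_trait_structure,
                                                exact_estimate):
        traits, Lam, Phi, Theta = nine_trait_structure
        spec = fm.ModelSpec(
            factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                     "F_alrg": traits[7:]}, trait_names=traits)
        fit = fm.fit_wls(exact_estimate, spec)
        base = fm.fit_wls(exact_estimate, fm.independence_spec(traits))
        fm.fit_indices(fit, base)
        assert fit.converged
        assert np.abs(fit.loadings - Lam).max() < 1e-6
        assert np.abs(fit.factor_corr - Phi).max() < 1e-6
        assert np.abs(fit.residual_var - Theta).max() < 1e-6
        assert fit.chi2 < 1e-6
        assert fit.cfi == 1.0
        assert fit.srmr < 1e-8

    def test_one_factor_misfit_has_larger_srmr(self, nine_trait_structure,
                                               exact_estimate):
        traits, *_ = nine_trait_structure
        spec3 = fm.ModelSpec(
            factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                     "F_alrg": traits[7:]}, trait_names=traits)
        spec1 = fm.ModelSpec(factors={"F": traits}, trait_names=traits)
        fit3 = fm.fit_wls(exact_estimate, spec3)
        fit1 = fm.fit_wls(exact_estimate, spec1)
        assert fit1.srmr > fit3.srmr

    def test_standardization_invariance(self, nine_trait_structure,
                                        exact_estimate):
        """Rescaling a trait (with matching V transform) leaves the
        standardized loadings unchanged."""
        traits, *_ = nine_trait_structure
        spec = fm.ModelSpec(
            factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                     "F_alrg": traits[7:]}, trait_names=traits)
        fit = fm.fit_wls(exact_estimate, spec)

        c = np.ones(9)
        c[0] = 2.0
        S2 = exact_estimate.S * np.outer(c, c)
        order = lower_tri_order(9)
        scale = np.array([c[i] * c[j] for i, j in order])
        V2 = exact_estimate.V * np.outer(scale, scale)
        est2 = GeneticCovarianceEstimate(S=S2, V=V2, intercepts=np.eye(9),
                                         trait_names=traits, n_blocks=200)
        fit2 = fm.fit_wls(est2, spec)
        std1 = fit.loadings / np.sqrt(np.diag(exact_estimate.S))[:, None]
        std2 = fit2.loadings / np.sqrt(np.diag(S2))[:, None]
        assert np.abs(std1 - std2).max() < 1e-6

    def test_restart_reproducibility(self, exact_estimate,
                                     nine_trait_structure):
        traits, *_ = nine_trait_structure
        spec = fm.ModelSpec(
            factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                     "F_alrg": traits[7:]}, trait_names=traits)
        f1 = fm.fit_wls(exact_estimate, spec)
        f2 = fm.fit_wls(exact_estimate, spec)
        assert np.allclose(f1.params, f2.params, atol=1e-6)

    def test_heywood_flagged_not_clamped(self):
        # a trait whose covariances imply loading^2 above its variance
        S = np.array([[0.18, 0.28, 0.28],
                      [0.28, 0.5, 0.4],
                      [0.28, 0.4, 0.5]])
        est = GeneticCovarianceEstimate(S=S, V=np.eye(6) * 1e-4,
                                        intercepts=np.eye(3),
                                        trait_names=list("ABC"), n_blocks=50)
        spec = fm.ModelSpec(factors={"F": list("ABC")},
                            trait_names=list("ABC"))
        fit = fm.fit_wls(est, spec)
        assert fit.heywood
        assert fit.residual_var.min() < 0

    def test_smoothing_recorded_for_non_psd_input(self, nine_trait_structure):
        traits, Lam, Phi, Theta = nine_trait_structure
        S = Lam @ Phi @ Lam.T + np.diag(Theta)
        S[0, 1] = S[1, 0] = 0.9            # breaks positive-definiteness
        est = GeneticCovarianceEstimate(S=S, V=np.eye(45) * 1e-4,
                                        intercepts=np.eye(9),
                                        trait_names=traits, n_blocks=50)
        spec = fm.ModelSpec(
            factors={"F_gut": traits[:3], "F_aid": traits[3:7],
                     "F_alrg": traits[7:]}, trait_names=traits)
        fit = fm.fit_wls(est, spec)
        assert fit.smoothed


class TestFitIndices:
    def test_cfi_and_srmr_match_longhand(self):
        """Both formulas agree with independent longhand evaluation."""
        chi2_m, df_m, chi2_b, df_b = 12.5, 5, 220.0, 10
        expected_cfi = 1.0 - max(chi2_m - df_m, 0.0) / max(
            chi2_b - df_b, chi2_m - df_m, 0.0)
        assert fm.cfi(chi2_m, df_m, chi2_b, df_b) == pytest.approx(
            expected_cfi, abs=1e-10)

        S = np.array([[0.3, 0.1, 0.05],
                      [0.1, 0.25, 0.08],
                      [0.05, 0.08, 0.28]])
        Sigma = np.array([[0.29, 0.12, 0.04],
                          [0.12, 0.25, 0.09],
                          [0.04, 0.09, 0.30]])
        d = np.sqrt(np.diag(S))
        acc = []
        for i in range(3):
            for j in range(i + 1):
                rs = S[i, j] / (d[i] * d[j])
                ri = Sigma[i, j] / (d[i] * d[j])
                acc.append((rs - ri) ** 2)
        assert fm.srmr(S, Sigma) == pytest.approx(np.sqrt(np.mean(acc)),
                                                  abs=1e-10)

    def test_perfect_fit_gives_cfi_one(self):
        assert fm.cfi(3.0, 5, 100.0, 10) == 1.0

    def test_identical_matrices_give_zero_srmr(self):
        S = np.array([[0.3, 0.1], [0.1, 0.2]])
        assert fm.srmr(S, S) == 0.0

    def test_baseline_df_must_exceed_model_df(self):
        with pytest.raises(ValueError):
            fm.cfi(10.0, 10, 20.0, 5)


class TestSelectModel:
    def _fake(self, name, n_factors, cfi_val, srmr_val):
        spec = fm.ModelSpec.__new__(fm.ModelSpec)
        spec.factors = {f"F{i}": [] for i in range(n_factors)}
        spec.trait_names = []
        spec.correlated_factors = True
        spec.name = name
        fit = fm.FittedFactorModel(
            spec=spec, loadings=np.zeros((0, n_factors)),
            factor_corr=np.eye(n_factors), residual_var=np.zeros(0),
            params=np.zeros(0), se=np.zeros(0), chi2=0.0, df=1,
            objective=0.0, converged=True)
        fit.cfi = cfi_val
        fit.srmr = srmr_val
        return fit

    def test_failing_one_factor_loses_to_passing_three_factor(self):
        sel = fm.select_model([self._fake("1f", 1, 0.80, 0.20),
                               self._fake("3f", 3, 0.99, 0.03)])
        assert sel.chosen.spec.name == "3f"

    def test_all_fail_returns_no_adequate_model(self):
        sel = fm.select_model([self._fake("1f", 1, 0.5, 0.3),
                               self._fake("2f", 2, 0.9, 0.2)])
        assert sel.chosen is None
        assert not sel.adequate

    def test_parsimony_prefers_fewer_factors(self):
        sel = fm.select_model([self._fake("3f", 3, 0.99, 0.02),
                               self._fake("2f", 2, 0.97, 0.04)])
        assert sel.chosen.spec.name == "2f"

    def test_declared_exclusion_is_honoured(self):
        sel = fm.select_model([self._fake("2f", 2, 0.97, 0.04),
                               self._fake("4f", 4, 0.999, 0.01)],
                              exclude=["4f"])
        assert sel.chosen.spec.name == "2f"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            fm.select_model([])
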