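"""Per-SNP effects on latent genetic factors and the Q_SNP heterogeneity test.

For each variant, the genetic covariance matrix is augmented with one row:
the SNP's variance 2f(1-f) and its covariance with each trait,
beta_t * 2f(1-f) (dosage-scale beta). Holding the measurement model
(loadings, factor covariance, residuals) fixed at the genome-wide fit, the
SNP -> factor regression paths are identified by the linear system

    cov(SNP, trait_t) = var(SNP) * sum_q loading_tq * gamma_q

and estimated by weighted least squares with sandwich standard errors,
using the sampling covariance of the SNP-trait covariances (per-trait
standard errors combined with the intercept-derived cross-trait error
correlation).

Q_SNP compares this common-pathway model against the independent-pathways
model in which the SNP hits every trait directly. The latter fits the k
SNP-trait covariances perfectly, so the difference in fit statistics is
the generalized-least-squares residual quadratic form of the
common-pathway model, chi-square with df = #traits - #factors under the
null that the SNP acts only through the factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factor_model import FittedFactorModel
from .ldsc import GeneticCovarianceEstimate

GENOME_WIDE_P = 5e-8
REGION_SEED_P = 1e-6


@dataclass
class AugmentedCovariance:
    """(S*, V*) for one variant: S with an appended SNP row/column.

    The SNP occupies the last index. ``v_c`` is the sampling covariance of
    the k SNP-trait covariance elements (the only stochastic part of the
    augmentation used downstream; the SNP variance is treated as fixed).
    """

    S_star: np.ndarray
    V_star: np.ndarray
    v_c: np.ndarray     # (k, k)
    var_snp: float

    @property
    def k(self) -> int:
        return self.S_star.shape[0] - 1

    @property
    def snp_trait_cov(self) -> np.ndarray:
        return self.S_star[-1, :-1]


def expand_covariance(est: GeneticCovarianceEstimate, beta: np.ndarray,
                      se: np.ndarray, freq: float) -> AugmentedCovariance:
    """Augment (S, V) with one variant's dosage-scale statistics.

    ``beta``/``se`` are per-trait effect sizes and standard errors in trait
    order; ``freq`` is the effect-allele frequency. Missing (NaN) trait
    statistics are rejected.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    k = est.k
    if beta.size != k or se.size != k:
        raise ValueError("need one beta and se per trait")
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)):
        raise ValueError("missing trait statistics for the variant")
    vg = 2.0 * freq * (1.0 - freq)
    S_star = np.zeros((k + 1, k + 1))
    S_star[:k, :k] = est.S
    S_star[k, :k] = S_star[:k, k] = beta * vg
    S_star[k, k] = vg

    C = est.error_corr()
    se_c = se * vg
    v_c = np.outer(se_c, se_c) * C

    n_old = k * (k + 1) // 2
    n_new = n_old + k + 1
    V_star = np.zeros((n_new, n_new))
    V_star[:n_old, :n_old] = est.V
    V_star[n_old:n_old + k, n_old:n_old + k] = v_c
    V_star[n_new - 1, n_new - 1] = 1e-12   # SNP variance held fixed
    return AugmentedCovariance(S_star=S_star, V_star=V_star, v_c=v_c,
                               var_snp=vg)


def estimate_snp_effects(aug: AugmentedCovariance, model: FittedFactorModel):
    """SNP -> factor path estimates with sandwich standard errors.

    With the measurement model fixed and the total factor covariance held
    at its genome-wide value, the SNP-trait covariances are linear in the
    factor paths: c = var_snp * Lambda @ gamma. The paths are estimated by
    WLS with weights 1/diag(v_c) and sandwich covariance using the full
    v_c.

    Returns (beta, se) arrays over factors (dosage scale).
    """
    c = aug.snp_trait_cov
    A = aug.var_snp * model.loadings
    w = 1.0 / np.clip(np.diag(aug.v_c), 1e-30, None)
    AtW = A.T * w
    bread = np.linalg.pinv(AtW @ A)
    gamma = bread @ (AtW @ c)
    meat = AtW @ aug.v_c @ AtW.T
    cov = bread @ meat @ bread
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return gamma, se


_negative_qsnp_count = 0


def q_snp(aug: AugmentedCovariance, model: FittedFactorModel):
    """Heterogeneity test of factor mediation for one variant.

    Returns ``(chi2, df, p)``: the GLS fit-statistic difference between the
    common-pathway model (SNP acts only through the factors) and the
    saturated independent-pathways model (SNP hits each trait directly),
    with df = #traits - #factors.
    """
    global _negative_qsnp_count
    c = aug.snp_trait_cov
    A = aug.var_snp * model.loadings
    Vi = np.linalg.pinv(aug.v_c)
    AtVi = A.T @ Vi
    gamma = np.linalg.pinv(AtVi @ A) @ (AtVi @ c)
    r = c - A @ gamma
    chi2 = float(r @ Vi @ r)
    if chi2 < 0:
        _negative_qsnp_count += 1
        warnings.warn("negative Q_SNP statistic clamped to 0")
        chi2 = 0.0
    df = aug.k - model.n_factors
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, max(p, np.finfo(float).tiny)


def run_factor_gwas(tables: dict[str, pd.DataFrame],
                    est: GeneticCovarianceEstimate,
                    model: FittedFactorModel) -> dict[str, pd.DataFrame]:
    """Factor-level GWAS over the variants shared by all trait tables.

    Emits one table per factor (SNP, CHR, BP, A1, A2, BETA, SE, Z, P, N,
    FREQ, QSNP_CHI2, QSNP_DF, QSNP_P), sorted by (CHR, BP). The N column is
    the implied effective sample size 1 / (se^2 * 2f(1-f)), which keeps the
    factor tables usable by the conditional-analysis stage.
    """
    names = est.trait_names
    shared = None
    for name in names:
        s = set(tables[name]["SNP"])
        shared = s if shared is None else shared & s
    if not shared:
        raise ValueError("no variants shared across all trait tables")
    base = tables[names[0]]
    base = base[base["SNP"].isin(shared)].sort_values(
        ["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    m = len(base)
    k = len(names)
    beta = np.empty((m, k))
    se = np.empty((m, k))
    for t, name in enumerate(names):
        df = tables[name].set_index("SNP")
        beta[:, t] = df["BETA"].reindex(base["SNP"]).to_numpy()
        se[:, t] = df["SE"].reindex(base["SNP"]).to_numpy()
    freq = base["FREQ"].to_numpy()

    q = model.n_factors
    g_hat = np.empty((m, q))
    g_se = np.empty((m, q))
    q_chi2 = np.empty(m)
    q_df = np.empty(m, dtype=int)
    q_p = np.empty(m)
    ok = np.ones(m, dtype=bool)
    for j in range(m):
        try:
            aug = expand_covariance(est, beta[j], se[j], freq[j])
            g_hat[j], g_se[j] = estimate_snp_effects(aug, model)
            q_chi2[j], q_df[j], q_p[j] = q_snp(aug, model)
        except (ValueError, np.linalg.LinAlgError):
            ok[j] = False
            g_hat[j] = g_se[j] = np.nan
            q_chi2[j] = q_p[j] = np.nan
            q_df[j] = k - q

    out = {}
    for fj, fname in enumerate(model.spec.factor_names):
        z = np.where(ok & (g_se[:, fj] > 0), g_hat[:, fj] / g_se[:, fj], np.nan)
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        vg = 2.0 * freq * (1.0 - freq)
        out[fname] = pd.DataFrame({
            "SNP": base["SNP"], "CHR": base["CHR"], "BP": base["BP"],
            "A1": base["A1"], "A2": base["A2"],
            "BETA": g_hat[:, fj], "SE": g_se[:, fj], "Z": z, "P": p,
            "N": 1.0 / np.clip(g_se[:, fj] ** 2 * vg, 1e-300, None),
            "FREQ": freq,
            "QSNP_CHI2": q_chi2, "QSNP_DF": q_df, "QSNP_P": q_p,
        })
    return out
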