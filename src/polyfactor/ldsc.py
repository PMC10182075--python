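"""Multivariate LD-score regression.

For a pair of traits (a, b) with harmonized z-scores, the regression

    E[z_aj * z_bj] = sqrt(N_aj * N_bj) * cov_g * l_j / m + intercept

identifies the genetic covariance ``cov_g`` (the heritability when a == b)
as the slope on LD scores ``l_j``, while the intercept absorbs population
stratification and, off the diagonal, correlated estimation error from
sample overlap. Standard errors come from a delete-one-block jackknife;
running all k(k+1)/2 pairwise regressions on a common variant set and
jointly resampling the jackknife blocks yields the genetic covariance
matrix S together with the sampling covariance V of its distinct elements,
the two inputs of the factor-model stage.

Heritabilities are on the observed scale under the summed-effective-N
convention (implied sample prevalence 1/2); no liability-scale conversion
is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import LDPanel


@dataclass
class LDScores:
    """Per-variant LD scores with the metadata needed to align them."""

    values: np.ndarray      # (m,) l_j
    rsids: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    window_kb: float
    m: int                  # number of variants used for normalization

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.rsids, "CHR": self.chrom,
                             "BP": self.positions, "L2": self.values})


def compute_ld_scores(panel: LDPanel, window_kb: float = 200.0) -> LDScores:
    """LD scores from the reference panel over a physical window.

    l_j sums the small-sample-adjusted squared correlations
    ``r2 - (1 - r2) / (n_ref - 2)`` between variant j and every variant
    within ``window_kb`` kilobases on the same chromosome (the self term
    included, contributing exactly 1 after adjustment).
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if panel.m == 0:
        raise ValueError("empty panel")
    n = panel.n_ref
    X = panel.genotypes.astype(float)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    X /= sd
    window_bp = int(window_kb * 1000)
    ell = np.empty(panel.m)
    order = np.lexsort((panel.positions, panel.chrom))
    pos = panel.positions[order]
    chrom = panel.chrom[order]
    Xs = X[:, order]
    for c in np.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        cpos = pos[sel]
        lo = np.searchsorted(cpos, cpos - window_bp, side="left")
        hi = np.searchsorted(cpos, cpos + window_bp, side="right")
        for i, j in enumerate(sel):
            w = sel[lo[i]:hi[i]]
            r = Xs[:, w].T @ Xs[:, j] / n
            r2 = r * r
            ell[j] = np.sum(r2 - (1.0 - r2) / (n - 2))
    out = np.empty(panel.m)
    out[order] = ell
    return LDScores(values=out, rsids=panel.rsids.copy(),
                    chrom=panel.chrom.copy(), positions=panel.positions.copy(),
                    window_kb=window_kb, m=panel.m)


# ---------------------------------------------------------------------------
# Pairwise regression with block jackknife
# ---------------------------------------------------------------------------

def _blocked_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                 block_id: np.ndarray, n_blocks: int):
    """Weighted regression of y on [1, x] with delete-one-block estimates.

    Returns (theta_hat, theta_delete) where theta = (intercept, slope) and
    theta_delete has shape (n_blocks, 2).
    """
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    A_blocks = np.zeros((n_blocks, 2, 2))
    b_blocks = np.zeros((n_blocks, 2))
    A_flat = np.einsum("ij,ik->ijk", Xw, X)
    bv = Xw * y[:, None]
    np.add.at(A_blocks, block_id, A_flat)
    np.add.at(b_blocks, block_id, bv)
    A = A_blocks.sum(axis=0)
    b = b_blocks.sum(axis=0)
    theta = np.linalg.solve(A, b)
    theta_del = np.linalg.solve(A[None] - A_blocks,
                                (b[None] - b_blocks)[..., None])[..., 0]
    return theta, theta_del


def _jackknife_se(theta_del: np.ndarray) -> np.ndarray:
    nb = theta_del.shape[0]
    mean = theta_del.mean(axis=0)
    return np.sqrt((nb - 1) / nb * np.sum((theta_del - mean) ** 2, axis=0))


@dataclass
class PairResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_delete: np.ndarray    # (n_blocks,) delete-one-block slopes
    n_variants: int


def ldsc_pair(za: np.ndarray, zb: np.ndarray, ell: np.ndarray,
              na: np.ndarray, nb: np.ndarray, n_blocks: int = 200,
              block_id: np.ndarray = None, m_norm: int = None,
              chi2_max: float = None) -> PairResult:
    """One LD-score regression (cross-trait or heritability when za is zb).

    Two weighting passes are used: an initial 1/l regression, then the
    standard heteroskedasticity weights rebuilt from the first-pass slope
    and intercept. The jackknife uses ``n_blocks`` contiguous equal-variant
    blocks (or an explicit ``block_id`` assignment shared across pairs).
    ``m_norm`` is the variant count normalizing per-SNP heritability (the
    reference panel size); it defaults to the regression variant count.
    """
    za = np.asarray(za, float)
    zb = np.asarray(zb, float)
    ell = np.asarray(ell, float)
    na = np.broadcast_to(np.asarray(na, float), za.shape)
    nb_arr = np.broadcast_to(np.asarray(nb, float), zb.shape)
    if not (za.shape == zb.shape == ell.shape):
        raise ValueError("misaligned inputs")

    if chi2_max is None:
        cap_a = np.maximum(80.0, 0.001 * na)
        cap_b = np.maximum(80.0, 0.001 * nb_arr)
    else:
        cap_a = cap_b = chi2_max
    keep = (za ** 2 <= cap_a) & (zb ** 2 <= cap_b)

    if block_id is None:
        block_id = np.minimum(
            (np.arange(za.size) * n_blocks) // za.size, n_blocks - 1)
    block_id = block_id[keep]
    n_blocks_eff = n_blocks
    za, zb, ell = za[keep], zb[keep], ell[keep]
    na, nb_arr = na[keep], nb_arr[keep]
    if ell.size < 2 * n_blocks_eff:
        raise ValueError("fewer than 2 variants per jackknife block")
    m = m_norm if m_norm is not None else ell.size

    ell_pos = np.maximum(ell, 1.0)
    x = ell * np.sqrt(na * nb_arr) / m
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) LD-score regressor")
    y = za * zb

    w = 1.0 / ell_pos
    theta, _ = _blocked_wls(x, y, w, block_id, n_blocks_eff)
    # second pass: heteroskedasticity weights from first-pass estimates
    icpt, slope = theta
    ea = np.maximum(1.0 + np.abs(slope) * na * ell_pos / m, 0.05)
    eb = np.maximum(1.0 + np.abs(slope) * nb_arr * ell_pos / m, 0.05)
    cross = slope * np.sqrt(na * nb_arr) * ell_pos / m + icpt
    var = ea * eb + cross ** 2
    w = 1.0 / (ell_pos * np.maximum(var, 1e-6))
    theta, theta_del = _blocked_wls(x, y, w, block_id, n_blocks_eff)
    se = _jackknife_se(theta_del)
    return PairResult(slope=float(theta[1]), intercept=float(theta[0]),
                      slope_se=float(se[1]), intercept_se=float(se[0]),
                      slope_delete=theta_del[:, 1], n_variants=ell.size)


# ---------------------------------------------------------------------------
# Multivariable wrapper
# ---------------------------------------------------------------------------

def lower_tri_order(k: int) -> list[tuple[int, int]]:
    """Row-major lower-triangle element order of a k x k symmetric matrix."""
    return [(i, j) for i in range(k) for j in range(i + 1)]


@dataclass
class GeneticCovarianceEstimate:
    """Genetic covariance matrix S with sampling covariance V and intercepts.

    V is the sampling covariance of the k(k+1)/2 distinct elements of S in
    row-major lower-triangle order; the intercept matrix carries the LDSC
    intercepts on the diagonal and the overlap-absorbing cross-trait
    intercepts off it.
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    trait_names: list[str]
    n_blocks: int
    n_variants: int = 0
    smoothed: bool = field(default=False)

    @property
    def k(self) -> int:
        return self.S.shape[0]

    def rg(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.S))
        return self.S / np.outer(d, d)

    def error_corr(self) -> np.ndarray:
        """Cross-trait error correlation implied by the intercepts."""
        d = np.sqrt(np.clip(np.diag(self.intercepts), 1e-6, None))
        c = self.intercepts / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        return np.clip(c, -0.99, 0.99)

    def save(self, prefix) -> None:
        np.savetxt(f"{prefix}.S.txt", self.S)
        np.savetxt(f"{prefix}.V.txt", self.V)
        np.savetxt(f"{prefix}.intercepts.txt", self.intercepts)
        meta = {"traits": self.trait_names, "n_blocks": self.n_blocks,
                "n_variants": self.n_variants,
                "element_order": "row-major lower triangle"}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, prefix) -> "GeneticCovarianceEstimate":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        return cls(S=np.loadtxt(f"{prefix}.S.txt"),
                   V=np.loadtxt(f"{prefix}.V.txt"),
                   intercepts=np.loadtxt(f"{prefix}.intercepts.txt"),
                   trait_names=meta["traits"], n_blocks=meta["n_blocks"],
                   n_variants=meta.get("n_variants", 0))


def multivariable_ldsc(tables: dict[str, pd.DataFrame], scores: LDScores,
                       n_blocks: int = 200) -> GeneticCovarianceEstimate:
    """All pairwise LD-score regressions on the shared variant set.

    The sampling covariance V is estimated from jointly resampled jackknife
    blocks, so dependence between elements (including overlap-induced
    dependence) is captured.
    """
    names = list(tables)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two traits")

    score_df = scores.frame()
    shared = None
    for name in names:
        s = set(tables[name]["SNP"])
        shared = s if shared is None else shared & s
    shared &= set(score_df["SNP"])
    if not shared:
        raise ValueError("no shared variants across traits and LD scores")

    base = score_df[score_df["SNP"].isin(shared)].sort_values(
        ["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    m = len(base)
    if m < 2 * n_blocks:
        raise ValueError("fewer than 2 shared variants per jackknife block")
    ell = base["L2"].to_numpy()
    Z = np.empty((m, k))
    N = np.empty((m, k))
    for t, name in enumerate(names):
        df = tables[name].set_index("SNP")
        if "Z" in df.columns:
            z = df["Z"]
        else:
            z = df["BETA"] / df["SE"]
        Z[:, t] = z.reindex(base["SNP"]).to_numpy()
        N[:, t] = df["N"].reindex(base["SNP"]).to_numpy()

    block_id = np.minimum((np.arange(m) * n_blocks) // m, n_blocks - 1)
    order = lower_tri_order(k)
    S = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    deletes = np.empty((n_blocks, len(order)))
    total_m = 0
    for e, (i, j) in enumerate(order):
        res = ldsc_pair(Z[:, i], Z[:, j], ell, N[:, i], N[:, j],
                        n_blocks=n_blocks, block_id=block_id, m_norm=scores.m)
        S[i, j] = S[j, i] = res.slope
        intercepts[i, j] = intercepts[j, i] = res.intercept
        deletes[:, e] = res.slope_delete
        total_m = max(total_m, res.n_variants)
    centred = deletes - deletes.mean(axis=0)
    V = (n_blocks - 1) / n_blocks * centred.T @ centred
    return GeneticCovarianceEstimate(S=S, V=V, intercepts=intercepts,
                                     trait_names=names, n_blocks=n_blocks,
                                     n_variants=total_m)
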