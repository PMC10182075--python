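"""Approximate conditional and joint association analysis from summary data.

Reconstructs the sufficient statistics of a multiple linear regression from
per-variant marginal effects, standard errors, sample sizes and allele
frequencies plus a reference LD correlation matrix:

    X'X[j,k] = r_jk * sqrt(D_j * D_k),   X'y[j] = D_j * beta_j,

with D_j the genotype sum of squares (2 f_j (1 - f_j) N_j under
Hardy-Weinberg, or the in-sample value when genotype variances are
supplied -- in which case the joint and conditional estimates coincide with
exact multiple regression on individual-level data). The phenotypic sum of
squares y'y is recovered from the marginal identity
y'y = D_j (beta_j^2 + se_j^2 (N_j - 2)) and taken as the median over
variants.

Stepwise forward selection adds, at each step, the variant with the
smallest conditional p-value given the current set and stops once every
conditional p-value exceeds the stopping threshold (1e-4). For each
selected index variant an "all-but-one" conditional dataset re-estimates
every region variant conditional on the other selected variants, the
substrate of the colocalization stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import LDPanel

P_STOP_DEFAULT = 1e-4
COLLINEARITY_R2 = 0.9
FREQ_DIFF_MAX = 0.2


@dataclass
class RegionLD:
    """Reference LD for one region: correlations, frequencies, metadata."""

    snps: np.ndarray          # (m,) rsids
    R: np.ndarray             # (m, m) dosage correlation
    freqs: np.ndarray         # (m,)
    n_ref: int
    var: np.ndarray = None    # optional in-sample dosage variances (ddof=0)
    n: float = None           # optional in-sample N (with var)

    @classmethod
    def from_panel(cls, panel: LDPanel, snp_ids, in_sample: bool = False,
                   n: float = None) -> "RegionLD":
        idx = np.array([panel.index_of(s) for s in snp_ids])
        g = panel.genotypes[:, idx].astype(float)
        sd = g.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic variant in region LD")
        R = np.corrcoef(g, rowvar=False)
        var = g.var(axis=0) if in_sample else None
        return cls(snps=np.asarray(snp_ids), R=R,
                   freqs=g.mean(axis=0) / 2.0, n_ref=panel.n_ref,
                   var=var, n=n if n is not None else panel.n_ref)

    def subset(self, mask: np.ndarray) -> "RegionLD":
        return RegionLD(snps=self.snps[mask], R=self.R[np.ix_(mask, mask)],
                        freqs=self.freqs[mask], n_ref=self.n_ref,
                        var=None if self.var is None else self.var[mask],
                        n=self.n)


@dataclass
class ConditionalDataset:
    """Per-variant statistics conditional on all selected variants but one."""

    target: str
    conditioned_on: list[str]
    records: pd.DataFrame   # SNP, CHR, BP, BETA, SE, P (marginal), BETA_C, SE_C, P_C

    @property
    def min_p_row(self) -> pd.Series:
        return self.records.loc[self.records["P_C"].idxmin()]


@dataclass
class SignalSet:
    """All conditionally independent signals of one trait in one region."""

    trait: str
    region_id: str
    selected: list[str]
    datasets: list[ConditionalDataset]
    valid: dict = field(default_factory=dict)   # target -> bool

    def valid_datasets(self) -> list[ConditionalDataset]:
        return [d for d in self.datasets if self.valid.get(d.target, True)]


class _JointEngine:
    """Sufficient-statistic algebra shared by selection and conditioning."""

    def __init__(self, stats_df: pd.DataFrame, ld: RegionLD):
        order = {s: i for i, s in enumerate(ld.snps)}
        df = stats_df[stats_df["SNP"].isin(order)].copy()
        df["_ld_idx"] = df["SNP"].map(order)
        df = df.sort_values("_ld_idx").reset_index(drop=True)
        idx = df["_ld_idx"].to_numpy()

        if "FREQ" in df.columns and ld.var is None:
            fdiff = np.abs(df["FREQ"].to_numpy() - ld.freqs[idx])
            bad = fdiff > FREQ_DIFF_MAX
            if bad.any():
                warnings.warn(f"dropping {bad.sum()} variants with "
                              "summary/reference frequency mismatch")
                df = df[~bad].reset_index(drop=True)
                idx = df["_ld_idx"].to_numpy()
        if df.empty:
            raise ValueError("no usable variants in region")

        self.df = df
        self.R = ld.R[np.ix_(idx, idx)]
        self.beta = df["BETA"].to_numpy(float)
        self.se = df["SE"].to_numpy(float)
        n = df["N"].to_numpy(float)
        if ld.var is not None:
            self.n = float(ld.n)
            D = ld.var[idx] * self.n
        else:
            self.n = float(np.median(n))
            f = ld.freqs[idx]
            D = 2.0 * f * (1.0 - f) * n
        self.D = D
        sqD = np.sqrt(D)
        self.C = self.R * np.outer(sqD, sqD)          # approximate X'X
        self.Xty = D * self.beta
        yty_j = D * (self.beta ** 2 + self.se ** 2 * (n - 2.0))
        self.yty = float(np.median(yty_j))
        self.m = len(df)

    def joint(self, idx: list[int]):
        """Joint estimates for the given variant indices.

        Returns (beta, se) with residual variance on n - p - 1 degrees of
        freedom (matching centred multiple regression with an intercept).
        """
        idx = list(idx)
        B = self.C[np.ix_(idx, idx)]
        rhs = self.Xty[idx]
        b = np.linalg.solve(B, rhs)
        p = len(idx)
        dof = max(self.n - p - 1.0, 1.0)
        sigma2 = max(self.yty - b @ rhs, 0.0) / dof
        Binv = np.linalg.inv(B)
        se = np.sqrt(np.clip(sigma2 * np.diag(Binv), 0, None))
        return b, se

    def conditional(self, j: int, cond: list[int]):
        """Estimate for variant j conditional on the variants in ``cond``."""
        b, se = self.joint([j] + list(cond))
        return b[0], se[0]

    def r2_with(self, j: int, idx: list[int]) -> float:
        if not idx:
            return 0.0
        return float(np.max(self.R[j, idx] ** 2))


def _pvalue(beta, se):
    z = np.divide(beta, se, out=np.zeros_like(np.asarray(beta, float)),
                  where=np.asarray(se) > 0)
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def stepwise_select(region_stats: pd.DataFrame, ld: RegionLD,
                    p_stop: float = P_STOP_DEFAULT,
                    collinearity_r2: float = COLLINEARITY_R2) -> list[str]:
    """Forward stepwise selection of conditionally independent variants.

    Ties in conditional p are broken by smaller p then lower position, and
    candidates nearly collinear with the selected set (r^2 above the cap)
    or with a singular joint system are skipped with a warning.
    """
    if region_stats.empty:
        return []
    eng = _JointEngine(region_stats, ld)
    bp = eng.df["BP"].to_numpy() if "BP" in eng.df.columns else np.arange(eng.m)
    p_marg = _pvalue(eng.beta, eng.se)
    selected: list[int] = []

    while True:
        best = None
        for j in range(eng.m):
            if j in selected:
                continue
            if eng.r2_with(j, selected) > collinearity_r2:
                continue
            if not selected:
                pj = p_marg[j]
            else:
                try:
                    bj, sj = eng.conditional(j, selected)
                except np.linalg.LinAlgError:
                    warnings.warn("singular LD submatrix; candidate skipped")
                    continue
                pj = float(_pvalue(bj, sj))
            if best is None or (pj, bp[j]) < best[:2]:
                best = (pj, bp[j], j)
        if best is None or best[0] > p_stop:
            break
        selected.append(best[2])
    return [str(eng.df["SNP"].iloc[j]) for j in selected]


def all_but_one(region_stats: pd.DataFrame, ld: RegionLD,
                selected: list[str]) -> list[ConditionalDataset]:
    """One conditional dataset per selected variant.

    For target t, every region variant is re-estimated conditional on
    selected \\ {t}; with a single selected variant the conditional dataset
    equals the marginal data. Variants inside the conditioning set are
    omitted from the records.
    """
    if not selected:
        raise ValueError("selected set must be non-empty")
    eng = _JointEngine(region_stats, ld)
    snp_idx = {str(s): i for i, s in enumerate(eng.df["SNP"])}
    sel_idx = [snp_idx[s] for s in selected]
    out = []
    for t_pos, target in enumerate(selected):
        cond = [i for i in sel_idx if i != sel_idx[t_pos]]
        rec = eng.df.drop(columns=["_ld_idx"]).copy()
        rec["P"] = _pvalue(eng.beta, eng.se)
        if not cond:
            rec["BETA_C"] = eng.beta
            rec["SE_C"] = eng.se
        else:
            bc = np.full(eng.m, np.nan)
            sc = np.full(eng.m, np.nan)
            for j in range(eng.m):
                if j in cond:
                    continue
                try:
                    bc[j], sc[j] = eng.conditional(j, cond)
                except np.linalg.LinAlgError:
                    continue
            rec["BETA_C"] = bc
            rec["SE_C"] = sc
            rec = rec[~rec.index.isin(cond)]
        rec = rec.dropna(subset=["BETA_C", "SE_C"]).reset_index(drop=True)
        rec["P_C"] = _pvalue(rec["BETA_C"].to_numpy(), rec["SE_C"].to_numpy())
        out.append(ConditionalDataset(
            target=target,
            conditioned_on=[s for s in selected if s != target],
            records=rec))
    return out


def validate_signals(datasets: list[ConditionalDataset],
                     original_stats: pd.DataFrame,
                     p_cond: float = 1e-6, p_orig: float = 5e-8) -> dict:
    """Truth rule for conditional signals.

    A signal is valid when its conditional dataset's minimum conditional
    p-value is below ``p_cond``, or when the variant attaining that minimum
    has a marginal p-value below ``p_orig`` in the original GWAS.
    """
    marg = original_stats.set_index("SNP")["P"]
    flags = {}
    for d in datasets:
        row = d.min_p_row
        ok = row["P_C"] < p_cond
        if not ok:
            p0 = marg.get(row["SNP"], 1.0)
            ok = p0 < p_orig
        flags[d.target] = bool(ok)
    return flags


def decompose_region(region_stats: pd.DataFrame, ld: RegionLD, trait: str,
                     region_id: str, p_stop: float = P_STOP_DEFAULT,
                     p_cond: float = 1e-6, p_orig: float = 5e-8) -> SignalSet:
    """Full decomposition of one region: select, condition, validate."""
    selected = stepwise_select(region_stats, ld, p_stop=p_stop)
    if not selected:
        return SignalSet(trait=trait, region_id=region_id, selected=[],
                         datasets=[], valid={})
    datasets = all_but_one(region_stats, ld, selected)
    valid = validate_signals(datasets, region_stats, p_cond=p_cond,
                             p_orig=p_orig)
    return SignalSet(trait=trait, region_id=region_id, selected=selected,
                     datasets=datasets, valid=valid)
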