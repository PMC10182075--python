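"""Synthetic GWAS / QTL summary-statistic generator with block-structured LD.

The generator produces the three ingredients every downstream stage consumes:

1. an LD reference panel of unphased allele dosages organised in mutually
   independent blocks with a first-order autoregressive haplotype correlation
   profile inside each block (closed-form expected LD, which makes exact
   oracle tests possible);
2. multi-trait GWAS summary statistics whose genetic signal is driven by a
   known trait x factor loading structure, with optional sample overlap
   inducing correlated estimation errors across traits;
3. single-causal-variant molecular-QTL summary statistics whose causal
   variant can be shared with, or distinct from, a GWAS signal.

Effects are specified on the standardized-genotype scale; the conversion to
the allele-dosage scale (dividing by sqrt(2f(1-f))) happens once, when the
summary table is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "FREQ"]

#: base-pair spacing of adjacent variants inside a block
_SPACING_BP = 1_000
#: gap separating consecutive blocks on the same chromosome (larger than any
#: default LD-score window, so blocks stay independent in every stage)
_BLOCK_GAP_BP = 1_000_000

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

@dataclass
class LDPanel:
    """Reference panel of allele dosages in {0,1,2} with block structure."""

    genotypes: np.ndarray      # (n_ref, m) int8
    freqs: np.ndarray          # (m,) effect-allele frequency in (0,1)
    chrom: np.ndarray          # (m,) int
    positions: np.ndarray      # (m,) 1-based bp
    block_map: np.ndarray      # (m,) block index
    rho: np.ndarray            # (n_blocks,) AR(1) parameter per block
    rsids: np.ndarray = field(default=None)
    a1: np.ndarray = field(default=None)
    a2: np.ndarray = field(default=None)

    def __post_init__(self):
        m = self.genotypes.shape[1]
        if self.rsids is None:
            self.rsids = np.array([f"rs{i + 1}" for i in range(m)])
        if self.a1 is None:
            pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
            self.a1 = np.array([p[0] for p in pairs])
            self.a2 = np.array([p[1] for p in pairs])

    @property
    def n_ref(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_blocks(self) -> int:
        return int(self.block_map.max()) + 1

    def block_indices(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.block_map == b)

    def theoretical_corr(self, b: int) -> np.ndarray:
        """Expected dosage correlation matrix of block ``b`` (AR(1) profile)."""
        idx = self.block_indices(b)
        d = np.abs(np.subtract.outer(np.arange(idx.size), np.arange(idx.size)))
        return self.rho[b] ** d

    def empirical_corr(self, idx: np.ndarray) -> np.ndarray:
        """Sample dosage correlation matrix over the given variant indices."""
        g = self.genotypes[:, idx].astype(float)
        return np.corrcoef(g, rowvar=False)

    def variant_table(self) -> pd.DataFrame:
        """Variant metadata usable as a harmonization reference."""
        return pd.DataFrame({
            "SNP": self.rsids, "CHR": self.chrom, "BP": self.positions,
            "A1": self.a1, "A2": self.a2, "FREQ": self.freqs,
        })

    def index_of(self, rsid: str) -> int:
        hits = np.flatnonzero(self.rsids == rsid)
        if hits.size == 0:
            raise KeyError(f"variant {rsid!r} not in panel")
        return int(hits[0])

    def save(self, genotype_path, variant_path) -> None:
        np.savetxt(genotype_path, self.genotypes, fmt="%d")
        tab = self.variant_table()
        tab["BLOCK"] = self.block_map
        tab.to_csv(variant_path, sep="\t", index=False)


def make_ld_panel(n_ref: int, n_blocks: int, block_size: int, rho,
                  seed: int, freq_range: tuple[float, float] = (0.05, 0.95),
                  n_chrom: int = 22) -> LDPanel:
    """Simulate a reference panel of dosages with AR(1) LD blocks.

    Each block shares one allele frequency; haplotypes follow a stationary
    copy chain in which the next allele duplicates the previous one with
    probability ``rho`` and is otherwise drawn fresh, so the haplotype (and
    dosage) correlation between variants at lag d is exactly ``rho**d``.

    Parameters
    ----------
    rho
        AR(1) parameter in [0, 1). A scalar applies to all blocks; a
        sequence of length ``n_blocks`` sets a per-block value (useful to
        spread LD scores across a wide range).
    """
    if n_ref < 50:
        raise ValueError("n_ref must be >= 50")
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (n_blocks,)).copy()
    if np.any((rho_arr < 0) | (rho_arr >= 1)):
        raise ValueError("rho must lie in [0, 1)")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = n_blocks * block_size
    n_hap = 2 * n_ref

    genotypes = np.empty((n_ref, m), dtype=np.int8)
    freqs = np.empty(m)
    block_map = np.repeat(np.arange(n_blocks), block_size)

    for b in range(n_blocks):
        f = rng.uniform(*freq_range)
        hap = np.empty((n_hap, block_size), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < f
        if block_size > 1:
            copy = rng.random((n_hap, block_size - 1)) < rho_arr[b]
            fresh = rng.random((n_hap, block_size - 1)) < f
            for j in range(1, block_size):
                hap[:, j] = np.where(copy[:, j - 1], hap[:, j - 1], fresh[:, j - 1])
        sl = slice(b * block_size, (b + 1) * block_size)
        genotypes[:, sl] = hap[0::2] + hap[1::2]
        freqs[sl] = f

    # lay blocks out over chromosomes, contiguous groups per chromosome
    n_chr = min(n_chrom, n_blocks)
    per_chr = np.array_split(np.arange(n_blocks), n_chr)
    chrom = np.empty(m, dtype=np.int64)
    positions = np.empty(m, dtype=np.int64)
    for c, blocks in enumerate(per_chr, start=1):
        cursor = 1_000_000
        for b in blocks:
            sl = slice(b * block_size, (b + 1) * block_size)
            chrom[sl] = c
            positions[sl] = cursor + _SPACING_BP * np.arange(block_size)
            cursor += _SPACING_BP * block_size + _BLOCK_GAP_BP

    return LDPanel(genotypes=genotypes, freqs=freqs, chrom=chrom,
                   positions=positions, block_map=block_map, rho=rho_arr)


# ---------------------------------------------------------------------------
# Generative model
# ---------------------------------------------------------------------------

@dataclass
class TrueGenerativeModel:
    """Ground-truth multi-trait architecture: traits = loadings @ factors + residual.

    All effect sizes live on the standardized-genotype scale. The implied
    genetic covariance is ``loadings @ factor_cov @ loadings.T +
    diag(residual_var)`` and per-variant causal effects decompose into a
    factor-mediated part (``snp_factor_effects``, gamma) and a direct,
    factor-bypassing part (``snp_direct_effects``, delta) -- the latter is
    exactly what the heterogeneity test downstream is built to detect.
    """

    loadings: np.ndarray          # (k, q)
    factor_cov: np.ndarray        # (q, q)
    residual_var: np.ndarray      # (k,)
    snp_factor_effects: np.ndarray  # (m, q)
    snp_direct_effects: np.ndarray  # (m, k)
    trait_neff: np.ndarray        # (k,)
    trait_names: list[str]
    factor_names: list[str]
    overlap_frac: np.ndarray = None     # (k, k) fraction of shared samples
    overlap_pheno_corr: np.ndarray = None  # (k, k) phenotypic corr in overlap
    labels: np.ndarray = None     # (m,) variant truth label

    def __post_init__(self):
        k, q = self.loadings.shape
        if self.overlap_frac is None:
            self.overlap_frac = np.eye(k)
        if self.overlap_pheno_corr is None:
            self.overlap_pheno_corr = np.eye(k)
        if self.labels is None:
            self.labels = np.full(self.snp_factor_effects.shape[0], "null", dtype=object)
        S = self.implied_cov()
        if not np.allclose(S, S.T):
            raise ValueError("implied genetic covariance must be symmetric")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("implied genetic covariance must be PSD")

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    @property
    def m(self) -> int:
        return self.snp_factor_effects.shape[0]

    def implied_cov(self) -> np.ndarray:
        return (self.loadings @ self.factor_cov @ self.loadings.T
                + np.diag(self.residual_var))

    def error_corr(self) -> np.ndarray:
        """Cross-trait z-score error correlation induced by sample overlap."""
        c = self.overlap_frac * self.overlap_pheno_corr
        np.fill_diagonal(c, 1.0)
        return c

    def joint_effects(self) -> np.ndarray:
        """Per-variant standardized causal effect on each trait (m, k)."""
        return self.snp_factor_effects @ self.loadings.T + self.snp_direct_effects

    def plant_variant(self, idx: int, gamma=None, delta=None, label=None) -> None:
        """Replace one variant's true effects (standardized scale).

        Unspecified parts are zeroed, so a planted factor-consistent
        variant carries no residual polygenic direct effect.
        """
        self.snp_factor_effects[idx] = 0.0
        self.snp_direct_effects[idx] = 0.0
        if gamma is not None:
            self.snp_factor_effects[idx] = np.asarray(gamma, dtype=float)
        if delta is not None:
            self.snp_direct_effects[idx] = np.asarray(delta, dtype=float)
        if label is None:
            if np.any(self.snp_direct_effects[idx] != 0):
                label = "heterogeneous"
            elif np.count_nonzero(self.snp_factor_effects[idx]) >= 2:
                label = "shared"
            elif np.count_nonzero(self.snp_factor_effects[idx]) == 1:
                label = "specific"
            else:
                label = "null"
        self.labels[idx] = label

    def truth_table(self, panel: LDPanel) -> pd.DataFrame:
        tab = {"SNP": panel.rsids, "CHR": panel.chrom, "BP": panel.positions,
               "LABEL": self.labels}
        for j, f in enumerate(self.factor_names):
            tab[f"GAMMA_{f}"] = self.snp_factor_effects[:, j]
        for t, name in enumerate(self.trait_names):
            tab[f"DELTA_{name}"] = self.snp_direct_effects[:, t]
        return pd.DataFrame(tab)


def polygenic_model(panel: LDPanel, loadings, factor_cov, residual_var,
                    trait_neff, trait_names, factor_names, seed: int,
                    overlap_frac=None, overlap_pheno_corr=None,
                    factor_effect_corr=None) -> TrueGenerativeModel:
    """Infinitesimal background architecture matching a target covariance.

    Every variant receives factor effects gamma_j ~ MVN(0, C_gamma/m) and
    direct effects delta_jt ~ N(0, theta_t/m), so the summed causal
    (co)variance converges to ``loadings @ factor_cov @ loadings.T +
    diag(residual_var)`` -- the quantity LD-score regression estimates.

    ``factor_effect_corr`` sets the per-variant covariance C_gamma of factor
    effects; it defaults to ``factor_cov`` itself (within- and cross-factor
    effect correlation mirroring the factor-level covariance).
    """
    loadings = np.asarray(loadings, dtype=float)
    factor_cov = np.asarray(factor_cov, dtype=float)
    residual_var = np.asarray(residual_var, dtype=float)
    m = panel.m
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    C = factor_cov if factor_effect_corr is None else np.asarray(factor_effect_corr)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    gamma = rng.standard_normal((m, C.shape[0])) @ L.T / np.sqrt(m)
    delta = rng.standard_normal((m, residual_var.size)) * np.sqrt(residual_var / m)
    labels = np.full(m, "polygenic", dtype=object)
    return TrueGenerativeModel(
        loadings=loadings, factor_cov=factor_cov, residual_var=residual_var,
        snp_factor_effects=gamma, snp_direct_effects=delta,
        trait_neff=np.asarray(trait_neff, dtype=float),
        trait_names=list(trait_names), factor_names=list(factor_names),
        overlap_frac=overlap_frac, overlap_pheno_corr=overlap_pheno_corr,
        labels=labels)


def null_model(panel: LDPanel, n_traits: int, trait_neff, seed: int = 0,
               overlap_frac=None, overlap_pheno_corr=None) -> TrueGenerativeModel:
    """All-null architecture (no genetic effects at all); one factor of zeros."""
    m = panel.m
    return TrueGenerativeModel(
        loadings=np.zeros((n_traits, 1)), factor_cov=np.eye(1),
        residual_var=np.zeros(n_traits),
        snp_factor_effects=np.zeros((m, 1)),
        snp_direct_effects=np.zeros((m, n_traits)),
        trait_neff=np.asarray(trait_neff, dtype=float),
        trait_names=[f"T{i + 1}" for i in range(n_traits)],
        factor_names=["F1"], overlap_frac=overlap_frac,
        overlap_pheno_corr=overlap_pheno_corr)


# ---------------------------------------------------------------------------
# Summary-statistic simulation
# ---------------------------------------------------------------------------

def _block_chols(panel: LDPanel) -> list[np.ndarray]:
    chols = []
    for b in range(panel.n_blocks):
        R = panel.theoretical_corr(b)
        chols.append(np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0])))
    return chols


def _propagate_through_ld(panel: LDPanel, b_joint: np.ndarray) -> np.ndarray:
    """Marginal standardized effects: joint effects smeared by block LD."""
    out = np.empty_like(b_joint)
    for b in range(panel.n_blocks):
        idx = panel.block_indices(b)
        out[idx] = panel.theoretical_corr(b) @ b_joint[idx]
    return out


def _ld_noise(panel: LDPanel, n_cols: int, rng, col_chol=None) -> np.ndarray:
    """(m, n_cols) noise with block-LD row covariance and col covariance."""
    eps = np.empty((panel.m, n_cols))
    chols = _block_chols(panel)
    for b in range(panel.n_blocks):
        idx = panel.block_indices(b)
        eps[idx] = chols[b] @ rng.standard_normal((idx.size, n_cols))
    if col_chol is not None:
        eps = eps @ col_chol.T
    return eps


def _assemble_table(panel: LDPanel, z: np.ndarray, n) -> pd.DataFrame:
    """Turn standardized z-scores into a dosage-scale summary table."""
    vg = 2.0 * panel.freqs * (1.0 - panel.freqs)
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), (panel.m,))
    se = 1.0 / np.sqrt(n_arr * vg)
    beta = z * se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "SNP": panel.rsids, "CHR": panel.chrom, "BP": panel.positions,
        "A1": panel.a1, "A2": panel.a2, "BETA": beta, "SE": se,
        "P": np.clip(p, np.finfo(float).tiny, 1.0), "N": n_arr,
        "FREQ": panel.freqs,
    })


def simulate_multitrait_sumstats(panel: LDPanel, model: TrueGenerativeModel,
                                 seed: int):
    """Simulate one GWAS summary table per trait plus the truth table.

    Marginal z-scores have mean sqrt(N_t) * (R @ b_t) where b_t is the joint
    standardized causal effect vector of trait t and R the block LD, and
    errors are MVN with block-LD covariance across variants and the
    overlap-induced correlation across traits.

    Returns ``(tables, truth)`` where ``tables`` maps trait name -> summary
    DataFrame and ``truth`` is the variant-level truth table.
    """
    if model.m != panel.m:
        raise ValueError("model variant count does not match panel")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    b_joint = model.joint_effects()                     # (m, k)
    mean_z = _propagate_through_ld(panel, b_joint) * np.sqrt(model.trait_neff)
    C = model.error_corr()
    eig_min = np.linalg.eigvalsh(C).min()
    if eig_min < -1e-10:
        raise ValueError("overlap-induced error correlation is not PSD")
    col_chol = np.linalg.cholesky(C + 1e-10 * np.eye(model.k))
    z = mean_z + _ld_noise(panel, model.k, rng, col_chol)
    tables = {name: _assemble_table(panel, z[:, t], model.trait_neff[t])
              for t, name in enumerate(model.trait_names)}
    truth = model.truth_table(panel)
    truth.attrs["seed"] = seed
    truth.attrs["seed_rule"] = "SeedSequence([seed, 202])"
    return tables, truth


def simulate_qtl_sumstats(panel: LDPanel, shared_with: str, effect: float,
                          n: int, seed: int) -> pd.DataFrame:
    """Simulate a molecular-QTL summary table with one causal variant.

    ``shared_with`` names the causal variant (an rsID in the panel) or is
    the string ``"none"`` for a pure-noise table. ``effect`` is the causal
    variant's standardized effect on the molecular trait.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    b = np.zeros(panel.m)
    if shared_with != "none":
        b[panel.index_of(shared_with)] = effect
    mean_z = _propagate_through_ld(panel, b[:, None])[:, 0] * np.sqrt(n)
    z = mean_z + _ld_noise(panel, 1, rng)[:, 0]
    return _assemble_table(panel, z, n)
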