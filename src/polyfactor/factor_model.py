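"""Confirmatory factor models on a genetic covariance matrix.

A candidate model specifies which traits load on which latent genetic
factors. Given the LD-score-regression output (S, V), the free parameters
(loadings, factor correlations, residual variances) are estimated by
weighted least squares: minimize

    F(theta) = (s - sigma(theta))' D^{-1} (s - sigma(theta))

over the k(k+1)/2 distinct elements s of S, with D the diagonal of the
sampling covariance V (full-V weighting is available behind a flag).
Factors are scaled to unit variance, so the loadings are directly the
standardized paths of the usual path diagram. Parameter standard errors
use the sandwich formula with the full V; the model fit statistic is the
residual quadratic form evaluated against the residuals' asymptotic
covariance, which is chi-square distributed with
df = k(k+1)/2 - #free parameters.

Model adequacy follows the conventional CFI > 0.95 and SRMR < 0.10 rule,
with a parsimony preference (fewest factors) among adequate candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import GeneticCovarianceEstimate, lower_tri_order


# ---------------------------------------------------------------------------
# Trait grouping
# ---------------------------------------------------------------------------

def propose_groups(rg, threshold: float = 0.4, trait_names=None):
    """Partition traits into groups connected by genetic correlation >= threshold.

    Groups are the connected components of the graph with an edge between
    two traits whenever their genetic correlation reaches the threshold.
    """
    rg = np.asarray(rg, dtype=float)
    if not np.allclose(rg, rg.T, atol=1e-8):
        raise ValueError("genetic correlation matrix must be symmetric")
    k = rg.shape[0]
    if trait_names is None:
        trait_names = [f"T{i + 1}" for i in range(k)]
    g = nx.Graph()
    g.add_nodes_from(trait_names)
    for i in range(k):
        for j in range(i):
            if rg[i, j] >= threshold:
                g.add_edge(trait_names[i], trait_names[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (trait_names.index(c[0])))


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A confirmatory factor pattern: factor name -> traits with free loadings."""

    factors: dict[str, list[str]]
    trait_names: list[str]
    correlated_factors: bool = True
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = f"{len(self.factors)}-factor"
        loaded = {t for traits in self.factors.values() for t in traits}
        missing = set(self.trait_names) - loaded
        if missing:
            raise ValueError(f"traits load on no factor: {sorted(missing)}")
        unknown = loaded - set(self.trait_names)
        if unknown:
            raise ValueError(f"unknown traits in pattern: {sorted(unknown)}")
        if self.n_free > self.n_elements:
            raise ValueError("model is not identified: more free parameters "
                             "than distinct covariance elements")

    @property
    def k(self) -> int:
        return len(self.trait_names)

    @property
    def q(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def loading_entries(self) -> list[tuple[int, int]]:
        """(trait index, factor index) pairs with a free loading."""
        entries = []
        for fj, (fname, traits) in enumerate(self.factors.items()):
            for t in traits:
                entries.append((self.trait_names.index(t), fj))
        return entries

    @property
    def n_free(self) -> int:
        n = len(self.loading_entries) + self.k
        if self.correlated_factors:
            n += self.q * (self.q - 1) // 2
        return n

    @property
    def n_elements(self) -> int:
        return self.k * (self.k + 1) // 2


def independence_spec(trait_names) -> "ModelSpec":
    """Baseline model: no common factors, free residual variances only."""
    spec = ModelSpec.__new__(ModelSpec)
    spec.factors = {}
    spec.trait_names = list(trait_names)
    spec.correlated_factors = False
    spec.name = "independence"
    return spec


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _unpack(spec: ModelSpec, theta: np.ndarray):
    k, q = spec.k, spec.q
    Lam = np.zeros((k, q))
    entries = spec.loading_entries
    for e, (t, f) in enumerate(entries):
        Lam[t, f] = theta[e]
    pos = len(entries)
    Phi = np.eye(q)
    if spec.correlated_factors and q > 1:
        for i in range(q):
            for j in range(i):
                Phi[i, j] = Phi[j, i] = theta[pos]
                pos += 1
    resid = theta[pos:pos + k]
    return Lam, Phi, resid


def _implied(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    Lam, Phi, resid = _unpack(spec, theta)
    return Lam @ Phi @ Lam.T + np.diag(resid)


def _tri(M: np.ndarray, order) -> np.ndarray:
    return np.array([M[i, j] for i, j in order])


def _sigma_jacobian(spec: ModelSpec, theta: np.ndarray, order) -> np.ndarray:
    """Analytic Jacobian of the implied distinct elements w.r.t. parameters."""
    k, q = spec.k, spec.q
    Lam, Phi, _ = _unpack(spec, theta)
    PL = Phi @ Lam.T                      # (q, k)
    entries = spec.loading_entries
    n_par = len(theta)
    J = np.zeros((len(order), n_par))
    for e_i, (i, j) in enumerate(order):
        for p, (t, f) in enumerate(entries):
            v = 0.0
            if i == t:
                v += PL[f, j]
            if j == t:
                v += PL[f, i]
            J[e_i, p] = v
        pos = len(entries)
        if spec.correlated_factors and q > 1:
            for a in range(q):
                for b in range(a):
                    J[e_i, pos] = Lam[i, a] * Lam[j, b] + Lam[i, b] * Lam[j, a]
                    pos += 1
        else:
            pos = len(entries)
        if i == j:
            J[e_i, pos + i] = 1.0
    return J


def smooth_to_psd(S: np.ndarray, floor: float = 1e-6):
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue floor)."""
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    if vals.min() >= floor:
        return S, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


@dataclass
class FittedFactorModel:
    spec: ModelSpec
    loadings: np.ndarray          # (k, q)
    factor_corr: np.ndarray       # (q, q)
    residual_var: np.ndarray      # (k,)
    params: np.ndarray
    se: np.ndarray
    chi2: float
    df: int
    objective: float
    converged: bool
    smoothed: bool = False
    heywood: bool = False
    cfi: float = field(default=np.nan)
    srmr: float = field(default=np.nan)

    @property
    def n_factors(self) -> int:
        return self.spec.q

    def implied_cov(self) -> np.ndarray:
        return (self.loadings @ self.factor_corr @ self.loadings.T
                + np.diag(self.residual_var))

    def summary(self) -> str:
        lines = [f"model: {self.spec.name}  converged={self.converged}",
                 f"chi2={self.chi2:.4g} df={self.df} "
                 f"CFI={self.cfi:.4f} SRMR={self.srmr:.4f}"]
        for fj, fname in enumerate(self.spec.factor_names):
            for t, name in enumerate(self.spec.trait_names):
                if (t, fj) in self.spec.loading_entries:
                    lines.append(f"  {fname} -> {name}: "
                                 f"{self.loadings[t, fj]:+.3f}")
        for i in range(self.spec.q):
            for j in range(i):
                lines.append(f"  {self.spec.factor_names[i]} <-> "
                             f"{self.spec.factor_names[j]}: "
                             f"{self.factor_corr[i, j]:+.3f}")
        if self.heywood:
            lines.append("  warning: Heywood case (negative residual variance)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"name": self.spec.name,
                "factors": self.spec.factors,
                "loadings": self.loadings.tolist(),
                "factor_corr": self.factor_corr.tolist(),
                "residual_var": self.residual_var.tolist(),
                "se": self.se.tolist(), "chi2": self.chi2, "df": self.df,
                "cfi": self.cfi, "srmr": self.srmr,
                "converged": self.converged, "heywood": self.heywood}


def _start_points(spec: ModelSpec, S: np.ndarray) -> list[np.ndarray]:
    k = spec.k
    diag = np.clip(np.diag(S), 1e-4, None)
    starts = []
    for lam0 in (0.7, 0.3):
        theta = []
        for t, f in spec.loading_entries:
            theta.append(lam0 * np.sqrt(diag[t]))
        if spec.correlated_factors and spec.q > 1:
            theta.extend([0.2] * (spec.q * (spec.q - 1) // 2))
        theta.extend(0.5 * diag)
        starts.append(np.array(theta))
    # correlation-informed start: loading = sqrt(mean within-factor rg) scaled
    d = np.sqrt(diag)
    rg = S / np.outer(d, d)
    theta = []
    for t, f in spec.loading_entries:
        others = [spec.trait_names.index(o)
                  for o in spec.factors[spec.factor_names[f]]
                  if spec.trait_names.index(o) != t]
        r = np.mean([abs(rg[t, o]) for o in others]) if others else 0.5
        theta.append(np.sqrt(max(r, 0.05)) * d[t])
    if spec.correlated_factors and spec.q > 1:
        theta.extend([0.2] * (spec.q * (spec.q - 1) // 2))
    theta.extend(0.5 * diag)
    starts.append(np.array(theta))
    return starts


def fit_wls(est: GeneticCovarianceEstimate, spec: ModelSpec,
            full_v_weights: bool = False) -> FittedFactorModel:
    """Fit a factor model to (S, V) by diagonally weighted least squares.

    Runs a trust-region least-squares optimizer from several deterministic
    starting points and keeps the best convergent optimum. Negative
    residual variances are flagged as Heywood cases, not clamped. If S is
    not positive semi-definite it is first projected to the nearest PSD
    matrix (eigenvalue floor 1e-6) and the smoothing is recorded.
    """
    k = est.k
    if spec.k != k or list(spec.trait_names) != list(est.trait_names):
        raise ValueError("spec traits do not match the covariance estimate")
    order = lower_tri_order(k)
    S, smoothed = smooth_to_psd(est.S)
    s = _tri(S, order)
    Vd = np.clip(np.diag(est.V), 1e-30, None)
    if np.any(np.diag(est.V) <= 0):
        raise ValueError("V must have strictly positive diagonal")
    if full_v_weights:
        W = np.linalg.pinv(est.V)
        Whalf = np.linalg.cholesky(W + 1e-12 * np.eye(W.shape[0])).T
    else:
        Whalf = np.diag(1.0 / np.sqrt(Vd))

    if spec.q == 0:
        # independence model: diagonal free, closed form under diagonal weights
        theta = np.diag(S).copy()
        resid_vec = Whalf @ (s - _tri(np.diag(theta), order))
        return _finalize(est, spec, theta, resid_vec, Whalf, order,
                         converged=True, smoothed=smoothed)

    def residuals(theta):
        return Whalf @ (s - _tri(_implied(spec, theta), order))

    def jac(theta):
        return -Whalf @ _sigma_jacobian(spec, theta, order)

    best = None
    for x0 in _start_points(spec, S):
        sol = optimize.least_squares(residuals, x0, jac=jac, method="trf",
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=2000)
        cost = 2.0 * sol.cost
        if sol.status > 0 and (best is None or cost < best[0] - 1e-12):
            best = (cost, sol)
    if best is None:
        theta = _start_points(spec, S)[0]
        return _finalize(est, spec, theta, residuals(theta), Whalf, order,
                         converged=False, smoothed=smoothed)
    _, sol = best
    return _finalize(est, spec, sol.x, sol.fun, Whalf, order,
                     converged=True, smoothed=smoothed)


def _finalize(est, spec, theta, resid_vec, Whalf, order, converged, smoothed):
    k = spec.k
    if spec.q == 0:
        Lam = np.zeros((k, 0))
        Phi = np.zeros((0, 0))
        resid = theta
    else:
        Lam, Phi, resid = _unpack(spec, theta)

    # Jacobian of sigma(theta) on the unweighted scale
    if spec.q == 0:
        Delta = np.zeros((len(order), k))
        for e_i, (i, j) in enumerate(order):
            if i == j:
                Delta[e_i, i] = 1.0
    else:
        Delta = _sigma_jacobian(spec, theta, order)
    W = Whalf.T @ Whalf
    bread = np.linalg.pinv(Delta.T @ W @ Delta)
    meat = Delta.T @ W @ est.V @ W @ Delta
    cov = bread @ meat @ bread
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # residual-based fit statistic: r' pinv(cov(r)) r ~ chi2_df
    P = Delta @ bread @ Delta.T @ W
    I = np.eye(P.shape[0])
    resid_cov = (I - P) @ est.V @ (I - P).T
    # recover unweighted residuals: resid_vec = Whalf @ (s - sigma)
    r = np.linalg.lstsq(Whalf, resid_vec, rcond=None)[0]
    chi2 = float(r @ np.linalg.pinv(resid_cov, rcond=1e-10) @ r)
    chi2 = max(chi2, 0.0)
    df = spec.n_elements - (spec.n_free if spec.q > 0 else k)
    objective = float(resid_vec @ resid_vec)

    fit = FittedFactorModel(
        spec=spec, loadings=Lam, factor_corr=Phi, residual_var=resid,
        params=np.asarray(theta, float), se=se, chi2=chi2, df=df,
        objective=objective, converged=converged, smoothed=smoothed,
        heywood=bool(np.any(resid < 0)))
    S_curr, _ = smooth_to_psd(est.S)
    fit.srmr = srmr(S_curr, fit.implied_cov())
    return fit


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def cfi(chi2_m: float, df_m: int, chi2_b: float, df_b: int) -> float:
    """Comparative fit index against an independence baseline."""
    if df_b <= df_m:
        raise ValueError("baseline must have more degrees of freedom than model")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean square residual over distinct elements."""
    d = np.sqrt(np.clip(np.diag(S), 1e-30, None))
    Rs = S / np.outer(d, d)
    Ri = Sigma / np.outer(d, d)
    k = S.shape[0]
    order = lower_tri_order(k)
    diffs = np.array([Rs[i, j] - Ri[i, j] for i, j in order])
    return float(np.sqrt(np.mean(diffs ** 2)))


def fit_indices(fit: FittedFactorModel, baseline: FittedFactorModel):
    """Attach (CFI, SRMR) to a fitted model given the independence baseline."""
    fit.cfi = cfi(fit.chi2, fit.df, baseline.chi2, baseline.df)
    return fit.cfi, fit.srmr


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelection:
    chosen: FittedFactorModel | None
    report: pd.DataFrame

    @property
    def adequate(self) -> bool:
        return self.chosen is not None


def select_model(fits: list[FittedFactorModel], cfi_min: float = 0.95,
                 srmr_max: float = 0.10, exclude: list[str] = ()) -> ModelSelection:
    """Choose among candidate fits by adequacy thresholds and parsimony.

    Candidates failing CFI > cfi_min or SRMR < srmr_max are removed, as are
    models named in ``exclude`` (interpretability exclusions are declared by
    the caller, never inferred). Among survivors the model with the fewest
    factors wins; ties go to input order.
    """
    if not fits:
        raise ValueError("no candidate models supplied")
    rows = []
    survivors = []
    for f in fits:
        passes = (f.converged and f.cfi > cfi_min and f.srmr < srmr_max)
        excluded = f.spec.name in exclude
        rows.append({"model": f.spec.name, "n_factors": f.n_factors,
                     "chi2": f.chi2, "df": f.df, "cfi": f.cfi,
                     "srmr": f.srmr, "converged": f.converged,
                     "passes_fit": passes, "excluded": excluded})
        if passes and not excluded:
            survivors.append(f)
    report = pd.DataFrame(rows)
    if not survivors:
        return ModelSelection(chosen=None, report=report)
    chosen = min(survivors, key=lambda f: f.n_factors)
    return ModelSelection(chosen=chosen, report=report)
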