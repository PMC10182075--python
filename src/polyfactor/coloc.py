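"""Bayesian colocalization under the single-causal-variant assumption.

Each variant's evidence is a Wakefield approximate Bayes factor computed
from its (conditional) effect and standard error with an effect-scale
prior. The five-hypothesis enumeration (no signal / trait A only / trait B
only / two distinct variants / one shared variant) combines per-variant
log-ABFs with per-variant priors p1, p2 and p12; log-sum-exp keeps the
computation overflow-safe. Signals whose posterior for a shared variant
(PP4) reaches a threshold are grouped into shared loci by connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .conditional import ConditionalDataset, RegionLD, SignalSet, decompose_region

PP4_MIN_DEFAULT = 0.9
MIN_OVERLAP_DEFAULT = 25
PRIOR_SD_CC = 0.2      # case/control (log-odds) traits
PRIOR_SD_QT = 0.15     # quantitative molecular traits


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    With shrinkage r = prior_sd^2 / (prior_sd^2 + se^2) and z = beta / se,
    returns 0.5 * (log(1 - r) + r * z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    r = prior_sd ** 2 / (prior_sd ** 2 + se ** 2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z * z)


@dataclass
class ColocResult:
    trait_a: str
    signal_a: str
    trait_b: str
    signal_b: str
    pp: np.ndarray = None        # PP0..PP4
    n_variants: int = 0
    priors: tuple = (1e-4, 1e-4, 1e-5)
    untestable: bool = False

    @property
    def pp4(self) -> float:
        return float(self.pp[4]) if self.pp is not None else np.nan

    def as_row(self) -> dict:
        row = {"trait_a": self.trait_a, "signal_a": self.signal_a,
               "trait_b": self.trait_b, "signal_b": self.signal_b,
               "nsnps": self.n_variants, "untestable": self.untestable}
        for h in range(5):
            row[f"PP{h}"] = float(self.pp[h]) if self.pp is not None else np.nan
        return row


def _extract(dataset) -> pd.DataFrame:
    """Accept a ConditionalDataset or a plain summary DataFrame."""
    if isinstance(dataset, ConditionalDataset):
        df = dataset.records
    else:
        df = dataset
    cols = {"SNP": df["SNP"]}
    if "BETA_C" in df.columns:
        cols["BETA"] = df["BETA_C"]
        cols["SE"] = df["SE_C"]
    else:
        cols["BETA"] = df["BETA"]
        cols["SE"] = df["SE"]
    return pd.DataFrame(cols).dropna()


def coloc_pair(a, b, p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
               prior_sd_a: float = PRIOR_SD_CC,
               prior_sd_b: float = PRIOR_SD_CC,
               min_overlap: int = MIN_OVERLAP_DEFAULT,
               labels: tuple = ("A", "a", "B", "b")) -> ColocResult:
    """Five-hypothesis colocalization of two (conditional) datasets.

    Datasets are intersected on rsID; fewer shared variants than
    ``min_overlap`` yields an explicit untestable result rather than a
    silent null posterior.
    """
    ta, sa, tb, sb = labels
    da = _extract(a)
    db = _extract(b)
    merged = da.merge(db, on="SNP", suffixes=("_a", "_b"))
    n = len(merged)
    if n < min_overlap:
        return ColocResult(trait_a=ta, signal_a=sa, trait_b=tb, signal_b=sb,
                           n_variants=n, priors=(p1, p2, p12),
                           untestable=True)
    la = log_abf(merged["BETA_a"], merged["SE_a"], prior_sd_a)
    lb = log_abf(merged["BETA_b"], merged["SE_b"], prior_sd_b)

    sum_a = logsumexp(la)
    sum_b = logsumexp(lb)
    sum_ab = logsumexp(la + lb)           # shared-variant configurations
    # distinct-variant configurations: sum_{i != j} = sum_i sum_j - sum_ii
    both = sum_a + sum_b
    with np.errstate(divide="ignore"):
        diff = 1.0 - np.exp(sum_ab - both)
    l3_body = both + np.log(diff) if diff > 0 else -np.inf

    lh = np.array([
        0.0,
        np.log(p1) + sum_a,
        np.log(p2) + sum_b,
        np.log(p1) + np.log(p2) + l3_body,
        np.log(p12) + sum_ab,
    ])
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(trait_a=ta, signal_a=sa, trait_b=tb, signal_b=sb,
                       pp=pp, n_variants=n, priors=(p1, p2, p12))


@dataclass
class LocusGroup:
    members: frozenset                      # of (trait, signal) nodes
    label: str                              # "shared" or "specific"
    group_id: int = 0

    @property
    def traits(self) -> set:
        return {t for t, _ in self.members}


def group_signals(results: list[ColocResult],
                  pp4_min: float = PP4_MIN_DEFAULT) -> list[LocusGroup]:
    """Connected components of the PP4-thresholded colocalization graph.

    Every signal appearing in any tested pair becomes a node; an edge joins
    two signals when their PP4 reaches ``pp4_min``. Components spanning two
    or more traits/factors are labelled shared.
    """
    g = nx.Graph()
    for r in results:
        na = (r.trait_a, r.signal_a)
        nb = (r.trait_b, r.signal_b)
        g.add_node(na)
        g.add_node(nb)
        if not r.untestable and r.pp4 >= pp4_min:
            g.add_edge(na, nb)
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c))
    for i, comp in enumerate(comps):
        traits = {t for t, _ in comp}
        groups.append(LocusGroup(members=frozenset(comp),
                                 label="shared" if len(traits) > 1 else "specific",
                                 group_id=i))
    return groups


@dataclass
class QTLColocOutcome:
    results: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    qtl_datasets: dict = field(default_factory=dict)   # signal id -> dataset


def qtl_coloc(factor_signals: list[SignalSet], qtl: pd.DataFrame,
              ld: RegionLD, mode: str = "decomposed",
              qtl_name: str = "qtl", pp4_min: float = PP4_MIN_DEFAULT,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              prior_sd_gwas: float = PRIOR_SD_CC,
              prior_sd_qtl: float = PRIOR_SD_QT,
              min_overlap: int = MIN_OVERLAP_DEFAULT) -> "QTLColocOutcome":
    """Colocalize factor signals with a molecular QTL over one region.

    ``mode="decomposed"`` first decomposes the QTL into conditionally
    independent signals (the expression-QTL route); ``mode="main_effect"``
    uses the marginal QTL statistics as a single dataset (the protein-QTL
    route, where no matching LD panel exists for conditioning).

    Returns an outcome bundling all pairwise results, the hits with
    PP4 >= pp4_min, and the QTL datasets keyed by signal id (for
    downstream instrument selection).
    """
    shared = qtl[qtl["SNP"].isin(set(ld.snps))]
    if len(shared) < min_overlap:
        return QTLColocOutcome()
    if mode == "decomposed":
        qtl_set = decompose_region(shared, ld, trait=qtl_name,
                                   region_id="qtl")
        qtl_datasets = {d.target: d for d in qtl_set.valid_datasets()}
    elif mode == "main_effect":
        qtl_datasets = {"main": shared}
    else:
        raise ValueError("mode must be 'decomposed' or 'main_effect'")

    results = []
    for sig_set in factor_signals:
        for d in sig_set.valid_datasets():
            for qname, qdata in qtl_datasets.items():
                res = coloc_pair(
                    d, qdata, p1=p1, p2=p2, p12=p12,
                    prior_sd_a=prior_sd_gwas, prior_sd_b=prior_sd_qtl,
                    min_overlap=min_overlap,
                    labels=(sig_set.trait, d.target, qtl_name, qname))
                results.append(res)
    hits = [r for r in results if not r.untestable and r.pp4 >= pp4_min]
    return QTLColocOutcome(results=results, hits=hits,
                           qtl_datasets=qtl_datasets)


def results_frame(results: list[ColocResult],
                  groups: list[LocusGroup] = None) -> pd.DataFrame:
    rows = [r.as_row() for r in results]
    df = pd.DataFrame(rows)
    if groups:
        node_group = {}
        for g in groups:
            for node in g.members:
                node_group[node] = g.group_id
        df["grouped_locus_id"] = [
            node_group.get((r.trait_a, r.signal_a), -1) for r in results]
    return df
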