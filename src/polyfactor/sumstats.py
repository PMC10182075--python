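"""Summary-statistics I/O, harmonization ("munging") and effective sample size.

Harmonization aligns each study table to a reference variant list: variants
absent from the reference are dropped, alleles are flipped to the reference
orientation (negating effects), strand-ambiguous (A/T, C/G) variants are
removed, rare variants (MAF below a floor, 1% by default) are filtered out,
and p-values are recomputed from the harmonized z-scores so that every
downstream threshold acts on a consistent scale.

For case/control studies the per-cohort effective sample size is
``4 * v * (1 - v) * (n_cases + n_controls)`` with sample prevalence
``v = n_cases / (n_cases + n_controls)``; meta-analysed studies sum the
cohort values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import SUMSTATS_COLUMNS

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID = set("ACGT")


class EmptyTableError(ValueError):
    """Raised when harmonization removes every variant."""


@dataclass(frozen=True)
class CohortSpec:
    """One case/control cohort contributing to a (possibly meta-analysed) GWAS."""

    n_cases: int
    n_controls: int

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort case and control counts must be positive")

    @property
    def sample_prevalence(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)

    @property
    def effective_n(self) -> float:
        v = self.sample_prevalence
        return 4.0 * v * (1.0 - v) * (self.n_cases + self.n_controls)


def effective_sample_size(cohorts: Iterable[CohortSpec | Sequence[int]]) -> float:
    """Summed effective sample size over contributing cohorts.

    Accepts :class:`CohortSpec` objects or plain ``(n_cases, n_controls)``
    pairs. The per-cohort value is maximised (and equals the total sample
    size) for a balanced design and shrinks with case/control imbalance.
    """
    total = 0.0
    for c in cohorts:
        if not isinstance(c, CohortSpec):
            c = CohortSpec(*c)
        total += c.effective_n
    return total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"SNP", "A1", "A2"} - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file missing columns: {sorted(missing)}")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")


def read_reference(path) -> pd.DataFrame:
    return read_sumstats(path)


# ---------------------------------------------------------------------------
# Munging
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = a1.map(_COMPLEMENT)
    return comp == a2


def munge(raw: pd.DataFrame, reference: pd.DataFrame,
          maf_min: float = 0.01) -> pd.DataFrame:
    """Harmonize a raw summary table against a reference variant list.

    Steps, in order: validate columns; drop variants with zero beta or zero
    standard error; restrict to reference variants; resolve allele
    orientation (direct match, swapped alleles with effect negation, strand
    complement, or removal when irreconcilable); drop strand-ambiguous
    variants; apply the MAF floor (study frequency when present, reference
    frequency otherwise); recompute z and p. The original p-value, when
    present, is retained in a ``P_ORIG`` audit column.
    """
    needed = {"SNP", "A1", "A2"}
    if not needed <= set(raw.columns):
        raise ValueError(f"missing mandatory columns: {sorted(needed - set(raw.columns))}")
    df = raw.copy()
    if "Z" not in df.columns:
        if not {"BETA", "SE"} <= set(df.columns):
            raise ValueError("need either Z or both BETA and SE columns")

    for col in ("A1", "A2"):
        df[col] = df[col].astype(str).str.upper()
    df = df[df["A1"].isin(_VALID) & df["A2"].isin(_VALID)]

    if {"BETA", "SE"} <= set(df.columns):
        df = df[(df["BETA"] != 0) & (df["SE"] > 0)]
        df["Z"] = df["BETA"] / df["SE"]
    else:
        df = df[df["Z"] != 0]

    if "P" in df.columns:
        df["P_ORIG"] = df["P"]

    ref = reference.rename(columns={
        "A1": "REF_A1", "A2": "REF_A2", "FREQ": "REF_FREQ",
        "CHR": "REF_CHR", "BP": "REF_BP"})
    keep_ref = [c for c in ("SNP", "REF_A1", "REF_A2", "REF_FREQ",
                            "REF_CHR", "REF_BP") if c in ref.columns]
    df = df.merge(ref[keep_ref], on="SNP", how="inner")

    ambiguous = _is_ambiguous(df["A1"], df["A2"])
    df = df[~ambiguous]

    a1, a2 = df["A1"], df["A2"]
    c1 = a1.map(_COMPLEMENT)
    c2 = a2.map(_COMPLEMENT)
    direct = (a1 == df["REF_A1"]) & (a2 == df["REF_A2"])
    swapped = (a1 == df["REF_A2"]) & (a2 == df["REF_A1"])
    strand = (c1 == df["REF_A1"]) & (c2 == df["REF_A2"])
    strand_swapped = (c1 == df["REF_A2"]) & (c2 == df["REF_A1"])
    df = df[direct | swapped | strand | strand_swapped]
    flip = (swapped | strand_swapped).loc[df.index]

    sign = np.where(flip, -1.0, 1.0)
    df["Z"] = df["Z"] * sign
    if "BETA" in df.columns:
        df["BETA"] = df["BETA"] * sign
    if "FREQ" in df.columns:
        df["FREQ"] = np.where(flip, 1.0 - df["FREQ"], df["FREQ"])
    df["A1"] = df["REF_A1"]
    df["A2"] = df["REF_A2"]

    if "FREQ" in df.columns:
        freq = df["FREQ"].where(df["FREQ"].notna(), df.get("REF_FREQ"))
    elif "REF_FREQ" in df.columns:
        freq = df["REF_FREQ"]
        df["FREQ"] = freq
    else:
        freq = None
    if freq is not None:
        maf = np.minimum(freq, 1.0 - freq)
        df = df[maf >= maf_min]

    # positions come from the reference when it carries them
    if "REF_CHR" in df.columns:
        df["CHR"] = df["REF_CHR"]
    if "REF_BP" in df.columns:
        df["BP"] = df["REF_BP"]
    df = df.drop(columns=[c for c in df.columns if c.startswith("REF_")])

    df["P"] = np.clip(2.0 * stats.norm.sf(np.abs(df["Z"])),
                      np.finfo(float).tiny, 1.0)
    if {"CHR", "BP"} <= set(df.columns):
        df = df.sort_values(["CHR", "BP"], kind="mergesort")
    df = df.reset_index(drop=True)
    if df.empty:
        raise EmptyTableError("harmonization removed every variant")
    return df
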