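"""Wald-ratio Mendelian randomization from a molecular QTL to a factor.

A single instrument (the variant with the smallest conditional p-value in
the exposure's signal) gives the causal-effect estimate
beta_outcome / beta_exposure, with a first-order delta-method standard
error and a two-sided normal p-value. A positive estimate means increased
exposure (expression or protein level) predicts increased disease risk
("predisposing"); a negative one is "protective".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MR_ALPHA_DEFAULT = 0.05


class WeakInstrumentError(ValueError):
    """Raised when the exposure effect of the instrument is exactly zero."""


@dataclass
class MRResult:
    exposure: str
    outcome: str
    instrument: str
    estimate: float
    se: float
    p: float
    direction: str
    cell_type: str = ""

    @property
    def significant(self) -> bool:
        return self.p < MR_ALPHA_DEFAULT

    def as_row(self) -> dict:
        return {"exposure": self.exposure, "cell_type": self.cell_type,
                "outcome": self.outcome, "instrument": self.instrument,
                "estimate": self.estimate, "se": self.se, "p": self.p,
                "direction": self.direction}


def wald_ratio(exposure_beta: float, exposure_se: float,
               outcome_beta: float, outcome_se: float,
               exposure: str = "exposure", outcome: str = "outcome",
               instrument: str = "", cell_type: str = "") -> MRResult:
    """Single-instrument Wald ratio with first-order delta-method SE."""
    if exposure_beta == 0:
        raise WeakInstrumentError("exposure effect is zero; no Wald ratio")
    if exposure_se <= 0 or outcome_se <= 0:
        raise ValueError("standard errors must be positive")
    est = outcome_beta / exposure_beta
    se = np.sqrt(outcome_se ** 2 / exposure_beta ** 2
                 + outcome_beta ** 2 * exposure_se ** 2 / exposure_beta ** 4)
    z = est / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return MRResult(exposure=exposure, outcome=outcome, instrument=instrument,
                    estimate=float(est), se=float(se), p=p,
                    direction="predisposing" if est > 0 else "protective",
                    cell_type=cell_type)


def mr_for_coloc_hit(exposure_dataset, outcome_dataset, exposure: str,
                     outcome: str, cell_type: str = "") -> MRResult:
    """Wald ratio for a colocalizing pair of (conditional) datasets.

    The instrument is the variant with the smallest conditional p-value on
    the exposure side that is also present in the outcome dataset.
    """
    from .coloc import _extract

    exp_df = exposure_dataset.records if hasattr(exposure_dataset, "records") \
        else exposure_dataset
    out_df = _extract(outcome_dataset).set_index("SNP")
    pcol = "P_C" if "P_C" in exp_df.columns else "P"
    bcol = "BETA_C" if "BETA_C" in exp_df.columns else "BETA"
    scol = "SE_C" if "SE_C" in exp_df.columns else "SE"
    cand = exp_df[exp_df["SNP"].isin(out_df.index)].sort_values(pcol)
    if cand.empty:
        raise ValueError("no shared instrument between exposure and outcome")
    row = cand.iloc[0]
    out_row = out_df.loc[row["SNP"]]
    return wald_ratio(row[bcol], row[scol], out_row["BETA"], out_row["SE"],
                      exposure=exposure, outcome=outcome,
                      instrument=str(row["SNP"]), cell_type=cell_type)


def mr_frame(results: list[MRResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
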