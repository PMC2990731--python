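"""Continuous and categorical evaluation of binding-affinity predictors.

Two benchmark metrics: the squared Pearson correlation (r^2) between
predicted and observed ln(ic50), and the area under the ROC curve (AROC)
after dichotomizing observed affinities into the conventional categories:
strong binders (SB, ic50 <= 50 nM), weak binders (WB, 50 < ic50 <= 500 nM)
and non-binders (NB, > 500 nM).  Because predictions are ln(ic50) -- lower
means stronger binding -- ranking scores are negated predictions, so an
AROC above 0.5 means better-than-random affinity ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

SB_THRESHOLD_NM = 50.0
WB_THRESHOLD_NM = 500.0


def categorize(ic50_nM: float) -> str:
    """SB if ic50 <= 50 nM, WB if 50 < ic50 <= 500 nM, NB above 500 nM."""
    if not ic50_nM > 0:
        raise ValueError(f"ic50 must be positive, got {ic50_nM}")
    if ic50_nM <= SB_THRESHOLD_NM:
        return "SB"
    if ic50_nM <= WB_THRESHOLD_NM:
        return "WB"
    return "NB"


def auroc(scores: Sequence[float], positives: Sequence[bool]) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2).

    Mann-Whitney formulation; returns NaN when only one class is present.
    """
    pos = np.asarray(positives, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != pos.shape:
        raise ValueError("scores and positives must have equal length")
    if pos.all() or not pos.any():
        return float("nan")
    return float(roc_auc_score(pos, s))


@dataclass(frozen=True)
class EvaluationResult:
    """Benchmark metrics of one predictor on one allele."""

    allele: str
    n: int
    r2: float
    pearson_r: float
    aroc_sb: float
    aroc_wb: float


def evaluate(
    predicted_ln: Sequence[float],
    observed_ic50_nM: Sequence[float],
    allele: str = "",
) -> EvaluationResult:
    """Continuous + categorical benchmark of predictions against measured ic50.

    ``aroc_sb`` uses positives = {observed <= 50 nM}; ``aroc_wb`` uses the
    nested dichotomy positives = {observed <= 500 nM} (binders vs
    non-binders).  Degenerate variance yields NaN sentinels.
    """
    pred = np.asarray(predicted_ln, dtype=float)
    obs = np.asarray(observed_ic50_nM, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    n = pred.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.any(obs <= 0):
        raise ValueError("observed ic50 must be positive (nM)")
    obs_ln = np.log(obs)
    if np.std(pred) < 1e-12 or np.std(obs_ln) < 1e-12:
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, obs_ln)[0, 1])
    return EvaluationResult(
        allele=allele,
        n=n,
        r2=r * r if math.isfinite(r) else float("nan"),
        pearson_r=r,
        aroc_sb=auroc(-pred, obs <= SB_THRESHOLD_NM),
        aroc_wb=auroc(-pred, obs <= WB_THRESHOLD_NM),
    )


def evaluation_table(results: Sequence[EvaluationResult]) -> "pd.DataFrame":
    """Benchmark table: rows = alleles (+ Average), columns AROC_SB/AROC_WB/r2."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "allele": [r.allele for r in results],
            "n": [r.n for r in results],
            "AROC_SB": [r.aroc_sb for r in results],
            "AROC_WB": [r.aroc_wb for r in results],
            "r2": [r.r2 for r in results],
        }
    ).set_index("allele")
    avg = df[["AROC_SB", "AROC_WB", "r2"]].mean()
    df.loc["Average"] = [df["n"].sum(), avg["AROC_SB"], avg["AROC_WB"], avg["r2"]]
    df["n"] = df["n"].astype(int)
    return df
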