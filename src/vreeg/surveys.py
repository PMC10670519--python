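"""SSQ scoring and the cybersickness statistics.

The Simulator Sickness Questionnaire has 16 symptom items rated 0-3, mapped
(with overlap) onto Nausea, Oculomotor and Disorientation subscales.  Raw
subscale sums are scaled by the standard conversion weights
(N x 9.54, O x 7.58, D x 13.92) and the total score is
TS = 3.74 x (rawN + rawO + rawD).

Scene effects are tested with the Friedman rank test (subjects as blocks,
scenes as treatments; the statistic is referred to the chi-square
distribution with k-1 df) followed by Conover's pairwise post-hoc
comparisons on the Friedman ranks, referred to the t distribution with
(n-1)(k-1) df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SSQ_ITEMS

SSQ_WEIGHTS = {"N": 9.54, "O": 7.58, "D": 13.92}
SSQ_TOTAL_WEIGHT = 3.74

#: item index (0-based) -> subscales it contributes to.
SSQ_ITEM_MAP = {i: subs for i, (_, subs) in enumerate(SSQ_ITEMS)}


@dataclass
class SSQScores:
    """Weighted subscale scores and the total score for one response."""

    N: float
    O: float
    D: float
    TS: float
    raw_N: int
    raw_O: int
    raw_D: int


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    scale: str = ""


@dataclass
class PosthocMatrix:
    """Symmetric k x k p-value matrix over conditions."""

    p_values: pd.DataFrame
    statistics: pd.DataFrame
    method: str = "conover"
    adjustment: str = "none"


def score_ssq(items) -> SSQScores:
    """Score one 16-item SSQ response (ratings in {0, 1, 2, 3})."""
    arr = np.asarray(items)
    if arr.shape != (16,):
        raise ValueError("exactly 16 item ratings required")
    if not np.all(np.isin(arr, [0, 1, 2, 3])):
        raise ValueError("ratings must be integers in {0, 1, 2, 3}")
    raw = {"N": 0, "O": 0, "D": 0}
    for i, rating in enumerate(arr):
        for sub in SSQ_ITEM_MAP[i]:
            raw[sub] += int(rating)
    return SSQScores(
        N=raw["N"] * SSQ_WEIGHTS["N"],
        O=raw["O"] * SSQ_WEIGHTS["O"],
        D=raw["D"] * SSQ_WEIGHTS["D"],
        TS=SSQ_TOTAL_WEIGHT * (raw["N"] + raw["O"] + raw["D"]),
        raw_N=raw["N"], raw_O=raw["O"], raw_D=raw["D"],
    )


def score_ssq_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a (subject, scene, item01..item16) table row-wise."""
    item_cols = [f"item{i + 1:02d}" for i in range(16)]
    missing = [c for c in item_cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    rows = []
    for _, r in table.iterrows():
        s = score_ssq(r[item_cols].to_numpy())
        rows.append({"subject": r["subject"], "scene": r["scene"],
                     "N": s.N, "O": s.O, "D": s.D, "TS": s.TS})
    return pd.DataFrame(rows)


def summarize_ssq(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean / median / SD of each scale per scene (report layout)."""
    out = []
    for scene, grp in scores.groupby("scene", sort=False):
        row = {"scene": scene}
        for scale in ("N", "O", "D", "TS"):
            row[f"{scale}_mean"] = grp[scale].mean()
            row[f"{scale}_median"] = grp[scale].median()
            row[f"{scale}_sd"] = grp[scale].std(ddof=1)
        out.append(row)
    return pd.DataFrame(out)


def _score_matrix(scores) -> np.ndarray:
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    return m


def friedman_test(scores, scale: str = "") -> FriedmanResult:
    """Friedman omnibus test on a subjects x conditions score matrix.

    Within-subject mid-ranks; the tie-corrected statistic is referred to
    chi-square with k-1 degrees of freedom.
    """
    m = _score_matrix(scores)
    k = m.shape[1]
    if np.ptp(stats.rankdata(m, axis=1, method="average"), axis=1).max() == 0:
        # all conditions tie within every subject -> zero statistic
        return FriedmanResult(statistic=0.0, df=k - 1, p_value=1.0,
                              scale=scale)
    chi2, p = stats.friedmanchisquare(*m.T)
    return FriedmanResult(statistic=float(chi2), df=k - 1,
                          p_value=float(p), scale=scale)


def conover_posthoc(scores, conditions=None,
                    adjust: str = "none") -> PosthocMatrix:
    """Conover's pairwise post-hoc comparisons after a Friedman test.

    With column rank sums R_j over within-block mid-ranks, treatments i, j
    are compared with

        t = (R_i - R_j) / sqrt(2 (n A - B) / ((n-1)(k-1))),

    A the sum of squared ranks, B = (sum_j R_j^2) / n, referred to the t
    distribution with (n-1)(k-1) df (two-sided).  Optional Holm adjustment
    over the k(k-1)/2 pairs.
    """
    if adjust not in {"none", "holm"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    m = _score_matrix(scores)
    n, k = m.shape
    if conditions is None:
        conditions = [f"c{j}" for j in range(k)]
    if len(conditions) != k:
        raise ValueError("one condition name per column required")

    ranks = stats.rankdata(m, axis=1, method="average")
    R = ranks.sum(axis=0)
    A = float((ranks ** 2).sum())
    B1 = float((R ** 2).sum())
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * (n * A - B1) / df

    tstat = np.zeros((k, k))
    pmat = np.ones((k, k))
    if denom_sq <= 0:
        warnings.warn("zero rank variance: all pairwise p-values set to 1",
                      RuntimeWarning)
    else:
        denom = np.sqrt(denom_sq)
        for i in range(k):
            for j in range(i + 1, k):
                t = (R[i] - R[j]) / denom
                p = 2.0 * stats.t.sf(abs(t), df)
                tstat[i, j], tstat[j, i] = t, -t
                pmat[i, j] = pmat[j, i] = min(p, 1.0)

    if adjust == "holm":
        iu = np.triu_indices(k, 1)
        flat = pmat[iu]
        order = np.argsort(flat)
        adj = np.empty_like(flat)
        mth = len(flat)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (mth - rank) * flat[idx])
            adj[idx] = min(running, 1.0)
        pmat[iu] = adj
        pmat.T[iu] = adj

    labels = list(conditions)
    return PosthocMatrix(
        p_values=pd.DataFrame(pmat, index=labels, columns=labels),
        statistics=pd.DataFrame(tstat, index=labels, columns=labels),
        method="conover", adjustment=adjust,
    )


def scene_score_matrix(scores: pd.DataFrame, scale: str = "TS",
                       scenes=None) -> tuple[np.ndarray, list[str]]:
    """Pivot a long scores table into subjects x scenes for one scale."""
    wide = scores.pivot(index="subject", columns="scene", values=scale)
    if scenes is not None:
        wide = wide[list(scenes)]
    if wide.isna().any().any():
        raise ValueError("incomplete subject x scene design")
    return wide.to_numpy(dtype=float), list(wide.columns)
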