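"""Reliability and exploratory factor analysis of the VRI questionnaire.

Implements the questionnaire-analysis toolkit used to validate the
hierarchical immersion model (engagement, engrossment, total immersion):
Cronbach's alpha internal consistency, the Kaiser-Meyer-Olkin sampling
adequacy statistic, Bartlett's test of sphericity, and exploratory factor
analysis by principal-component extraction of the item correlation matrix
with varimax rotation.  Factor retention defaults to the Kaiser
eigenvalue > 1 rule with an explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _as_matrix(items) -> np.ndarray:
    X = np.asarray(items, dtype=float)
    if isinstance(items, pd.DataFrame):
        X = items.to_numpy(dtype=float)
    if X.ndim != 2:
        raise ValueError("need a respondents x items matrix")
    return X


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum(item var) / var(total)).

    Sample (n-1) variances, the questionnaire convention.  The total column
    is the respondent-wise sum of the items.
    """
    X = _as_matrix(items)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant item(s): correlation undefined")
    return np.corrcoef(X, rowvar=False)


def kmo(items) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy over all items.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal zero-order
    correlations r and anti-image partial correlations q.
    """
    X = _as_matrix(items)
    R = _correlation(X)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(items) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5) / 6) ln|R|, df = p(p-1)/2.
    """
    X = _as_matrix(items)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more respondents than items")
    R = _correlation(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


def varimax(loadings: np.ndarray, max_iter: int = 100,
            tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a p x m loading matrix."""
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L
    Rot = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        Rot = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ Rot


@dataclass
class ReliabilityReport:
    """Reliability + EFA results for one item subset (report layout)."""

    alpha: float
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_factors: int
    variance_explained_pct: float
    loadings: pd.DataFrame
    top_items: dict[str, list[str]] = field(default_factory=dict)


def efa(items, n_factors: int | str = "auto",
        loading_cutoff: float = 0.5) -> ReliabilityReport:
    """Exploratory factor analysis of a respondents x items table.

    Principal-component extraction from the item correlation matrix;
    ``n_factors="auto"`` retains eigenvalues > 1 (Kaiser rule).  Loadings
    are varimax-rotated; variance explained is 100 x (retained eigenvalue
    sum)/p; top items are those with |loading| >= *loading_cutoff* on each
    factor.
    """
    X = _as_matrix(items)
    n, p = X.shape
    names = (list(items.columns) if isinstance(items, pd.DataFrame)
             else [f"item{i + 1:02d}" for i in range(p)])
    if n <= p:
        raise ValueError("need more respondents than items")
    R = _correlation(X)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if n_factors == "auto":
        m = max(int((evals > 1.0).sum()), 1)
    else:
        m = int(n_factors)
        if not 1 <= m <= p:
            raise ValueError(f"n_factors must be in [1, {p}]")

    L = evecs[:, :m] * np.sqrt(np.clip(evals[:m], 0.0, None))
    L = varimax(L)
    # orient each factor so its largest loading is positive
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    L = L * signs
    fac_names = [f"F{j + 1}" for j in range(m)]
    load_df = pd.DataFrame(L, index=names, columns=fac_names)

    top = {f: [names[i] for i in np.flatnonzero(
        np.abs(L[:, j]) >= loading_cutoff)]
        for j, f in enumerate(fac_names)}

    chi2, df, pval = bartlett_sphericity(X)
    return ReliabilityReport(
        alpha=cronbach_alpha(X),
        kmo=kmo(X),
        bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval,
        eigenvalues=evals,
        n_factors=m,
        variance_explained_pct=float(100.0 * evals[:m].sum() / p),
        loadings=load_df,
        top_items=top,
    )


def level_report(vri: pd.DataFrame, item_map: pd.DataFrame,
                 level: str, n_factors: int | str = "auto"
                 ) -> ReliabilityReport:
    """EFA + reliability for the items of one immersion level."""
    items = item_map.loc[item_map["level"] == level, "item"].tolist()
    if not items:
        raise ValueError(f"unknown immersion level {level!r}")
    return efa(vri[items], n_factors=n_factors)
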