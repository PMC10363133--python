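"""Spearman co-occurrence matrices and predator-prey link extraction.

All correlations are Spearman rank correlations (Pearson correlation of
mid-ranks, average ranks for ties) with two-sided p-values from the
t-approximation.  Matrices are pairwise-complete: each variable pair is
correlated over the sampling dates where both are observed, and the
per-pair sample count is reported alongside rho and p.  Predator-prey
links are the significant (p < alpha, no multiple-testing correction)
correlations between predator relative biomasses (mesozooplankton groups
plus the mixotrophic ciliate class Litostomatea) and prey relative
biomasses (phyto- and bacterioplankton groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "spearman_rho",
    "spearman_pvalue",
    "spearman_test",
    "correlation_matrix",
    "predator_prey_links",
]

MIN_PAIRS = 3


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired observations of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation over complete pairs.

    Pairs with a missing value in either variable are dropped first; fewer
    than three remaining pairs is an error.  Zero variance in either rank
    vector leaves rho undefined (NaN).
    """
    x, y = _complete_pairs(x, y)
    if x.size < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {x.size}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t-approximation.

    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom;
    |rho| = 1 maps to p = 0.
    """
    if n < MIN_PAIRS:
        raise ValueError(f"need n >= {MIN_PAIRS}")
    if np.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_test(x, y) -> tuple[float, float, int]:
    """(rho, p, n) over complete pairs."""
    xc, yc = _complete_pairs(x, y)
    if xc.size < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {xc.size}")
    rho = spearman_rho(xc, yc)
    return rho, spearman_pvalue(rho, xc.size), int(xc.size)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Spearman matrix with p-values and pair counts."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_pairs: pd.DataFrame
    total_n: pd.Series
    alpha: float = 0.05

    @property
    def variables(self) -> list[str]:
        return list(self.rho.columns)

    def significant(self) -> pd.DataFrame:
        """Boolean mask of entries with p below alpha (off-diagonal)."""
        sig = self.p_value < self.alpha
        np.fill_diagonal(sig.values, False)
        return sig


def correlation_matrix(frame: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """All-pairs Spearman correlations of date-aligned variables.

    ``frame`` holds one column per variable, indexed by sampling date;
    missing observations are NaN.  Every unordered pair is correlated on
    its pairwise-complete dates at individual-sampling resolution.  Pairs
    with fewer than three shared dates are reported missing with their
    count.
    """
    cols = list(frame.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    npairs = np.zeros((k, k), dtype=int)
    data = frame.to_numpy(dtype=float)
    notna = ~np.isnan(data)
    for a in range(k):
        rho[a, a] = 1.0
        pval[a, a] = 0.0
        npairs[a, a] = int(notna[:, a].sum())
        for b in range(a + 1, k):
            keep = notna[:, a] & notna[:, b]
            n = int(keep.sum())
            npairs[a, b] = npairs[b, a] = n
            if n < MIN_PAIRS:
                continue
            r = spearman_rho(data[keep, a], data[keep, b])
            rho[a, b] = rho[b, a] = r
            p = spearman_pvalue(r, n)
            pval[a, b] = pval[b, a] = p
    idx = pd.Index(cols)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_value=pd.DataFrame(pval, index=idx, columns=idx),
        n_pairs=pd.DataFrame(npairs, index=idx, columns=idx),
        total_n=pd.Series(notna.sum(axis=0), index=idx),
        alpha=alpha,
    )


def predator_prey_links(
    predators: pd.DataFrame,
    prey: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant predator-prey Spearman links on shared sampling dates.

    ``predators`` and ``prey`` are date-indexed relative-biomass tables
    (one column per group).  Each (predator, prey) pair is correlated on
    the dates present in both tables; edges with p < ``alpha`` are kept
    (no multiple-testing correction, mirroring a plain p < 0.05 display
    rule).  Returns an edge list (predator, prey, rho, p, n), empty with a
    warning when no dates are shared.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    shared = predators.index.intersection(prey.index)
    edges: list[dict] = []
    if len(shared) == 0:
        import logging
        logging.getLogger(__name__).warning("no shared sampling dates between tables")
        return pd.DataFrame(columns=["predator", "prey", "rho", "p", "n"])
    pred = predators.loc[shared]
    pry = prey.loc[shared]
    for pcol in pred.columns:
        for qcol in pry.columns:
            x = pred[pcol].to_numpy(dtype=float)
            y = pry[qcol].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < MIN_PAIRS:
                continue
            rho = spearman_rho(x[keep], y[keep])
            if np.isnan(rho):
                continue
            p = spearman_pvalue(rho, int(keep.sum()))
            if p < alpha:
                edges.append({"predator": pcol, "prey": qcol,
                              "rho": rho, "p": p, "n": int(keep.sum())})
    return pd.DataFrame(edges, columns=["predator", "prey", "rho", "p", "n"])
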