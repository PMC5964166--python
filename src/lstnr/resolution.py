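"""GLM transformants, pooled gene x group ANOVA, and resolution weights.

The fitted threshold family is restated in exponential-family form; its
linear predictor B maps shifted RPM onto a scale where within-gene group
differences can be tested by an ordinary two-way (gene x group) ANOVA with
a single pooled error term.  Gene significance in that test measures how
well each gene's counts are *resolved* by the sequencing run, not whether
it is differentially expressed.  Significance ranks are converted into
cumulative-hazard weights, w = -ln(survival of the gene's rank), which are
later used to scale fold-changes: near zero for the least-resolved gene,
about ln(2G) for the best-resolved of G genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix
from .distfit import FitResult

__all__ = [
    "TransformantMatrix",
    "ResolutionTable",
    "PooledAnova",
    "transformant",
    "pooled_anova",
    "bh_adjust",
    "resolution_weights",
]


@dataclass
class TransformantMatrix:
    """Linear predictor B and link-normalized values eta per gene x sample."""

    B: pd.DataFrame
    eta: pd.DataFrame
    family: str
    sample_groups: pd.Series


def transformant(em: ExpressionMatrix, fit: FitResult) -> TransformantMatrix:
    """Compute B and eta from a gamma-shifted RPM matrix.

    lognormal3: B = ln(y + gamma), eta = B (already normal-scale).
    weibull3:   B = 1/(y + gamma) (reciprocal of exceedance over the
                threshold), normalized back by eta = 1/B.
    """
    if fit.gamma > 0 and em.shift == 0.0 and (em.values.to_numpy() <= 0).any():
        raise ValueError(
            "matrix contains zeros and is unshifted; call apply_shift(em, fit.gamma) first"
        )
    v = em.values
    if (v.to_numpy() <= 0).any():
        raise ValueError("transformant needs strictly positive (shifted) values")
    if fit.family == "lognormal3":
        B = np.log(v)
        eta = B
    elif fit.family == "weibull3":
        B = 1.0 / v
        eta = v
    else:
        raise ValueError(f"unknown family {fit.family!r}")
    return TransformantMatrix(B=B, eta=eta, family=fit.family, sample_groups=em.sample_groups)


@dataclass
class PooledAnova:
    """Per-gene group F tests sharing one pooled residual variance.

    For gene g with J groups: MS_group(g) = sum_j n_j (vbar_gj - vbar_g)^2
    / (J - 1); the error term is pooled over every gene x group block,
    MSE = sum_g SS_resid(g) / [G (N - J)]; F_g = MS_group(g) / MSE with
    (J - 1, G(N - J)) degrees of freedom.
    """

    table: pd.DataFrame  # per gene: F, p
    group_means: pd.DataFrame  # genes x groups
    n_per_group: pd.Series
    mse: float
    df1: int
    df2: int

    @property
    def sigma(self) -> float:
        """Pooled residual SD."""
        return float(np.sqrt(self.mse))


def _group_stats(values: pd.DataFrame, groups: pd.Series):
    groups = groups.reindex(values.columns)
    order = list(dict.fromkeys(groups))
    means = {}
    rss = np.zeros(values.shape[0])
    n = {}
    for g in order:
        cols = groups.index[groups == g]
        block = values[cols].to_numpy()
        m = block.mean(axis=1)
        means[g] = m
        rss += ((block - m[:, None]) ** 2).sum(axis=1)
        n[g] = len(cols)
    gm = pd.DataFrame(means, index=values.index)
    return gm, pd.Series(n)[order], rss


def pooled_anova(values: pd.DataFrame, groups: pd.Series) -> PooledAnova:
    """Gene x group two-way ANOVA with a common pooled error term."""
    gm, n, rss = _group_stats(values, groups)
    J = len(n)
    if J < 2:
        raise ValueError("pooled ANOVA needs at least 2 groups")
    if (n < 2).all():
        raise ValueError("need >= 2 replicates in at least one group")
    N = int(n.sum())
    G = values.shape[0]
    df1 = J - 1
    df2 = G * (N - J)
    if df2 <= 0:
        raise ValueError("pooled residual degrees of freedom <= 0")
    grand = (gm * n.to_numpy()).sum(axis=1) / N
    ms_group = ((gm.sub(grand, axis=0) ** 2) * n.to_numpy()).sum(axis=1) / df1
    mse = rss.sum() / df2
    if mse <= 0:
        raise ValueError("pooled MSE is zero: degenerate (constant) data")
    F = ms_group / mse
    p = stats.f.sf(F, df1, df2)
    # survival can underflow to exactly 0 for extreme F; keep p in (0, 1]
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({"F": F, "p": p}, index=values.index)
    return PooledAnova(table=table, group_means=gm, n_per_group=n, mse=float(mse), df1=df1, df2=df2)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if (arr <= 0).any() or (arr > 1).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


@dataclass
class ResolutionTable:
    """Per-gene transformant significance, rank, survival and weight."""

    table: pd.DataFrame  # F, p, fdr_p, resolved, rank, survival, weight

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    @property
    def n_resolved(self) -> int:
        return int(self.table["resolved"].sum())


def resolution_weights(
    p: pd.Series, F: pd.Series | None = None, alpha: float = 0.05
) -> ResolutionTable:
    """Cumulative-hazard resolution weights from transformant p-values.

    Significance scores s = -log10(p) are ranked ascending (least
    significant first, ties get average rank); the survival of a gene's
    rank uses the Hazen plotting position S = 1 - (r - 0.5)/G so the top
    gene keeps a finite weight w = -ln(S) = ln(2G).  ``resolved`` flags
    BH-adjusted p < alpha.
    """
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    s = -np.log10(p.to_numpy())
    r = stats.rankdata(s, method="average")
    G = len(p)
    S = 1.0 - (r - 0.5) / G
    w = -np.log(S)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "F": F.reindex(p.index) if F is not None else np.nan,
            "p": p,
            "fdr_p": fdr,
            "resolved": fdr < alpha,
            "rank": r,
            "survival": S,
            "weight": w,
        },
        index=p.index,
    )
    return ResolutionTable(table=table)
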