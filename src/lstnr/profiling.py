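"""Retrospective power and Profiler selection among DEGREEs.

For every DEGREE the observed within-gene effect size Delta_Log2FC (range
of unweighted group-mean Log2FC) is paired with the mean retrospective
power <<pi>> of its pairwise group contrasts under a two-sample noncentral
t model, and with pi_low, the power re-evaluated at the 95% lower
confidence limit of the noncentrality (Neyman inversion of the noncentral
t CDF at the observed statistic).  Candidates with <<pi>> above a floor
(default 90%) are ranked by pi_low; the Profiler set is the maximal prefix
of that ranking whose successive Delta_Log2FC lag differences remain
non-positive — the genes for which larger power coincides with larger
observed effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .detest import DEResult

__all__ = ["PowerTable", "pairwise_power", "retrospective_power", "select_profilers"]


def _power_at_ncp(tcrit: float, df: int, ncp) -> np.ndarray:
    """P(|T'| > tcrit) for a noncentral t with noncentrality ncp.

    The lower-tail term is bounded by the central 0.025 and vanishes for
    ncp of a few units; scipy's nct.cdf can return NaN there, which is
    safely replaced by 0.
    """
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = np.nan_to_num(stats.nct.cdf(-tcrit, df, ncp), nan=0.0)
    return upper + lower


def pairwise_power(d, n_a, n_b, alpha: float = 0.05):
    """Two-sided two-sample t power at standardized effect size d.

    ncp = d sqrt(n_a n_b / (n_a + n_b)), df = n_a + n_b - 2.  At d = 0 the
    power equals alpha (the test's size).
    """
    d = np.asarray(d, dtype=float)
    df = n_a + n_b - 2
    if min(n_a, n_b) < 2:
        raise ValueError("power needs >= 2 samples per group")
    ncp = d * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return _power_at_ncp(tcrit, df, ncp)


def _ncp_lower_cl(t_obs: np.ndarray, df: int, conf: float = 0.95) -> np.ndarray:
    """95% lower confidence limit of the noncentrality given observed t.

    Solves nct.cdf(t_obs; df, ncp) = (1+conf)/2 for ncp (vectorized
    bisection); clamped at 0 when even a central t makes t_obs unremarkable.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    target = (1 + conf) / 2
    lo = np.zeros_like(t_obs)
    # at ncp=0 the cdf is t.cdf(t_obs); if already below target, the CL is 0
    at_zero = stats.t.cdf(t_obs, df)
    solvable = at_zero > target
    hi = np.maximum(t_obs + 10.0, 10.0)
    lo_b, hi_b = lo.copy(), hi.copy()
    for _ in range(80):
        mid = 0.5 * (lo_b + hi_b)
        c = stats.nct.cdf(t_obs, df, mid)
        take_hi = c > target  # cdf decreasing in ncp: still above target -> move lo up
        lo_b = np.where(take_hi, mid, lo_b)
        hi_b = np.where(take_hi, hi_b, mid)
    out = 0.5 * (lo_b + hi_b)
    return np.where(solvable, out, 0.0)


@dataclass
class PowerTable:
    """Per-DEGREE effect size, retrospective power and Profiler flag."""

    table: pd.DataFrame  # delta, pi_mean, pi_low, rank, lag_diff, profiler

    @property
    def profilers(self) -> pd.Index:
        return self.table.index[self.table["profiler"]]


def retrospective_power(
    de: DEResult,
    genes: pd.Index | None = None,
    alpha: float = 0.05,
    conf: float = 0.95,
    sigma: float | None = None,
) -> PowerTable:
    """Observed effect sizes and retrospective power for candidate genes.

    ``genes`` defaults to the DEGREE stratum.  The standardized effect of a
    contrast is d = |Lbar_a - Lbar_b| / sigma, with sigma the pooled
    unweighted-residual SD on the Log2FC scale (pass the noise benchmark's
    sigma_SSR; when omitted it is approximated from the weighted model);
    power and its lower limit come from the noncentral t at two-sided
    ``alpha``.
    """
    if genes is None:
        genes = de.genes("degree")
    genes = pd.Index(genes)
    L = de.group_means.loc[genes]
    n = _group_sizes(de)
    if (n < 2).any():
        raise ValueError("retrospective power needs >= 2 samples per group")
    if sigma is None:
        sigma = _unweighted_sigma(de)
    pairs = list(combinations(L.columns, 2))
    pi_mean = np.zeros(len(genes))
    pi_low = np.zeros(len(genes))
    for a, b in pairs:
        d = (L[a] - L[b]).abs().to_numpy() / sigma
        na, nb = int(n[a]), int(n[b])
        scale = np.sqrt(na * nb / (na + nb))
        df = na + nb - 2
        pi_mean += pairwise_power(d, na, nb, alpha)
        ncp_lo = _ncp_lower_cl(d * scale, df, conf)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        pi_low += _power_at_ncp(tcrit, df, ncp_lo)
    pi_mean /= len(pairs)
    pi_low /= len(pairs)
    delta = L.max(axis=1) - L.min(axis=1)
    table = pd.DataFrame(
        {"delta": delta, "pi_mean": pi_mean, "pi_low": pi_low}, index=genes
    )
    return PowerTable(table=table)


def _group_sizes(de: DEResult) -> pd.Series:
    return de.anova.n_per_group


def _unweighted_sigma(de: DEResult) -> float:
    # pooled residual SD of the *unweighted* Log2FC model: back out the
    # weighted residuals gene by gene (z-resid = w * L-resid)
    w = de.weights.to_numpy()
    # residual SS per gene is not stored; reconstruct from weighted MSE is
    # biased by heterogeneity, so recompute from group means and data scale:
    # sigma^2 = mean over genes of Var(L residuals) -- use weighted MSE / E[w^2]
    ew2 = float(np.mean(w * w))
    return float(np.sqrt(de.anova.mse / ew2))


def select_profilers(pt: PowerTable, pi_min: float = 0.90) -> PowerTable:
    """Rank candidates and keep the monotone-effect-size prefix.

    Keep genes with pi_mean > pi_min; sort by pi_low descending (ties:
    delta descending, then gene ID); the Profiler set is the prefix before
    the first positive lag difference of delta down the ranking.  An empty
    candidate set yields an empty (not erroring) result.
    """
    t = pt.table
    cand = t[t["pi_mean"] > pi_min].copy()
    cand["_gene"] = cand.index
    cand = cand.sort_values(
        ["pi_low", "delta", "_gene"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_gene")
    cand["rank"] = np.arange(1, len(cand) + 1)
    lag = cand["delta"].diff()
    cand["lag_diff"] = lag
    positive = np.flatnonzero(lag.to_numpy() > 0)
    cut = positive[0] if len(positive) else len(cand)
    cand["profiler"] = cand["rank"] <= cut
    out = t.copy()
    for col in ("rank", "lag_diff"):
        out[col] = cand[col]
    out["profiler"] = cand["profiler"].reindex(out.index, fill_value=False)
    pt.table = out
    return pt
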