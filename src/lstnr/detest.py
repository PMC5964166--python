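"""Resolution-weighed differential expression testing and gene stratification.

Log2 fold-changes are computed against a fixed per-gene reference (the
baseline-group mean of shifted RPM, or the grand mean for profiling
designs), scaled by each gene's resolution weight, and tested in the
pooled gene x group ANOVA.  Genes are then stratified:

* SG      - significant under the weighed ANOVA at FDR < 0.05;
* DEG     - SG with practical effect size (delta_Log2FC > 0.3 sigma_SSR)
            and at least one pairwise-significant group contrast;
* LSTNR   - SG with practical effect size and at least one group whose
            mean Log2FC exceeds the transcriptome-wide noise threshold
            (the half-width of a 95%/95% normal tolerance interval of
            gene x group residuals among SGs, i.e. SNR > 1);
* DEGREE  - a gene that is both DEG and LSTNR (and, when annotation is
            in play, carries an official symbol).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from .data_io import ExpressionMatrix
from .resolution import PooledAnova, ResolutionTable, bh_adjust, pooled_anova

__all__ = [
    "Log2FCMatrix",
    "DEResult",
    "NoiseBenchmark",
    "log2fc",
    "weighed_anova",
    "effect_size",
    "posthoc_pairwise",
    "tolerance_factor",
    "tolerance_factor_exact",
    "noise_benchmark",
    "stratify",
]

GRAND_MEAN = "grand-mean"


@dataclass
class Log2FCMatrix:
    """log2((y + gamma)/ref_g) per gene x sample, with the reference recorded."""

    values: pd.DataFrame
    sample_groups: pd.Series
    reference: str
    ref_values: pd.Series  # per-gene reference level on the shifted scale


def log2fc(em: ExpressionMatrix, reference: str | None = None) -> Log2FCMatrix:
    """Log2 fold-change of shifted RPM against a fixed per-gene reference.

    ``reference`` names a sample group (treatment-vs-control designs) or is
    ``"grand-mean"`` (phenotype profiling); ``None`` uses the matrix's
    baseline group if set, else the grand mean.
    """
    if (em.values.to_numpy() <= 0).any():
        raise ValueError("log2fc needs strictly positive values; apply_shift first")
    if reference is None:
        reference = em.baseline_group or GRAND_MEAN
    if reference == GRAND_MEAN:
        ref = em.values.mean(axis=1)
    else:
        cols = em.sample_groups.index[em.sample_groups == reference]
        if len(cols) == 0:
            raise ValueError(f"unknown reference group {reference!r}")
        ref = em.values[cols].mean(axis=1)
    L = np.log2(em.values.div(ref, axis=0))
    return Log2FCMatrix(
        values=L, sample_groups=em.sample_groups, reference=reference, ref_values=ref
    )


@dataclass
class DEResult:
    """Weighed-ANOVA statistics, effect sizes, post-hoc p's and strata flags."""

    table: pd.DataFrame  # per gene: F, p, fdr_p, delta, posthoc_min_p, flags
    weighted_group_means: pd.DataFrame  # zbar_gj
    group_means: pd.DataFrame  # unweighted Lbar_gj
    anova: PooledAnova
    weights: pd.Series
    alpha: float = 0.05

    def genes(self, stratum: str) -> pd.Index:
        """Gene IDs carrying a given flag ('sg', 'deg', 'lstnr', 'degree')."""
        return self.table.index[self.table[stratum]]

    def counts(self) -> dict[str, int]:
        return {s: int(self.table[s].sum()) for s in ("sg", "deg", "lstnr", "degree") if s in self.table}


def weighed_anova(
    lfc: Log2FCMatrix, weights: ResolutionTable | pd.Series, alpha: float = 0.05
) -> DEResult:
    """Pooled gene x group ANOVA of resolution-weighed Log2FC, z = w_g * L.

    The F statistic is invariant to a global rescaling of the weights
    (both MS_group and the pooled MSE pick up the same factor), so only
    the *relative* resolution of genes matters.
    """
    w = weights.weights if isinstance(weights, ResolutionTable) else weights
    missing = lfc.values.index.difference(w.index)
    if len(missing):
        raise ValueError(f"missing resolution weights for genes: {list(missing[:5])}")
    w = w.reindex(lfc.values.index)
    z = lfc.values.mul(w, axis=0)
    an = pooled_anova(z, lfc.sample_groups)
    fdr = bh_adjust(an.table["p"])
    gm, _, _ = _unweighted_group_means(lfc)
    table = pd.DataFrame(
        {
            "F": an.table["F"],
            "p": an.table["p"],
            "fdr_p": fdr,
            "sg": fdr < alpha,
        },
        index=lfc.values.index,
    )
    return DEResult(
        table=table,
        weighted_group_means=an.group_means,
        group_means=gm,
        anova=an,
        weights=w,
        alpha=alpha,
    )


def _unweighted_group_means(lfc: Log2FCMatrix):
    from .resolution import _group_stats

    return _group_stats(lfc.values, lfc.sample_groups)


def effect_size(de: DEResult, frac: float = 0.3) -> pd.Series:
    """Practical effect-size flag: delta_Log2FC > frac * sigma_SSR.

    delta_Log2FC is the range of weighted group means; sigma_SSR is the
    pooled residual SD of the weighed model, so frac = 0.3 corresponds to
    the "5% of gene-wise variation" practical floor.
    """
    zbar = de.weighted_group_means
    delta = zbar.max(axis=1) - zbar.min(axis=1)
    threshold = frac * de.anova.sigma
    de.table["delta"] = delta
    de.table["delta_flag"] = delta > threshold
    de.table.attrs["delta_effect"] = threshold
    return de.table["delta_flag"]


def posthoc_pairwise(de: DEResult) -> pd.DataFrame:
    """Fisher-LSD pairwise contrasts of weighted group means.

    t = (zbar_a - zbar_b) / sqrt(MSE (1/n_a + 1/n_b)) with the pooled
    residual df; two-sided p, unadjusted.  Adds ``posthoc_min_p``.
    """
    an = de.anova
    n = an.n_per_group
    if (n < 2).any() and len(n) < 2:
        raise ValueError("post-hoc contrasts need at least two groups")
    zbar = de.weighted_group_means
    cols = {}
    for a, b in combinations(zbar.columns, 2):
        se = np.sqrt(an.mse * (1.0 / n[a] + 1.0 / n[b]))
        t = (zbar[a] - zbar[b]) / se
        cols[f"{a}|{b}"] = 2.0 * stats.t.sf(np.abs(t), an.df2)
    out = pd.DataFrame(cols, index=zbar.index)
    de.table["posthoc_min_p"] = out.min(axis=1)
    return out


def tolerance_factor(n: int, P: float = 0.95, conf: float = 0.95, nu: int | None = None) -> float:
    """Two-sided normal tolerance factor k, Howe's approximation.

    k = z_{(1+P)/2} * sqrt(nu (1 + 1/n) / chi2_{1-conf, nu}); the interval
    mean +/- k s contains at least a fraction P of the population with
    confidence ``conf``.  ``nu`` defaults to n - 1.
    """
    if n < 2:
        raise ValueError("tolerance factor needs n >= 2")
    nu = n - 1 if nu is None else nu
    z = stats.norm.ppf((1 + P) / 2)
    chi = stats.chi2.ppf(1 - conf, nu)
    return float(z * np.sqrt(nu * (1 + 1.0 / n) / chi))


def tolerance_factor_exact(n: int, P: float = 0.95, conf: float = 0.95, nu: int | None = None) -> float:
    """Exact two-sided normal tolerance factor (numerical integral).

    Solves for k in  conf = 2 int_0^inf P[chi2_nu > nu q(z)/k^2] phi(z) dz
    where q(z) is the P-quantile of the noncentral chi-square with 1 df and
    noncentrality z^2/n.  Used as an independent check of Howe's formula.
    """
    nu = n - 1 if nu is None else nu

    def confidence(k: float) -> float:
        def integrand(z: float) -> float:
            q = stats.ncx2.ppf(P, 1, z * z / n)
            return stats.chi2.sf(nu * q / (k * k), nu) * 2 * stats.norm.pdf(z)

        val, _ = quad(integrand, 0, 8.0, limit=200)
        return val

    lo, hi = 0.5, 50.0
    return float(brentq(lambda k: confidence(k) - conf, lo, hi, xtol=1e-8))


@dataclass
class NoiseBenchmark:
    """Transcriptome-wide measurement-noise threshold (SNR = 1 level)."""

    sigma_ssr: float
    n_resid: int
    k: float
    half_width: float
    P: float = 0.95
    conf: float = 0.95


def noise_benchmark(
    lfc: Log2FCMatrix, sg: pd.Index, P: float = 0.95, conf: float = 0.95
) -> NoiseBenchmark:
    """95%/95% tolerance interval of gene x group Log2FC residuals among SGs.

    Residuals are unweighted Log2FC minus their gene x group block means;
    the half-width k * sigma_SSR is the noise level a group-mean Log2FC
    must exceed for SNR > 1.
    """
    if len(sg) == 0:
        raise ValueError("noise benchmark needs a non-empty SG set")
    sub = lfc.values.loc[sg]
    groups = lfc.sample_groups.reindex(sub.columns)
    resid = []
    n_blocks = 0
    for g in dict.fromkeys(groups):
        block = sub[groups.index[groups == g]].to_numpy()
        resid.append(block - block.mean(axis=1, keepdims=True))
        n_blocks += block.shape[0]
    r = np.concatenate([b.ravel() for b in resid])
    n = r.size
    if n < 3:
        raise ValueError("too few residuals for a tolerance interval")
    df = n - n_blocks
    sigma = float(np.sqrt((r * r).sum() / df)) if df > 0 else float(r.std())
    k = tolerance_factor(n, P=P, conf=conf, nu=max(df, 1))
    return NoiseBenchmark(
        sigma_ssr=sigma, n_resid=n, k=k, half_width=k * sigma, P=P, conf=conf
    )


def stratify(
    de: DEResult,
    nb: NoiseBenchmark,
    annotated: pd.Index | None = None,
    posthoc_alpha: float = 0.05,
) -> DEResult:
    """Fill in the DEG / LSTNR / DEGREE flags.

    DEG    = SG & effect-size flag & min pairwise p < posthoc_alpha;
    LSTNR  = SG & effect-size flag & some group with |mean Log2FC| above
             the noise half-width (pairwise significance not required);
    DEGREE = DEG & LSTNR (& annotated with an official symbol, when an
             annotation set is supplied).
    """
    t = de.table
    for col in ("delta_flag", "posthoc_min_p"):
        if col not in t:
            raise ValueError(f"run effect_size/posthoc_pairwise before stratify ({col} missing)")
    snr = (de.group_means.abs() > nb.half_width).any(axis=1)
    t["snr_flag"] = snr
    t["deg"] = t["sg"] & t["delta_flag"] & (t["posthoc_min_p"] < posthoc_alpha)
    t["lstnr"] = t["sg"] & t["delta_flag"] & snr
    degree = t["deg"] & t["lstnr"]
    if annotated is not None:
        degree &= t.index.isin(annotated)
    t["degree"] = degree
    return de
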