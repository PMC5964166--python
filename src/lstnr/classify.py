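"""Clustering, confusion scoring, partition-tree biomarkers and forests.

Covers the downstream machine-learning tier of the pipeline: Ward
hierarchical clustering of fold-change profiles; confusion matrices of
inferred clades against prescribed co-expression patterns (sensitivity =
per-pattern true-positive rate; specificity uses the total number of
patterned genes as denominator, the convention reverse-engineered from
the published tables); greedy G2-based sequential partition trees without
gene repetition for biomarker selection; linear canonical discriminant
analysis of the selected biomarkers; and bootstrap-forest G2 contribution
tables for candidate gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionResult",
    "BiomarkerResult",
    "ward_cluster",
    "correlation_cluster",
    "confusion_stats",
    "sequential_partition",
    "discriminant_analysis",
    "bootstrap_forest_g2",
]


def ward_cluster(X: pd.DataFrame, k: int):
    """Ward-linkage clades on Euclidean distances between rows of X.

    Returns (labels, linkage matrix); labels are 1..k, deterministic for a
    given row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} items to cluster")
    Z = linkage(X.to_numpy(), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=X.index, name="clade"), Z


def correlation_cluster(X: pd.DataFrame, k: int):
    """Pearson-correlation clades: cluster rows on 1 - r distance.

    Returns (r matrix, labels, linkage).  A zero-variance row has no
    defined correlation and is rejected by name.
    """
    if X.shape[1] < 3:
        raise ValueError("correlation clustering needs >= 3 samples")
    sd = X.std(axis=1, ddof=0)
    bad = sd.index[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance gene(s): {list(bad[:5])}")
    r = np.corrcoef(X.to_numpy())
    rdf = pd.DataFrame(r, index=X.index, columns=X.index)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return rdf, pd.Series(labels, index=X.index, name="clade"), Z


@dataclass
class ConfusionResult:
    """Clade x pattern contingency with per-clade sensitivity/specificity."""

    matrix: pd.DataFrame  # clades x patterns, gene counts
    mapping: dict  # clade -> majority pattern
    sensitivity: pd.Series  # %, per clade
    specificity: pd.Series  # %, per clade


def confusion_stats(
    clades: pd.Series | pd.DataFrame,
    truth: pd.Series | None = None,
    pattern_size: int | pd.Series = 200,
    total_patterned: int | None = None,
    patterns: list | None = None,
) -> ConfusionResult:
    """Score clade assignments of patterned genes against ground truth.

    Accepts either per-gene ``clades`` + ``truth`` labels, or a
    ready-made clade x pattern count matrix (DataFrame) directly.  Each
    clade maps to its majority pattern (ties: larger raw count, then
    pattern column order).  Sensitivity = matched / pattern_size x 100;
    specificity = (1 - mismatched-in-clade / total_patterned) x 100.
    """
    if isinstance(clades, pd.DataFrame):
        mat = clades.copy()
    else:
        if truth is None:
            raise ValueError("per-gene clade labels need a truth series")
        common = clades.index.intersection(truth.index)
        tr = truth.loc[common]
        cl = clades.loc[common]
        if patterns is None:
            patterns = sorted(tr.unique())
        unknown = set(tr.unique()) - set(patterns)
        if unknown:
            raise ValueError(f"unknown pattern labels: {sorted(unknown)}")
        mat = pd.crosstab(cl, tr).reindex(columns=patterns, fill_value=0)
    if total_patterned is None:
        total_patterned = int(mat.to_numpy().sum())
    sizes = (
        pd.Series(pattern_size, index=mat.columns)
        if np.isscalar(pattern_size)
        else pattern_size
    )
    arr = mat.to_numpy()
    best = arr.argmax(axis=1)  # argmax breaks ties at the first (column-order) pattern
    mapping = {clade: mat.columns[j] for clade, j in zip(mat.index, best)}
    matched = arr[np.arange(len(mat)), best]
    row_tot = arr.sum(axis=1)
    sens = 100.0 * matched / sizes.loc[[mapping[c] for c in mat.index]].to_numpy()
    spec = 100.0 * (1.0 - (row_tot - matched) / total_patterned)
    return ConfusionResult(
        matrix=mat,
        mapping=mapping,
        sensitivity=pd.Series(sens, index=mat.index),
        specificity=pd.Series(spec, index=mat.index),
    )


# ---------------------------------------------------------------------------
# G2 partition trees


def _deviance(counts: np.ndarray) -> float:
    """Multinomial deviance G2 = -2 sum n_c ln(n_c / n) of a label count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    nz = counts[counts > 0]
    return float(-2.0 * np.sum(nz * np.log(nz / n)))


def _best_split_for_gene(x: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Best (threshold, G2 reduction) of one gene within one node.

    Thresholds are midpoints of adjacent sorted unique values; children's
    deviances are computed from cumulative class counts in one sweep.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    ys = y_codes[order]
    n = x.size
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    cut_ok = np.flatnonzero(np.diff(xs) > 0)  # split after position i
    if len(cut_ok) == 0:
        return None
    left = cum[cut_ok]
    right = total - left
    parent_dev = _deviance(total)

    def devs(c):
        nrow = c.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(c > 0, c * np.log(c / np.maximum(nrow, 1)), 0.0)
        return -2.0 * term.sum(axis=1)

    red = parent_dev - devs(left) - devs(right)
    j = int(np.argmax(red))
    if red[j] <= 1e-12:
        return None
    thr = 0.5 * (xs[cut_ok[j]] + xs[cut_ok[j] + 1])
    return thr, float(red[j])


@dataclass(eq=False)
class _Node:
    idx: np.ndarray
    gene: str | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    def to_dict(self):
        if self.gene is None:
            return {"n": int(self.idx.size)}
        return {
            "gene": self.gene,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class BiomarkerResult:
    """Sequential-partition biomarkers with tree, AUCs and leaf classes."""

    biomarkers: list[str]
    auc: dict
    tree: dict
    leaf_labels: pd.Series  # per-sample majority class of its leaf
    misclassification: float
    leaf_scores: pd.DataFrame = field(default_factory=pd.DataFrame)


def sequential_partition(X: pd.DataFrame, phenotypes: pd.Series) -> BiomarkerResult:
    """Greedy G2 partition tree over (gene, threshold) pairs, no gene reuse.

    X is samples x genes.  Splitting continues until every phenotype is
    the majority class of some leaf or no remaining split reduces G2; the
    minimum achievable biomarker count is therefore (#phenotypes - 1).
    Per-phenotype one-vs-rest ROC AUC is computed from leaf phenotype
    proportions.
    """
    y = phenotypes.reindex(X.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 phenotypes to partition")
    if (X.nunique(axis=0) <= 1).all():
        raise ValueError("all candidate genes are constant")
    codes = pd.Categorical(y, categories=classes).codes.astype(int)
    n_classes = len(classes)
    xmat = X.to_numpy()
    genes = list(X.columns)
    used: set[str] = set()
    root = _Node(idx=np.arange(X.shape[0]))
    leaves = [root]

    def covered() -> bool:
        maj = set()
        for leaf in leaves:
            cnt = np.bincount(codes[leaf.idx], minlength=n_classes)
            maj.add(int(cnt.argmax()))
        return maj >= set(range(n_classes))

    while not covered():
        best = None  # (reduction, leaf, gene index, threshold)
        for leaf in leaves:
            if leaf.idx.size < 2:
                continue
            for gi, gname in enumerate(genes):
                if gname in used:
                    continue
                found = _best_split_for_gene(xmat[leaf.idx, gi], codes[leaf.idx], n_classes)
                if found is None:
                    continue
                thr, red = found
                if best is None or red > best[0]:
                    best = (red, leaf, gi, thr)
        if best is None:
            break
        _, leaf, gi, thr = best
        gname = genes[gi]
        used.add(gname)
        mask = xmat[leaf.idx, gi] <= thr
        leaf.gene, leaf.threshold = gname, float(thr)
        leaf.left = _Node(idx=leaf.idx[mask])
        leaf.right = _Node(idx=leaf.idx[~mask])
        leaves.remove(leaf)
        leaves.extend([leaf.left, leaf.right])

    # leaf-proportion scores and majority labels
    scores = np.zeros((X.shape[0], n_classes))
    labels = np.empty(X.shape[0], dtype=int)
    for leaf in leaves:
        cnt = np.bincount(codes[leaf.idx], minlength=n_classes)
        prop = cnt / cnt.sum()
        scores[leaf.idx] = prop
        labels[leaf.idx] = int(cnt.argmax())
    auc = {}
    for j, c in enumerate(classes):
        truth = (codes == j).astype(int)
        auc[c] = float(roc_auc_score(truth, scores[:, j])) if 0 < truth.sum() < len(truth) else float("nan")
    order = [g for g in genes if g in used]
    return BiomarkerResult(
        biomarkers=order,
        auc=auc,
        tree=root.to_dict(),
        leaf_labels=pd.Series([classes[i] for i in labels], index=X.index),
        misclassification=float(np.mean(labels != codes)),
        leaf_scores=pd.DataFrame(scores, index=X.index, columns=classes),
    )


def discriminant_analysis(X: pd.DataFrame, phenotypes: pd.Series, ridge: float = 1e-6):
    """Linear canonical discriminant analysis of biomarker fold-changes.

    Pooled within-class covariance (ridge-regularized by eps * trace/p when
    near-singular); min(#phenotypes - 1, #genes) canonical factors;
    classification by nearest class centroid in canonical space.  Returns
    (canonical scores, per-phenotype AUC, misclassification rate).
    """
    y = phenotypes.reindex(X.index)
    classes = sorted(y.unique())
    k, p, n = len(classes), X.shape[1], X.shape[0]
    if n <= p:
        raise ValueError("need more samples than biomarker genes")
    xm = X.to_numpy()
    grand = xm.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    centroids = {}
    for c in classes:
        sub = xm[(y == c).to_numpy()]
        mu = sub.mean(axis=0)
        centroids[c] = mu
        W += (sub - mu).T @ (sub - mu)
        B += len(sub) * np.outer(mu - grand, mu - grand)
    W /= n - k
    if np.linalg.cond(W) > 1e10:
        W = W + ridge * np.trace(W) / p * np.eye(p)
    try:
        from scipy.linalg import eigh

        evals, evecs = eigh(B, W)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular within-class covariance; increase ridge") from err
    m = min(k - 1, p)
    A = evecs[:, ::-1][:, :m]  # top generalized eigenvectors
    Z = (xm - grand) @ A
    cz = {c: (centroids[c] - grand) @ A for c in classes}
    dists = np.stack([np.linalg.norm(Z - cz[c], axis=1) for c in classes], axis=1)
    pred = np.array(classes)[dists.argmin(axis=1)]
    auc = {}
    for j, c in enumerate(classes):
        truth = (y == c).astype(int).to_numpy()
        if 0 < truth.sum() < len(truth):
            auc[c] = float(roc_auc_score(truth, -dists[:, j]))
        else:
            auc[c] = float("nan")
    scores = pd.DataFrame(Z, index=X.index, columns=[f"canon{i+1}" for i in range(m)])
    return scores, auc, float(np.mean(pred != y.to_numpy()))


def bootstrap_forest_g2(
    X: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 100,
    seed: int = 0,
    max_depth: int = 12,
) -> pd.DataFrame:
    """Per-gene G2 contributions from a bootstrap forest of partition trees.

    Each tree grows on a bootstrap resample of the samples, choosing at
    every split among a random sqrt(p) subset of genes (reuse allowed
    within a tree) by maximal G2 reduction.  Reports the per-gene mean
    summed G2 reduction across trees, its share of the total (%), rank,
    and a chi-square tail p at df = #clusters - 1.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = labels.reindex(X.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    codes = pd.Categorical(y, categories=classes).codes.astype(int)
    xmat = X.to_numpy()
    p = X.shape[1]
    mtry = max(1, int(round(np.sqrt(p))))
    rng = np.random.default_rng(seed)
    acc = np.zeros(p)

    def grow(idx: np.ndarray, depth: int) -> None:
        cnt = np.bincount(codes[idx], minlength=len(classes))
        if depth >= max_depth or idx.size < 2 or (cnt > 0).sum() < 2:
            return
        cand = rng.choice(p, size=mtry, replace=False)
        best = None
        for gi in cand:
            found = _best_split_for_gene(xmat[idx, gi], codes[idx], len(classes))
            if found is None:
                continue
            thr, red = found
            if best is None or red > best[0]:
                best = (red, gi, thr)
        if best is None:
            return
        red, gi, thr = best
        acc[gi] += red
        mask = xmat[idx, gi] <= thr
        grow(idx[mask], depth + 1)
        grow(idx[~mask], depth + 1)

    n = X.shape[0]
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        grow(np.asarray(boot), 0)
    g2 = acc / n_trees
    total = g2.sum()
    share = 100.0 * g2 / total if total > 0 else np.zeros(p)
    df = len(classes) - 1
    out = pd.DataFrame(
        {
            "g2": g2,
            "share_pct": share,
            "rank": stats.rankdata(-g2, method="min").astype(int),
            "p": stats.chi2.sf(g2, df),
        },
        index=X.columns,
    )
    return out.sort_values("g2", ascending=False)
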