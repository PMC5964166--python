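import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lstnr.classify import (
    bootstrap_forest_g2,
    confusion_stats,
    correlation_cluster,
    discriminant_analysis,
    sequential_partition,
    ward_cluster,
)


def _blobs(seed=0, n=20, sep=10.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n, 3))
    b = rng.normal(sep, 1, size=(n, 3))
    X = pd.DataFrame(np.vstack([a, b]), index=[f"i{j}" for j in range(2 * n)])
    return X


class TestWardCluster:
    def test_separated_blobs_split_perfectly(self):
        X = _blobs(seed=1)
        labels, Z = ward_cluster(X, k=2)
        assert labels.iloc[:20].nunique() == 1
        assert labels.iloc[20:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert (np.diff(Z[:, 2]) >= -1e-9).all()  # merge heights non-decreasing

    def test_k_equal_items_gives_singletons(self):
        X = _blobs(seed=2, n=3)
        labels, _ = ward_cluster(X, k=6)
        assert labels.nunique() == 6

    def test_duplicate_rows_share_a_clade(self):
        X = _blobs(seed=3, n=5)
        X.iloc[1] = X.iloc[0]
        labels, _ = ward_cluster(X, k=4)
        assert labels.iloc[0] == labels.iloc[1]

    def test_k_beyond_items_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(_blobs(n=2), k=10)


class TestCorrelationCluster:
    def test_self_and_negation_correlations(self):
        base = np.sin(np.linspace(0, 6, 12))
        X = pd.DataFrame(
            [base, -base, base + 0.01 * np.arange(12)],
            index=["g", "neg", "near"],
        )
        r, labels, _ = correlation_cluster(X, k=2)
        assert r.loc["g", "g"] == pytest.approx(1.0)
        assert r.loc["g", "neg"] == pytest.approx(-1.0)
        assert labels["g"] == labels["near"] != labels["neg"]

    def test_zero_variance_gene_named(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_cluster(X, k=2)

    def test_block_patterns_correlate_within(self):
        rng = np.random.default_rng(4)
        up = np.array([0, 2.0, 4.0] * 4)
        down = -up
        X = pd.DataFrame(
            np.vstack(
                [up + rng.normal(0, 0.3, 12) for _ in range(6)]
                + [down + rng.normal(0, 0.3, 12) for _ in range(6)]
            )
        )
        r, _, _ = correlation_cluster(X, k=2)
        within = r.iloc[:6, :6].to_numpy()[np.triu_indices(6, 1)].mean()
        between = r.iloc[:6, 6:].to_numpy().mean()
        assert within > between


class TestConfusionStats:
    def test_published_style_row(self):
        # one clade capturing 195/200 of its pattern, 55 strays, of 1000 patterned
        mat = pd.DataFrame(
            [[22, 0, 33, 0, 195]], index=["cladeE"], columns=list("ABCDE")
        )
        res = confusion_stats(mat, pattern_size=200, total_patterned=1000)
        assert res.mapping["cladeE"] == "E"
        assert res.sensitivity["cladeE"] == pytest.approx(97.5)
        assert res.specificity["cladeE"] == pytest.approx(94.5)

    def test_perfect_diagonal(self):
        mat = pd.DataFrame(np.diag([200] * 5), index=list("vwxyz"), columns=list("ABCDE"))
        res = confusion_stats(mat, pattern_size=200, total_patterned=1000)
        assert (res.sensitivity == 100).all() and (res.specificity == 100).all()

    def test_random_matrices_recomputed_independently(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mat = pd.DataFrame(rng.integers(0, 50, size=(4, 4)), columns=list("ABCD"))
            mat.iloc[0, 0] += 1  # avoid an all-zero table
            total = int(mat.to_numpy().sum())
            res = confusion_stats(mat, pattern_size=60, total_patterned=total)
            for c in mat.index:
                row = mat.loc[c]
                best = row.idxmax()
                assert res.mapping[c] == best
                assert res.sensitivity[c] == pytest.approx(100 * row[best] / 60)
                assert res.specificity[c] == pytest.approx(
                    100 * (1 - (row.sum() - row[best]) / total)
                )

    def test_per_gene_labels_interface(self):
        clades = pd.Series([1, 1, 2, 2], index=list("abcd"))
        truth = pd.Series(["X", "X", "Y", "X"], index=list("abcd"))
        res = confusion_stats(clades, truth, pattern_size=pd.Series({"X": 3, "Y": 1}))
        assert res.matrix.loc[1, "X"] == 2
        assert res.mapping[1] == "X"


def _five_class_data(seed=6, n_per=8):
    """Five phenotypes, each separable along its own marker gene."""
    rng = np.random.default_rng(seed)
    classes = list("PQRST")
    rows, y = [], []
    for ci, c in enumerate(classes):
        for _ in range(n_per):
            x = rng.normal(0, 0.2, 6)
            if ci > 0:
                x[ci - 1] += 5.0  # gene i-1 marks class i
            rows.append(x)
            y.append(c)
    X = pd.DataFrame(rows, columns=[f"m{i}" for i in range(6)])
    X.index = [f"s{i}" for i in range(len(X))]
    return X, pd.Series(y, index=X.index)


class TestSequentialPartition:
    def test_two_classes_one_gene(self):
        X, y = _five_class_data()
        keep = y.isin(["P", "Q"])
        res = sequential_partition(X.loc[keep], y.loc[keep])
        assert res.biomarkers == ["m0"]
        assert res.auc["P"] == pytest.approx(1.0)
        assert res.misclassification == 0.0

    def test_five_phenotypes_need_at_least_four_biomarkers(self):
        X, y = _five_class_data()
        res = sequential_partition(X, y)
        assert len(res.biomarkers) >= 4
        assert len(set(res.biomarkers)) == len(res.biomarkers)  # no repetition
        assert res.misclassification == 0.0

    def test_deterministic(self):
        X, y = _five_class_data()
        r1 = sequential_partition(X, y)
        r2 = sequential_partition(X, y)
        assert r1.biomarkers == r2.biomarkers

    def test_constant_candidates_rejected(self):
        X = pd.DataFrame({"m": [1.0] * 6}, index=[f"s{i}" for i in range(6)])
        y = pd.Series(["a"] * 3 + ["b"] * 3, index=X.index)
        with pytest.raises(ValueError, match="constant"):
            sequential_partition(X, y)


class TestDiscriminantAnalysis:
    def test_separated_classes_perfectly_classified(self):
        X, y = _five_class_data(seed=7)
        scores, auc, misclass = discriminant_analysis(X, y)
        assert misclass == 0.0
        assert scores.shape[1] == min(y.nunique() - 1, X.shape[1])
        assert min(auc.values()) > 0.99

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(300, 2)), index=[f"s{i}" for i in range(300)])
        y = pd.Series(["a", "b", "c"] * 100, index=X.index)
        _, _, misclass = discriminant_analysis(X, y)
        assert abs(misclass - 2 / 3) < 0.1


class TestBootstrapForest:
    def test_informative_gene_ranks_first_and_shares_sum(self):
        rng = np.random.default_rng(9)
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"m{i}" for i in range(10)])
        X.index = [f"s{i}" for i in range(n)]
        y = pd.Series(["a"] * 20 + ["b"] * 20, index=X.index)
        X.loc[y == "b", "m3"] += 6.0
        out = bootstrap_forest_g2(X, y, n_trees=30, seed=1)
        assert out.index[0] == "m3"
        assert out.loc["m3", "rank"] == 1
        assert out["share_pct"].sum() == pytest.approx(100.0)
        # chi-square p uses df = #classes - 1
        assert out["p"].iloc[0] == pytest.approx(
            stats.chi2.sf(out["g2"].iloc[0], y.nunique() - 1)
        )

    def test_reproducible_by_seed(self):
        X, y = _five_class_data(seed=10)
        o1 = bootstrap_forest_g2(X, y, n_trees=10, seed=3)
        o2 = bootstrap_forest_g2(X, y, n_trees=10, seed=3)
        pd.testing.assert_frame_equal(o1, o2)

    def test_zero_trees_rejected(self):
        X, y = _five_class_data(seed=11)
        with pytest.raises(ValueError):
            bootstrap_forest_g2(X, y, n_trees=0)
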