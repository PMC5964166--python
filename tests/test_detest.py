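import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lstnr.data_io import ExpressionMatrix
from lstnr.detest import (
    log2fc,
    noise_benchmark,
    posthoc_pairwise,
    effect_size,
    stratify,
    tolerance_factor,
    tolerance_factor_exact,
    weighed_anova,
)
from lstnr.resolution import resolution_weights


def _em(values, groups, shift=0.5, baseline=None):
    return ExpressionMatrix(
        values=values,
        sample_groups=pd.Series(groups, index=values.columns),
        baseline_group=baseline,
        shift=shift,
    )


class TestLog2FC:
    def test_arithmetic_against_baseline_mean(self):
        v = pd.DataFrame([[2.0, 2.0, 4.0], [2.0, 2.0, 2.0]],
                         index=["g1", "g2"], columns=["b1", "b2", "t1"])
        lfc = log2fc(_em(v, ["base", "base", "trt"]), reference="base")
        assert lfc.values.loc["g1", "t1"] == pytest.approx(1.0)
        assert lfc.values.loc["g2", "t1"] == pytest.approx(0.0)
        # shifted 0.5 against ref 2 -> -2
        v2 = pd.DataFrame([[2.0, 2.0, 0.5]], index=["g"], columns=["b1", "b2", "t1"])
        lfc2 = log2fc(_em(v2, ["base", "base", "trt"]), reference="base")
        assert lfc2.values.loc["g", "t1"] == pytest.approx(-2.0)

    def test_grand_mean_reference(self):
        v = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["s1", "s2"])
        lfc = log2fc(_em(v, ["a", "b"]), reference="grand-mean")
        assert lfc.ref_values["g"] == 2.0

    def test_unknown_group_rejected(self):
        v = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="nope"):
            log2fc(_em(v, ["a", "b"]), reference="nope")


def _toy_dataset(seed=0, n_genes=100, shifted_gene="g000", effect=0.0):
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    groups = ["a"] * 5 + ["b"] * 5
    vals = rng.normal(0, 1, size=(n_genes, 10))
    idx = pd.Index([f"g{i:03d}" for i in range(n_genes)])
    df = pd.DataFrame(vals, index=idx, columns=cols)
    if effect:
        df.loc[shifted_gene, df.columns[5:]] += effect
    lfc_values = df
    from lstnr.detest import Log2FCMatrix

    return Log2FCMatrix(
        values=lfc_values,
        sample_groups=pd.Series(groups, index=cols),
        reference="a",
        ref_values=pd.Series(1.0, index=idx),
    )


class TestWeighedAnova:
    def test_uniform_weights_match_unweighted_and_rescaling_invariant(self):
        lfc = _toy_dataset(seed=1)
        w1 = pd.Series(1.0, index=lfc.values.index)
        de1 = weighed_anova(lfc, w1)
        de2 = weighed_anova(lfc, w1 * 7.3)
        assert np.allclose(de1.table["F"], de2.table["F"])
        assert np.allclose(de1.table["p"], de2.table["p"])
        assert (de1.table["sg"] == de2.table["sg"]).all()

    def test_strong_shift_gene_attains_minimum_fdr(self):
        lfc = _toy_dataset(seed=2, effect=10.0)
        rng = np.random.default_rng(3)
        w = pd.Series(rng.uniform(0.5, 2.0, len(lfc.values)), index=lfc.values.index)
        de = weighed_anova(lfc, w)
        assert de.table["fdr_p"].idxmin() == "g000"
        assert de.table.loc["g000", "sg"]

    def test_missing_weights_rejected(self):
        lfc = _toy_dataset(seed=4)
        w = pd.Series(1.0, index=lfc.values.index[:-5])
        with pytest.raises(ValueError, match="missing"):
            weighed_anova(lfc, w)


class TestEffectSizeAndPosthoc:
    def test_null_gene_has_zero_delta_and_unit_posthoc_p(self):
        lfc = _toy_dataset(seed=5)
        # make g001 perfectly balanced between groups
        lfc.values.loc["g001"] = [1.0, 2.0, 3.0, 1.5, 2.5, 1.0, 2.0, 3.0, 1.5, 2.5]
        de = weighed_anova(lfc, pd.Series(1.0, index=lfc.values.index))
        effect_size(de)
        ph = posthoc_pairwise(de)
        assert de.table.loc["g001", "delta"] == pytest.approx(0.0)
        assert not de.table.loc["g001", "delta_flag"]
        assert ph.loc["g001", "a|b"] == pytest.approx(1.0)

    def test_flag_matches_threshold_rule_and_is_monotone(self):
        lfc = _toy_dataset(seed=6, effect=3.0)
        de = weighed_anova(lfc, pd.Series(1.0, index=lfc.values.index))
        flags = effect_size(de, frac=0.3)
        thr = 0.3 * de.anova.sigma
        assert (flags == (de.table["delta"] > thr)).all()
        # monotone: raising frac never adds flags
        more = effect_size(de, frac=0.6)
        assert (more <= flags).all()

    def test_posthoc_formula_hand_example(self):
        # n=3 vs 3, means 0 vs 2, MSE=1, df=20 -> t = 2.449, p = 0.0237
        t = 2.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(2.449, abs=1e-3)
        assert 2 * stats.t.sf(t, 20) == pytest.approx(0.0237, abs=5e-4)

    def test_pair_count_is_j_choose_2(self):
        rng = np.random.default_rng(7)
        cols = [f"s{i}" for i in range(12)]
        from lstnr.detest import Log2FCMatrix

        lfc = Log2FCMatrix(
            values=pd.DataFrame(rng.normal(size=(4, 12)), columns=cols),
            sample_groups=pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3, index=cols),
            reference="a",
            ref_values=pd.Series(1.0, index=range(4)),
        )
        de = weighed_anova(lfc, pd.Series(1.0, index=lfc.values.index))
        assert posthoc_pairwise(de).shape[1] == 6


class TestToleranceInterval:
    def test_asymptotic_k_approaches_z(self):
        assert tolerance_factor(100_000) == pytest.approx(stats.norm.ppf(0.975), abs=0.02)

    def test_howe_matches_exact_integral_at_n50(self):
        k = tolerance_factor(50)
        assert k == pytest.approx(2.38, abs=0.01)
        exact = tolerance_factor_exact(50)
        assert abs(k / exact - 1) < 0.01

    def test_k_exceeds_normal_quantile_for_finite_n(self):
        for n in (5, 20, 200):
            assert tolerance_factor(n) > stats.norm.ppf(0.975)

    def test_zero_variance_gives_zero_half_width(self):
        lfc = _toy_dataset(seed=8)
        lfc.values.loc[:, :] = np.tile(
            np.repeat([1.0, 2.0], 5), (len(lfc.values), 1)
        )  # constant within each group block
        nb = noise_benchmark(lfc, lfc.values.index)
        assert nb.half_width == pytest.approx(0.0)

    def test_benchmark_on_standard_normal_residuals(self):
        lfc = _toy_dataset(seed=9, n_genes=5000)
        nb = noise_benchmark(lfc, lfc.values.index)
        assert nb.half_width == pytest.approx(1.96, rel=0.03)
        assert nb.k > stats.norm.ppf(0.975)


class TestStratify:
    def _de_with(self, sg, delta_flag, posthoc_p, group_mean):
        lfc = _toy_dataset(seed=10, n_genes=4)
        de = weighed_anova(lfc, pd.Series(1.0, index=lfc.values.index))
        effect_size(de)
        posthoc_pairwise(de)
        de.table["sg"] = sg
        de.table["delta_flag"] = delta_flag
        de.table["posthoc_min_p"] = posthoc_p
        de.group_means = pd.DataFrame(
            {"a": [0.0] * 4, "b": group_mean}, index=de.table.index
        )
        return de

    def test_flag_combinations(self):
        from lstnr.detest import NoiseBenchmark

        nb = NoiseBenchmark(sigma_ssr=1.0, n_resid=100, k=2.0, half_width=2.0)
        de = self._de_with(
            sg=[True, True, True, False],
            delta_flag=[True, True, True, True],
            posthoc_p=[0.01, 0.5, 0.01, 0.01],
            group_mean=[3.0, 3.0, 1.0, 3.0],
        )
        stratify(de, nb)
        t = de.table
        g = list(t.index)
        # gene 0: everything -> all flags
        assert t.loc[g[0], ["sg", "deg", "lstnr", "degree"]].all()
        # gene 1: loud signal but no pairwise significance -> LSTNR, not DEG
        assert t.loc[g[1], "lstnr"] and not t.loc[g[1], "deg"] and not t.loc[g[1], "degree"]
        # gene 2: pairwise-significant but within noise -> DEG, not LSTNR
        assert t.loc[g[2], "deg"] and not t.loc[g[2], "lstnr"]
        # gene 3: not SG -> nothing
        assert not t.loc[g[3], ["deg", "lstnr", "degree"]].any()

    def test_containment_chain_on_pipeline(self, small_pipeline):
        res, _ = small_pipeline
        t = res.de.table
        assert (t["deg"] <= t["sg"]).all()
        assert (t["lstnr"] <= t["sg"]).all()
        assert (t["degree"] == (t["deg"] & t["lstnr"])).all()
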