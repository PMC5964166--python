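import numpy as np
import pandas as pd
import pytest

from lstnr.data_io import CountMatrix
from lstnr.simulate import default_spec, simulate_counts
from lstnr.workflow import PipelineConfig, run_pipeline


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    """2 genes x 6 samples, two groups, hand-checkable."""
    counts = pd.DataFrame(
        [[10, 12, 8, 40, 44, 36], [2, 8, 5, 3, 6, 9]],
        index=pd.Index(["g1", "g2"], name="gene"),
        columns=[f"s{i}" for i in range(1, 7)],
    )
    groups = pd.Series(
        ["ctl", "ctl", "ctl", "trt", "trt", "trt"], index=counts.columns
    )
    return CountMatrix(counts=counts, sample_groups=groups, baseline_group="ctl")


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down patterned simulation: 3,000 genes, 5 x 30 patterned.

    Pattern sizes are shrunk with the gene count so the patterned fraction
    stays at the benchmark's 5%.
    """
    spec = default_spec(seed=7, n_genes=3000)
    for p in spec.patterns:
        p.n_genes = 30
    spec.__post_init__()
    return simulate_counts(spec), spec


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    (cm, truth), _ = small_sim
    res = run_pipeline(cm, PipelineConfig(seed=7))
    return res, truth
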