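"""Synthetic patterned RNA-seq counts with ground truth.

Emulates the classic *in silico* validation design: 20,000 pseudogenes
observed in four condition groups (one baseline) of 35 pseudoreplicates
each, of which five co-expression patterns of 200 pseudogenes carry
prescribed per-group Log2FC profiles and the rest are pure noise.

The generative model is the standard count surrogate: per-gene baseline
expected RPM drawn from a lognormal abundance law; per-group expected RPM
scaled by 2^profile; per-sample library sizes lognormal; and counts drawn
negative-binomially around mu_gj * N_s / 1e6 with dispersion phi (phi = 0
degenerates to Poisson).  This is an emulation of the published benchmark
design, not a byte-level replication of its generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .data_io import CountMatrix

__all__ = ["Pattern", "SimulationSpec", "simulate_counts", "simulate_gene_means", "default_spec"]


@dataclass
class Pattern:
    id: str
    n_genes: int
    profile: dict[str, float]  # non-baseline group -> Log2FC vs baseline


@dataclass
class SimulationSpec:
    """Generative description of a patterned pseudo-count experiment."""

    n_genes: int = 20_000
    groups: dict[str, int] = field(
        default_factory=lambda: {"baseline": 35, "group1": 35, "group2": 35, "group3": 35}
    )
    baseline_group: str = "baseline"
    patterns: list[Pattern] = field(default_factory=list)
    abundance_meanlog: float = 3.0  # ln-scale location of baseline expected RPM
    abundance_sdlog: float = 1.8
    phi: float = 0.1  # NB dispersion; 0 -> Poisson
    libsize_meanlog: float = float(np.log(5e6))
    libsize_sdlog: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.phi < 0:
            raise ValueError("dispersion phi must be >= 0")
        if self.baseline_group not in self.groups:
            raise ValueError(f"baseline group {self.baseline_group!r} not among groups")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs n >= 2 samples")
        total_patterned = sum(p.n_genes for p in self.patterns)
        if total_patterned > self.n_genes:
            raise ValueError("patterned genes exceed n_genes")
        non_base = [g for g in self.groups if g != self.baseline_group]
        for p in self.patterns:
            missing = set(p.profile) - set(non_base)
            if missing:
                raise ValueError(f"pattern {p.id}: unknown groups {sorted(missing)}")
            if not all(np.isfinite(list(p.profile.values()))):
                raise ValueError(f"pattern {p.id}: non-finite profile")


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The shipped benchmark-emulation spec (5 patterns x 200 genes of 20,000)."""
    cfg = yaml.safe_load(
        resources.files("lstnr.data").joinpath("default_patterns.yaml").read_text()
    )
    spec = SimulationSpec(seed=seed, **overrides)
    non_base = [g for g in spec.groups if g != spec.baseline_group]
    spec.patterns = [
        Pattern(
            id=str(p["id"]),
            n_genes=int(p["n_genes"]),
            profile=dict(zip(non_base, map(float, p["profile"]))),
        )
        for p in cfg["patterns"]
    ]
    spec.__post_init__()
    return spec


def simulate_counts(spec: SimulationSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a (CountMatrix, TruthTable) pair, reproducible from spec.seed.

    The truth table maps every gene to its pattern ("unpatterned" for the
    noise pool) and records the prescribed per-group expected Log2FC.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(spec.n_genes)], name="gene")
    groups_order = list(spec.groups)
    samples = []
    sample_groups = []
    for g in groups_order:
        for i in range(spec.groups[g]):
            samples.append(f"{g}_s{i+1:02d}")
            sample_groups.append(g)
    samples = pd.Index(samples, name="sample")
    sample_groups = pd.Series(sample_groups, index=samples, name="group")

    mu = rng.lognormal(spec.abundance_meanlog, spec.abundance_sdlog, spec.n_genes)

    # assign patterned genes at random positions, deterministically from seed
    truth = pd.DataFrame(
        {"pattern": "unpatterned"}, index=gene_ids
    )
    profile = pd.DataFrame(0.0, index=gene_ids, columns=groups_order)
    n_patterned = sum(p.n_genes for p in spec.patterns)
    chosen = rng.choice(spec.n_genes, size=n_patterned, replace=False)
    at = 0
    for p in spec.patterns:
        idx = gene_ids[chosen[at : at + p.n_genes]]
        truth.loc[idx, "pattern"] = p.id
        for g, lfc in p.profile.items():
            profile.loc[idx, g] = lfc
        at += p.n_genes
    truth = truth.join(profile.add_prefix("log2fc_"))

    libsize = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, len(samples))
    counts = np.empty((spec.n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        g = sample_groups.iloc[j]
        mean = mu * np.power(2.0, profile[g].to_numpy()) * libsize[j] / 1e6
        if spec.phi == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            lam = rng.gamma(shape=1.0 / spec.phi, scale=mean * spec.phi)
            counts[:, j] = rng.poisson(lam)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        sample_groups=sample_groups,
        baseline_group=spec.baseline_group,
    )
    return cm, truth


def simulate_gene_means(
    family: str, params: dict[str, float], n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. draws of gene-wise mean RPM from a threshold family."""
    from .distfit import _frozen

    if n < 1:
        raise ValueError("n must be positive")
    if family == "weibull3" and (params["alpha"] <= 0 or params["beta"] <= 0):
        raise ValueError("weibull3 needs alpha > 0 and beta > 0")
    if family == "lognormal3" and params["sigma"] <= 0:
        raise ValueError("lognormal3 needs sigma > 0")
    if params.get("gamma", 0.0) < 0:
        raise ValueError("threshold gamma must be >= 0")
    rng = np.random.default_rng(seed)
    return _frozen(family, params).rvs(size=n, random_state=rng)
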