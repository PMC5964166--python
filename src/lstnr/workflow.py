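"""End-to-end pipeline orchestration and split-pool consensus.

``run_pipeline`` chains the whole method on one count matrix: RPM
normalization -> threshold-distribution fit -> independent filtering ->
gamma shift -> GLM transformant -> pooled transformant ANOVA -> resolution
weights -> Log2FC -> resolution-weighed ANOVA -> effect size / post-hoc /
tolerance-interval noise benchmark -> SG/DEG/LSTNR/DEGREE strata ->
retrospective power -> Profiler selection.

``split_pool`` deals samples within each group into R mutually exclusive,
group-balanced realizations (seeded shuffle + round-robin), runs the full
pipeline independently per realization, and intersects the strata — the
consensus gene sets whose concordance the method uses as its
reproducibility readout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, detest, distfit, profiling, resolution

__all__ = ["PipelineConfig", "PipelineResult", "ConsensusResult", "run_pipeline", "split_pool"]

STRATA = ("sg", "deg", "lstnr", "degree")


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run."""

    reference: str | None = None  # baseline group name, "grand-mean", or None (auto)
    family: str = "auto"  # "auto" | "lognormal3" | "weibull3"
    fdr: float = 0.05
    effect_fraction: float = 0.3
    ti_coverage: float = 0.95
    ti_confidence: float = 0.95
    pi_min: float = 0.90
    posthoc_alpha: float = 0.05
    realizations: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fdr", "posthoc_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("ti_coverage", "ti_confidence", "pi_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.effect_fraction < 0:
            raise ValueError("effect_fraction must be >= 0")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything one run produced, plus the strata-count report."""

    fit: distfit.FitResult
    retained: pd.Index
    weights: resolution.ResolutionTable
    de: detest.DEResult
    noise: detest.NoiseBenchmark
    power: profiling.PowerTable
    report: dict
    config: PipelineConfig

    def strata(self) -> dict[str, set]:
        out = {s: set(self.de.genes(s)) for s in STRATA}
        out["profiler"] = set(self.power.profilers)
        return out


def run_pipeline(cm: data_io.CountMatrix, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full method on a validated count matrix."""
    cfg = cfg or PipelineConfig()
    em = data_io.rpm_normalize(cm)
    means = em.gene_means()

    if cfg.family == "auto":
        fit = distfit.select_best_family(means)
    else:
        fit = distfit.fit_family(means, cfg.family)
    retained = distfit.independent_filter(means, fit)

    # the gamma shift guards positivity of log/reciprocal transforms; if the
    # fitted threshold is exactly 0 but zero RPM entries remain, fall back to
    # half the smallest nonzero RPM as a minimal positivity offset
    gamma_shift = fit.gamma
    sub = em.values.loc[retained].to_numpy()
    if gamma_shift == 0.0 and (sub == 0).any():
        gamma_shift = 0.5 * sub[sub > 0].min()
    shifted = data_io.apply_shift(em, gamma_shift).subset_genes(retained)
    tm = resolution.transformant(shifted, fit)
    tr_anova = resolution.pooled_anova(tm.eta, tm.sample_groups)
    weights = resolution.resolution_weights(
        tr_anova.table["p"], F=tr_anova.table["F"], alpha=cfg.fdr
    )

    lfc = detest.log2fc(shifted, cfg.reference)
    de = detest.weighed_anova(lfc, weights, alpha=cfg.fdr)
    detest.effect_size(de, frac=cfg.effect_fraction)
    detest.posthoc_pairwise(de)
    nb = detest.noise_benchmark(
        lfc, de.genes("sg"), P=cfg.ti_coverage, conf=cfg.ti_confidence
    )
    detest.stratify(de, nb, posthoc_alpha=cfg.posthoc_alpha)

    degree = de.genes("degree")
    if len(degree):
        pt = profiling.retrospective_power(de, degree, alpha=cfg.posthoc_alpha, sigma=nb.sigma_ssr)
        profiling.select_profilers(pt, pi_min=cfg.pi_min)
    else:
        pt = profiling.PowerTable(
            table=pd.DataFrame(
                columns=["delta", "pi_mean", "pi_low", "rank", "lag_diff", "profiler"]
            )
        )

    report = {
        "n_genes": int(cm.counts.shape[0]),
        "n_samples": int(cm.counts.shape[1]),
        "family": fit.family,
        "params": fit.params,
        "filter_threshold_rpm": fit.filter_threshold,
        "gamma_shift_rpm": gamma_shift,
        "n_filtered": int(len(retained)),
        "n_resolved": weights.n_resolved,
        "n_sg": int(de.table["sg"].sum()),
        "n_deg": int(de.table["deg"].sum()),
        "n_lstnr": int(de.table["lstnr"].sum()),
        "n_degree": int(de.table["degree"].sum()),
        "n_profiler": int(len(pt.profilers)),
        "ti_half_width_log2": nb.half_width,
        "sigma_ssr_log2": nb.sigma_ssr,
        "reference": lfc.reference,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    result = PipelineResult(
        fit=fit, retained=retained, weights=weights, de=de, noise=nb, power=pt,
        report=report, config=cfg,
    )
    if cfg.outdir:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config": asdict(res.config), "report": res.report}
    data_io.write_table(res.weights.table, outdir / "weights.tsv", prov)
    data_io.write_table(res.de.table, outdir / "de.tsv")
    data_io.write_table(res.power.table, outdir / "profilers.tsv")
    (outdir / "report.json").write_text(json.dumps(res.report, indent=2, default=str) + "\n")


@dataclass
class ConsensusResult:
    """Per-realization strata, their intersections and concordance rates."""

    per_realization: list[dict[str, set]]
    consensus: dict[str, set]
    concordance_pct: dict[str, list[float]] = field(default_factory=dict)
    reports: list[dict] = field(default_factory=list)


def _deal_realizations(cm: data_io.CountMatrix, R: int, seed: int) -> list[list[str]]:
    """Seeded shuffle within each group, then round-robin into R subsets."""
    rng = np.random.default_rng(seed)
    subsets: list[list[str]] = [[] for _ in range(R)]
    for g in cm.groups:
        samples = list(cm.sample_groups.index[cm.sample_groups == g])
        if len(samples) < 2 * R:
            raise ValueError(
                f"group {g!r} has {len(samples)} samples; needs >= {2 * R} for R={R}"
            )
        rng.shuffle(samples)
        for i, s in enumerate(samples):
            subsets[i % R].append(s)
    return subsets


def split_pool(cm: data_io.CountMatrix, cfg: PipelineConfig, R: int | None = None) -> ConsensusResult:
    """Run the pipeline on R mutually exclusive realizations and intersect.

    Each realization is a self-contained pipeline (its own distribution
    fit, gamma shift and weights).  Consensus is the strict intersection
    of each stratum across realizations; concordance is the percentage of
    each realization's stratum retained in the consensus.
    """
    R = cfg.realizations if R is None else R
    if R == 1:
        res = run_pipeline(cm, cfg)
        strata = res.strata()
        return ConsensusResult(
            per_realization=[strata],
            consensus={k: set(v) for k, v in strata.items()},
            concordance_pct={k: [100.0 if v else float("nan")] for k, v in strata.items()},
            reports=[res.report],
        )
    subsets = _deal_realizations(cm, R, cfg.seed)
    per = []
    reports = []
    for sub in subsets:
        res = run_pipeline(cm.subset_samples(sub), cfg)
        per.append(res.strata())
        reports.append(res.report)
    consensus = {}
    concord = {}
    for s in per[0]:
        inter = set.intersection(*[r[s] for r in per])
        consensus[s] = inter
        concord[s] = [
            100.0 * len(inter) / len(r[s]) if r[s] else float("nan") for r in per
        ]
    return ConsensusResult(
        per_realization=per, consensus=consensus, concordance_pct=concord, reports=reports
    )
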