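# lstnr

Resolution-weighed differential expression analysis for noisy,
low-replication RNA-seq count data.

## The problem

RNA-seq scores countable read differences across thousands of genes at
once, but typical experiments run at N = 3 replicates per group, and noisy
designs (patient cohorts, toxicological mode-of-action panels, pilot
studies) leave ordinary per-gene tests underpowered and irreproducible.
Fold-changes alone are blind to *resolution*: a log2 ratio computed from a
handful of reads and one computed from saturating coverage look identical
once the counts are divided out.

`lstnr` implements a leveraged signal-to-noise (LSTNR) pipeline that keeps
resolution in play:

1. **Normalization.** Counts become reads per million (RPM),
   y = count / library_total x 10^6.
2. **Detection floor.** Gene-wise mean RPM is fit by profiled maximum
   likelihood to 3-parameter threshold families,
   P(y) ~ Lognormal3P(log y; sigma', mu', gamma) and
   P(y) ~ Weibull3P(y; alpha, beta, gamma); the best family by AICc
   supplies an independent filter (mean y > gamma for the lognormal fit,
   mean y > alpha for the Weibull fit — the latter retains at most the
   upper e^-1 ~ 37% of genes, since alpha is the 63rd percentile).
3. **Resolution weights.** The fitted family is restated in GLM
   exponential-family form; its linear predictor B (log y for lognormal,
   (y - gamma)^-1 for Weibull) is tested in a pooled-error gene x group
   ANOVA. Gene significance ranks are turned into cumulative-hazard
   weights w = -ln S(rank): ~0 for the least-resolved gene, ln(2G) for
   the best-resolved of G genes.
4. **Weighed testing.** Log2 fold-changes L = log2((y + gamma)/ref) against
   a fixed baseline (or grand mean) are scaled as z = w * L and tested in
   the same pooled ANOVA; Benjamini-Hochberg FDR < 0.05 defines
   significant genes (SGs).
5. **Stratification.** SGs are tiered by practical effect size
   (delta_Log2FC > 0.3 sigma_SSR), post-hoc pairwise significance
   (DEGs), and a transcriptome-wide noise threshold — the half-width of a
   95%/95% normal tolerance interval of gene x group residuals — giving
   LSTNR genes (SNR > 1) and DEGREEs (DEG and LSTNR).
6. **Profiling and biomarkers.** Retrospective noncentral-t power
   (<<pi>> and its 95% lower limit pi_low) ranks DEGREEs; the monotone
   effect-size prefix defines Profiler genes, from which a greedy G2
   partition tree (no gene reuse) extracts a minimal biomarker panel,
   checked by canonical discriminant analysis and bootstrap-forest G2
   contributions.

A patterned pseudo-count simulator (negative-binomial counts around
prescribed per-group Log2FC profiles, 20,000 genes, 4 x 35 replicates,
5 x 200 patterned genes by default) provides ground truth for validating
every stage.

## Worked example

Simulate the default benchmark design and run the full pipeline:

```sh
lstnr simulate --seed 3 --out-prefix sim/
lstnr run --counts sim/counts.tsv --meta sim/meta.tsv --outdir out/ --seed 3
```

which prints:

```
family: lognormal3
n_filtered: 20000
n_resolved: 1887
n_sg: 1813
n_deg: 1813
n_lstnr: 378
n_degree: 378
n_profiler: 1
ti_half_width_log2: 3.7235436265135546
```

Reading: the lognormal threshold family fit the simulated gene means best,
and its fitted floor excluded no genes (the simulation draws every gene
from the fitted abundance law, so all 20,000 are "detectable"); 1,887
genes had read-count variation resolvable against the pooled error; 1,813
genes were significant after resolution-weighed testing (all 1,000
patterned genes are recovered, plus unpatterned genes whose noise the
weighting amplifies — see `docs/methods.md`); 378 of them also cleared the
effect-size and signal-to-noise tiers. The tolerance half-width says that
95% of single-replicate Log2FC measurements are expected within +/-3.7 of
their block mean with 95% confidence — the reproducibility benchmark a
follow-up qPCR assay would be designed against.

The same objects are available as a library:

```python
from lstnr import default_spec, simulate_counts, run_pipeline, PipelineConfig

cm, truth = simulate_counts(default_spec(seed=3))
res = run_pipeline(cm, PipelineConfig(seed=3))
res.de.table.head()          # per-gene F, p, fdr_p, delta, flags
res.power.profilers          # Profiler gene IDs
res.report                   # strata counts as printed above
```

`lstnr splitpool -R 4 ...` runs the split-pool design: samples are dealt
within each group into R mutually exclusive realizations, each analyzed
as a self-contained pipeline, and the strata are intersected into a
consensus list with per-realization concordance rates.

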