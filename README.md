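# npmvs — nonparametric mean-variance smoothing for differential expression

`npmvs` analyzes small-replicate, log-scale expression data (microarray or
any normalized genes × samples matrix) for differential expression between
two conditions. With only 2–3 replicates per gene, per-gene variance
estimates are too noisy to trust; expression data also show a systematic,
often nonlinear, relationship between a gene's mean and its variance.
`npmvs` exploits that relationship twice:

1. **Smooth variances using means.** Per condition, the log sample variance
   `z_g = ln s²_g` is regressed on the sample mean `x̄_g` with a penalized
   spline — a truncated-line basis at quantile knots,

       z_g = β₀ + β₁ x̄_g + Σₖ uₖ (x̄_g − κₖ)₊ + ε_g,   uₖ ~ N(0, σ²_u),

   the mixed-model form whose ridge weight λ = σ²_ε/σ²_u is chosen by REML
   and whose fitted values are the BLUP. Every gene borrows strength from
   all others; the smoothed variance is `σ̃²_g = exp(ẑ_g)` (after the
   analytic `ln χ²` mean-bias correction).

2. **Shrink means treating variances as known.** Each gene carries a latent
   Bernoulli indicator `I_g` of differential expression with prior
   `P(I_g = 1) = p`. Given smoothed per-mean variances `v_c = σ̃²_c/n_c`,
   `v_t = σ̃²_t/n_t` and the grand mean `μ₀` as plug-in center, the marginal
   likelihoods are

       m₀ = ∫ BVN((ȳ_c, ȳ_t); (μ₀, μ₀), [[v_c+v, v], [v, v_t+v]]) π(v) dv
       m₁ = ∫ N(ȳ_c; μ₀, v_c+v) · N(ȳ_t; μ₀, v_t+v) π(v) dv

   (shared latent mean under the null, independent means under the
   alternative; `π(v)` uniform by default, inverse-gamma optionally), each a
   one-dimensional integral over the between-gene variance `v` evaluated by
   20-point Gaussian quadrature. The posterior probability of differential
   expression is `P_g = p·m₁ / (p·m₁ + (1−p)·m₀)`, and genes are called at
   `P_g > 0.99` with an optional |log2 fold change| > 1 filter.

The package also ships the simulation study the method is validated on
(10,000 genes, four mean-variance laws, exact DE strata), type-I/type-II
error-curve evaluation against a per-gene t-test baseline, and downstream
gene-set statistics (one-tailed Fisher enrichment, Benjamini–Hochberg FDR).

## Worked example

```python
from npmvs import RunConfig, SimulationDesign, fit_expression_pair, simulate_dataset

design = SimulationDesign(n_genes=2000, pi1=0.05, n_replicates=3, case=0)
ds = simulate_dataset(design, seed=1)
result = fit_expression_pair(ds.control, ds.treatment, RunConfig())
print((result.table.call != "none").sum())
```

Running `python examples/01_simulate_and_fit.py` prints:

```
genes: 2000, truly DE: 100
called at posterior > 0.99: 85 (85 true positives)
grand mean used as prior center: 7.986
posterior of true DE genes (mean): 0.881
posterior of null genes (mean):    0.019
```

Of 100 truly differentially expressed genes, 85 are recovered at the 0.99
posterior cutoff with zero false calls; null genes sit near posterior 0.02
(just below the prior `p = 0.05`, as expected when the data carry no
evidence either way). The other scripts in `examples/` demonstrate variance
smoothing diagnostics, averaged error curves against the t-test baseline,
and gene-set enrichment.

A thin CLI wraps the same library calls for shell use:

```bash
npmvs simulate --genes 10000 --pi1 0.05 --case 0 --seed 7 --outdir sim/
npmvs fit --control sim/control.tsv --treatment sim/treatment.tsv --outdir fit/
npmvs evaluate --case 0 --n-datasets 100 --seed 7 --outdir eval/
npmvs enrich --results fit/results.tsv --gene-sets sets.tsv --universe-size 22000 --outdir enr/
```

Every run writes a `manifest.json` (config, seed, versions) next to its
outputs. Input expression tables are TSV with gene ids in column 1 and are
assumed to be on a log2 scale (e.g. RMA-normalized exports); the tool never
downloads or normalizes raw data.

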