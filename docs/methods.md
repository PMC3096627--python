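# Methods

## Model overview

`npmvs` is a two-step empirical-Bayes procedure for two-condition
differential expression (DE) in small-replicate, log-scale expression data.
Replicates are modelled as independent normals per gene and condition,
`y_gj ~ N(μ_g, σ²_g)`. The method assumes the gene variances are a smooth
(not necessarily monotone or linear) function of the gene means plus
gene-level scatter; if means and variances are unrelated, the smoothing
step adds nothing and the method should not be preferred. Inputs are
assumed to be on a log2-like scale (e.g. RMA output); the package never
normalizes data and rejects missing values rather than imputing them,
because the model needs complete replicate vectors.

### Step 1 — variance smoothing

Per condition, `z_g = ln(max(s²_g, floor))` is regressed on the sample mean
`x̄_g` with a degree-1 truncated power ("truncated line") basis at K knots
placed at the k/(K+1) empirical quantiles of the means. Treating the knot
coefficients as random effects `u_k ~ N(0, σ²_u)` with noise
`ε ~ N(0, σ²_ε)` makes the smoother a linear mixed model: the coefficient
estimates are the BLUP solution of the penalized normal equations with
ridge weight `λ = σ²_ε/σ²_u`, and `λ` is selected by REML. All genes
participate; each gene receives a strictly positive smoothed variance
`σ̃²_g = exp(ẑ_g + c_ν)`.

`c_ν = ln(ν/2) − ψ(ν/2)` (with `ν = n − 1` and `ψ` the digamma function) is
the analytic mean bias of `ln s²` for normal data: `E[ln s²] = ln σ² − c_ν`.
At n = 3 the bias is −0.577, i.e. `exp(E[ln s²]) ≈ 0.56 σ²`; without the
correction the smoothed variances would systematically underestimate the
truth by almost a factor of two. The correction is exact on the log scale
and is on by default (`debias=True`). No further adjustment is made for the
convexity of `exp` around the fitted value (a much smaller effect once
thousands of genes are pooled); this residual convexity bias is a known
limitation.

Defaults and rationale:

- **K (knot count):** `min(G/4, 35)` — the customary penalized-spline
  default; with REML shrinkage, results are insensitive to K beyond
  sufficiency.
- **Variance floor `1e−8`:** keeps `ln s²` finite for genes with constant
  replicates (possible in quantized data); such genes still receive a
  positive smoothed variance from the trend.
- **REML, GCV fallback:** REML is profiled over `η = σ²_u/σ²_ε` on a coarse
  log grid followed by bounded scalar refinement; all linear algebra uses
  (K+2)-dimensional cross-products via Woodbury identities, so the fit is
  O(G) regardless of K. If the REML criterion is non-finite everywhere,
  generalized cross-validation over the same grid is used; if both fail the
  fit errors out with the evaluation trace.
- **Per-condition vs pooled:** variances are smoothed separately per
  condition by default (the laws may differ); a pooled single-curve fit is
  available (`pooled_variance_fit`) for designs where one assumes a common
  mean-variance law.
- **λ limits:** as `σ²_u → 0` the fit degenerates gracefully to the
  ordinary least-squares line (this is not an error — it is the correct
  answer for a log-linear law); as `λ → 0` it approaches the unpenalized
  spline.

### Step 2 — hierarchical posterior with known variances

Each gene has a latent DE indicator `I_g ~ Bernoulli(p)`. Condition means
are normal with known variances `v_c = σ̃²_c/n_c`, `v_t = σ̃²_t/n_t`. The
gene-level means are anchored at the plug-in center `μ₀`, the grand mean of
all expression values (no prior is placed on it). The between-gene variance
`v` — the spread of gene means around `μ₀` — gets its own prior `π(v)`; it
is deliberately *not* tied to the within-gene variance (the common
`v = c·σ²` shortcut buys closed forms but has no biological justification,
and the smoothing step already supplies good within-gene variances).

- Null (`I_g = 0`): both condition means share one latent mean
  `μ ~ N(μ₀, v)`; integrating `μ` analytically leaves a bivariate normal
  with covariance `[[v_c+v, v], [v, v_t+v]]`.
- Alternative (`I_g = 1`): the two condition means are independent, each
  `N(μ₀, v)`.

Both marginals reduce to one-dimensional integrals over `v`, evaluated by a
Q-point Gaussian rule (Q = 20 default), and the posterior
`P_g = p·m₁/(p·m₁ + (1−p)·m₀)` is computed with log-sum-exp throughout; no
underflow-driven zeros occur even for extreme genes. A one-sample variant
for paired log-ratio designs places the null at mean zero:
`m₀ = N(d̄; 0, v_g)`, `m₁ = ∫ N(d̄; 0, v_g+v) π(v) dv`.

Priors and settings:

- **Uniform prior (default):** `v ~ U(v_L, v_U)` with `v_L = 1e−4` and
  data-driven `v_U` = empirical variance of the per-gene condition means —
  the natural scale of the spread the parameter describes. Both bounds are
  configurable.
- **Inverse-gamma prior:** `IG(a₀, b₀)` (e.g. the conventional weak choices
  0.5 or 0.01) is supported through the same quadrature after the change of
  variable `v = eᵗ`.
- **Mixing proportion `p = 0.05`:** a typical prior DE fraction; an
  optional self-consistent update `p ← mean(P_g)` iterated to a `1e−6`
  fixed point is available but off by default.
- **Calls:** `P_g > 0.99` (reporting cutoff), with the downstream up/down
  sets additionally requiring |log2 fold change| > 1 (strict inequalities;
  boundary genes are excluded).

### Quadrature accuracy

The uniform-prior integrand is analytic on `(v_L, v_U)` but has complex
branch points at `v = −v_c, −v_t`; when a gene's within-variance is small
these approach the interval and a plain affine Gauss–Legendre map loses
several digits. The integral is therefore evaluated after the shifted-log
reparametrization `t = ln(v + c)` with `c = min(v_c, v_t)` per gene — the
same interval, but with the singularities pushed far from the path. The
20-point Legendre rule then agrees with adaptive integration to ~1e−12
relative error (worst case over randomized realistic inputs), and to
~1e−6 for the inverse-gamma prior with moderate shapes (IG(3, 2)); very
heavy-tailed hyperparameters (shape < 1) retain ~1e−3 tail error.

A Gauss–Hermite path is also provided (nodes mapped through the Gaussian
probability integral onto the same interval, or Laplace-centered for the
inverse-gamma prior). A Hermite rule is a natural fit for smooth
bell-shaped integrands but not for the hard truncation of a uniform prior:
its verified accuracy there is ~3e−3 relative, and the Legendre scheme is
the default for this reason.

Degenerate cases are handled exactly: as `v_U − v_L → 0` both marginals
collapse to their closed bivariate/univariate normal forms (the interval
width is computed with `log1p` to avoid cancellation), and `p ∈ {0, 1}`
collapses the posterior to 0/1 without evaluating ratios.

## The synthetic-data generator

`simulate_dataset` emulates a small-replicate two-condition microarray
study on the log2 scale:

- control gene means `~ N(8, 1)` (typical RMA intensity scale);
- a fraction `pi1 ∈ {0.02, 0.05, 0.10}` of genes is DE; their treatment
  means are drawn uniformly from four strata with exact 25% shares — up
  [8.1, 11], strongly up [11.1, 14], down [5, 7.9], strongly down
  [2, 4.9] — allocated deterministically over a shuffled index so the
  shares are exact, not multinomial;
- non-DE genes keep their control mean exactly;
- per-gene variance follows a deterministic case law in the mean —
  case 1 constant log-variance (−3), case 2 linear (−6 + 0.35 μ), case 3
  quadratic (−2 − 0.08 (μ−8)²), case 0 strongly nonlinear, non-monotone
  (−3 + 1.2 sin(0.9 (μ−8))) — times log-normal gene scatter with SD 0.25
  on the natural-log scale. Coefficients are presets chosen so the
  generated log-variances span roughly the range seen in RMA-normalized
  Arabidopsis arrays (about e⁻⁵ to e⁻¹), and are overridable;
- one variance law and one scatter draw per gene, evaluated at each
  condition's own mean (so DE genes' treatment variances follow the law at
  the shifted mean);
- replicates (default 3 per condition) are independent normal draws; a
  fixed seed yields bit-identical output.

What the generator does *not* emulate: non-normal noise, probe-level
effects, correlated genes, batch or array effects, and intensity-dependent
normalization artifacts. Passing tests on these data therefore validate
the estimation machinery under the model's own assumptions, not robustness
to real-data pathologies.

## Evaluation protocol

Per simulated dataset, genes are scored (posterior `P_g`, or `1 − p` for
the t-test baseline) and swept over a shared grid of 199 cutoffs in (0, 1);
calls are `score > cutoff`. FPR = FP / (# truly non-DE), FNR = FN /
(# truly DE); curves are averaged pointwise across datasets. The baseline
is a pooled-variance two-sample t-test (pooled, not Welch, matching the
generator's shared per-gene variance); genes with zero pooled variance get
p = 1 with a warning. Comparisons at matched FPR use linear interpolation
of FNR as a function of FPR along each averaged curve.

Default problem sizes in the shipped tests and the acceptance script —
2,000 genes and 10 datasets for curve comparisons, 100-point oracle grids —
are the package's own choices for a quick, reproducible check; the full
10,000-gene, 100-dataset protocol is available through
`npmvs evaluate --genes 10000 --n-datasets 100`.

## Enrichment statistics

Up/down DE gene sets (posterior cutoff + fold-change filter) are tested for
over-representation in user-supplied gene sets with the exact one-tailed
hypergeometric tail `P(K ≥ k)`, summed in log space with log-gamma terms
(no normal approximation; set sizes are small). The universe size N is a
required explicit input — whether N is the array's probe set or the whole
genome is a scientific choice the tool does not make for the user.
Benjamini–Hochberg step-up adjustment is applied across sets.

## Known limitations

- **Level-dependent ranking.** With a fixed plug-in center `μ₀` and an
  independent-means alternative, the posterior is not a function of the
  within-gene standardized shift alone: null genes whose (shared) level
  sits near `μ₀` retain posteriors near the prior `p`, while null genes far
  from `μ₀` are pushed toward 0 — so the mid-range ranking mixes
  level information into the DE score. In simulations with a strongly
  nonlinear mean-variance law the posterior clearly beats the raw t-test at
  low false-positive rates, but its margin in the 0.2–0.4 FPR region is
  small and can dip below the t-test for some data realizations. A
  standardized-shift score built on the same smoothed variances
  (`|ȳ_t − ȳ_c| / sqrt(v_c + v_t)`) dominates the t-test uniformly,
  confirming the variance smoothing itself is the source of the gain.
- **Exp-convexity bias** in `exp(ẑ)` is uncorrected (small next to the
  corrected `ln χ²` mean bias).
- The one-sample variant fixes the null at log-ratio zero; designs with a
  nonzero reference shift must recenter their ratios first.
- Variance smoothing assumes a mean-variance relationship exists; for data
  where means and variances are unrelated the spline collapses toward a
  constant/linear fit and the method reduces to (approximately) a common
  shrunken variance.
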