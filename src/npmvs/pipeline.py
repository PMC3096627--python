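"""The full two-step analysis: smooth variances, then score genes.

``fit_expression_pair`` runs the whole method on a control/treatment pair:

1. per-condition gene means and sample variances;
2. penalized-spline smoothing of log variance on mean (per condition, or a
   single pooled fit across both conditions on request);
3. empirical-Bayes posterior DE probability per gene, treating the smoothed
   variances as known, with the grand mean of all expression values as the
   plug-in prior center;
4. a results table with means, smoothed variances, log2 fold change (the
   input is assumed log2-scale, so the fold change is the difference of
   condition means), posterior and call.

A gene is called ``up``/``down`` when its posterior exceeds the cutoff,
with the direction given by the sign of the fold change, and ``none``
otherwise.  The stricter up/down gene *sets* that additionally require
|log2FC| above the fold-change threshold come from
:func:`npmvs.enrichment.fold_change_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import ExpressionMatrix
from .posterior import (
    DEPosterior,
    HierarchicalInputs,
    InverseGammaPrior,
    UniformPrior,
    grand_mean,
    posterior_de,
    quadrature_rule,
)
from .smoothing import (
    GeneStats,
    SmoothFit,
    default_knot_count,
    fit_penalized_spline,
    gene_stats,
    log_variance_bias,
    select_knots,
    smooth_variances,
)

__all__ = ["FitResult", "fit_expression_pair", "fit_matrix", "build_prior"]


@dataclass
class FitResult:
    table: pd.DataFrame
    posterior: DEPosterior
    smooth_control: SmoothFit
    smooth_treatment: SmoothFit
    mu0: float


def build_prior(config: RunConfig, gene_means: np.ndarray = None):
    """Prior on the between-gene variance from the run configuration.

    With ``prior_kind="uniform"`` and no explicit upper bound, the bound is
    data-driven: the empirical variance of the per-gene means.
    """
    if config.prior_kind == "inverse_gamma":
        return InverseGammaPrior(config.ig_shape, config.ig_scale)
    v_upper = config.v_upper
    if v_upper is None:
        if gene_means is None:
            raise ValueError("data-driven v_upper needs gene means")
        v_upper = float(np.var(np.asarray(gene_means, dtype=float), ddof=1))
        if v_upper <= config.v_lower:
            v_upper = config.v_lower + 1.0
    return UniformPrior(config.v_lower, v_upper)


def _pooled_smooth(stats_c: GeneStats, stats_t: GeneStats, K):
    """One spline over both conditions; per-condition slices and debiasing."""
    x = np.concatenate([stats_c.mean, stats_t.mean])
    z = np.concatenate([stats_c.log_variance, stats_t.log_variance])
    if K is None:
        K = default_knot_count(x.size)
    fit = fit_penalized_spline(z, x, select_knots(x, K))
    G = stats_c.mean.size
    out = []
    for sl, stats in ((slice(None, G), stats_c), (slice(G, None), stats_t)):
        zhat = fit.fitted_log_variance[sl] - log_variance_bias(stats.n)
        out.append(SmoothFit(
            knots=fit.knots, beta=fit.beta, u=fit.u,
            sigma2_u=fit.sigma2_u, sigma2_eps=fit.sigma2_eps, lam=fit.lam,
            fitted_log_variance=zhat,
            smoothed_variance=np.exp(zhat), method=fit.method,
        ))
    return out


def fit_expression_pair(
    control: ExpressionMatrix,
    treatment: ExpressionMatrix,
    config: RunConfig = None,
) -> FitResult:
    """Run the complete method on a control/treatment matrix pair."""
    if config is None:
        config = RunConfig()
    if list(control.gene_ids) != list(treatment.gene_ids):
        raise ValueError("control and treatment must share gene ids in order")

    stats_c = gene_stats(control, control.conditions[0], floor=config.variance_floor)
    stats_t = gene_stats(treatment, treatment.conditions[0], floor=config.variance_floor)

    if config.pooled_variance_fit:
        fit_c, fit_t = _pooled_smooth(stats_c, stats_t, config.knots)
    else:
        fit_c = smooth_variances(stats_c, K=config.knots, floor=config.variance_floor)
        fit_t = smooth_variances(stats_t, K=config.knots, floor=config.variance_floor)

    mu0 = grand_mean(control, treatment)
    all_means = np.concatenate([stats_c.mean, stats_t.mean])
    prior = build_prior(config, gene_means=all_means)
    rule = quadrature_rule(config.quadrature_scheme, config.quadrature_order)
    inputs = HierarchicalInputs(
        y_c=stats_c.mean, y_t=stats_t.mean,
        v_c=fit_c.smoothed_variance / stats_c.n,
        v_t=fit_t.smoothed_variance / stats_t.n,
        mu0=mu0, prior=prior, p=config.mixing_p,
    )
    post = posterior_de(inputs, rule, cutoff=config.posterior_cutoff)

    lfc = stats_t.mean - stats_c.mean
    call = np.where(post.call, np.where(lfc > 0, "up", "down"), "none")
    table = pd.DataFrame({
        "gene_id": list(control.gene_ids),
        "mean_control": stats_c.mean,
        "mean_treatment": stats_t.mean,
        "smoothed_variance_control": fit_c.smoothed_variance,
        "smoothed_variance_treatment": fit_t.smoothed_variance,
        "log2_fold_change": lfc,
        "posterior_de_prob": post.posterior,
        "call": call,
    })
    return FitResult(table=table, posterior=post, smooth_control=fit_c,
                     smooth_treatment=fit_t, mu0=mu0)


def fit_matrix(X: ExpressionMatrix, config: RunConfig = None) -> FitResult:
    """Run the method on a single matrix carrying two condition labels.

    The first label in column order is treated as control.
    """
    labels = X.conditions
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {labels}")
    return fit_expression_pair(
        X.subset_condition(labels[0]), X.subset_condition(labels[1]), config
    )
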