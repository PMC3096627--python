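"""Nonparametric smoothing of gene variances against gene means.

With only a handful of replicates per gene, raw sample variances are very
noisy.  Across a microarray (or any log-scale expression matrix) the
variances show a systematic, often nonlinear, trend in the gene means.  This
module borrows strength across all genes by regressing log sample variance
``z_g = ln s2_g`` on the sample mean ``x_g`` with a penalized spline,

    z_g = beta0 + beta1 * x_g + sum_k u_k (x_g - kappa_k)_+ + eps_g,

a truncated-line basis at quantile knots.  Treating the knot coefficients
``u_k ~ N(0, sigma2_u)`` as random effects makes this a linear mixed model:
the ridge weight is ``lambda = sigma2_eps / sigma2_u``, the fitted
coefficients are the BLUP solution of the penalized normal equations, and the
smoothing parameter is chosen by REML (with a GCV fallback).  The smoothed
per-gene variance is ``exp(z_hat_g)``, strictly positive for every gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import digamma

from .data import ExpressionMatrix

__all__ = [
    "GeneStats",
    "SmoothFit",
    "gene_stats",
    "select_knots",
    "build_spline_basis",
    "fit_penalized_spline",
    "smooth_variances",
    "plot_mean_variance",
]

log = logging.getLogger(__name__)

#: default cap on the number of quantile knots
MAX_KNOTS = 35


class SmootherError(RuntimeError):
    pass


class RemlConvergenceError(SmootherError):
    """REML optimization failed; carries the evaluation trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class GeneStats:
    """Per-gene summary statistics for one condition."""

    condition: str
    mean: np.ndarray       # sample mean per gene
    variance: np.ndarray   # unbiased sample variance (divisor n-1)
    n: int                 # replicate count
    log_variance: np.ndarray  # ln(max(variance, floor))
    floor: float


@dataclass
class SmoothFit:
    """A fitted penalized spline for the mean-variance trend."""

    knots: np.ndarray
    beta: np.ndarray          # (intercept, slope)
    u: np.ndarray             # random knot coefficients
    sigma2_u: float
    sigma2_eps: float
    lam: float                # ridge weight sigma2_eps / sigma2_u
    fitted_log_variance: np.ndarray
    smoothed_variance: np.ndarray
    method: str               # "reml", "gcv" or "fixed"

    def predict_log_variance(self, x: np.ndarray) -> np.ndarray:
        X, Z = build_spline_basis(x, self.knots)
        return X @ self.beta + Z @ self.u


def gene_stats(X: ExpressionMatrix, condition: str, floor: float = 1e-8) -> GeneStats:
    """Per-gene mean and unbiased variance over one condition's replicates.

    Variances are floored at ``floor`` before taking logs so genes with
    constant replicates contribute a finite (very low) log variance.
    """
    idx = X.samples_of(condition)
    if idx.size < 2:
        raise ValueError(f"condition {condition!r} has {idx.size} sample(s); need >= 2")
    vals = X.values[:, idx]
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    return GeneStats(
        condition=condition,
        mean=mean,
        variance=var,
        n=int(idx.size),
        log_variance=np.log(np.maximum(var, floor)),
        floor=floor,
    )


def select_knots(means: Sequence[float], K: int) -> np.ndarray:
    """K strictly increasing knots at the k/(K+1) empirical quantiles."""
    x = np.asarray(means, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if np.unique(x).size < K + 2:
        raise ValueError(
            f"only {np.unique(x).size} distinct mean values for K={K} knots; reduce K"
        )
    probs = np.arange(1, K + 1) / (K + 1)
    knots = np.quantile(x, probs)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "tied empirical quantiles produce duplicate knots; reduce K"
        )
    return knots


def build_spline_basis(x: Sequence[float], knots: Sequence[float]):
    """Truncated-line design: fixed columns [1, x], random column k = (x - kappa_k)_+."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    X = np.column_stack([np.ones_like(x), x])
    Z = np.maximum(x[:, None] - knots[None, :], 0.0)
    return X, Z


def _solve_blup(XtX, XtZ, ZtZ, Xty, Zty, lam):
    """Solve the penalized normal equations (C'C + lam*D) theta = C'y."""
    p = XtX.shape[0]
    K = ZtZ.shape[0]
    A = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * np.eye(K)]])
    rhs = np.concatenate([Xty, Zty])
    theta = np.linalg.solve(A, rhs)
    return theta[:p], theta[p:]


def _profile_reml(eta, G, p, XtX, XtZ, ZtZ, Xty, Zty, yty):
    """-2 * restricted log-likelihood profiled over sigma2_eps, up to a constant.

    eta = sigma2_u / sigma2_eps.  Uses Woodbury identities on the K x K
    system so the cost is independent of the number of genes.
    """
    K = ZtZ.shape[0]
    M = np.eye(K) + eta * ZtZ
    cho = np.linalg.cholesky(M)
    logdetM = 2.0 * np.sum(np.log(np.diag(cho)))
    Minv_ZtX = np.linalg.solve(M, XtZ.T)
    Minv_Zty = np.linalg.solve(M, Zty)
    XtHX = XtX - eta * XtZ @ Minv_ZtX
    XtHy = Xty - eta * XtZ @ Minv_Zty
    ytHy = yty - eta * Zty @ Minv_Zty
    sign, logdetXtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf, np.nan
    quad = ytHy - XtHy @ np.linalg.solve(XtHX, XtHy)
    if quad <= 0:
        return np.inf, np.nan
    sigma2_eps = quad / (G - p)
    crit = (G - p) * np.log(quad) + logdetM + logdetXtHX
    return crit, sigma2_eps


def _gcv(lam, G, XtX, XtZ, ZtZ, Xty, Zty, yty):
    """Generalized cross-validation score at ridge weight lam."""
    p = XtX.shape[0]
    K = ZtZ.shape[0]
    CtC = np.block([[XtX, XtZ], [XtZ.T, ZtZ]])
    A = CtC + lam * np.diag(np.concatenate([np.zeros(p), np.ones(K)]))
    rhs = np.concatenate([Xty, Zty])
    theta = np.linalg.solve(A, rhs)
    rss = yty - 2 * rhs @ theta + theta @ CtC @ theta
    edf = np.trace(np.linalg.solve(A, CtC))
    return G * max(rss, 0.0) / (G - edf) ** 2


def fit_penalized_spline(
    z: Sequence[float],
    x: Sequence[float],
    knots: Sequence[float],
    method: str = "reml",
    lam: Optional[float] = None,
) -> SmoothFit:
    """Fit the truncated-line penalized spline of ``z`` on ``x``.

    ``method="reml"`` (default) estimates the variance components of the
    equivalent mixed model by restricted maximum likelihood and falls back
    to GCV if the REML search fails.  Passing ``lam`` fixes the ridge weight
    instead (``method`` is recorded as ``"fixed"``).
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    X, Z = build_spline_basis(x, knots)
    G = z.size
    p, K = X.shape[1], Z.shape[1]
    if G <= K + 2:
        raise ValueError(f"need more than K+2={K + 2} observations, got {G}")

    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    Xty = X.T @ z
    Zty = Z.T @ z
    yty = float(z @ z)

    if lam is not None:
        beta, u = _solve_blup(XtX, XtZ, ZtZ, Xty, Zty, lam)
        fitted = X @ beta + Z @ u
        resid = z - fitted
        sigma2_eps = float(resid @ resid) / max(G - p, 1)
        return SmoothFit(
            knots=knots, beta=beta, u=u,
            sigma2_u=sigma2_eps / lam, sigma2_eps=sigma2_eps, lam=float(lam),
            fitted_log_variance=fitted, smoothed_variance=np.exp(fitted),
            method="fixed",
        )

    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    trace: list = []

    def objective(log_eta):
        crit, s2e = _profile_reml(np.exp(log_eta), G, p, XtX, XtZ, ZtZ, Xty, Zty, yty)
        trace.append((log_eta, crit))
        return crit

    # coarse grid then local refinement; eta spans ~e-25 .. e25
    grid = np.linspace(-25.0, 25.0, 51)
    vals = np.array([objective(g) for g in grid])
    fit_method = "reml"
    if not np.any(np.isfinite(vals)):
        log.warning("REML criterion non-finite on the whole grid; falling back to GCV")
        fit_method = "gcv"
    else:
        i = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.nan)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if not res.success:
            log.warning("REML refinement failed (%s); falling back to GCV", res.message)
            fit_method = "gcv"
        else:
            eta = float(np.exp(res.x))

    if fit_method == "gcv":
        gcv_grid = np.exp(np.linspace(-25.0, 25.0, 51))
        scores = np.array([_gcv(l, G, XtX, XtZ, ZtZ, Xty, Zty, yty) for l in gcv_grid])
        if not np.any(np.isfinite(scores)):
            raise RemlConvergenceError("REML and GCV both failed", trace)
        lam_hat = float(gcv_grid[int(np.nanargmin(scores))])
        eta = 1.0 / lam_hat

    lam_hat = 1.0 / eta
    beta, u = _solve_blup(XtX, XtZ, ZtZ, Xty, Zty, lam_hat)
    fitted = X @ beta + Z @ u
    _, sigma2_eps = _profile_reml(eta, G, p, XtX, XtZ, ZtZ, Xty, Zty, yty)
    if not np.isfinite(sigma2_eps):
        resid = z - fitted
        sigma2_eps = float(resid @ resid) / (G - p)
    return SmoothFit(
        knots=knots, beta=beta, u=u,
        sigma2_u=eta * sigma2_eps, sigma2_eps=float(sigma2_eps), lam=lam_hat,
        fitted_log_variance=fitted, smoothed_variance=np.exp(fitted),
        method=fit_method,
    )


def default_knot_count(G: int) -> int:
    return max(1, min(G // 4, MAX_KNOTS))


def log_variance_bias(n: int) -> float:
    """Mean bias of ln(s^2) for a normal sample of size n: E[ln s^2] - ln sigma^2.

    s^2 ~ sigma^2 * chi2_nu / nu with nu = n - 1, so the bias is
    psi(nu/2) + ln 2 - ln nu, a negative constant (-0.577 at n = 3).
    """
    nu = n - 1
    if nu < 1:
        raise ValueError("need n >= 2")
    return float(digamma(nu / 2.0) + np.log(2.0) - np.log(nu))


def smooth_variances(
    stats: GeneStats,
    K: Optional[int] = None,
    floor: float = 1e-8,
    debias: bool = True,
) -> SmoothFit:
    """Smooth per-gene log variances against means; returns exp-fitted variances.

    All genes participate in the fit and every gene receives a strictly
    positive smoothed variance.  With ``debias=True`` (default) the fitted
    log variances are shifted by the analytic log-chi-square mean bias of
    ln(s^2) (see :func:`log_variance_bias`), so ``exp(z_hat)`` estimates the
    true variance rather than ``exp(E[ln s^2]) ~ 0.56 sigma^2`` at n = 3.
    No further correction is applied for the convexity of exp.
    """
    if K is None:
        K = default_knot_count(stats.mean.size)
    z = np.log(np.maximum(stats.variance, floor))
    knots = select_knots(stats.mean, K)
    fit = fit_penalized_spline(z, stats.mean, knots, method="reml")
    if debias:
        c = -log_variance_bias(stats.n)
        fit.beta = fit.beta.copy()
        fit.beta[0] += c
        fit.fitted_log_variance = fit.fitted_log_variance + c
        fit.smoothed_variance = np.exp(fit.fitted_log_variance)
    return fit


def plot_mean_variance(stats: GeneStats, fit: SmoothFit, path) -> None:
    """Scatter of mean vs log sample variance with the fitted trend curve."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = np.argsort(stats.mean)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(stats.mean, stats.log_variance, ".", ms=2, alpha=0.3, color="gray")
    ax.plot(stats.mean[order], fit.fitted_log_variance[order], "-", color="green", lw=2)
    ax.set_xlabel("sample mean")
    ax.set_ylabel("log sample variance")
    ax.set_title(f"condition {stats.condition} (n={stats.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
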