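"""Type-I / type-II error curves on labelled simulated data.

For each score cutoff c, genes with score > c are called DE; the false
positive rate is FP over the number of truly non-DE genes and the false
negative rate is FN over the number of truly DE genes.  Curves are computed
per simulated dataset on a shared cutoff grid and averaged pointwise across
datasets.  The comparison baseline is a per-gene pooled-variance two-sample
t-test (scored as 1 - p so larger always means more evidence of DE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data import ExpressionMatrix

__all__ = [
    "ErrorCurve",
    "error_rates",
    "error_curve",
    "average_curves",
    "t_test_baseline",
    "default_cutoff_grid",
]


@dataclass
class ErrorCurve:
    cutoffs: np.ndarray
    fpr: np.ndarray
    fnr: np.ndarray
    method: str = ""
    n_datasets: int = 1

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.fnr = np.asarray(self.fnr, dtype=float)
        if not (self.cutoffs.size == self.fpr.size == self.fnr.size):
            raise ValueError("cutoffs, fpr, fnr must have equal length")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")

    def fnr_at_fpr(self, fpr_grid) -> np.ndarray:
        """FNR linearly interpolated as a function of FPR."""
        order = np.argsort(self.fpr, kind="stable")
        return np.interp(np.asarray(fpr_grid, float), self.fpr[order], self.fnr[order])


def default_cutoff_grid(n: int = 199) -> np.ndarray:
    """Evenly spaced score cutoffs strictly inside (0, 1)."""
    return np.linspace(0.0, 1.0, n + 2)[1:-1]


def error_rates(truth: Sequence, calls: Sequence) -> tuple[float, float]:
    """(FPR, FNR) of boolean DE calls against boolean truth labels."""
    truth = np.asarray(truth, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one DE and one non-DE gene")
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    return fp / n_neg, fn / n_pos


def error_curve(truth, scores, grid, method: str = "") -> ErrorCurve:
    """One (FPR, FNR) point per cutoff, calling score > cutoff.

    Scores must be oriented so larger means more evidence of differential
    expression (posterior probabilities directly; 1 - p for p-values).
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(grid, dtype=float)
    fpr = np.empty(grid.size)
    fnr = np.empty(grid.size)
    for i, c in enumerate(grid):
        fpr[i], fnr[i] = error_rates(truth, scores > c)
    return ErrorCurve(cutoffs=grid, fpr=fpr, fnr=fnr, method=method)


def average_curves(curves: Sequence[ErrorCurve]) -> ErrorCurve:
    """Pointwise mean of curves computed on an identical cutoff grid."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].cutoffs
    for c in curves[1:]:
        if c.cutoffs.size != grid.size or not np.allclose(c.cutoffs, grid):
            raise ValueError("curves must share the same cutoff grid")
    return ErrorCurve(
        cutoffs=grid,
        fpr=np.mean([c.fpr for c in curves], axis=0),
        fnr=np.mean([c.fnr for c in curves], axis=0),
        method=curves[0].method,
        n_datasets=len(curves),
    )


def t_test_baseline(control: ExpressionMatrix, treatment: ExpressionMatrix) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test p-value per gene.

    Genes with zero pooled variance get p = 1 with a warning (no evidence
    can be extracted from constant replicates).
    """
    a = control.values
    b = treatment.values
    if a.shape[0] != b.shape[0]:
        raise ValueError("control and treatment must have the same genes")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    pooled = (a.var(axis=1, ddof=1) * (a.shape[1] - 1)
              + b.var(axis=1, ddof=1) * (b.shape[1] - 1))
    degenerate = ~np.isfinite(p) | (pooled == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero pooled variance; p set to 1"
        )
        p[degenerate] = 1.0
    return p


def plot_error_curves(curves: Sequence[ErrorCurve], path) -> None:
    """FNR-vs-FPR comparison plot for a set of averaged curves."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        order = np.argsort(c.fpr, kind="stable")
        ax.plot(c.fpr[order], c.fnr[order], label=c.method or "method")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("false negative rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
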