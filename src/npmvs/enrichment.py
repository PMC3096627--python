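"""Downstream gene-set statistics: DE filtering, one-tailed Fisher
enrichment, Benjamini-Hochberg FDR adjustment.

The over-representation p-value for a set with m members in a universe of N
genes, given n DE genes of which k fall in the set, is the upper tail
P(K >= k) of Hypergeometric(N, m, n), summed exactly in log space with
log-gamma terms (no normal approximation — gene-set counts are small).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fold_change_filter",
    "fisher_enrichment",
    "bh_adjust",
    "EnrichmentResult",
    "enrich_gene_sets",
    "read_gene_sets",
]


def fold_change_filter(
    results: pd.DataFrame,
    threshold: float = 1.0,
    posterior_cutoff: float = 0.99,
) -> tuple[list[str], list[str]]:
    """Split called DE genes into up/down sets by log2 fold change.

    A gene enters the up set iff posterior > posterior_cutoff AND
    log2FC > threshold; the down set iff posterior > cutoff AND
    log2FC < -threshold.  Both inequalities are strict, so boundary genes
    (|log2FC| exactly at the threshold) are excluded, and the sets are
    disjoint by construction.
    """
    post = results["posterior_de_prob"].to_numpy(dtype=float)
    lfc = results["log2_fold_change"].to_numpy(dtype=float)
    ids = results["gene_id"].astype(str)
    called = post > posterior_cutoff
    up = ids[called & (lfc > threshold)].tolist()
    down = ids[called & (lfc < -threshold)].tolist()
    return up, down


def _log_hyper_pmf(k, N, m, n):
    return (
        gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
        + gammaln(N - m + 1) - gammaln(n - k + 1) - gammaln(N - m - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_enrichment(N: int, m: int, n: int, k: int) -> float:
    """One-tailed (over-representation) Fisher p-value P(K >= k).

    N: universe size; m: genes in the set; n: DE genes; k: DE genes in the
    set.  Exact log-space tail summation of the hypergeometric pmf.
    """
    for name, val in (("N", N), ("m", m), ("n", n), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    N, m, n, k = int(N), int(m), int(n), int(k)
    if m > N or n > N:
        raise ValueError("set size and DE count cannot exceed the universe")
    if k > min(m, n) or k < max(0, n + m - N):
        raise ValueError(f"k={k} inconsistent with (N={N}, m={m}, n={n})")
    ks = np.arange(k, min(m, n) + 1)
    if ks.size == 0:
        return 1.0
    p = float(np.exp(logsumexp(_log_hyper_pmf(ks, N, m, n))))
    return min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    set_id: str
    N: int
    m: int
    n: int
    k: int
    p: float
    p_adj: float


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a two-column TSV (set id, gene id) into set-membership dict."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {line!r}"
                )
            sets.setdefault(parts[0], set()).add(parts[1])
    return sets


def enrich_gene_sets(
    de_genes: Sequence[str],
    gene_sets: Mapping[str, set],
    universe_size: int,
) -> pd.DataFrame:
    """Fisher over-representation test per gene set, BH-adjusted.

    ``universe_size`` (N) is a required explicit input: the caller decides
    whether the universe is the array's probe set or the whole genome.
    """
    de = set(map(str, de_genes))
    n = len(de)
    if n > universe_size:
        raise ValueError("more DE genes than the universe size")
    rows = []
    for set_id in sorted(gene_sets):
        members = {str(g) for g in gene_sets[set_id]}
        m = len(members)
        k = len(members & de)
        p = fisher_enrichment(universe_size, m, n, k) if n else 1.0
        rows.append((set_id, universe_size, m, n, k, p))
    df = pd.DataFrame(rows, columns=["set_id", "N", "m", "n", "k", "p"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df
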