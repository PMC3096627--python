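"""Core data containers and TSV readers/writers.

Expression data is held as an :class:`ExpressionMatrix`: a genes x samples
array of log-scale (assumed log2) normalized intensities together with a
condition label per sample.  Inputs are expected to be already normalized
(e.g. RMA output exported as a tab-separated table); no normalization is
performed here and missing values are rejected rather than imputed, because
the downstream model assumes complete replicate vectors per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RESULT_COLUMNS",
    "read_expression_matrix",
    "write_results",
    "read_results",
]


class ExpressionDataError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with per-sample condition labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    values
        ``(G, S)`` float array of log-scale expression.
    condition_of_sample
        One condition label per column; exactly one or two distinct labels,
        each backed by at least two samples so per-condition variances exist.
    sample_ids
        Optional column names; defaults to ``s1..sS``.
    """

    gene_ids: Sequence[str]
    values: np.ndarray
    condition_of_sample: Sequence[str]
    sample_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.condition_of_sample = list(map(str, self.condition_of_sample))
        if self.values.ndim != 2:
            raise ExpressionDataError("values must be a 2-D genes x samples array")
        g, s = self.values.shape
        if g < 2:
            raise ExpressionDataError("need at least 2 genes")
        if len(self.gene_ids) != g:
            raise ExpressionDataError("gene_ids length does not match row count")
        if len(set(self.gene_ids)) != g:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ExpressionDataError(f"duplicate gene ids: {dupes[:5]}")
        if len(self.condition_of_sample) != s:
            raise ExpressionDataError("condition_of_sample length does not match column count")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(s)]
        else:
            self.sample_ids = list(map(str, self.sample_ids))
            if len(self.sample_ids) != s:
                raise ExpressionDataError("sample_ids length does not match column count")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionDataError(
                f"non-finite value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        labels = self.conditions
        if not 1 <= len(labels) <= 2:
            raise ExpressionDataError(f"expected 1 or 2 conditions, got {len(labels)}")
        for lab in labels:
            if sum(c == lab for c in self.condition_of_sample) < 2:
                raise ExpressionDataError(
                    f"condition {lab!r} has fewer than 2 samples; variances are undefined"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.condition_of_sample:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> np.ndarray:
        """Column indices belonging to ``condition``."""
        idx = np.array([i for i, c in enumerate(self.condition_of_sample) if c == condition])
        if idx.size == 0:
            raise KeyError(f"no samples with condition {condition!r}")
        return idx

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        idx = self.samples_of(condition)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            values=self.values[:, idx],
            condition_of_sample=[condition] * idx.size,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


#: Fixed column order of the results table written by :func:`write_results`.
RESULT_COLUMNS = [
    "gene_id",
    "mean_control",
    "mean_treatment",
    "smoothed_variance_control",
    "smoothed_variance_treatment",
    "log2_fold_change",
    "posterior_de_prob",
    "call",
]


def read_expression_matrix(path, condition_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression table (gene ids in column 1, samples after).

    Every sample column must appear in ``condition_map`` (sample name ->
    condition label).  Missing or non-numeric cells are load errors naming
    the offending row and column; nothing is dropped or imputed.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ExpressionDataError(f"{path}: expected gene id column plus sample columns")
    gene_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    missing = [s for s in sample_cols if s not in condition_map]
    if missing:
        raise ExpressionDataError(f"{path}: samples missing from condition map: {missing}")
    gene_ids = df[gene_col].tolist()
    raw = df[sample_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionDataError(
            f"{path}: non-numeric or missing value at gene {gene_ids[i]!r}, "
            f"sample {sample_cols[j]!r} (value {raw.iat[i, j]!r})"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        values=numeric.to_numpy(dtype=float),
        condition_of_sample=[condition_map[s] for s in sample_cols],
        sample_ids=sample_cols,
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV with the fixed :data:`RESULT_COLUMNS` order.

    Floats are serialized with 12 significant digits so a read-back
    reproduces posteriors to at least 10 digits.
    """
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    out = table[RESULT_COLUMNS]
    p = out["posterior_de_prob"].to_numpy(dtype=float)
    if out.shape[0] and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("posterior_de_prob outside [0, 1]")
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"gene_id": str, "call": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionDataError(f"{path}: missing result columns {missing}")
    return df
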