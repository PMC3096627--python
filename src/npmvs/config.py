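"""Run configuration: prior choice, quadrature, cutoffs, knots, seed.

The defaults encode the reference analysis settings: a uniform prior on the
between-gene variance, 20-point quadrature, a posterior cutoff of 0.99 and a
log2 fold-change threshold of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings for a full differential-expression run.

    Attributes
    ----------
    prior_kind
        ``"uniform"`` (default) or ``"inverse_gamma"`` prior on the
        between-gene variance v of the DE means.
    v_lower, v_upper
        Uniform prior support ``(v_L, v_U)``.  ``v_upper=None`` means
        "data-driven": the empirical variance of the gene means.
    ig_shape, ig_scale
        Inverse-gamma hyperparameters, used when ``prior_kind`` is
        ``"inverse_gamma"``.
    mixing_p
        Prior probability that a gene is differentially expressed.
    quadrature_order, quadrature_scheme
        Order Q and scheme (``"legendre"`` or ``"hermite"``) of the 1-D rule
        used for the marginal-likelihood integral over v.
    posterior_cutoff
        Posterior probability above which a gene is called DE.
    fold_change_threshold
        |log2 fold change| a called gene must exceed in the up/down filter.
    knots
        Number of spline knots K; ``None`` selects ``min(G // 4, 35)``.
    pooled_variance_fit
        Fit one mean-variance curve on both conditions jointly instead of
        one per condition.
    variance_floor
        Floor applied to sample variances before taking logs.
    """

    prior_kind: str = "uniform"
    v_lower: float = 1e-4
    v_upper: Optional[float] = None
    ig_shape: float = 0.5
    ig_scale: float = 0.01
    mixing_p: float = 0.05
    quadrature_order: int = 20
    quadrature_scheme: str = "legendre"
    posterior_cutoff: float = 0.99
    fold_change_threshold: float = 1.0
    knots: Optional[int] = None
    pooled_variance_fit: bool = False
    variance_floor: float = 1e-8
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.prior_kind not in ("uniform", "inverse_gamma"):
            raise ValueError(f"unknown prior_kind {self.prior_kind!r}")
        if self.v_lower < 0:
            raise ValueError("v_lower must be >= 0")
        if self.v_upper is not None and self.v_upper <= self.v_lower:
            raise ValueError("v_upper must exceed v_lower")
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if not 0 < self.mixing_p < 1:
            raise ValueError("mixing_p must lie in (0, 1)")
        if self.quadrature_order < 1:
            raise ValueError("quadrature_order must be >= 1")
        if self.quadrature_scheme not in ("legendre", "hermite"):
            raise ValueError(f"unknown quadrature scheme {self.quadrature_scheme!r}")
        if not 0 < self.posterior_cutoff < 1:
            raise ValueError("posterior_cutoff must lie in (0, 1)")
        if self.fold_change_threshold < 0:
            raise ValueError("fold_change_threshold must be >= 0")
        if self.knots is not None and self.knots < 1:
            raise ValueError("knots must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path, **overrides) -> RunConfig:
    """Load a flat YAML config; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)
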