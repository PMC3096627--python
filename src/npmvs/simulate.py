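"""Synthetic two-condition expression data with known DE labels.

The generator emulates a small-replicate microarray comparison on the log2
scale.  Control gene means are drawn Normal(8, 1).  A fraction ``pi1`` of
genes is differentially expressed; their treatment means are reassigned
uniformly within four strata with exact 25% shares each:

  up          [8.1, 11.0]     down        [5.0, 7.9]
  high-up     [11.1, 14.0]    deep-down   [2.0, 4.9]

Non-DE genes keep their control mean in the treatment arm.  Per-gene
variances follow a deterministic mean-variance law chosen by ``case``
(constant, linear, quadratic or strongly nonlinear log-variance in the
mean), multiplied by log-normal noise, and each condition's variance is
evaluated at that condition's own mean.  Replicates are independent normal
draws.  The default design (10,000 genes, 3 replicates per condition)
matches the reference simulation study; coefficients of the variance laws
are presets spanning roughly the log-variance range seen in RMA-normalized
Arabidopsis arrays, and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data import ExpressionMatrix

__all__ = [
    "SimulationDesign",
    "LabeledDataset",
    "mean_variance_curve",
    "simulate_dataset",
    "simulate_batch",
    "DE_STRATA",
]

#: (name, low, high) of the four DE treatment-mean strata, 25% of DE genes each.
DE_STRATA = (
    ("up", 8.1, 11.0),
    ("high_up", 11.1, 14.0),
    ("down", 5.0, 7.9),
    ("deep_down", 2.0, 4.9),
)

#: preset coefficients of the per-case log-variance laws (natural-log scale)
CASE_PARAMS = {
    # case 0: strongly nonlinear, non-monotone log-variance
    0: {"base": -3.0, "amp": 1.2, "freq": 0.9},
    # case 1: constant log-variance
    1: {"base": -3.0},
    # case 2: log-variance linear in the mean
    2: {"base": -6.0, "slope": 0.35},
    # case 3: log-variance quadratic in the mean
    3: {"base": -2.0, "curv": -0.08, "center": 8.0},
}


@dataclass
class SimulationDesign:
    """Generator parameters for one simulated two-condition study."""

    n_genes: int = 10_000
    pi1: float = 0.05            # DE fraction; catalog values 0.02 / 0.05 / 0.10
    n_replicates: int = 3
    case: int = 0
    control_mean: float = 8.0
    control_mean_sd: float = 1.0
    log_variance_noise_sd: float = 0.25
    case_params: Optional[dict] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 < self.pi1 < 1:
            raise ValueError("pi1 must lie in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.case not in CASE_PARAMS:
            raise ValueError(f"unknown mean-variance case {self.case}; choose 0..3")
        if self.log_variance_noise_sd < 0:
            raise ValueError("log_variance_noise_sd must be >= 0")


@dataclass
class LabeledDataset:
    """A simulated control/treatment pair with full ground truth."""

    control: ExpressionMatrix
    treatment: ExpressionMatrix
    is_de: np.ndarray               # boolean per gene
    stratum: np.ndarray             # stratum name per gene ("" for non-DE)
    true_mean_control: np.ndarray
    true_mean_treatment: np.ndarray
    true_variance_control: np.ndarray
    true_variance_treatment: np.ndarray
    design: SimulationDesign = field(repr=False)


def mean_variance_curve(case: int, mu, params: Optional[dict] = None):
    """Deterministic variance law sigma^2(mu) for one case (noise excluded).

    case 1 is constant, case 2 log-linear with positive slope, case 3
    log-quadratic (non-monotone), and case 0 a strongly nonlinear sinusoidal
    log-variance with several slope sign changes over the expression range.
    """
    if case not in CASE_PARAMS:
        raise ValueError(f"unknown mean-variance case {case}; choose 0..3")
    mu = np.asarray(mu, dtype=float)
    b = dict(CASE_PARAMS[case])
    if params:
        b.update(params)
    if case == 1:
        log_var = np.full_like(mu, b["base"])
    elif case == 2:
        log_var = b["base"] + b["slope"] * mu
    elif case == 3:
        log_var = b["base"] + b["curv"] * (mu - b["center"]) ** 2
    else:  # case 0
        log_var = b["base"] + b["amp"] * np.sin(b["freq"] * (mu - 8.0))
    out = np.exp(log_var)
    return out if out.ndim else float(out)


def simulate_dataset(design: SimulationDesign, seed: Optional[int] = None) -> LabeledDataset:
    """Draw one labelled control/treatment dataset from the design.

    A fixed seed gives bit-identical output.  The DE gene set is a uniform
    random subset of size round(G * pi1); strata are filled by deterministic
    25% blocks of the shuffled DE indices, so the shares are exact.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    G, n = design.n_genes, design.n_replicates

    n_de_exact = G * design.pi1
    n_de = int(round(n_de_exact))
    if abs(n_de_exact - n_de) > 1e-9:
        import warnings

        warnings.warn(
            f"G * pi1 = {n_de_exact} is not an integer; rounding to {n_de} DE genes"
        )

    mu_control = rng.normal(design.control_mean, design.control_mean_sd, size=G)
    mu_treatment = mu_control.copy()

    de_idx = rng.permutation(G)[:n_de]
    stratum = np.full(G, "", dtype=object)
    bounds = np.linspace(0, n_de, len(DE_STRATA) + 1).round().astype(int)
    for (name, lo, hi), a, b in zip(DE_STRATA, bounds[:-1], bounds[1:]):
        idx = de_idx[a:b]
        mu_treatment[idx] = rng.uniform(lo, hi, size=idx.size)
        stratum[idx] = name
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True

    noise = rng.normal(0.0, design.log_variance_noise_sd, size=G)
    var_control = mean_variance_curve(design.case, mu_control, design.case_params) * np.exp(noise)
    var_treatment = mean_variance_curve(design.case, mu_treatment, design.case_params) * np.exp(noise)

    y_control = rng.normal(mu_control[:, None], np.sqrt(var_control)[:, None], size=(G, n))
    y_treatment = rng.normal(mu_treatment[:, None], np.sqrt(var_treatment)[:, None], size=(G, n))

    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    control = ExpressionMatrix(
        gene_ids=gene_ids, values=y_control,
        condition_of_sample=["control"] * n,
        sample_ids=[f"c{j + 1}" for j in range(n)],
    )
    treatment = ExpressionMatrix(
        gene_ids=gene_ids, values=y_treatment,
        condition_of_sample=["treatment"] * n,
        sample_ids=[f"t{j + 1}" for j in range(n)],
    )
    return LabeledDataset(
        control=control, treatment=treatment,
        is_de=is_de, stratum=np.asarray(stratum, dtype=object),
        true_mean_control=mu_control, true_mean_treatment=mu_treatment,
        true_variance_control=var_control, true_variance_treatment=var_treatment,
        design=replace(design, seed=seed),
    )


def simulate_batch(design: SimulationDesign, n_datasets: int, base_seed: int):
    """n independent datasets with per-dataset seeds base_seed + index."""
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    return [simulate_dataset(design, seed=base_seed + i) for i in range(n_datasets)]
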