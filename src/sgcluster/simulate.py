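"""Synthetic clustered scRNA-seq counts with controllable dropout.

The generative model follows the standard Splatter-style recipe: per-gene
base means drawn from a gamma distribution, per-group differential-expression
multipliers (log-normal, half down-regulated) applied to a configurable
fraction of genes, per-cell library sizes (log-normal), negative-binomial
sampling, and an optional mean-dependent logistic dropout step that zeroes
low-expression entries preferentially.  ``realized_dropout`` reports the
fraction of zero entries in the final matrix (structural NB zeros plus
dropout zeros), which is the sparsity level the robustness experiments are
phrased in; :func:`calibrate_dropout` bisects the logistic midpoint to hit a
requested sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io import ExpressionMatrix

__all__ = ["SimConfig", "simulate", "calibrate_dropout", "subsample_depth"]


@dataclass
class SimConfig:
    """Simulation parameters; defaults give four well-separated groups of
    1000 cells x 1000 genes at roughly 20% overall sparsity."""

    n_cells: int = 1000
    n_genes: int = 1000
    n_groups: int = 4
    proportions: Sequence[float] | None = None  # None -> equal
    gene_mean_shape: float = 2.0     # gamma shape of per-gene base means
    gene_mean_rate: float = 0.5      # gamma rate (mean = shape/rate)
    de_prob: float = 0.3             # fraction of genes DE in each group
    de_factor_loc: float = 1.0       # log-normal log-mean of DE multipliers
    de_factor_scale: float = 0.4     # log-normal log-sd of DE multipliers
    de_down_prob: float = 0.5        # fraction of DE factors inverted (down-regulated)
    libsize_loc: float = np.log(20000.0)  # log-normal log-mean of library sizes
    libsize_scale: float = 0.25
    nb_dispersion: float = 0.2       # NB variance = mu + dispersion * mu^2
    dropout_enabled: bool = True
    dropout_midpoint: float = 0.85   # logistic midpoint on the log-mean scale
    dropout_shape: float = 1.0       # logistic steepness (> 0)
    depth_fraction: float = 1.0      # binomial thinning of final counts
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_genes < 1 or self.n_groups < 1:
            raise ValueError("n_cells, n_genes and n_groups must be positive")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if len(p) != self.n_groups or (p <= 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("proportions must be n_groups positive values summing to 1")
        for name in ("gene_mean_shape", "gene_mean_rate", "de_factor_scale",
                     "libsize_scale", "nb_dispersion", "dropout_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")
        if not 0.0 < self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must be in (0, 1]")

    def group_sizes(self) -> np.ndarray:
        p = (np.full(self.n_groups, 1.0 / self.n_groups)
             if self.proportions is None else np.asarray(self.proportions, float))
        sizes = np.floor(p * self.n_cells).astype(int)
        # distribute the remainder by largest fractional part
        rem = self.n_cells - sizes.sum()
        order = np.argsort(-(p * self.n_cells - sizes))
        sizes[order[:rem]] += 1
        return sizes


def _mean_matrix(cfg: SimConfig, rng: np.random.Generator):
    base = rng.gamma(cfg.gene_mean_shape, 1.0 / cfg.gene_mean_rate, size=cfg.n_genes)
    base = np.maximum(base, 1e-8)
    factors = np.ones((cfg.n_groups, cfg.n_genes))
    for g in range(cfg.n_groups):
        de = rng.random(cfg.n_genes) < cfg.de_prob
        f = rng.lognormal(cfg.de_factor_loc, cfg.de_factor_scale, size=cfg.n_genes)
        down = rng.random(cfg.n_genes) < cfg.de_down_prob
        f = np.where(down, 1.0 / f, f)
        factors[g, de] = f[de]
    profiles = base[None, :] * factors                 # (groups, genes)
    profiles /= profiles.sum(axis=1, keepdims=True)    # expression fractions

    sizes = cfg.group_sizes()
    labels = np.repeat(np.arange(cfg.n_groups), sizes)
    rng.shuffle(labels)
    libsize = rng.lognormal(cfg.libsize_loc, cfg.libsize_scale, size=cfg.n_cells)
    mu = libsize[:, None] * profiles[labels, :]        # (cells, genes)
    return mu, labels


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, np.ndarray, float]:
    """Draw a count matrix; returns (counts, group labels, realized zero fraction)."""
    rng = np.random.default_rng(cfg.seed)
    mu, labels = _mean_matrix(cfg, rng)

    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    if cfg.dropout_enabled:
        p_drop = expit(cfg.dropout_shape * (cfg.dropout_midpoint - np.log(mu)))
        counts[rng.random(counts.shape) < p_drop] = 0

    if cfg.depth_fraction < 1.0:
        counts = rng.binomial(counts, cfg.depth_fraction)

    realized_dropout = float((counts == 0).mean())
    em = ExpressionMatrix(
        values=counts.astype(np.float64),
        cell_ids=[f"cell_{i}" for i in range(cfg.n_cells)],
        gene_ids=[f"gene_{j}" for j in range(cfg.n_genes)],
        is_counts=True,
    )
    return em, labels, realized_dropout


def calibrate_dropout(cfg: SimConfig, target_rate: float, tol: float = 0.01,
                      lo: float = -15.0, hi: float = 15.0,
                      max_iter: int = 60) -> SimConfig:
    """Bisect ``dropout_midpoint`` so the realized zero fraction hits ``target_rate``.

    The realized rate is monotone non-decreasing in the midpoint (a larger
    midpoint drops entries of higher mean).  The rate is estimated on the
    seeded draw defined by ``cfg.seed``; the floor of the achievable range is
    the NB structural zero fraction.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    if not cfg.dropout_enabled:
        raise ValueError("dropout is disabled in this configuration")

    def rate_at(mid: float) -> float:
        return simulate(replace(cfg, dropout_midpoint=mid))[2]

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not r_lo - tol <= target_rate <= r_hi + tol:
        raise ValueError(
            f"target rate {target_rate:.4f} outside achievable range "
            f"[{r_lo:.4f}, {r_hi:.4f}] for midpoints in [{lo}, {hi}]"
        )
    a, b = lo, hi
    for _ in range(max_iter):
        mid = (a + b) / 2.0
        r = rate_at(mid)
        if abs(r - target_rate) <= tol:
            return replace(cfg, dropout_midpoint=mid)
        if r < target_rate:
            a = mid
        else:
            b = mid
    raise RuntimeError("bisection failed to reach the target rate")


def subsample_depth(counts: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Binomially thin each entry: every molecule kept with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vals = counts.values
    if not np.array_equal(vals, np.round(vals)):
        raise ValueError("subsample_depth requires integer counts")
    if fraction == 1.0:
        return ExpressionMatrix(vals.copy(), list(counts.cell_ids),
                                list(counts.gene_ids), is_counts=True)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(vals.astype(np.int64), fraction).astype(np.float64)
    return ExpressionMatrix(thinned, list(counts.cell_ids),
                            list(counts.gene_ids), is_counts=True)
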