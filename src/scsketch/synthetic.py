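"""Synthetic data generators for every pipeline stage.

Three families of fixtures:

* Gaussian mixtures in embedding space (for clustering benchmarks with
  controlled imbalance and separation).
* Gamma-Poisson count matrices with group-specific differential
  expression, lognormal library-size variation and logistic-in-log-mean
  dropout, in the style of splatter.
* Rare-population spike-in mixtures (an abundant and a small shifted
  population plus a truth mask).

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .io import ExpressionMatrix

__all__ = [
    "SimSpec",
    "simulate_gaussian_mixture",
    "simulate_counts",
    "add_dropout",
    "spike_rare_mixture",
    "calibrate_dropout_midpoint",
]


@dataclass
class SimSpec:
    """Parameters of the gamma-Poisson count simulator."""

    n_cells: int = 1000
    n_genes: int = 2000
    group_sizes: tuple[int, ...] | None = None
    group_proportions: tuple[float, ...] | None = None
    de_fraction: float = 0.1
    de_strength: float | tuple[float, ...] = 1.0
    mean_shape: float = 0.6
    mean_scale: float = 2.0
    lib_sigma: float = 0.25
    dropout_midpoint: float | None = None
    dropout_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.group_sizes is not None and self.group_proportions is not None:
            raise ValueError("give group_sizes or group_proportions, not both")
        if self.group_sizes is not None:
            if any(s < 1 for s in self.group_sizes):
                raise ValueError("group sizes must be positive")
            if sum(self.group_sizes) != self.n_cells:
                raise ValueError(
                    f"group sizes sum to {sum(self.group_sizes)}, expected {self.n_cells}"
                )
        if self.group_proportions is not None:
            props = np.asarray(self.group_proportions, dtype=float)
            if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
                raise ValueError("group proportions must be positive and sum to 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")

    @property
    def n_groups(self) -> int:
        if self.group_sizes is not None:
            return len(self.group_sizes)
        if self.group_proportions is not None:
            return len(self.group_proportions)
        return 1

    def per_group_strength(self) -> np.ndarray:
        s = self.de_strength
        if np.isscalar(s):
            return np.full(self.n_groups, float(s))
        s = np.asarray(s, dtype=float)
        if s.shape != (self.n_groups,):
            raise ValueError("per-group de_strength length must match group count")
        return s


def simulate_gaussian_mixture(
    sizes: Sequence[int],
    d: int,
    separation: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance isotropic Gaussian clusters with controlled spacing.

    Means are placed along the first axis at multiples of ``separation``,
    so the nearest inter-mean distance equals ``separation`` exactly.
    """
    sizes = [int(s) for s in sizes]
    if d < 1:
        raise ValueError("dimension must be at least 1")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    points = []
    labels = []
    for c, size in enumerate(sizes):
        mean = np.zeros(d)
        mean[0] = c * separation
        points.append(rng.standard_normal((size, d)) + mean)
        labels.append(np.full(size, c, dtype=int))
    return np.concatenate(points), np.concatenate(labels)


def _resolve_sizes(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.group_sizes is not None:
        return np.asarray(spec.group_sizes, dtype=int)
    if spec.group_proportions is not None:
        sizes = rng.multinomial(spec.n_cells, np.asarray(spec.group_proportions))
        # multinomial noise may empty a tiny group; guarantee >= 1 each
        while np.any(sizes == 0):
            donor = int(np.argmax(sizes))
            sizes[int(np.argmin(sizes))] += 1
            sizes[donor] -= 1
        return sizes
    return np.asarray([spec.n_cells], dtype=int)


def _dropout_mask(
    values: np.ndarray, midpoint: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-entry Bernoulli zeroing keyed to each gene's mean expression."""
    gene_means = values.mean(axis=0)
    p_drop = expit(shape * (midpoint - np.log1p(gene_means)))
    return rng.random(values.shape) < p_drop[None, :]


def simulate_counts(spec: SimSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Gamma-Poisson counts with group DE, library-size noise and dropout.

    Returns the raw count matrix and the per-cell group labels.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _resolve_sizes(spec, rng)
    n_groups = len(sizes)
    strengths = (
        spec.per_group_strength()
        if spec.group_sizes is not None or spec.group_proportions is not None
        else np.atleast_1d(np.asarray(spec.de_strength, dtype=float))[:1]
    )
    if strengths.shape[0] != n_groups:
        strengths = np.full(n_groups, float(strengths[0]))

    base_means = rng.gamma(spec.mean_shape, spec.mean_scale, size=spec.n_genes)
    group_means = np.tile(base_means, (n_groups, 1))
    n_de = int(round(spec.de_fraction * spec.n_genes))
    for g in range(n_groups):
        if n_de == 0 or strengths[g] == 0.0:
            continue
        de_genes = rng.choice(spec.n_genes, n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        magnitude = np.abs(rng.normal(strengths[g], strengths[g] / 3.0, size=n_de))
        group_means[g, de_genes] = base_means[de_genes] * np.exp(signs * magnitude)

    lib = np.exp(rng.normal(0.0, spec.lib_sigma, size=spec.n_cells))
    labels = np.repeat(np.arange(n_groups), sizes)
    counts = np.empty((spec.n_cells, spec.n_genes))
    start = 0
    for g, size in enumerate(sizes):
        block_means = lib[start:start + size, None] * group_means[g][None, :]
        counts[start:start + size] = rng.poisson(block_means)
        start += size

    if spec.dropout_midpoint is not None:
        mask = _dropout_mask(counts, spec.dropout_midpoint, spec.dropout_shape, rng)
        counts[mask] = 0.0

    m = ExpressionMatrix(counts, layer="raw")
    return m, labels


def add_dropout(
    m: ExpressionMatrix,
    midpoint: float,
    shape: float,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Zero entries of a count matrix with gene-level logistic probability.

    A gene's dropout probability is ``logistic(shape * (midpoint -
    log(mean_g + 1)))``; lowly expressed genes drop out first. Sparsity is
    non-decreasing by construction.
    """
    if m.layer != "raw":
        raise ValueError("add_dropout expects the raw layer")
    values = m.values.copy()
    mask = _dropout_mask(values, midpoint, shape, rng)
    values[mask] = 0.0
    return ExpressionMatrix(values, list(m.cell_ids), list(m.gene_ids), layer="raw")


def spike_rare_mixture(
    n_abundant: int,
    n_rare: int,
    base_spec: SimSpec,
    shift_strength: float,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Two-population mixture: abundant reference plus a small shifted group.

    Only the rare group receives differential-expression factors (of size
    ``shift_strength``); ``shift_strength = 0`` makes the populations
    statistically indistinguishable. Returns the count matrix and a
    boolean mask marking rare cells.
    """
    if n_rare < 1:
        raise ValueError("need at least one rare cell")
    if n_abundant < n_rare:
        raise ValueError("the abundant population must be at least as large")
    spec = replace(
        base_spec,
        n_cells=n_abundant + n_rare,
        group_sizes=(n_abundant, n_rare),
        group_proportions=None,
        de_strength=(0.0, float(shift_strength)),
        seed=base_spec.seed if seed is None else seed,
    )
    m, labels = simulate_counts(spec)
    return m, labels == 1


def calibrate_dropout_midpoint(
    sparsity_fn: Callable[[float], float],
    target: float,
    lo: float = -10.0,
    hi: float = 30.0,
    tol: float = 2e-3,
    max_iter: int = 50,
) -> float:
    """Bisection on the dropout midpoint to hit a target realized sparsity.

    ``sparsity_fn`` must be non-decreasing in the midpoint (true when the
    underlying generator reuses a fixed seed, so the per-entry uniforms are
    shared across evaluations).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target sparsity must be in (0, 1)")
    f_lo, f_hi = sparsity_fn(lo), sparsity_fn(hi)
    if target <= f_lo:
        return lo
    if target >= f_hi:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = sparsity_fn(mid)
        if abs(f_mid - target) <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
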