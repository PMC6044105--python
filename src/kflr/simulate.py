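"""Synthetic benchmark generator: random networks and linear AR(1) dynamics.

Networks are random directed graphs with signed weights; expression follows
the linear dynamics x(t+1) = Wᵀ x(t) + e with i.i.d. Gaussian process noise,
the discrete-time analogue of the regression model the inference method
fits, so parameter recovery has a known optimum.  The default dimensions
mirror the small in-silico benchmark layout: 10 genes, 5 replicate series
of 21 time points each.

A noise-injection protocol is included for robustness studies: each cell is
perturbed by ``fraction`` times a standard-normal draw (so ``fraction=0.1``
adds noise of amplitude 0.1); a relative mode scales the perturbation by
each gene's standard deviation instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionDataset, GoldStandard

__all__ = [
    "SyntheticNetwork",
    "SimulationConfig",
    "sample_network",
    "simulate_timeseries",
    "add_noise",
    "make_benchmark",
]

_MAX_SPECTRAL_RADIUS = 0.95


@dataclass
class SyntheticNetwork:
    """Directed weighted network; entry (j, i) is the effect of gene j on gene i."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))}

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.adjacency))))

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(n_genes=self.n_genes, edges=self.edges())


@dataclass
class SimulationConfig:
    """Benchmark dimensions and dynamics parameters."""

    n_genes: int = 10
    n_series: int = 5
    n_timepoints: int = 21
    edge_prob: float = 0.15
    weight_range: tuple[float, float] = (0.5, 1.0)
    process_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_series, self.n_timepoints) < 1:
            raise ValueError("counts must be at least 1")
        lo, hi = self.weight_range
        if not (hi >= lo > 0):
            raise ValueError("weight range must satisfy hi >= lo > 0")
        if not 0 <= self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in [0, 1]")


def sample_network(config: SimulationConfig) -> SyntheticNetwork:
    """Random directed network with independent edges and signed weights.

    Each ordered pair (no self-loops) is an edge with probability
    ``edge_prob``; weights are uniform on ±[w_lo, w_hi].  The weight matrix
    is rescaled when necessary so its spectral radius is at most 0.95,
    keeping the AR(1) dynamics stable.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    lo, hi = config.weight_range
    present = rng.random((g, g)) < config.edge_prob
    np.fill_diagonal(present, False)
    magnitude = rng.uniform(lo, hi, size=(g, g))
    sign = rng.choice([-1.0, 1.0], size=(g, g))
    W = np.where(present, sign * magnitude, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(W))) if g > 1 else 0.0
    if radius > _MAX_SPECTRAL_RADIUS:
        W *= _MAX_SPECTRAL_RADIUS / radius
    return SyntheticNetwork(adjacency=W)


def simulate_timeseries(network: SyntheticNetwork, config: SimulationConfig) -> ExpressionDataset:
    """Simulate replicate series from x(t+1) = Wᵀ x(t) + e.

    Initial states are standard normal per gene; process noise is
    N(0, process_noise_sd²) i.i.d. per gene and step.  Deterministic given
    the config seed.
    """
    if network.spectral_radius() >= 1.0:
        raise ValueError("network dynamics are unstable (spectral radius >= 1)")
    rng = np.random.default_rng(config.seed + 1)
    g, s, t = network.n_genes, config.n_series, config.n_timepoints
    Wt = network.adjacency.T
    series, times = [], []
    for _ in range(s):
        x = np.empty((t, g))
        x[0] = rng.standard_normal(g)
        noise = config.process_noise_sd * rng.standard_normal((t - 1, g)) if t > 1 else None
        for k in range(1, t):
            x[k] = Wt @ x[k - 1] + noise[k - 1]
        series.append(x)
        times.append(np.arange(t, dtype=float))
    names = [f"G{k + 1}" for k in range(g)]
    return ExpressionDataset(gene_names=names, series=series, time_points=times)


def add_noise(dataset: ExpressionDataset, fraction: float, seed: int = 0,
              mode: str = "amplitude") -> ExpressionDataset:
    """Perturb every expression cell with Gaussian measurement noise.

    ``amplitude`` mode (default) adds ``fraction``·N(0,1) per cell, so the
    perturbation's standard deviation equals ``fraction`` in expression
    units.  ``relative`` mode scales the draw by each gene's per-series
    standard deviation instead.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    for k, mat in enumerate(out.series):
        eta = rng.standard_normal(mat.shape)
        if mode == "amplitude":
            out.series[k] = mat + fraction * eta
        elif mode == "relative":
            sd = mat.std(axis=0, keepdims=True)
            out.series[k] = mat + fraction * sd * eta
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def make_benchmark(config: SimulationConfig) -> tuple[ExpressionDataset, GoldStandard, SyntheticNetwork]:
    """Bundle a sampled network, its simulated data and the gold standard."""
    network = sample_network(config)
    dataset = simulate_timeseries(network, config)
    return dataset, network.gold_standard(), network
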