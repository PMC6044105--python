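"""Discretization, entropy, mutual information and conditional MI.

All information quantities are in bits (log base 2).  Expression values are
discretized per gene before any entropy is computed; MI then measures static
dependence between two genes, and CMI(X,Y|Z) measures the dependence that
remains once one or two conditioning genes are accounted for.  These
quantities drive the knowledge-matrix screen (phase 1) and the
false-positive pruning (phase 3) of the inference pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionDataset

__all__ = [
    "DiscretizedMatrix",
    "KnowledgeMatrix",
    "discretize",
    "discretize_matrix",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "build_knowledge_matrix",
    "default_n_bins",
]


@dataclass
class DiscretizedMatrix:
    """Per-gene binned expression: an ``(N, G)`` integer matrix of bin indices."""

    values: np.ndarray
    n_bins: int

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]


@dataclass
class KnowledgeMatrix:
    """Symmetric MI screen over gene pairs.

    ``mi[i, j]`` is the pairwise mutual information in bits; ``mask[i, j]``
    is 1 when that MI reaches the resolved threshold.  Both matrices are
    symmetric with a zero diagonal.
    """

    mask: np.ndarray
    mi: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask) != 0):
            raise ValueError("mask diagonal must be zero")


def default_n_bins(n_samples: int) -> int:
    """Plug-in bin count for the discrete entropy estimator: max(2, ⌊√N/2⌋)."""
    return max(2, int(np.sqrt(n_samples) // 2))


def _discretize_column(col: np.ndarray, n_bins: int, scheme: str) -> np.ndarray:
    if np.ptp(col) == 0:
        return np.zeros(len(col), dtype=int)
    if scheme == "equal_frequency":
        edges = np.quantile(col, np.arange(1, n_bins) / n_bins)
        bins = np.searchsorted(edges, col, side="right")
    elif scheme == "equal_width":
        edges = np.linspace(col.min(), col.max(), n_bins + 1)[1:-1]
        bins = np.searchsorted(edges, col, side="right")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # heavy ties can leave empty bins; compact to consecutive indices
    _, bins = np.unique(bins, return_inverse=True)
    return bins.astype(int)


def discretize_matrix(data: np.ndarray, n_bins: int, scheme: str = "equal_frequency") -> DiscretizedMatrix:
    data = np.asarray(data, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if data.shape[0] < n_bins:
        raise ValueError("need at least n_bins samples")
    cols = [_discretize_column(data[:, j], n_bins, scheme) for j in range(data.shape[1])]
    return DiscretizedMatrix(values=np.column_stack(cols), n_bins=n_bins)


def discretize(dataset: ExpressionDataset, n_bins: int | None = None,
               scheme: str = "equal_frequency") -> DiscretizedMatrix:
    """Bin each gene's pooled expression independently.

    Replicate series are concatenated row-wise first: the MI screen treats
    samples as exchangeable draws from the joint expression distribution.
    """
    pooled = dataset.pooled()
    if n_bins is None:
        n_bins = default_n_bins(pooled.shape[0])
    return discretize_matrix(pooled, n_bins, scheme)


def entropy(joint_counts: np.ndarray) -> float:
    """Shannon entropy in bits of a contingency table over 1-3 variables.

    H = −Σ p log2 p over nonzero cells, with p the normalized counts.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("contingency table is all zero")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _contingency(*columns: np.ndarray) -> np.ndarray:
    cols = [np.asarray(c).ravel() for c in columns]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("columns must have equal length")
    shape = tuple(int(c.max()) + 1 for c in cols)
    table = np.zeros(shape, dtype=float)
    np.add.at(table, tuple(cols), 1.0)
    return table


def _encode_joint(z) -> np.ndarray:
    """Collapse one or two conditioning columns into a single discrete variable."""
    z = np.asarray(z)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] not in (1, 2):
        raise ValueError("conditioning set must contain 1 or 2 columns")
    _, codes = np.unique(z, axis=0, return_inverse=True)
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI(X;Y) in bits via the entropy identity H(X)+H(Y)−H(X,Y)."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError("columns must have equal length")
    joint = _contingency(x, y)
    hx = entropy(joint.sum(axis=1))
    hy = entropy(joint.sum(axis=0))
    hxy = entropy(joint)
    return max(0.0, hx + hy - hxy)


def conditional_mutual_information(x: np.ndarray, y: np.ndarray, z) -> float:
    """CMI(X;Y|Z) in bits; Z is one column or a pair treated jointly.

    Computed from the empirical joint distribution via the entropy identity
    H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z).
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    zc = _encode_joint(z)
    if not (len(x) == len(y) == len(zc)):
        raise ValueError("columns must have equal length")
    joint = _contingency(x, y, zc)
    hxz = entropy(joint.sum(axis=1))
    hyz = entropy(joint.sum(axis=0))
    hz = entropy(joint.sum(axis=(0, 1)))
    hxyz = entropy(joint)
    return max(0.0, hxz + hyz - hxyz - hz)


def pairwise_mi_matrix(disc: DiscretizedMatrix) -> np.ndarray:
    g = disc.values.shape[1]
    mi = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            mi[i, j] = mi[j, i] = mutual_information(disc.column(i), disc.column(j))
    return mi


def build_knowledge_matrix(dataset: ExpressionDataset, n_bins: int | None = None,
                           threshold_mode: str = "quantile",
                           threshold_value: float = 0.7,
                           scheme: str = "equal_frequency") -> KnowledgeMatrix:
    """Phase-1 screen: pairwise MI thresholded into a binary knowledge mask.

    A cell (i, j) of the mask is 1 when MI(i, j) reaches the threshold and 0
    otherwise; only masked pairs can later contribute candidate regulators.
    ``quantile`` mode resolves the threshold as a quantile of the
    off-diagonal MI values (scale-free); ``absolute`` uses the value in bits.
    """
    if dataset.n_genes < 2:
        raise ValueError("need at least 2 genes")
    disc = discretize(dataset, n_bins=n_bins, scheme=scheme)
    mi = pairwise_mi_matrix(disc)
    g = mi.shape[0]
    off_diag = mi[~np.eye(g, dtype=bool)]
    if threshold_mode == "quantile":
        if not 0 <= threshold_value < 1:
            raise ValueError("quantile must be in [0, 1)")
        threshold = float(np.quantile(off_diag, threshold_value))
    elif threshold_mode == "absolute":
        threshold = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    mask = (mi >= threshold).astype(int)
    np.fill_diagonal(mask, 0)
    return KnowledgeMatrix(mask=mask, mi=mi, threshold=threshold)
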