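"""DREAM-style evaluation of ranked edge predictions.

A ranking of all ordered gene pairs is scored against a gold standard by
AUROC and AUPR; empirical p-values come from Monte-Carlo shuffles of the
ranking; per-network and overall challenge scores combine the p-values as

    score(net)  = −0.5 · log10(p_aupr · p_auroc)
    p̄           = (p₁ · … · p_n)^(1/n)            (geometric mean)
    Overall     = −0.5 · log10(p̄_aupr · p̄_auroc)
    Total       = Σ score(net) = n · Overall
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io_formats import GoldStandard

__all__ = [
    "DreamScore",
    "ranking_arrays",
    "roc_curve_auc",
    "pr_curve_aupr",
    "empirical_pvalue",
    "dream_scores",
]


@dataclass
class NetworkScore:
    aupr: float
    auroc: float
    p_aupr: float
    p_auroc: float
    net_score: float


@dataclass
class DreamScore:
    """Challenge score across a set of networks."""

    per_network: list[NetworkScore]
    overall_p_aupr: float
    overall_p_auroc: float
    overall: float
    total: float


def ranking_arrays(ranking: list[tuple[str, str, float]], gold: GoldStandard,
                   gene_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Align a (regulator, target, score) ranking with gold labels.

    Self-pairs are excluded; pairs absent from the gold edge set are
    negatives.  Returns (labels, scores) over the ranked pairs.
    """
    index = {name: k for k, name in enumerate(gene_names)}
    labels, scores = [], []
    for reg, tgt, score in ranking:
        i, j = index[reg], index[tgt]
        if i == j:
            continue
        labels.append(1 if (i, j) in gold.edges else 0)
        scores.append(score)
    return np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)


def roc_curve_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by trapezoidal integration; ties averaged (Mann–Whitney)."""
    labels = np.asarray(labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def pr_curve_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUPR by step-wise summation Σ (R_k − R_{k−1}) P_k, ties grouped."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("need at least one positive")
    return float(average_precision_score(labels, scores))


def empirical_pvalue(observed: float, statistic: str, labels: np.ndarray,
                     n_permutations: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo p-value of a ranking statistic under random orderings.

    p = (1 + #{shuffled rankings with statistic ≥ observed}) / (B + 1),
    the add-one convention, so p is never exactly zero and saturates at
    1/(B+1) — far above the analytic p-values challenge organizers report.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    stat = {"aupr": pr_curve_aupr, "auroc": roc_curve_auc}[statistic]
    rng = np.random.default_rng(seed)
    n = len(labels)
    hits = 0
    for _ in range(n_permutations):
        null = stat(labels, rng.permutation(n).astype(float))
        if null >= observed:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def dream_scores(pvalues: list[tuple[float, float]]) -> DreamScore:
    """Combine per-network (p_aupr, p_auroc) pairs into challenge scores.

    Per-network score is −0.5·log10(p_aupr·p_auroc); the overall score uses
    the geometric means of the two p-value families; the total is the sum
    of per-network scores and equals n times the overall score.
    """
    if not pvalues:
        raise ValueError("need at least one network")
    per_network = []
    for p_aupr, p_auroc in pvalues:
        if not (0 < p_aupr <= 1 and 0 < p_auroc <= 1):
            raise ValueError("p-values must lie in (0, 1]")
        net_score = -0.5 * np.log10(p_aupr * p_auroc)
        per_network.append(
            NetworkScore(aupr=np.nan, auroc=np.nan, p_aupr=p_aupr,
                         p_auroc=p_auroc, net_score=float(net_score))
        )
    log_pa = np.log10([p for p, _ in pvalues])
    log_pr = np.log10([p for _, p in pvalues])
    p_bar_aupr = float(10 ** log_pa.mean())
    p_bar_auroc = float(10 ** log_pr.mean())
    overall = float(-0.5 * (log_pa.mean() + log_pr.mean()))
    total = float(sum(s.net_score for s in per_network))
    return DreamScore(per_network=per_network, overall_p_aupr=p_bar_aupr,
                      overall_p_auroc=p_bar_auroc, overall=overall, total=total)
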