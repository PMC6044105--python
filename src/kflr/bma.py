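"""Phase 2: Bayesian model averaging over regression parent sets.

For each target gene, candidate regulators are the genes within a small
shortest-path distance of the target in the knowledge graph (the local
neighbourhood containing the Markov blanket).  Every parent set drawn from
the candidates (up to a size and count cap) defines one linear regression
model; its evidence comes from the Kalman recursion, and the posterior
probability of an edge j→i is the summed posterior mass of all models for
target i whose parent set contains j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .infotheory import KnowledgeMatrix
from .io_formats import ExpressionDataset
from .kalman import KalmanBelief, kf_filter_regression

__all__ = [
    "CandidateSet",
    "ModelScore",
    "candidate_regulators",
    "enumerate_parent_sets",
    "build_regression_samples",
    "score_target",
    "edge_posteriors",
]


@dataclass
class CandidateSet:
    """Candidate regulators for one target gene."""

    target: int
    candidates: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target in self.candidates:
            raise ValueError("target cannot be its own candidate")


@dataclass
class ModelScore:
    """One parent-set regression model with its evidence and posterior."""

    parents: frozenset[int]
    log_evidence: float
    posterior: float = 0.0


def candidate_regulators(knowledge: KnowledgeMatrix, target: int,
                         k_hops: int = 2, max_candidates: int = 10) -> CandidateSet:
    """Genes within ``k_hops`` of the target in the knowledge graph.

    When the neighbourhood exceeds ``max_candidates``, the genes with the
    highest MI to the target are kept.  An isolated target yields an empty
    candidate set (it receives no incoming edges).
    """
    mask = knowledge.mask
    graph = nx.from_numpy_array(mask)
    lengths = nx.single_source_shortest_path_length(graph, target, cutoff=k_hops)
    cands = sorted(g for g in lengths if g != target)
    if len(cands) > max_candidates:
        mi_to_target = knowledge.mi[target]
        cands = sorted(
            sorted(cands, key=lambda g: (-mi_to_target[g], g))[:max_candidates]
        )
    return CandidateSet(target=target, candidates=cands)


def enumerate_parent_sets(candidates: CandidateSet, max_parents: int = 3,
                          max_models: int = 100,
                          rank: list[int] | None = None) -> list[frozenset[int]]:
    """All parent sets of size ≤ ``max_parents``, capped at ``max_models``.

    The empty set is always included.  When the full count exceeds the cap,
    candidates are taken in ``rank`` order (best singles first, as supplied
    by the caller) and subsets are enumerated by (size, ranked positions),
    so the best-ranked regulators populate the retained sets.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be nonnegative")
    order = list(rank) if rank is not None else list(candidates.candidates)
    if set(order) != set(candidates.candidates):
        raise ValueError("rank must be a permutation of the candidates")
    sets: list[frozenset[int]] = [frozenset()]
    for size in range(1, max_parents + 1):
        for combo in combinations(range(len(order)), size):
            sets.append(frozenset(order[k] for k in combo))
            if len(sets) >= max_models:
                return sets[:max_models]
    return sets


def _standardize_series(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mean) / sd


def build_regression_samples(dataset: ExpressionDataset, target: int,
                             parents, lag: int = 1,
                             standardize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack regression pairs (y = x_target(t+lag), H = [x_parents(t), 1]).

    Pairs are formed within each replicate series independently and never
    span a series boundary; series shorter than lag+1 are skipped.  Genes
    are standardized per series so the unit-scale priors are appropriate.
    """
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    parents = sorted(parents)
    ys, hs = [], []
    for mat in dataset.series:
        if mat.shape[0] <= lag:
            import warnings

            warnings.warn(f"series of length {mat.shape[0]} skipped (lag={lag})")
            continue
        x = _standardize_series(mat) if standardize else mat
        t_max = x.shape[0] - lag
        y = x[lag:, target]
        h = np.column_stack([x[:t_max, parents], np.ones(t_max)]) if parents else np.ones((t_max, 1))
        ys.append(y)
        hs.append(h)
    if not ys:
        return np.empty(0), np.empty((0, len(parents) + 1))
    return np.concatenate(ys), np.vstack(hs)


def score_target(dataset: ExpressionDataset, candidates: CandidateSet,
                 max_parents: int = 3, max_models: int = 100, lag: int = 1,
                 prior_tau: float = 1.0, process_q: float = 0.0,
                 obs_r: float = 1.0, standardize: bool = True,
                 parent_prior: str = "uniform",
                 prior_gamma: float = 0.5) -> list[ModelScore]:
    """Score every enumerated parent-set model for one target gene.

    Each model's log evidence is the Kalman-filter marginal likelihood of
    its regression; posteriors are exp(evidence + log prior) normalized via
    log-sum-exp.  The default parent-set prior is uniform over the
    enumerated sets; ``geometric`` applies a per-parent penalty factor
    ``prior_gamma``.
    """

    def evidence(parents: frozenset[int]) -> float:
        y, H = build_regression_samples(dataset, candidates.target, parents,
                                        lag=lag, standardize=standardize)
        prior = KalmanBelief.isotropic(H.shape[1], tau=prior_tau)
        if len(y) == 0:
            return -np.inf
        _, log_ml = kf_filter_regression(y, H, prior, q=process_q, r=obs_r)
        return log_ml

    rank = None
    n_full = sum(
        _n_subsets(len(candidates.candidates), k) for k in range(0, max_parents + 1)
    )
    if n_full > max_models and candidates.candidates:
        single_ev = {g: evidence(frozenset([g])) for g in candidates.candidates}
        rank = sorted(candidates.candidates, key=lambda g: (-single_ev[g], g))
    parent_sets = enumerate_parent_sets(candidates, max_parents=max_parents,
                                        max_models=max_models, rank=rank)

    scores = [ModelScore(parents=ps, log_evidence=evidence(ps)) for ps in parent_sets]
    log_post = np.array([s.log_evidence for s in scores], dtype=float)
    if parent_prior == "geometric":
        log_post = log_post + np.array([len(s.parents) * np.log(prior_gamma) for s in scores])
    elif parent_prior != "uniform":
        raise ValueError(f"unknown parent_prior {parent_prior!r}")
    if np.all(np.isneginf(log_post)):
        raise ValueError("all model evidences are -inf (degenerate data)")
    log_post = log_post - logsumexp(log_post)
    post = np.exp(log_post)
    for s, p in zip(scores, post):
        s.posterior = float(p)
    return scores


def _n_subsets(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def edge_posteriors(model_scores: dict[int, list[ModelScore]], n_genes: int) -> np.ndarray:
    """Aggregate per-target model posteriors into an edge-score matrix.

    Entry (j, i) is the posterior probability of the directed edge j→i:
    the summed posterior of target i's models whose parent set contains j.
    """
    scores = np.zeros((n_genes, n_genes))
    for target, models in model_scores.items():
        for m in models:
            for parent in m.parents:
                scores[parent, target] += m.posterior
    return np.clip(scores, 0.0, 1.0)
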