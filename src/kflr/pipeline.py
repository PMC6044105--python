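"""Three-phase network inference pipeline.

Phase 1 screens gene pairs by mutual information into a knowledge matrix;
phase 2 scores directed edges by Kalman-filter Bayesian model averaging
over regression parent sets drawn from each target's knowledge-graph
neighbourhood; phase 3 prunes edges whose conditional mutual information
given shared neighbours shows no residual dependence.  The pipeline is a
pure function of (dataset, config).
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import bma, infotheory, refine
from .io_formats import ExpressionDataset

__all__ = ["KflrConfig", "run_kflr"]


@dataclass
class KflrConfig:
    """Every free parameter of the three phases, with defaults.

    Phase 1: ``n_bins`` (None → max(2, ⌊√N/2⌋)), ``threshold_mode``
    ('quantile' or 'absolute') and ``threshold_value``.
    Phase 2: neighbourhood radius ``k_hops``, caps ``max_candidates`` /
    ``max_parents`` / ``max_models``, regression ``lag``, prior scale
    ``prior_tau``, process-noise scale ``process_q``, observation noise
    ``obs_r``, and the parent-set prior.
    Phase 3: CMI threshold ``alpha`` in bits, conditioning order
    ``max_order``, and the skeleton quantile ``score_quantile``.
    """

    # phase 1
    n_bins: int | None = None
    threshold_mode: str = "quantile"
    threshold_value: float = 0.7
    # phase 2
    k_hops: int = 2
    max_candidates: int = 10
    max_parents: int = 3
    max_models: int = 100
    lag: int = 1
    prior_tau: float = 1.0
    process_q: float = 0.0
    obs_r: float = 1.0
    parent_prior: str = "uniform"
    standardize: bool = True
    # phase 3
    prune: bool = True
    alpha: float = 0.05
    max_order: int = 2
    score_quantile: float = 0.7
    seed: int = 0

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}" for f in fields(self)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "KflrConfig":
        kwargs = {}
        casts = {f.name: f for f in fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _parse_value(value)
        return cls(**kwargs)


def _parse_value(text: str):
    if text in {"None", ""}:
        return None
    if text in {"True", "False"}:
        return text == "True"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def run_kflr(dataset: ExpressionDataset, config: KflrConfig | None = None
             ) -> tuple[np.ndarray, dict]:
    """Run all three phases and return (edge score matrix, run report).

    The report records the resolved thresholds, per-phase edge counts and
    wall-clock timings, and the config used.
    """
    config = config or KflrConfig()
    dataset.validate()
    g = dataset.n_genes
    report: dict = {"config": asdict(config), "n_genes": g,
                    "n_series": dataset.n_series,
                    "n_samples": int(dataset.pooled().shape[0])}

    t0 = time.perf_counter()
    knowledge = infotheory.build_knowledge_matrix(
        dataset, n_bins=config.n_bins, threshold_mode=config.threshold_mode,
        threshold_value=config.threshold_value)
    report["phase1"] = {
        "mi_threshold_bits": knowledge.threshold,
        "n_pairs_kept": int(knowledge.mask.sum() // 2),
        "seconds": time.perf_counter() - t0,
    }

    t0 = time.perf_counter()
    per_target: dict[int, list[bma.ModelScore]] = {}
    for target in range(g):
        cands = bma.candidate_regulators(knowledge, target,
                                         k_hops=config.k_hops,
                                         max_candidates=config.max_candidates)
        per_target[target] = bma.score_target(
            dataset, cands, max_parents=config.max_parents,
            max_models=config.max_models, lag=config.lag,
            prior_tau=config.prior_tau, process_q=config.process_q,
            obs_r=config.obs_r, standardize=config.standardize,
            parent_prior=config.parent_prior)
    scores = bma.edge_posteriors(per_target, g)
    report["phase2"] = {
        "n_nonzero_edges": int(np.count_nonzero(scores)),
        "seconds": time.perf_counter() - t0,
    }

    if config.prune:
        t0 = time.perf_counter()
        disc = infotheory.discretize(dataset, n_bins=config.n_bins)
        nonzero = scores[scores > 0]
        score_threshold = (
            float(np.quantile(nonzero, config.score_quantile)) if nonzero.size else 0.0
        )
        scores = refine.prune_with_cmi(scores, disc, alpha=config.alpha,
                                       max_order=config.max_order,
                                       score_threshold=score_threshold)
        report["phase3"] = {
            "score_threshold": score_threshold,
            "alpha_bits": config.alpha,
            "n_nonzero_edges": int(np.count_nonzero(scores)),
            "seconds": time.perf_counter() - t0,
        }
    return scores, report
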