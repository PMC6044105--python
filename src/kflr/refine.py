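"""Phase 3: conditional-mutual-information pruning of false-positive edges.

MI and the model average can both retain indirect links (i and j coupled
only through a shared regulator k).  For every retained gene pair the CMI of
the pair given single conditioning genes — and, if needed, pairs of them —
drawn from the shared neighbourhood is examined; when no conditioning set
shows residual dependence of at least ``alpha`` bits, the edge is judged
indirect and both directions are zeroed.  Pruning only ever removes edges.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .infotheory import DiscretizedMatrix, conditional_mutual_information

__all__ = ["prune_with_cmi"]


def prune_with_cmi(scores: np.ndarray, disc: DiscretizedMatrix, alpha: float = 0.05,
                   max_order: int = 2, score_threshold: float = 0.0) -> np.ndarray:
    """Remove edges whose best conditional MI falls below ``alpha`` bits.

    The retained skeleton is the undirected graph of pairs with
    ``max(score(i→j), score(j→i)) ≥ score_threshold``.  For each skeleton
    pair, conditioning genes come from the shared skeleton neighbourhood of
    the two endpoints; the maximum CMI over single conditioners (and, when
    that falls short and ``max_order`` is 2, over conditioner pairs) decides
    removal.  Pairs with no eligible conditioner are kept.  Both directions
    of a removed pair are zeroed; no score is ever raised.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    scores = np.asarray(scores, dtype=float)
    g = scores.shape[0]
    out = scores.copy()

    adj = (np.maximum(scores, scores.T) >= score_threshold) & ~np.eye(g, dtype=bool)
    # only pairs actually present (some score > 0) are candidates for removal
    present = (np.maximum(scores, scores.T) > 0) & adj
    neighbours = [set(np.flatnonzero(adj[i])) for i in range(g)]

    for i in range(g):
        for j in range(i + 1, g):
            if not present[i, j]:
                continue
            shared = sorted((neighbours[i] & neighbours[j]) - {i, j})
            if not shared:
                continue
            xi, xj = disc.column(i), disc.column(j)
            best = max(
                conditional_mutual_information(xi, xj, disc.column(k)) for k in shared
            )
            if best < alpha and max_order == 2 and len(shared) >= 2:
                best = max(
                    best,
                    max(
                        conditional_mutual_information(
                            xi, xj, disc.values[:, [k, l]]
                        )
                        for k, l in combinations(shared, 2)
                    ),
                )
            if best < alpha:
                out[i, j] = 0.0
                out[j, i] = 0.0
    return out
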