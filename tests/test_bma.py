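from itertools import chain, combinations

import numpy as np
import pytest

from kflr.bma import (
    CandidateSet,
    build_regression_samples,
    candidate_regulators,
    edge_posteriors,
    enumerate_parent_sets,
    score_target,
)
from kflr.infotheory import KnowledgeMatrix
from kflr.io_formats import ExpressionDataset
from kflr.kalman import KalmanBelief, batch_regression_posterior
from kflr.simulate import SimulationConfig, SyntheticNetwork, simulate_timeseries


def _knowledge(mask, mi=None):
    mask = np.asarray(mask)
    return KnowledgeMatrix(mask=mask, mi=mi if mi is not None else mask.astype(float),
                           threshold=0.5)


class TestCandidateRegulators:
    def test_complete_graph_all_others(self):
        mask = 1 - np.eye(4, dtype=int)
        cs = candidate_regulators(_knowledge(mask), target=2, k_hops=2)
        assert cs.candidates == [0, 1, 3]

    def test_path_graph_two_hops(self):
        # path A-B-C-D: from A, B is 1 hop and C is 2; D is 3 hops away
        mask = np.zeros((4, 4), dtype=int)
        for a, b in [(0, 1), (1, 2), (2, 3)]:
            mask[a, b] = mask[b, a] = 1
        cs = candidate_regulators(_knowledge(mask), target=0, k_hops=2)
        assert cs.candidates == [1, 2]

    def test_isolated_target_empty(self):
        cs = candidate_regulators(_knowledge(np.zeros((3, 3), dtype=int)), target=1)
        assert cs.candidates == []

    def test_cap_keeps_highest_mi(self):
        mask = 1 - np.eye(5, dtype=int)
        mi = np.zeros((5, 5))
        mi[0] = mi[:, 0] = [0, 0.9, 0.1, 0.5, 0.7]
        cs = candidate_regulators(_knowledge(mask, mi), target=0, max_candidates=2)
        assert cs.candidates == [1, 4]


class TestEnumerateParentSets:
    def test_full_enumeration_counts(self):
        cs = CandidateSet(target=0, candidates=[1, 2, 3])
        sets = enumerate_parent_sets(cs, max_parents=2, max_models=1000)
        assert len(sets) == 7
        assert frozenset() in sets

    def test_no_candidates_empty_set_only(self):
        sets = enumerate_parent_sets(CandidateSet(target=0, candidates=[]))
        assert sets == [frozenset()]

    def test_cap_returns_exactly_max_models(self):
        cs = CandidateSet(target=0, candidates=list(range(1, 11)))
        sets = enumerate_parent_sets(cs, max_parents=3, max_models=100)
        assert len(sets) == 100
        assert frozenset() in sets
        assert len(set(sets)) == 100

    def test_rank_order_prioritizes_top_singles(self):
        cs = CandidateSet(target=0, candidates=[1, 2, 3])
        sets = enumerate_parent_sets(cs, max_parents=1, max_models=3, rank=[3, 1, 2])
        assert sets == [frozenset(), frozenset([3]), frozenset([1])]


class TestBuildRegressionSamples:
    def _dataset(self, n_series=5, t=21, g=3, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionDataset(
            [f"G{k}" for k in range(g)],
            [rng.standard_normal((t, g)) for _ in range(n_series)],
            [np.arange(float(t)) for _ in range(n_series)],
        )

    def test_lag1_sample_count(self):
        y, H = build_regression_samples(self._dataset(), target=0, parents=[1], lag=1)
        assert len(y) == 5 * 20
        assert H.shape == (100, 2)

    def test_lag0_contemporaneous_count(self):
        y, H = build_regression_samples(self._dataset(), target=0, parents=[1, 2], lag=0)
        assert len(y) == 5 * 21

    def test_empty_parents_intercept_only(self):
        _, H = build_regression_samples(self._dataset(), target=0, parents=[], lag=1)
        assert H.shape[1] == 1
        assert np.all(H == 1.0)

    def test_never_spans_series_boundary(self):
        # two series with a jump between them: the pair across the boundary must not appear
        ds = ExpressionDataset(
            ["A", "B"],
            [np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([[100.0, 100.0], [101.0, 101.0]])],
            [np.arange(2.0), np.arange(2.0)],
        )
        y, H = build_regression_samples(ds, target=0, parents=[1], lag=1, standardize=False)
        assert len(y) == 2
        assert set(zip(H[:, 0], y)) == {(0.0, 1.0), (100.0, 101.0)}


def _brute_force_posteriors(dataset, target, candidates, lag=1, tau=1.0, r=1.0):
    """Independent oracle: joint-Gaussian evidence per parent set, then normalize."""
    sets = [frozenset(c) for k in range(len(candidates) + 1)
            for c in combinations(candidates, k)]
    evidences = {}
    for ps in sets:
        y, H = build_regression_samples(dataset, target, ps, lag=lag)
        prior = KalmanBelief.isotropic(H.shape[1], tau=tau)
        _, log_ev = batch_regression_posterior(y, H, prior, r=r)
        evidences[ps] = log_ev
    m = max(evidences.values())
    z = sum(np.exp(v - m) for v in evidences.values())
    posts = {ps: np.exp(v - m) / z for ps, v in evidences.items()}
    edge = {}
    for j in candidates:
        edge[j] = sum(p for ps, p in posts.items() if j in ps)
    return posts, edge


class TestScoreTarget:
    def _sim(self, seed=0):
        cfg = SimulationConfig(n_genes=4, n_series=3, n_timepoints=15, edge_prob=0.4,
                               process_noise_sd=0.3, seed=seed)
        W = np.zeros((4, 4))
        W[1, 0], W[2, 0], W[3, 2] = 0.8, -0.6, 0.7
        net = SyntheticNetwork(adjacency=W)
        return simulate_timeseries(net, cfg)

    def test_single_model_posterior_one(self):
        ds = self._sim()
        scores = score_target(ds, CandidateSet(target=0, candidates=[]), max_parents=0)
        assert len(scores) == 1
        assert scores[0].posterior == pytest.approx(1.0)

    def test_posteriors_normalized(self):
        ds = self._sim()
        scores = score_target(ds, CandidateSet(target=0, candidates=[1, 2, 3]))
        assert sum(s.posterior for s in scores) == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        """Kalman-scored BMA equals direct joint-Gaussian evidence normalization."""
        ds = self._sim(seed=3)
        target, cands = 0, [1, 2, 3]
        scores = score_target(ds, CandidateSet(target=target, candidates=cands),
                              max_parents=3, max_models=1000)
        posts_oracle, edge_oracle = _brute_force_posteriors(ds, target, cands)
        got = {s.parents: s.posterior for s in scores}
        assert set(got) == set(posts_oracle)
        for ps in got:
            assert got[ps] == pytest.approx(posts_oracle[ps], abs=1e-8)


class TestEdgePosteriors:
    def test_single_edge_sum(self):
        from kflr.bma import ModelScore

        models = {1: [ModelScore(frozenset(), 0.0, 0.3), ModelScore(frozenset([0]), 0.0, 0.7)]}
        scores = edge_posteriors(models, 2)
        assert scores[0, 1] == pytest.approx(0.7)
        assert scores[1, 0] == 0.0

    def test_two_model_sum(self):
        from kflr.bma import ModelScore

        models = {2: [
            ModelScore(frozenset(), 0.0, 0.25),
            ModelScore(frozenset([0]), 0.0, 0.25),
            ModelScore(frozenset([1]), 0.0, 0.25),
            ModelScore(frozenset([0, 1]), 0.0, 0.25),
        ]}
        scores = edge_posteriors(models, 3)
        assert scores[0, 2] == pytest.approx(0.5)
        assert scores[1, 2] == pytest.approx(0.5)

    def test_random_posteriors_match_indicator_sum(self):
        from kflr.bma import ModelScore

        rng = np.random.default_rng(0)
        cands = [0, 1, 2]
        sets = [frozenset(c) for k in range(4) for c in combinations(cands, k)]
        w = rng.random(len(sets))
        w /= w.sum()
        models = {3: [ModelScore(ps, 0.0, p) for ps, p in zip(sets, w)]}
        scores = edge_posteriors(models, 4)
        for j in cands:
            expected = sum(p for ps, p in zip(sets, w) if j in ps)
            assert scores[j, 3] == pytest.approx(expected, abs=1e-12)


def test_true_parent_dominates_on_noiseless_single_parent_systems():
    """With exact single-parent linear dynamics the true edge posterior wins (20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        W = np.zeros((3, 3))
        W[0, 1] = 0.9  # gene 0 drives gene 1
        net = SyntheticNetwork(adjacency=W)
        cfg = SimulationConfig(n_genes=3, n_series=3, n_timepoints=15,
                               process_noise_sd=0.05, seed=seed)
        ds = simulate_timeseries(net, cfg)
        scores = score_target(ds, CandidateSet(target=1, candidates=[0, 2]),
                              max_parents=2, max_models=1000)
        mat = edge_posteriors({1: scores}, 3)
        assert mat[0, 1] > mat[2, 1]
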