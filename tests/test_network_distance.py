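import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metclust.network_distance import (
    DistanceMatrix,
    TransitionMatrix,
    js_distance,
    js_divergence,
    m2_distance,
    node_distributions,
    pairwise_distances,
    transition_matrix,
)
from metclust.summarization import NodePartition, SummarizedGraph

from conftest import random_symmetric_weights


def js_oracle(p, q):
    """Brute-force base-2 Jensen-Shannon divergence: elementwise summation
    with the 0*log0 = 0 convention, independent of the vectorized path."""
    m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
    total = 0.0
    for x, mix in ((p, m), (q, m)):
        for xi, mi in zip(x, mix):
            if xi > 0:
                total += 0.5 * xi * math.log2(xi / mi)
    return total


def make_summary(W_s, sample_id="s", partition=None):
    k = W_s.shape[0]
    if partition is None:
        partition = NodePartition(
            k=k, labels=np.arange(k), node_order=tuple(f"n{i}" for i in range(k))
        )
    return SummarizedGraph(sample_id=sample_id, k=k, W_s=W_s, partition=partition)


def random_summary(rng, k, partition=None, sample_id="s"):
    W = random_symmetric_weights(rng, k)
    return make_summary(W, sample_id=sample_id, partition=partition)


class TestTransitionMatrix:
    def test_two_node_exchange(self):
        T = transition_matrix(make_summary(np.array([[0.0, 1.0], [1.0, 0.0]])))
        np.testing.assert_array_equal(T.T, [[0.0, 1.0], [1.0, 0.0]])

    def test_columns_rescaled_by_strength(self):
        """Strengths (2, 4) counting the diagonal once -> columns (0,1) and
        (1/2, 1/2)."""
        T = transition_matrix(make_summary(np.array([[0.0, 2.0], [2.0, 2.0]])))
        np.testing.assert_allclose(T.T, [[0.0, 0.5], [1.0, 0.5]])
        np.testing.assert_allclose(T.T.sum(axis=0), [1.0, 1.0])

    def test_isolated_supernode_is_absorbing(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        T = transition_matrix(make_summary(W))
        assert T.T[2, 2] == 1.0
        np.testing.assert_allclose(T.T.sum(axis=0), np.ones(3))

    def test_negative_weight_rejected(self):
        sg = make_summary(np.array([[0.0, 1.0], [1.0, 0.0]]))
        sg.W_s[0, 1] = sg.W_s[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            transition_matrix(sg)

    def test_column_stochastic_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionMatrix(sample_id="s", k=2, T=np.array([[0.5, 0.2], [0.4, 0.8]]))


class TestJensenShannon:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_distance(p, p) == 0.0

    def test_disjoint_support_is_one(self):
        assert js_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_half_half_vs_point_mass(self):
        """J((1/2,1/2),(1,0)) = 0.311278... bits; d_JS = sqrt."""
        p = np.array([0.5, 0.5])
        q = np.array([1.0, 0.0])
        expected_j = js_oracle(p, q)
        assert expected_j == pytest.approx(0.3112781244591328, abs=1e-12)
        assert js_divergence(p, q) == pytest.approx(expected_j, abs=1e-12)
        assert js_distance(p, q) == pytest.approx(np.sqrt(expected_j), abs=1e-12)
        assert js_distance(p, q) == pytest.approx(0.557923, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            js_distance(np.array([1.0]), np.array([0.5, 0.5]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            js_distance(np.array([0.5, 0.4]), np.array([0.5, 0.5]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        p = rng.random(n)
        p /= p.sum()
        q = rng.random(n)
        q /= q.sum()
        assert js_divergence(p, q) == pytest.approx(js_oracle(p, q), abs=1e-12)
        assert 0.0 <= js_distance(p, q) <= 1.0


class TestM2:
    def test_identical_networks_distance_zero(self):
        rng = np.random.default_rng(0)
        sg = random_summary(rng, 5)
        assert m2_distance(transition_matrix(sg), transition_matrix(sg)) == 0.0

    def test_single_supernode_degenerate(self):
        a = make_summary(np.array([[2.0]]))
        b = make_summary(np.array([[5.0]]))
        assert m2_distance(transition_matrix(a), transition_matrix(b)) == 0.0

    def test_opposite_exchange_networks_distance_one(self):
        """k=2 with disjoint per-supernode supports gives (1/2)(1+1) = 1."""
        part = NodePartition(k=2, labels=np.array([0, 1]), node_order=("a", "b"))
        Tp = TransitionMatrix("p", 2, np.array([[0.0, 1.0], [1.0, 0.0]]), part)
        Tq = TransitionMatrix("q", 2, np.array([[1.0, 0.0], [0.0, 1.0]]), part)
        assert m2_distance(Tp, Tq) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_k_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="supernode counts"):
            m2_distance(
                transition_matrix(random_summary(rng, 3)),
                transition_matrix(random_summary(rng, 4)),
            )

    def test_mismatched_partition_rejected(self):
        rng = np.random.default_rng(2)
        p1 = NodePartition(k=2, labels=np.array([0, 1, 1]), node_order=("a", "b", "c"))
        p2 = NodePartition(k=2, labels=np.array([0, 0, 1]), node_order=("a", "b", "c"))
        with pytest.raises(ValueError, match="partitions"):
            m2_distance(
                transition_matrix(random_summary(rng, 2, partition=p1)),
                transition_matrix(random_summary(rng, 2, partition=p2)),
            )

    def test_scale_invariance(self):
        """Transition matrices ignore global expression scale, so scaling
        every weight matrix by one constant leaves all distances unchanged."""
        rng = np.random.default_rng(3)
        part = NodePartition(
            k=6, labels=np.arange(6), node_order=tuple(f"n{i}" for i in range(6))
        )
        summaries = [random_summary(rng, 6, partition=part, sample_id=f"S{i}") for i in range(4)]
        scaled = [
            make_summary(7.5 * sg.W_s, sample_id=sg.sample_id, partition=part)
            for sg in summaries
        ]
        np.testing.assert_allclose(
            pairwise_distances(summaries).D, pairwise_distances(scaled).D, atol=1e-12
        )


class TestPairwiseDistances:
    def test_identical_summaries_give_zero_matrix(self):
        rng = np.random.default_rng(4)
        part = NodePartition(
            k=4, labels=np.arange(4), node_order=tuple(f"n{i}" for i in range(4))
        )
        W = random_symmetric_weights(rng, 4)
        summaries = [make_summary(W.copy(), f"S{i}", part) for i in range(5)]
        D = pairwise_distances(summaries)
        np.testing.assert_array_equal(D.D, np.zeros((5, 5)))

    def test_two_samples_matches_direct_m2(self):
        rng = np.random.default_rng(5)
        part = NodePartition(
            k=5, labels=np.arange(5), node_order=tuple(f"n{i}" for i in range(5))
        )
        a = random_summary(rng, 5, partition=part, sample_id="A")
        b = random_summary(rng, 5, partition=part, sample_id="B")
        D = pairwise_distances([a, b])
        d = m2_distance(transition_matrix(a), transition_matrix(b))
        assert D.D[0, 1] == pytest.approx(d, abs=1e-12)
        assert D.D[1, 0] == D.D[0, 1] and D.D[0, 0] == 0.0

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(6)
        part = NodePartition(
            k=5, labels=np.arange(5), node_order=tuple(f"n{i}" for i in range(5))
        )
        for _ in range(20):
            summaries = [
                random_summary(rng, 5, partition=part, sample_id=f"S{i}") for i in range(3)
            ]
            D = pairwise_distances(summaries).D
            for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_round_trip_tsv(self, tmp_path):
        rng = np.random.default_rng(7)
        part = NodePartition(
            k=3, labels=np.arange(3), node_order=tuple(f"n{i}" for i in range(3))
        )
        summaries = [random_summary(rng, 3, partition=part, sample_id=f"S{i}") for i in range(4)]
        D = pairwise_distances(summaries)
        D.to_tsv(tmp_path / "D.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "D.tsv")
        assert back.sample_ids == D.sample_ids
        np.testing.assert_allclose(back.D, D.D, atol=1e-12)


def test_node_distributions_rows_are_stochastic():
    rng = np.random.default_rng(8)
    P = node_distributions(random_summary(rng, 7))
    np.testing.assert_allclose(P.sum(axis=1), np.ones(7), atol=1e-12)
    assert np.all(P >= 0)
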