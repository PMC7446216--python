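from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metclust.evaluation import (
    METRIC_ORDER,
    PairCounts,
    adjusted_rand,
    ami,
    cluster_accuracy,
    evaluate,
    expected_mutual_information,
    f_measure,
    fowlkes_mallows,
    misclassification_rate,
    mutual_information,
    nmi,
    pair_counts,
    rand_index,
)


def pair_counts_oracle(pred, truth):
    """O(n^2) enumeration over all unordered sample pairs."""
    tp = fp = fn = tn = 0
    for i, j in combinations(range(len(pred)), 2):
        sp = pred[i] == pred[j]
        st_ = truth[i] == truth[j]
        if sp and st_:
            tp += 1
        elif sp:
            fp += 1
        elif st_:
            fn += 1
        else:
            tn += 1
    return PairCounts(tp, fp, fn, tn)


labelings = st.lists(st.integers(0, 4), min_size=2, max_size=40)


class TestPairCounts:
    def test_perfect_agreement(self):
        pc = pair_counts([1, 1, 2, 2], [1, 1, 2, 2])
        assert (pc.TP, pc.FP, pc.FN, pc.TN) == (2, 0, 0, 4)

    def test_worked_six_sample_example(self):
        pc = pair_counts([1, 1, 2, 2, 2, 2], [1, 1, 1, 2, 2, 2])
        assert (pc.TP, pc.FP, pc.FN, pc.TN) == (4, 3, 2, 6)
        assert pc == pair_counts_oracle([1, 1, 2, 2, 2, 2], [1, 1, 1, 2, 2, 2])

    def test_singletons_vs_single_class(self):
        pc = pair_counts([1, 2, 3], [7, 7, 7])
        assert (pc.TP, pc.FP, pc.FN, pc.TN) == (0, 0, 3, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pair_counts([1, 2], [1, 2, 3])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, data):
        pred = data.draw(labelings)
        truth = data.draw(st.lists(st.integers(0, 4), min_size=len(pred), max_size=len(pred)))
        pc = pair_counts(pred, truth)
        assert pc == pair_counts_oracle(pred, truth)
        assert pc.total == len(pred) * (len(pred) - 1) // 2


class TestPairCountingMetrics:
    def test_worked_values(self):
        pc = PairCounts(TP=4, FP=3, FN=2, TN=6)
        assert rand_index(pc) == pytest.approx(10 / 15)
        assert misclassification_rate(pc) == pytest.approx(5 / 15)
        assert f_measure(pc) == pytest.approx(2 * (4 / 7) * (4 / 6) / (4 / 7 + 4 / 6))
        assert fowlkes_mallows(pc) == pytest.approx(4 / np.sqrt(42))

    def test_perfect_agreement_extremes(self):
        pc = PairCounts(TP=6, FP=0, FN=0, TN=9)
        assert rand_index(pc) == 1.0
        assert misclassification_rate(pc) == 0.0
        assert f_measure(pc) == 1.0
        assert fowlkes_mallows(pc) == 1.0

    def test_zero_tp_conventions(self):
        pc = PairCounts(TP=0, FP=3, FN=2, TN=5)
        assert f_measure(pc) == 0.0
        assert fowlkes_mallows(pc) == 0.0

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_mr_is_one_minus_ri(self, data):
        pred = data.draw(labelings)
        truth = data.draw(st.lists(st.integers(0, 4), min_size=len(pred), max_size=len(pred)))
        pc = pair_counts(pred, truth)
        assert misclassification_rate(pc) == pytest.approx(1.0 - rand_index(pc), abs=1e-12)


class TestAdjustedRand:
    def test_identical_labelings(self):
        assert adjusted_rand([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == pytest.approx(1.0)

    def test_closed_form_matches_exhaustive_permutation_expectation(self):
        """On n=6 the hypergeometric E[sum C(n_ij,2)] equals the average
        over all 720 label-vector permutations."""
        truth = [1, 1, 1, 2, 2, 2]
        pred = [1, 1, 2, 2, 2, 2]
        from metclust.evaluation import contingency_table, _comb2

        sum_ij = lambda p, t: float(_comb2(contingency_table(p, t)).sum())
        exhaustive = np.mean([sum_ij(perm, truth) for perm in permutations(pred)])
        table = contingency_table(pred, truth)
        a = float(_comb2(table.sum(axis=1)).sum())
        b = float(_comb2(table.sum(axis=0)).sum())
        expected = a * b / float(_comb2(6))
        assert exhaustive == pytest.approx(expected, abs=1e-12)
        observed = sum_ij(pred, truth)
        ari_oracle = (observed - expected) / ((a + b) / 2 - expected)
        assert adjusted_rand(pred, truth) == pytest.approx(ari_oracle, abs=1e-12)

    def test_monte_carlo_null_mean_near_zero(self):
        rng = np.random.default_rng(123)
        truth = np.repeat([0, 1, 2], 20)
        vals = []
        for _ in range(2000):
            vals.append(adjusted_rand(rng.permutation(truth), truth))
        assert abs(np.mean(vals)) < 0.02


class TestClusterAccuracy:
    def test_identical(self):
        assert cluster_accuracy([0, 1, 1], [0, 1, 1]) == 1.0

    def test_worked_example(self):
        # overlaps: pred cluster 1 -> max(2, 0) = 2; pred cluster 2 -> max(1, 3) = 3
        assert cluster_accuracy([1, 1, 2, 2, 2, 2], [1, 1, 1, 2, 2, 2]) == pytest.approx(5 / 6)

    def test_single_cluster_majority_share(self):
        assert cluster_accuracy([0, 0, 0, 0], [1, 1, 2, 2]) == 0.5


class TestInformationMetrics:
    def test_identical_labelings_give_one(self):
        labels = [0, 0, 1, 1, 2, 2]
        assert nmi(labels, labels) == pytest.approx(1.0)
        assert ami(labels, labels) == pytest.approx(1.0)

    def test_uniform_contingency_has_zero_mi(self):
        pred, truth = [1, 2, 1, 2], [1, 1, 2, 2]
        assert mutual_information(pred, truth) == pytest.approx(0.0, abs=1e-12)
        assert nmi(pred, truth) == pytest.approx(0.0, abs=1e-12)
        assert ami(pred, truth) <= 0.0  # E[MI] > 0 makes AMI negative here

    def test_single_cluster_degenerates_to_zero(self):
        assert nmi([0, 0, 0], [0, 1, 2]) == 0.0
        assert ami([0, 0, 0], [0, 1, 2]) == 0.0

    def test_emi_matches_permutation_monte_carlo(self):
        """The exact hypergeometric E[MI] equals the Monte-Carlo average of
        MI over random label permutations."""
        rng = np.random.default_rng(7)
        truth = np.repeat([0, 1, 2], [5, 7, 4])
        pred = rng.integers(0, 3, size=len(truth))
        from metclust.evaluation import contingency_table

        table = contingency_table(pred, truth)
        exact = expected_mutual_information(table.sum(axis=1), table.sum(axis=0))
        mc = np.mean(
            [mutual_information(rng.permutation(pred), truth) for _ in range(4000)]
        )
        assert exact == pytest.approx(mc, abs=0.01)

    def test_monte_carlo_null_mean_near_zero(self):
        rng = np.random.default_rng(99)
        truth = np.repeat([0, 1, 2], 20)
        vals = [ami(rng.permutation(truth), truth) for _ in range(2000)]
        assert abs(np.mean(vals)) < 0.02


class TestAgainstReferenceImplementations:
    """Cross-checks against sklearn's implementations (geometric averaging
    matches the sqrt normalizations used here)."""

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_ari_nmi_ami_match_sklearn(self, seed):
        from sklearn.metrics import (
            adjusted_mutual_info_score,
            adjusted_rand_score,
            fowlkes_mallows_score,
            normalized_mutual_info_score,
        )

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        pred = rng.integers(0, int(rng.integers(2, 6)), size=n)
        truth = rng.integers(0, int(rng.integers(2, 6)), size=n)
        assert adjusted_rand(pred, truth) == pytest.approx(
            adjusted_rand_score(truth, pred), abs=1e-10
        )
        assert nmi(pred, truth) == pytest.approx(
            normalized_mutual_info_score(truth, pred, average_method="geometric"),
            abs=1e-10,
        )
        assert ami(pred, truth) == pytest.approx(
            adjusted_mutual_info_score(truth, pred, average_method="geometric"),
            abs=1e-9,
        )
        assert fowlkes_mallows(pair_counts(pred, truth)) == pytest.approx(
            fowlkes_mallows_score(truth, pred), abs=1e-10
        )


class TestEvaluateReport:
    def test_relabeling_invariance(self):
        pred = [0, 0, 1, 1, 2, 2, 2]
        truth = [5, 5, 9, 9, 9, 7, 7]
        remap_pred = [{0: 7, 1: 3, 2: 0}[x] for x in pred]
        remap_truth = [{5: 1, 9: 0, 7: 2}[x] for x in truth]
        r1 = evaluate(pred, truth)
        r2 = evaluate(remap_pred, remap_truth)
        for m in METRIC_ORDER:
            assert getattr(r1, m) == pytest.approx(getattr(r2, m), abs=1e-12)

    def test_codomain_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            pred = rng.integers(0, 4, size=n)
            truth = rng.integers(0, 4, size=n)
            r = evaluate(pred, truth)
            for m in ("RI", "MR", "F1", "FMI", "CA", "NMI"):
                assert 0.0 <= getattr(r, m) <= 1.0
            assert -1.0 <= r.ARI <= 1.0 and -1.0 <= r.AMI <= 1.0

    def test_tsv_export_scaled_by_100(self, tmp_path):
        r = evaluate([0, 0, 1, 1], [0, 0, 1, 1])
        r.to_tsv(tmp_path / "metrics.tsv")
        lines = (tmp_path / "metrics.tsv").read_text().splitlines()
        assert lines[0].split("\t") == METRIC_ORDER
        assert lines[1].split("\t")[0] == "100.00"
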