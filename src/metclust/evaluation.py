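"""Clustering evaluation metrics.

Eight standard external-validation metrics computed from a predicted
labeling CP and a ground-truth labeling GT over the same n samples:

* pair-counting family, from TP/FP/FN/TN over the n(n-1)/2 unordered
  sample pairs: Rand index RI = (TP+TN)/total, misclassification rate
  MR = 1 - RI, F-measure F1 = 2PR/(P+R) with P = TP/(TP+FP) and
  R = TP/(TP+FN), Fowlkes-Mallows FMI = TP/sqrt((TP+FP)(TP+FN));
* chance-corrected Rand: ARI = (RI - E[RI]) / (max(RI) - E[RI]) via the
  standard contingency-table closed form under the permutation
  (hypergeometric) null with fixed marginals;
* cluster accuracy CA: each predicted cluster claims its best-overlapping
  truth class (many-to-one), summed overlap divided by n;
* information-theoretic family, in nats (the base cancels in both
  normalizations): NMI = MI/sqrt(H(CP)H(GT)) and
  AMI = (MI - E[MI])/(sqrt(H(CP)H(GT)) - E[MI]), with E[MI] the exact
  hypergeometric-model expectation.

Degenerate labelings (a single cluster on either side) make the adjusted
and normalized metrics undefined; they are reported as 0 with a warning
rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "PairCounts",
    "MetricsReport",
    "contingency_table",
    "pair_counts",
    "rand_index",
    "misclassification_rate",
    "f_measure",
    "fowlkes_mallows",
    "adjusted_rand",
    "cluster_accuracy",
    "mutual_information",
    "expected_mutual_information",
    "nmi",
    "ami",
    "evaluate",
]

METRIC_ORDER = ["RI", "ARI", "MR", "F1", "FMI", "CA", "NMI", "AMI"]


@dataclass(frozen=True)
class PairCounts:
    """Agreement counts over unordered sample pairs."""

    TP: int  # same cluster in both labelings
    FP: int  # same in predicted, different in truth
    FN: int  # different in predicted, same in truth
    TN: int  # different in both

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    RI: float
    ARI: float
    MR: float
    F1: float
    FMI: float
    CA: float
    NMI: float
    AMI: float

    def as_dict(self, scale: float = 1.0) -> dict[str, float]:
        return {m: getattr(self, m) * scale for m in METRIC_ORDER}

    def to_tsv(self, path: str | Path, scale: float = 100.0) -> None:
        """Write one row in Table-style column order; values x100 by default."""
        vals = self.as_dict(scale)
        with open(path, "w") as fh:
            fh.write("\t".join(METRIC_ORDER) + "\n")
            fh.write("\t".join(f"{vals[m]:.2f}" for m in METRIC_ORDER) + "\n")


def _as_labels(x: Sequence) -> np.ndarray:
    arr = np.asarray(x)
    _, enc = np.unique(arr, return_inverse=True)
    return enc


def contingency_table(pred: Sequence, truth: Sequence) -> np.ndarray:
    p = _as_labels(pred)
    t = _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("label vectors must have equal length")
    R, C = p.max() + 1, t.max() + 1
    table = np.zeros((R, C), dtype=np.int64)
    np.add.at(table, (p, t), 1)
    return table


def _comb2(x: np.ndarray | int):
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_counts(pred: Sequence, truth: Sequence) -> PairCounts:
    """TP/FP/FN/TN over all n(n-1)/2 unordered pairs, via the contingency
    table (equivalent to direct pair enumeration)."""
    table = contingency_table(pred, truth)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least two samples")
    tp = int(_comb2(table).sum())
    same_pred = int(_comb2(table.sum(axis=1)).sum())
    same_truth = int(_comb2(table.sum(axis=0)).sum())
    total = int(_comb2(n))
    fp = same_pred - tp
    fn = same_truth - tp
    tn = total - tp - fp - fn
    return PairCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def rand_index(pc: PairCounts) -> float:
    return (pc.TP + pc.TN) / pc.total


def misclassification_rate(pc: PairCounts) -> float:
    return (pc.FP + pc.FN) / pc.total


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", name)
        return 0.0
    return num / den


def f_measure(pc: PairCounts) -> float:
    precision = _safe_ratio(pc.TP, pc.TP + pc.FP, "precision")
    recall = _safe_ratio(pc.TP, pc.TP + pc.FN, "recall")
    return _safe_ratio(2 * precision * recall, precision + recall, "F1")


def fowlkes_mallows(pc: PairCounts) -> float:
    den = np.sqrt(float(pc.TP + pc.FP) * float(pc.TP + pc.FN))
    return _safe_ratio(pc.TP, den, "FMI")


def adjusted_rand(pred: Sequence, truth: Sequence) -> float:
    """Chance-corrected Rand index (hypergeometric permutation null)."""
    table = contingency_table(pred, truth)
    n = int(table.sum())
    sum_ij = float(_comb2(table).sum())
    a = float(_comb2(table.sum(axis=1)).sum())
    b = float(_comb2(table.sum(axis=0)).sum())
    total = float(_comb2(n))
    expected = a * b / total
    max_index = (a + b) / 2.0
    if max_index == expected:
        logger.warning("ARI undefined for degenerate labelings; reporting 0")
        return 0.0
    return (sum_ij - expected) / (max_index - expected)


def cluster_accuracy(pred: Sequence, truth: Sequence) -> float:
    """Sum over predicted clusters of their maximum overlap with any truth
    class, divided by n (many-to-one mapping)."""
    table = contingency_table(pred, truth)
    return float(table.max(axis=1).sum()) / float(table.sum())


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(pred: Sequence, truth: Sequence) -> float:
    """MI of the joint labeling contingency table, in nats."""
    table = contingency_table(pred, truth).astype(float)
    n = table.sum()
    outer = table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True)
    nz = table > 0
    return float((table[nz] / n * np.log(table[nz] * n / outer[nz])).sum())


def expected_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Exact E[MI] under the permutation model with fixed marginals
    (hypergeometric summation), in nats.

    ``a`` and ``b`` are the row/column marginals of the contingency table.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n = int(a.sum())
    if n != int(b.sum()):
        raise ValueError("marginals must share the same total")
    emi = 0.0
    gln_a = gammaln(a + 1)
    gln_b = gammaln(b + 1)
    gln_na = gammaln(n - a + 1)
    gln_nb = gammaln(n - b + 1)
    gln_n = gammaln(n + 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = nij / n * np.log(n * nij / (ai * bj))
            log_prob = (
                gln_a[i]
                + gln_b[j]
                + gln_na[i]
                + gln_nb[j]
                - gln_n
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float((term1 * np.exp(log_prob)).sum())
    return emi


def nmi(pred: Sequence, truth: Sequence) -> float:
    """Normalized mutual information with sqrt(H(CP)H(GT)) normalization."""
    table = contingency_table(pred, truth)
    h_p = _entropy(table.sum(axis=1).astype(float))
    h_t = _entropy(table.sum(axis=0).astype(float))
    if h_p == 0 or h_t == 0:
        logger.warning("NMI undefined for a single-cluster labeling; reporting 0")
        return 0.0
    return mutual_information(pred, truth) / np.sqrt(h_p * h_t)


def ami(pred: Sequence, truth: Sequence) -> float:
    """Adjusted mutual information: (MI - E[MI]) / (sqrt(H H) - E[MI])."""
    table = contingency_table(pred, truth)
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    h_p = _entropy(a.astype(float))
    h_t = _entropy(b.astype(float))
    if h_p == 0 or h_t == 0:
        logger.warning("AMI undefined for a single-cluster labeling; reporting 0")
        return 0.0
    mi = mutual_information(pred, truth)
    emi = expected_mutual_information(a, b)
    den = np.sqrt(h_p * h_t) - emi
    if abs(den) < 1e-15:
        logger.warning("AMI denominator vanishes; reporting 0")
        return 0.0
    return (mi - emi) / den


def evaluate(pred: Sequence, truth: Sequence) -> MetricsReport:
    """All eight metrics for one (predicted, ground-truth) labeling pair."""
    pc = pair_counts(pred, truth)
    return MetricsReport(
        RI=rand_index(pc),
        ARI=adjusted_rand(pred, truth),
        MR=misclassification_rate(pc),
        F1=f_measure(pc),
        FMI=fowlkes_mallows(pc),
        CA=cluster_accuracy(pred, truth),
        NMI=nmi(pred, truth),
        AMI=ami(pred, truth),
    )
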