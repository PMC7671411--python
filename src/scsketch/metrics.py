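"""Partition-agreement metrics and the rare-population detection score."""

from __future__ import annotations

import numpy as np

__all__ = [
    "contingency",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "rare_detection_f1",
]


def contingency(u, v) -> np.ndarray:
    """Co-occurrence counts between two label sequences.

    Rows follow the sorted distinct labels of ``u``, columns of ``v``.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(
            f"label sequences must be 1-D and equal length, got {u.shape} and {v.shape}"
        )
    if u.size == 0:
        raise ValueError("empty label sequences")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(u, v) -> float:
    """Pair-counting agreement corrected for chance; 1 for identical partitions."""
    table = contingency(u, v)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 points")
    sum_ij = _comb2(table.astype(float)).sum()
    sum_i = _comb2(table.sum(axis=1).astype(float)).sum()
    sum_j = _comb2(table.sum(axis=0).astype(float)).sum()
    total = _comb2(float(n))
    expected = sum_i * sum_j / total
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both partitions trivial (and identical)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(u, v) -> float:
    """Mutual information over the arithmetic mean of the two entropies.

    Both partitions trivial (zero entropy) returns 1.0; exactly one trivial
    partition returns 0.0.
    """
    table = contingency(u, v).astype(float)
    n = table.sum()
    pi = table.sum(axis=1) / n
    pj = table.sum(axis=0) / n
    hu = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    hv = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    if hu == 0.0 and hv == 0.0:
        return 1.0
    if hu == 0.0 or hv == 0.0:
        return 0.0
    pij = table / n
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / np.outer(pi, pj)[mask])))
    return mi / (0.5 * (hu + hv))


def rare_detection_f1(truth_rare, predicted, rare_cluster=None) -> float:
    """F1 of recovering a rare population from a clustering.

    The predicted rare set is the smallest predicted cluster (ties broken
    toward the lower label), unless ``rare_cluster`` names one explicitly.
    Returns 0.0 when precision + recall is zero.
    """
    truth_rare = np.asarray(truth_rare, dtype=bool)
    predicted = np.asarray(predicted)
    if truth_rare.shape != predicted.shape:
        raise ValueError("truth mask and predicted labels must be equal length")
    labels, counts = np.unique(predicted, return_counts=True)
    if rare_cluster is None:
        rare_cluster = labels[np.argmin(counts)]  # argmin ties -> first (lowest) label
    pred_rare = predicted == rare_cluster
    tp = int(np.sum(pred_rare & truth_rare))
    fp = int(np.sum(pred_rare & ~truth_rare))
    fn = int(np.sum(~pred_rare & truth_rare))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
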