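"""Independent brute-force oracles used by the test suite.

Each routine here re-derives a quantity by the most direct method available
(exhaustive enumeration, the textbook update formula, a closed form), without
reusing the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def ward_heights_bruteforce(X: np.ndarray) -> np.ndarray:
    """Ward merge heights via the Lance-Williams recurrence on squared distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = {}
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        pair, best = None, np.inf
        for i, j in itertools.combinations(sorted(active), 2):
            v = d2[(min(i, j), max(i, j))]
            if v < best - 1e-15:
                best, pair = v, (i, j)
        a, b = pair
        heights.append(math.sqrt(best))
        na, nb = sizes[a], sizes[b]
        for k in sorted(active - {a, b}):
            nk = sizes[k]
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            dab = best
            new = ((na + nk) * dak + (nb + nk) * dbk - nk * dab) / (na + nb + nk)
            d2[(k, next_id)] = new
        sizes[next_id] = na + nb
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return np.asarray(heights)


def all_partitions(n: int):
    """Every set partition of range(n) as a dense label array."""
    labels = np.zeros(n, dtype=int)
    maxima = np.zeros(n, dtype=int)
    while True:
        yield labels.copy()
        for i in range(n - 1, 0, -1):
            if labels[i] <= maxima[i - 1]:
                labels[i] += 1
                maxima[i] = max(maxima[i - 1], labels[i])
                labels[i + 1 :] = 0
                maxima[i + 1 :] = maxima[i]
                break
        else:
            return


def max_modularity_bruteforce(A: np.ndarray, resolution: float = 1.0) -> float:
    """Maximum Newman-Girvan modularity over every partition (small graphs)."""
    A0 = np.array(A, dtype=float)
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    B = A0 - resolution * np.outer(k, k) / two_m
    best = -np.inf
    for labels in all_partitions(A0.shape[0]):
        same = labels[:, None] == labels[None, :]
        best = max(best, B[same].sum() / two_m)
    return float(best)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    n = a.size
    mi = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            nij = np.sum((a == va) & (b == vb))
            if nij == 0:
                continue
            ai, bj = np.sum(a == va), np.sum(b == vb)
            mi += (nij / n) * math.log(n * nij / (ai * bj))
    return mi


def expected_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """E[MI] over random contingency tables with fixed margins (hypergeometric)."""
    n = a.size
    a_counts = np.unique(a, return_counts=True)[1]
    b_counts = np.unique(b, return_counts=True)[1]
    emi = 0.0
    for ai in a_counts:
        for bj in b_counts:
            lo = max(ai + bj - n, 1)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                p = hypergeom.pmf(nij, n, ai, bj)
                emi += p * (nij / n) * math.log(n * nij / (ai * bj))
    return emi


def ami_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted mutual information from the contingency table, arithmetic mean."""
    mi = mutual_information(a, b)
    emi = expected_mutual_information(a, b)
    denom = 0.5 * (_entropy(a) + _entropy(b)) - emi
    if abs(denom) < 1e-15:
        return 1.0
    return (mi - emi) / denom


def homogeneity_bruteforce(clusters: np.ndarray, classes: np.ndarray) -> float:
    """1 - H(classes | clusters) / H(classes) from the contingency table."""
    h_classes = _entropy(classes)
    if h_classes == 0.0:
        return 1.0
    n = classes.size
    h_cond = 0.0
    for vk in np.unique(clusters):
        mask = clusters == vk
        nk = mask.sum()
        h_cond += (nk / n) * _entropy(classes[mask])
    return 1.0 - h_cond / h_classes
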