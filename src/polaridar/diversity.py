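"""Diversity indices and clustering-agreement metrics.

Cluster solutions are summarized by Hill numbers of order 0, 1 and 2:
richness H0 = S, the Shannon-effective cluster count H1 = exp(H') with
H' = -sum p_j ln p_j, and the dominance-weighted count H2 = 1 / sum p_j^2,
where p_j is the relative size of cluster j.  H0 >= H1 >= H2 always, with
equality for perfectly even abundances.

Agreement between two solutions uses adjusted mutual information (chance
corrected, ~0 for independent labelings) and the homogeneity score
1 - H(classes|clusters)/H(classes), which is 1 when every cluster of one
solution lies inside a single cluster of the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score, homogeneity_score


@dataclass
class ClusterSolution:
    """Per-observation labels plus provenance of the clustering route."""

    labels: np.ndarray
    method: str  # "hca" | "gmm"
    mode: str  # "unpol" | "copol" | "dolp"
    k: int = 0
    extras: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty vector")
        self.k = int(np.unique(self.labels).size)


@dataclass(frozen=True)
class DiversityIndices:
    h0: int
    shannon: float
    h1: float
    h2: float


def relative_abundances(solution: ClusterSolution | np.ndarray) -> np.ndarray:
    """Relative cluster sizes p_j (one entry per distinct label, summing to 1)."""
    labels = solution.labels if isinstance(solution, ClusterSolution) else np.asarray(solution)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    return counts / counts.sum()


def hill_indices(p: np.ndarray) -> DiversityIndices:
    """Hill numbers of order 0, 1 (via the Shannon index, in nats) and 2."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a valid abundance vector summing to 1")
    nz = p[p > 0]
    shannon = float(-np.sum(nz * np.log(nz)))
    return DiversityIndices(
        h0=int(nz.size),
        shannon=shannon,
        h1=float(np.exp(shannon)),
        h2=float(1.0 / np.sum(nz**2)),
    )


def rad(solution: ClusterSolution | np.ndarray) -> np.ndarray:
    """Ranked abundance distribution: cluster sizes in descending order."""
    labels = solution.labels if isinstance(solution, ClusterSolution) else np.asarray(solution)
    _, counts = np.unique(labels, return_counts=True)
    return np.sort(counts)[::-1]


def ami(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted mutual information between two labelings (1 = perfect, ~0 = chance)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_mutual_info_score(a, b))


def homogeneity(clusters: np.ndarray, classes: np.ndarray) -> float:
    """Homogeneity of ``clusters`` with respect to ``classes``.

    1 - H(classes|clusters)/H(classes); 1 when each cluster contains members
    of a single class (and by convention when H(classes) = 0).  Directional:
    report both orientations when comparing two clustering solutions.
    """
    clusters, classes = np.asarray(clusters), np.asarray(classes)
    if clusters.shape != classes.shape:
        raise ValueError("label vectors must have equal length")
    return float(homogeneity_score(classes, clusters))
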