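"""Hierarchical clustering with compensated-linkage model selection.

Feature vectors (area-normalized, log-transformed spectra) are agglomerated
under Ward's criterion with Euclidean distances.  The number of clusters is
chosen from the merge heights themselves: reverse-ordered linkage values decay
approximately as a power law of the merge index under random spectral
variation, so on log-log axes the decay is linear.  The median log-log slope
gamma estimates that trend; rescaling each linkage by the trend,

    L*_i = (i/N)^(-gamma) * L_i,

maps an exact power law to a constant ("compensated" linkages).  Merges that
stand above the compensated bulk - values exceeding Q3 + 1.5 x IQR - mark
cluster-defining joins, and their count is the selected number of clusters.

Note on the exponent sign: with gamma the (negative) median slope of
log L versus log(i/N), the flattening rescale must use the opposite sign,
(i/N)^(-gamma); this is the convention implemented here since it is the one
that makes compensated values of a pure power law constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .diversity import ClusterSolution

_HEIGHT_EPS = 1e-12


@dataclass
class LinkageSequence:
    """Ward merge heights (in merge order) plus the scipy linkage matrix."""

    heights: np.ndarray
    tree: np.ndarray  # scipy linkage matrix, shape (n-1, 4)

    @property
    def n_steps(self) -> int:
        return self.heights.size


@dataclass
class CompensationResult:
    gamma: float
    compensated: np.ndarray  # per reverse-ordered step, largest first
    n_outliers: int
    k_selected: int


def ward_tree(X: np.ndarray) -> LinkageSequence:
    """Agglomerate rows of ``X`` under Ward's minimum-variance criterion.

    Euclidean metric; merge heights are nondecreasing in merge order
    (ultrametricity of Ward linkage).  Ties are broken deterministically by
    the underlying nearest-neighbor chain algorithm.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least two rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must contain only finite values")
    Z = linkage(X, method="ward", metric="euclidean")
    return LinkageSequence(heights=Z[:, 2].copy(), tree=Z)


def compensate_and_select(seq: LinkageSequence | np.ndarray) -> CompensationResult:
    """Select the number of clusters from reverse-ordered linkage heights.

    Steps: (1) reverse heights to L_1 >= ... >= L_N; (2) gamma = median of
    finite-difference slopes of log L against log(i/N); (3) compensate
    L*_i = (i/N)^(-gamma) L_i; (4) count outliers L*_i > Q3 + 1.5 IQR;
    (5) the count is the selected k, floored at 1.
    """
    heights = seq.heights if isinstance(seq, LinkageSequence) else np.asarray(seq, dtype=float)
    N = heights.size
    if N < 3:
        raise ValueError("need at least 3 merge steps to estimate the linkage trend")
    L = np.sort(heights)[::-1].astype(float)
    if np.any(L <= 0):
        warnings.warn(
            "non-positive linkage heights floored for the log-log trend",
            RuntimeWarning,
            stacklevel=2,
        )
        L = np.maximum(L, _HEIGHT_EPS)
    x = np.arange(1, N + 1) / N
    log_L, log_x = np.log(L), np.log(x)
    dy, dx = np.diff(log_L), np.diff(log_x)
    slopes = dy / dx  # dx is strictly positive, so always finite here
    slopes = slopes[np.isfinite(slopes)]
    gamma = float(np.median(slopes)) if slopes.size else 0.0
    compensated = x ** (-gamma) * L
    q1, q3 = np.percentile(compensated, [25.0, 75.0])
    fence = q3 + 1.5 * (q3 - q1)
    # relative tolerance: an exactly flat compensated sequence must yield
    # zero outliers despite floating-point jitter around the fence
    tol = 1e-9 * float(np.max(np.abs(compensated)))
    n_outliers = int(np.sum(compensated > fence + tol))
    return CompensationResult(
        gamma=gamma,
        compensated=compensated,
        n_outliers=n_outliers,
        k_selected=max(n_outliers, 1),
    )


def cluster_hca(X: np.ndarray, k: int | None = None, mode: str = "unpol") -> ClusterSolution:
    """Ward-cluster ``X``, cutting the tree at ``k`` groups.

    If ``k`` is omitted it is chosen by :func:`compensate_and_select`.
    """
    seq = ward_tree(X)
    comp = compensate_and_select(seq) if k is None or X.shape[0] >= 4 else None
    if k is None:
        if comp is None:
            raise ValueError("too few observations to select k automatically")
        k = comp.k_selected
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    labels = fcluster(seq.tree, t=k, criterion="maxclust")
    extras = {"heights": seq.heights}
    if comp is not None:
        extras.update({"gamma": comp.gamma, "k_selected": comp.k_selected})
    return ClusterSolution(labels=labels, method="hca", mode=mode, extras=extras)
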