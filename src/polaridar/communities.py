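"""Time/range community structure and DoLP characterization of clusters.

Clusters of observations are compared through the time-of-day and range
stamps of their members: every cluster pair gets a two-sample
Kolmogorov-Smirnov p-value, yielding a symmetric similarity matrix per axis.
Communities - groups of clusters with mutually similar profiles - are found
by maximizing Newman-Girvan modularity of that weighted similarity graph
(resolution 1, self-loops excluded), with a deterministic Louvain scheme and
exact enumeration on small graphs.  The modularity score M of the returned
partition quantifies how much within-community similarity exceeds the
degree-based expectation.

Cluster glossiness is summarized by the bootstrap mean DoLP with percentile
95 % confidence intervals, compared against randomly assembled clusters of
the same size, and binned into quartile groups Q1 (glossiest) to Q4 (most
diffuse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .diversity import ClusterSolution

#: 96 15-minute solar-time bins (centers 00:07:30 ... 23:52:30)
TIME_BIN_EDGES = np.arange(0.0, 86400.0 + 1.0, 900.0)
#: 20 logarithmically spaced range bins between 48 m and 427 m
RANGE_BIN_EDGES = np.geomspace(48.0, 427.0, 21)

#: exact K-S p-values below this per-side sample size, asymptotic above
_KS_EXACT_MAX_N = 10


@dataclass
class ClusterProfile:
    cluster_id: object
    time_prob: np.ndarray
    range_prob: np.ndarray
    member_times: np.ndarray
    member_ranges: np.ndarray


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    cluster_ids: list

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class CommunityPartition:
    assignment: dict  # cluster_id -> community index
    modularity: float
    resolution: float = 1.0


@dataclass
class DoLPSummary:
    cluster_id: object
    mean_dolp: float
    ci_low: float
    ci_high: float
    null_ci_low: float
    null_ci_high: float
    quartile: int = 0  # 1 = glossiest ... 4 = most diffuse
    significant: bool = False
    degenerate: bool = False  # singleton cluster: CI has zero width


def cluster_profiles(
    solution: ClusterSolution,
    times: np.ndarray,
    ranges: np.ndarray,
) -> list[ClusterProfile]:
    """Normalized time (96-bin) and range (20-bin) histograms per cluster."""
    times = np.asarray(times, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    labels = solution.labels
    if times.shape != labels.shape or ranges.shape != labels.shape:
        raise ValueError("stamps must be available for every observation")
    profiles = []
    for cid in np.unique(labels):
        member = labels == cid
        if not np.any(member):  # pragma: no cover - unique() precludes this
            warnings.warn(f"cluster {cid!r} has no members; skipped", RuntimeWarning)
            continue
        t_hist, _ = np.histogram(times[member], bins=TIME_BIN_EDGES)
        r_hist, _ = np.histogram(
            np.clip(ranges[member], RANGE_BIN_EDGES[0], RANGE_BIN_EDGES[-1]),
            bins=RANGE_BIN_EDGES,
        )
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                time_prob=t_hist / t_hist.sum(),
                range_prob=r_hist / r_hist.sum(),
                member_times=times[member].copy(),
                member_ranges=ranges[member].copy(),
            )
        )
    return profiles


def ks_similarity(
    solution: ClusterSolution,
    stamps: np.ndarray,
    min_members: int = 2,
) -> SimilarityMatrix:
    """Pairwise two-sample K-S p-values between the raw member stamps of clusters.

    The test runs on raw stamps, not on the binned display profiles.  Exact
    p-values are used for small samples (< 10 per side), the asymptotic
    distribution otherwise.  Clusters with fewer than ``min_members`` members
    are skipped with a warning; the diagonal is set to 1.
    """
    stamps = np.asarray(stamps, dtype=float)
    labels = solution.labels
    if stamps.shape != labels.shape:
        raise ValueError("stamps must be available for every observation")
    ids, samples = [], []
    for cid in np.unique(labels):
        sample = stamps[labels == cid]
        if sample.size < min_members:
            warnings.warn(
                f"cluster {cid!r} has fewer than {min_members} members; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        ids.append(cid)
        samples.append(sample)
    S = len(ids)
    if S < 2:
        raise ValueError("need at least two clusters with enough members")
    values = np.eye(S)
    for i in range(S):
        for j in range(i + 1, S):
            method = (
                "exact"
                if min(samples[i].size, samples[j].size) < _KS_EXACT_MAX_N
                else "asymp"
            )
            p = ks_2samp(samples[i], samples[j], method=method).pvalue
            values[i, j] = values[j, i] = p
    return SimilarityMatrix(values=values, cluster_ids=ids)


# ---------------------------------------------------------------------------
# modularity maximization


def _modularity_matrix(A: np.ndarray, resolution: float) -> tuple[np.ndarray, float]:
    """Newman-Girvan modularity matrix (self-loops excluded) and total weight 2m."""
    A0 = np.array(A, dtype=float)
    np.fill_diagonal(A0, 0.0)
    degree = A0.sum(axis=1)
    two_m = float(degree.sum())
    if two_m <= 0:
        return np.zeros_like(A0), 0.0
    B = A0 - resolution * np.outer(degree, degree) / two_m
    return B, two_m


def modularity_score(A: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Modularity M of a partition of the weighted similarity graph."""
    B, two_m = _modularity_matrix(A, resolution)
    if two_m == 0:
        return 0.0
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    # the diagonal (A_ii = 0, -gamma k_i^2 / 2m) is always within-community;
    # keeping it gives Q = 0 for the single-community partition of any graph
    return float(B[same].sum() / two_m)


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
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


def _exact_partition(B: np.ndarray) -> np.ndarray:
    n = B.shape[0]
    B_off = B.copy()
    np.fill_diagonal(B_off, 0.0)
    best_q, best = -np.inf, np.zeros(n, dtype=int)
    for labels in _partitions(n):
        same = labels[:, None] == labels[None, :]
        q = B_off[same].sum()
        if q > best_q + 1e-15:
            best_q, best = q, labels
    return best


def _louvain(B: np.ndarray) -> np.ndarray:
    """Deterministic Louvain on a symmetric modularity matrix.

    Nodes are scanned in fixed index order with best-improvement moves (ties
    keep the lowest community index); once a pass makes no move the
    communities are aggregated into supernodes and the process repeats on the
    quotient matrix.  Self-loop weights travel with their supernode and so
    cancel in every gain comparison; only off-diagonal sums matter.
    """
    membership = np.arange(B.shape[0])  # original node -> community label
    W = B.copy()
    while True:
        m = W.shape[0]
        comm = np.arange(m)
        W_off = W.copy()
        np.fill_diagonal(W_off, 0.0)
        moved_any = False
        improved = True
        while improved:
            improved = False
            for u in range(m):
                # total link weight from u into each community (u itself excluded)
                weights = np.zeros(m)
                np.add.at(weights, comm, W_off[u])
                own = comm[u]
                best_c, best_gain = own, weights[own]
                for c in range(m):
                    if weights[c] > best_gain + 1e-12:
                        best_gain, best_c = weights[c], c
                if best_c != own:
                    comm[u] = best_c
                    improved = True
                    moved_any = True
        uniq, dense = np.unique(comm, return_inverse=True)
        membership = dense[membership]
        if not moved_any or uniq.size == m:
            break
        agg = np.zeros((uniq.size, uniq.size))
        for a in range(uniq.size):
            in_a = dense == a
            for b in range(uniq.size):
                agg[a, b] = W[np.ix_(in_a, dense == b)].sum()
        W = agg
    _, out = np.unique(membership, return_inverse=True)
    return out


def detect_communities(
    A: SimilarityMatrix | np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "auto",
) -> CommunityPartition:
    """Partition the similarity graph into communities by modularity maximization.

    ``method='exact'`` enumerates all partitions (feasible for <= ~12
    clusters); ``'louvain'`` runs the deterministic Louvain scheme; ``'auto'``
    picks exact for up to 10 clusters and Louvain above.  ``seed`` is accepted
    for interface symmetry; both routes are deterministic.

    An all-zero similarity matrix yields a single community with M = 0.
    """
    if isinstance(A, SimilarityMatrix):
        ids, values = A.cluster_ids, A.values
    else:
        values = np.asarray(A, dtype=float)
        ids = list(range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("similarity matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("similarity matrix must be nonnegative")
    n = values.shape[0]
    B, two_m = _modularity_matrix(values, resolution)
    if two_m == 0:
        return CommunityPartition(
            assignment={cid: 0 for cid in ids}, modularity=0.0, resolution=resolution
        )
    if method == "auto":
        method = "exact" if n <= 10 else "louvain"
    if method == "exact":
        labels = _exact_partition(B)
    elif method == "louvain":
        labels = _louvain(B)
    else:
        raise ValueError(f"unknown method {method!r}")
    _, labels = np.unique(labels, return_inverse=True)
    M = modularity_score(values, labels, resolution)
    return CommunityPartition(
        assignment={cid: int(c) for cid, c in zip(ids, labels)},
        modularity=M,
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# bootstrap and DoLP characterization


def bootstrap_ci(
    values: np.ndarray,
    statistic=np.mean,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap of a statistic: (mean, 2.5th, 97.5th percentile).

    ``n_boot`` resamples with replacement; the reported mean is the mean of
    the bootstrap distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    if statistic is np.mean:
        stats = values[idx].mean(axis=1)
    else:
        stats = np.apply_along_axis(statistic, 1, values[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(stats.mean()), float(lo), float(hi)


def _quartile_groups(cluster_means: np.ndarray) -> np.ndarray:
    """Quartile group (1 glossiest ... 4 most diffuse) per cluster mean DoLP.

    Boundaries are the quartiles of the cluster-level mean-DoLP distribution,
    each cluster weighted equally.
    """
    q25, q50, q75 = np.percentile(cluster_means, [25.0, 50.0, 75.0])
    groups = np.full(cluster_means.size, 4, dtype=int)
    groups[cluster_means > q25] = 3
    groups[cluster_means > q50] = 2
    groups[cluster_means > q75] = 1
    return groups


def dolp_summaries(
    solution: ClusterSolution,
    dolp: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[DoLPSummary]:
    """Bootstrap DoLP characterization of every cluster against a random null.

    For each cluster: a percentile bootstrap CI of the mean DoLP of its
    members, and a null CI from ``n_boot`` randomly assembled clusters of the
    same size (drawn without replacement from the full observation pool,
    independently per repetition).  A cluster is significant when the two
    intervals are disjoint.  Clusters are assigned DoLP quartile groups from
    the distribution of cluster-level means.
    """
    dolp = np.asarray(dolp, dtype=float)
    labels = solution.labels
    if dolp.shape != labels.shape:
        raise ValueError("a DoLP value is required for every observation")
    rng = np.random.default_rng(seed)
    cluster_ids = np.unique(labels)
    summaries = []
    for cid in cluster_ids:
        members = dolp[labels == cid]
        size = members.size
        boot_mean, lo, hi = bootstrap_ci(
            members, np.mean, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        # null: same-size clusters assembled at random from the pool
        null_means = np.empty(n_boot)
        if size >= dolp.size:
            null_means[:] = dolp.mean()
        else:
            for b in range(n_boot):
                null_means[b] = dolp[rng.choice(dolp.size, size=size, replace=False)].mean()
        null_lo, null_hi = np.percentile(null_means, [2.5, 97.5])
        summaries.append(
            DoLPSummary(
                cluster_id=cid,
                mean_dolp=boot_mean,
                ci_low=lo,
                ci_high=hi,
                null_ci_low=float(null_lo),
                null_ci_high=float(null_hi),
                significant=bool(hi < null_lo or lo > null_hi),
                degenerate=bool(size == 1),
            )
        )
    groups = _quartile_groups(np.array([s.mean_dolp for s in summaries]))
    for s, g in zip(summaries, groups):
        s.quartile = int(g)
    return summaries


def observation_quartiles(
    solution: ClusterSolution, summaries: list[DoLPSummary]
) -> np.ndarray:
    """Per-observation quartile group inherited from the assigned cluster."""
    lookup = {s.cluster_id: s.quartile for s in summaries}
    return np.array([lookup[label] for label in solution.labels], dtype=int)


def quartile_flows(
    quartiles_a: np.ndarray, quartiles_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """4x4 flow table of observations between quartile groups of two dataset modes.

    Entry (i, j) counts observations in quartile i+1 under the first mode and
    quartile j+1 under the second; row sums equal the source quartile sizes.
    Also returns the fraction of observations reassigned across non-adjacent
    quartiles (|i - j| >= 2).
    """
    qa = np.asarray(quartiles_a, dtype=int)
    qb = np.asarray(quartiles_b, dtype=int)
    if qa.shape != qb.shape:
        raise ValueError("quartile assignments must cover the same observations")
    table = np.zeros((4, 4), dtype=int)
    for i in range(4):
        for j in range(4):
            table[i, j] = int(np.sum((qa == i + 1) & (qb == j + 1)))
    non_adjacent = float(np.sum(np.abs(qa - qb) >= 2) / qa.size)
    return table, non_adjacent


def shared_quartile_fraction(assignments: list[np.ndarray]) -> dict[int, float]:
    """Per-quartile sharing across dataset modes: |intersection| / |union|.

    For each quartile group k, the fraction of observations assigned to Q_k
    under *every* mode among those assigned to Q_k under at least one mode.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assignments to compare")
    arrs = [np.asarray(a, dtype=int) for a in assignments]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("assignments must cover the same observations")
    out = {}
    for k in range(1, 5):
        in_k = np.stack([a == k for a in arrs])
        union = np.any(in_k, axis=0).sum()
        inter = np.all(in_k, axis=0).sum()
        out[k] = float(inter / union) if union else float("nan")
    return out
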