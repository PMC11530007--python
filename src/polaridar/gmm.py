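"""UMAP embedding plus Gaussian-mixture clustering with BIC model selection.

The feature matrix is first reduced to three dimensions with UMAP
(min_dist = 0.01 for tight grouping, n_neighbors = 199 - clamped to n-1 on
small inputs - to balance local and global structure, Euclidean metric).
Full-covariance Gaussian mixtures are then fitted over a grid of component
counts and the solution minimizing the Bayesian information criterion

    BIC = ln(n) k - 2 ln(L)

is kept, where k counts all free mixture parameters (weights, means, full
covariances).  The Akaike criterion AIC = 2k - 2 ln(L) is recorded alongside;
BIC penalizes parameters more strongly and so tends to select fewer
components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .diversity import ClusterSolution

#: component-count scan used at full scale (the desk-scale demos use smaller grids)
FULL_SCAN_KMIN = 55
FULL_SCAN_KMAX = 555
FULL_SCAN_STEP = 10


@dataclass(frozen=True)
class EmbeddingConfig:
    n_components: int = 3
    min_dist: float = 0.01
    n_neighbors: int = 199
    metric: str = "euclidean"
    seed: int = 0


@dataclass
class MixtureScanResult:
    k_grid: np.ndarray
    bic: np.ndarray
    aic: np.ndarray
    best_k_bic: int
    best_k_aic: int
    labels: np.ndarray  # maximum-posterior labels under the BIC-optimal model
    log_likelihoods: np.ndarray = field(default_factory=lambda: np.empty(0))


def embed(X: np.ndarray, cfg: EmbeddingConfig | None = None) -> np.ndarray:
    """Three-dimensional UMAP embedding of the feature matrix.

    Deterministic given ``cfg.seed`` (a fixed random_state forces
    single-threaded layout).  ``n_neighbors`` is clamped to n-1 with a
    warning when the input is smaller than the configured neighborhood.
    """
    import umap  # deferred: numba compilation is expensive at import time

    cfg = cfg or EmbeddingConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("X must be a 2-D matrix with at least 3 rows")
    n_neighbors = cfg.n_neighbors
    if n_neighbors >= X.shape[0]:
        n_neighbors = X.shape[0] - 1
        warnings.warn(
            f"n_neighbors clamped to {n_neighbors} for n={X.shape[0]}",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; intended
        warnings.filterwarnings("ignore", message=".*random_state.*")
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        reducer = umap.UMAP(
            n_components=cfg.n_components,
            min_dist=cfg.min_dist,
            n_neighbors=n_neighbors,
            metric=cfg.metric,
            random_state=cfg.seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def information_criteria(log_likelihood: float, k_params: int, n: int) -> tuple[float, float]:
    """(BIC, AIC) from a maximized log-likelihood and a free-parameter count."""
    if n < 1 or k_params < 1:
        raise ValueError("n and k_params must be positive")
    bic = math.log(n) * k_params - 2.0 * log_likelihood
    aic = 2.0 * k_params - 2.0 * log_likelihood
    return bic, aic


def gmm_param_count(n_components: int, n_features: int = 3) -> int:
    """Free parameters of a full-covariance mixture: weights + means + covariances."""
    cov = n_features * (n_features + 1) // 2
    return (n_components - 1) + n_components * n_features + n_components * cov


def fit_gmm_scan(
    Y: np.ndarray,
    k_min: int,
    k_max: int,
    seed: int = 0,
    step: int = 1,
) -> MixtureScanResult:
    """Scan mixture component counts and select by BIC.

    Each count is fitted once (single replicate) with full covariances,
    covariance regularization 1e-6, at most 100 EM iterations and tolerance
    1e-3, using a per-count seed derived from ``seed`` so the scan is
    reproducible.  Counts whose fit fails are recorded as non-finite and
    excluded from the argmin.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if not (1 <= k_min <= k_max < n):
        raise ValueError("require 1 <= k_min <= k_max < n")
    k_grid = np.arange(k_min, k_max + 1, step)
    bic = np.full(k_grid.size, np.nan)
    aic = np.full(k_grid.size, np.nan)
    lls = np.full(k_grid.size, np.nan)
    models: dict[int, GaussianMixture] = {}
    for i, k in enumerate(k_grid):
        try:
            gm = GaussianMixture(
                n_components=int(k),
                covariance_type="full",
                reg_covar=1e-6,
                max_iter=100,
                tol=1e-3,
                n_init=1,
                random_state=(seed + 7919 * int(k)) % (2**31),
            )
            gm.fit(Y)
            ll = float(gm.score(Y) * n)
        except Exception:
            continue
        lls[i] = ll
        bic[i], aic[i] = information_criteria(ll, gmm_param_count(int(k), Y.shape[1]), n)
        models[int(k)] = gm
    if not np.any(np.isfinite(bic)):
        raise RuntimeError("every mixture fit in the scan failed")
    best_k_bic = int(k_grid[np.nanargmin(bic)])
    best_k_aic = int(k_grid[np.nanargmin(aic)])
    labels = models[best_k_bic].predict(Y)
    return MixtureScanResult(
        k_grid=k_grid,
        bic=bic,
        aic=aic,
        best_k_bic=best_k_bic,
        best_k_aic=best_k_aic,
        labels=labels,
        log_likelihoods=lls,
    )


def cluster_gmm(
    X: np.ndarray,
    k_min: int,
    k_max: int,
    seed: int = 0,
    step: int = 1,
    mode: str = "unpol",
    cfg: EmbeddingConfig | None = None,
) -> ClusterSolution:
    """Embed the feature matrix and cluster it with a BIC-selected mixture."""
    cfg = cfg or EmbeddingConfig(seed=seed)
    Y = embed(X, cfg)
    scan = fit_gmm_scan(Y, k_min=k_min, k_max=k_max, seed=seed, step=step)
    return ClusterSolution(
        labels=scan.labels,
        method="gmm",
        mode=mode,
        extras={
            "k_grid": scan.k_grid,
            "bic": scan.bic,
            "aic": scan.aic,
            "best_k_bic": scan.best_k_bic,
            "best_k_aic": scan.best_k_aic,
            "embedding": Y,
        },
    )
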