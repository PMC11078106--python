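"""Hotspot detection: Gaussian-mixture fits, CH-index model selection,
Mahalanobis outlier exclusion, and per-cluster composition.

Ribbon-synapse x–y coordinates are fit with mixtures of K = 2..10 full-
covariance Gaussians; the best K maximizes the Calinski–Harabasz index
computed on hard (argmax-responsibility) assignments,

    CH = [Σ_k n_k ‖c_k − c‖² / (K−1)] / [Σ_k Σ_{i∈k} ‖d_i − c_k‖² / (N−K)],

where c is the global centroid and n_k, c_k the size and centroid of
cluster k.  Points whose Mahalanobis distance d = sqrt((x−µ) Σ⁻¹ (x−µ)ᵀ)
exceeds 3 SD from *every* component are flagged as outliers and excluded
from composition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .model import SynapseRecord


class InsufficientDataError(ValueError):
    """Too few points for the requested number of components."""


@dataclass
class ClusterComponent:
    weight: float
    mean: np.ndarray  # (2,), µm
    covariance: np.ndarray  # (2, 2), µm², symmetric positive-definite


@dataclass
class ClusterModel:
    """A fitted K-component mixture with hard labels in 1..K."""

    K: int
    components: list[ClusterComponent]
    assignments: np.ndarray  # per-point labels, 1..K
    ch_index: float
    log_likelihood: float  # total log-likelihood of the data
    outlier_mask: np.ndarray  # True = outlier (set by flag_outliers)
    seed: int

    def component_sds(self) -> list[float]:
        """Geometric-mean standard deviation per component (µm)."""
        return [float(np.linalg.det(c.covariance) ** 0.25) for c in self.components]


def fit_gmm(points: np.ndarray, K: int, n_restarts: int = 10, seed: int = 0) -> ClusterModel:
    """EM fit of a K-component full-covariance mixture; best of restarts.

    k-means++-style initialization, convergence at mean log-likelihood
    change < 1e-8, diagonal regularization 1e-6 scaled to the data's
    average variance.  Deterministic given ``seed``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if K < 1:
        raise ValueError("K must be ≥ 1")
    if n < 2 * K:
        raise InsufficientDataError(f"{n} points cannot support K={K} (need ≥ {2 * K})")
    scale = float(np.var(pts, axis=0).mean())
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        tol=1e-8,
        max_iter=500,
        reg_covar=1e-6 * max(scale, 1e-12),
        random_state=seed,
    )
    labels0 = gm.fit_predict(pts)
    components = [
        ClusterComponent(float(w), m.copy(), c.copy())
        for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_)
    ]
    labels = labels0 + 1  # public labels are 1..K
    if K >= 2 and len(np.unique(labels0)) == K:
        ch = ch_index(pts, gm.means_, labels0)
    else:
        ch = float("nan")
    return ClusterModel(
        K=K,
        components=components,
        assignments=labels,
        ch_index=ch,
        log_likelihood=float(gm.score(pts) * n),
        outlier_mask=np.zeros(n, dtype=bool),
        seed=seed,
    )


def ch_index(points: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index of a hard partition.

    ``labels`` index rows of ``centroids`` (0-based).  Requires K ≥ 2,
    N > K, every cluster non-empty.  Zero within-cluster dispersion
    returns +inf.
    """
    pts = np.asarray(points, dtype=float)
    cents = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels)
    N, K = len(pts), len(cents)
    if K < 2:
        raise ValueError("CH index needs K ≥ 2")
    if N <= K:
        raise ValueError("CH index needs N > K")
    c = pts.mean(axis=0)
    between = 0.0
    within = 0.0
    for k in range(K):
        members = pts[labels == k]
        if len(members) == 0:
            raise ValueError(f"cluster {k} is empty")
        between += len(members) * float(np.sum((cents[k] - c) ** 2))
        within += float(np.sum((members - cents[k]) ** 2))
    if within == 0.0:
        return float("inf")
    return (between / (K - 1)) / (within / (N - K))


def select_components(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[ClusterModel, dict[int, float]]:
    """Fit K = k_min..k_max and return the CH-maximizing model.

    CH is evaluated on hard assignments, with cluster centroids taken as
    the empirical centroids of the assigned points (the partition the
    printed formula is defined on).  Ties break toward smaller K; K
    values whose fit failed or produced an empty cluster are skipped and
    recorded as NaN in the returned table.  The winning model is flagged
    ``low_contrast`` when max CH < 2× median CH over the scanned K —
    the signature of data without a pronounced interior optimum.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if k_min < 2:
        raise ValueError("k_min must be ≥ 2")
    if k_max < k_min:
        raise ValueError("k_max must be ≥ k_min")
    if len(pts) < 2 * k_min:
        raise InsufficientDataError(f"{len(pts)} points cannot support K={k_min}")
    ch_by_k: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for K in range(k_min, k_max + 1):
        try:
            m = fit_gmm(pts, K, n_restarts=n_restarts, seed=seed)
        except (InsufficientDataError, ValueError):
            ch_by_k[K] = float("nan")
            continue
        labels0 = m.assignments - 1
        used = np.unique(labels0)
        if len(used) < K:  # degenerate fit left empty hard clusters
            ch_by_k[K] = float("nan")
            continue
        cents = np.stack([pts[labels0 == k].mean(axis=0) for k in range(K)])
        m.ch_index = ch_index(pts, cents, labels0)
        ch_by_k[K] = m.ch_index
        models[K] = m
    if not models:
        raise RuntimeError("every mixture fit failed in the scanned K range")
    best_k = max(sorted(models), key=lambda k: (ch_by_k[k], -k))
    best = models[best_k]
    finite = [v for v in ch_by_k.values() if np.isfinite(v)]
    best.low_contrast = bool(np.max(finite) < 2.0 * np.median(finite))  # type: ignore[attr-defined]
    return best, ch_by_k


def mahalanobis_distance(x: np.ndarray, component: ClusterComponent) -> float:
    """Distance of x from the component mean in standard-deviation units."""
    x = np.asarray(x, dtype=float)
    diff = x - component.mean
    cov = component.covariance
    det = np.linalg.det(cov)
    if det <= 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError("covariance is singular")
    return float(np.sqrt(diff @ np.linalg.solve(cov, diff)))


def flag_outliers(points: np.ndarray, model: ClusterModel, threshold: float = 3.0) -> np.ndarray:
    """Mask of points farther than ``threshold`` SD from *every* component.

    A point must exceed the bound of all clusters to be excluded; the mask
    is stored on the model and returned.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    inv = [np.linalg.inv(c.covariance) for c in model.components]
    mask = np.empty(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        dmin = min(
            float(np.sqrt((p - c.mean) @ vi @ (p - c.mean)))
            for c, vi in zip(model.components, inv)
        )
        mask[i] = dmin > threshold
    model.outlier_mask = mask
    return mask


def cluster_composition(
    synapses: list[SynapseRecord], model: ClusterModel
) -> dict[int, dict[str, float]]:
    """Per-cluster presynaptic-type proportions over non-outlier members.

    ``synapses`` must align with the points the model was fit on.
    Clusters emptied by outlier removal map to an empty dict.
    """
    if len(synapses) != len(model.assignments):
        raise ValueError("synapse list does not align with model assignments")
    out: dict[int, dict[str, float]] = {k: {} for k in range(1, model.K + 1)}
    counts: dict[int, dict[str, int]] = {k: {} for k in range(1, model.K + 1)}
    for s, label, is_out in zip(synapses, model.assignments, model.outlier_mask):
        if is_out:
            continue
        c = counts[int(label)]
        c[s.pre_type] = c.get(s.pre_type, 0) + 1
    for k, c in counts.items():
        total = sum(c.values())
        if total:
            out[k] = {t: n / total for t, n in sorted(c.items())}
    return out
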