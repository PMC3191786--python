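"""Sign- and scale-invariant clustering of spatial filters.

CSP filters are defined only up to sign and length, so they live on the
unit hypersphere with antipodal points identified.  The natural metric is
the squared sine of the angle between two filters,

    d(v1, v2) = 1 - (v1'v2)^2 / ((v1'v1)(v2'v2)),

which is zero for parallel or antiparallel filters and maximal (1) for
orthogonal ones.  Clustering alternates a nearest-center assignment with a
center update: the center of a cluster is the principal eigenvector of the
scatter ``sum_s v_s v_s'`` of its (unit-norm) members, which maximizes the
within-cluster sum of squared cosines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterModel",
    "angle_distance",
    "assign_step",
    "update_center",
    "cluster_filters",
]


def angle_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Squared sine of the angle between two direction vectors, in [0, 1]."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    n1 = v1 @ v1
    n2 = v2 @ v2
    if n1 == 0 or n2 == 0:
        raise ValueError("angle distance undefined for zero vectors")
    c2 = (v1 @ v2) ** 2 / (n1 * n2)
    return float(np.clip(1.0 - c2, 0.0, 1.0))


def assign_step(filters: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Binary S x K membership matrix: each filter to its nearest center.

    Nearest in the squared-sine metric (equivalently, largest squared
    cosine); ties break to the lowest cluster index.
    """
    filters = np.atleast_2d(np.asarray(filters, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    S, K = filters.shape[0], centers.shape[0]
    alpha = np.zeros((S, K), dtype=int)
    for s in range(S):
        dists = [angle_distance(filters[s], centers[k]) for k in range(K)]
        alpha[s, int(np.argmin(dists))] = 1  # argmin takes the first minimum
    return alpha


def update_center(members: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the member scatter ``sum_s v_s v_s'``.

    Members are assumed unit norm; the returned center is unit norm with a
    deterministic sign (largest-magnitude component positive).
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.shape[0] == 0:
        raise ValueError("cannot update the center of an empty cluster")
    scatter = members.T @ members
    vals, vecs = np.linalg.eigh(scatter)
    w = vecs[:, -1]
    i = int(np.argmax(np.abs(w)))
    if w[i] < 0:
        w = -w
    return w / np.linalg.norm(w)


def _objective(filters: np.ndarray, centers: np.ndarray, alpha: np.ndarray) -> float:
    # total within-cluster squared cosine (maximization form)
    total = 0.0
    for s in range(filters.shape[0]):
        k = int(np.argmax(alpha[s]))
        total += 1.0 - angle_distance(filters[s], centers[k])
    return total


@dataclass
class ClusterModel:
    """Hypersphere clustering of S filters into K clusters.

    ``centers`` are K unit vectors; ``assignments`` is the binary S x K
    membership matrix (rows sum to 1); ``objective`` is the total
    within-cluster squared cosine, which the alternating algorithm never
    decreases.
    """

    centers: np.ndarray
    assignments: np.ndarray
    objective: float
    n_iter: int

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.assignments, axis=1)


def _update_all_centers(
    filters: np.ndarray, K: int, alpha: np.ndarray
) -> np.ndarray:
    """Centers for all K clusters, repairing empty ones.

    An empty cluster is reseeded with the filter farthest (angle metric)
    from the center of the cluster it currently belongs to, drawn from a
    cluster with more than one member.
    """
    S, d = filters.shape
    centers = np.zeros((K, d))
    repaired = False
    sizes = alpha.sum(axis=0)
    for k in np.flatnonzero(sizes > 0):
        centers[k] = update_center(filters[alpha[:, k] == 1])
    for k in np.flatnonzero(sizes == 0):
        repaired = True
        far_s, far_d = -1, -1.0
        for s in range(S):
            j = int(np.argmax(alpha[s]))
            if alpha[:, j].sum() <= 1:
                continue
            dist = angle_distance(filters[s], centers[j])
            if dist > far_d:
                far_s, far_d = s, dist
        if far_s < 0:  # all clusters singletons; take any filter
            far_s = int(np.argmax(alpha[:, 0]))
        alpha[far_s] = 0
        alpha[far_s, k] = 1
        centers[k] = filters[far_s]
        sizes = alpha.sum(axis=0)
    return centers, repaired


def _single_run(
    filters: np.ndarray,
    K: int,
    alpha: np.ndarray,
    max_iter: int,
) -> ClusterModel:
    obj_prev = -np.inf
    alpha = alpha.copy()
    for it in range(1, max_iter + 1):
        centers, repaired = _update_all_centers(filters, K, alpha)
        new_alpha = assign_step(filters, centers)
        obj = _objective(filters, centers, new_alpha)
        # repair moves a member by fiat, which may transiently lower the score
        assert repaired or obj >= obj_prev - 1e-10, "clustering objective decreased"
        if np.array_equal(new_alpha, alpha):
            return ClusterModel(centers, alpha, obj, it)
        alpha, obj_prev = new_alpha, obj
    return ClusterModel(centers, alpha, obj, max_iter)


def cluster_filters(
    filters: np.ndarray,
    K: int,
    init: np.ndarray | int | None = None,
    max_iter: int = 100,
    n_restarts: int = 8,
) -> ClusterModel:
    """Cluster S spatial filters into K groups on the unit hypersphere.

    Parameters
    ----------
    filters : (S, d) array
        Input filters; normalized to unit norm on entry.
    K : int
        Number of clusters, ``1 <= K <= S``.
    init : array or int or None
        Either an explicit initial assignment (length-S label vector or
        S x K binary matrix), or an integer seed for random initialization
        (K distinct filters as seed centers).  ``None`` seeds with 0.
    max_iter : int
        Cap on assignment/update sweeps per restart.
    n_restarts : int
        Number of seeded random restarts (best objective kept) when no
        explicit assignment is given; the alternating scheme only finds a
        local optimum, so restarts matter for small separations.
    """
    filters = np.atleast_2d(np.asarray(filters, dtype=float))
    norms = np.linalg.norm(filters, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero filter cannot be clustered")
    filters = filters / norms
    S = filters.shape[0]
    if not 1 <= K <= S:
        raise ValueError(f"need 1 <= K <= S, got K={K}, S={S}")

    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        init = np.asarray(init)
        if init.ndim == 1:
            alpha = np.zeros((S, K), dtype=int)
            alpha[np.arange(S), init.astype(int)] = 1
        else:
            alpha = init.astype(int)
        if alpha.shape != (S, K) or not np.all(alpha.sum(axis=1) == 1):
            raise ValueError("invalid initial assignment")
        return _single_run(filters, K, alpha, max_iter)

    seed = 0 if init is None else int(init)
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(S, size=K, replace=False)
        alpha = assign_step(filters, filters[idx])
        model = _single_run(filters, K, alpha, max_iter)
        if best is None or model.objective > best.objective + 1e-12:
            best = model
    return best
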