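"""Cluster-based multisubject CSP (clmtCSP).

The single shared filter of mtCSP assumes all subjects are similar.  Here
subjects are grouped into K clusters, each with its own shared filter
``w_k`` and per-subject deviations ``v_sk`` (``w_sk = w_k + v_sk``), and
the method alternates two steps:

1. assignment — each subject joins the cluster with the largest penalized
   quotient

       (w_sl' S1_s w_sl) / (w_sl' S2_s w_sl + l1 ||w_l||^2 + l2 ||v_sl||^2),

   where for non-member clusters ``v_sl`` is first optimized with ``w_l``
   held fixed (a restricted Newton solve over the ``v`` block);

2. refit — mtCSP is run on the members of each cluster, warm-started from
   the current ``w_k`` and ``v_sk``.

Initialization uses the hypersphere clustering of the per-subject bCSP
filters: cluster centers become the ``w_k``, and ``v_sk`` is the
(sign-aligned) difference between a member's bCSP filter and its center.
An explicit initial assignment can be passed instead.  The two class
directions are fitted independently, each with its own assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import cluster_filters, update_center
from .csp import fit_bcsp
from .mtcsp import (
    MultiSubjectModel,
    StackedFilter,
    build_augmented,
    fit_mtcsp_direction,
    gradient,
    hessian,
    objective_terms,
)
from .trials import CovariancePair

__all__ = [
    "ClusteredMSModel",
    "score_subject_against_cluster",
    "clmt_assign_step",
    "fit_clmtcsp_direction",
    "fit_clmtcsp",
    "ClusteredMultiSubjectCSP",
    "ClusteredMultiSubjectCSPResults",
]


def penalized_quotient(
    cp: CovariancePair, w_l: np.ndarray, v: np.ndarray, lambda1: float, lambda2: float
) -> float:
    """The assignment-rule score for one subject against one cluster."""
    u = w_l + v
    den = float(u @ cp.sigma2 @ u) + lambda1 * float(w_l @ w_l) + lambda2 * float(v @ v)
    if den <= 0:
        raise ValueError("nonpositive denominator in penalized quotient")
    return float(u @ cp.sigma1 @ u) / den


def score_subject_against_cluster(
    cp: CovariancePair,
    w_l: np.ndarray,
    lambda1: float,
    lambda2: float,
    v_init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Best subject-specific part ``v`` for a fixed cluster filter ``w_l``.

    Maximizes the penalized quotient over ``v`` only, using a damped Newton
    iteration on the ``v`` block of the stacked single-subject problem
    (the problem is not scale invariant once ``w_l`` is fixed, so no
    renormalization is applied).  Returns ``(v, score)``.
    """
    w_l = np.asarray(w_l, dtype=float).ravel()
    d = w_l.size
    ap = build_augmented([cp], lambda1, lambda2)
    v = np.zeros(d) if v_init is None else np.asarray(v_init, dtype=float).ravel().copy()

    def full(vv: np.ndarray) -> np.ndarray:
        return np.concatenate([w_l, vv])

    score = objective_terms(full(v), ap).value
    for _ in range(max_iter):
        w = full(v)
        g = gradient(w, ap)[d:]
        H = hessian(w, ap)[d:, d:]
        try:
            p = -np.linalg.solve(H - 1e-10 * np.eye(d), g)
        except np.linalg.LinAlgError:
            p = g.copy()
        if p @ g <= 0:
            p = g.copy()
        t, improved = 1.0, False
        while t > 1e-14:
            cand = v + t * p
            try:
                cand_score = objective_terms(full(cand), ap).value
            except ValueError:
                cand_score = -np.inf
            if cand_score > score:
                v, score, improved = cand, cand_score, True
                break
            t *= 0.5
        if not improved or np.linalg.norm(t * p) < tol:
            break
    if not np.isfinite(score):
        raise FloatingPointError("non-finite score in restricted optimization")
    return v, score


def clmt_assign_step(scores: np.ndarray) -> np.ndarray:
    """Binary S x K assignment maximizing the per-subject score.

    Ties break to the lowest cluster index.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    S, K = scores.shape
    alpha = np.zeros((S, K), dtype=int)
    alpha[np.arange(S), np.argmax(scores, axis=1)] = 1
    return alpha


@dataclass
class ClusteredMSModel:
    """Fitted clmtCSP for one class direction.

    ``w_k[k]`` is the shared filter of cluster ``k``; ``v_sk[s]`` the
    specific part of subject ``s`` for its assigned cluster; ``alpha`` the
    binary assignment; ``scores[s]`` the achieved penalized quotient.
    """

    w_k: list[np.ndarray]
    v_sk: list[np.ndarray]
    alpha: np.ndarray
    scores: np.ndarray
    objective: float
    log: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def S(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.alpha, axis=1)

    def effective_filter(self, s: int) -> np.ndarray:
        """``w_sk = w_k + v_sk`` for subject ``s`` (1-based), assigned k."""
        k = int(self.labels[s - 1])
        return self.w_k[k] + self.v_sk[s - 1]


def _align(f: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return f if f @ ref >= 0 else -f


def _initial_state(
    cov_pairs: list[CovariancePair],
    K: int,
    init: np.ndarray | None,
    seed: int,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Initial (alpha, w_k, v_sk) from clustered bCSP filters."""
    S = len(cov_pairs)
    filters = np.vstack(
        [fit_bcsp(cp, n_per_class=1, ridge=True).for_class(1)[0] for cp in cov_pairs]
    )
    if init is None:
        model = cluster_filters(filters, K, init=seed)
        alpha = model.assignments
        centers = [model.centers[k].copy() for k in range(K)]
    else:
        init = np.asarray(init)
        if init.ndim == 1:
            alpha = np.zeros((S, K), dtype=int)
            alpha[np.arange(S), init.astype(int)] = 1
        else:
            alpha = init.astype(int)
        if alpha.shape != (S, K) or not np.all(alpha.sum(axis=1) == 1):
            raise ValueError("invalid initial assignment")
        # honor the requested assignment exactly; centers from its members
        centers = []
        for k in range(K):
            members = filters[alpha[:, k] == 1]
            if members.shape[0] == 0:
                raise ValueError(f"initial assignment leaves cluster {k} empty")
            centers.append(update_center(members))
    v_sk = []
    for s in range(S):
        k = int(np.argmax(alpha[s]))
        f = _align(filters[s], centers[k])
        v_sk.append(f - centers[k])
    return alpha, centers, v_sk


def fit_clmtcsp_direction(
    cov_pairs: list[CovariancePair],
    K: int,
    lambda1: float,
    lambda2: float,
    init: np.ndarray | None = None,
    seed: int = 0,
    max_outer: int = 20,
    newton_opts: dict | None = None,
) -> ClusteredMSModel:
    """Alternating assignment / per-cluster mtCSP refit for one direction."""
    S = len(cov_pairs)
    if not 1 <= K <= S:
        raise ValueError(f"need 1 <= K <= S, got K={K}, S={S}")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("trade-off parameters must be nonnegative")
    newton_opts = newton_opts or {}

    alpha, w_k, v_sk = _initial_state(cov_pairs, K, init, seed)
    log: list[dict] = []
    converged = False
    scores = np.zeros((S, K))

    for outer in range(1, max_outer + 1):
        # (2) per-cluster mtCSP refit on current members, warm-started
        for k in range(K):
            members = np.flatnonzero(alpha[:, k] == 1)
            if members.size == 0:
                continue
            sf = StackedFilter.from_parts(w_k[k], [v_sk[s] for s in members])
            model = fit_mtcsp_direction(
                [cov_pairs[s] for s in members],
                lambda1,
                lambda2,
                init=sf,
                **newton_opts,
            )
            w_k[k] = model.w0
            for j, s in enumerate(members):
                v_sk[s] = model.v[j]

        # (1) score every subject against every cluster
        v_trial = [[None] * K for _ in range(S)]
        for s in range(S):
            own = int(np.argmax(alpha[s]))
            for k in range(K):
                if k == own:
                    v_trial[s][k] = v_sk[s]
                    scores[s, k] = penalized_quotient(
                        cov_pairs[s], w_k[k], v_sk[s], lambda1, lambda2
                    )
                else:
                    v, sc = score_subject_against_cluster(
                        cov_pairs[s], w_k[k], lambda1, lambda2, v_init=None
                    )
                    v_trial[s][k] = v
                    scores[s, k] = sc

        new_alpha = clmt_assign_step(scores)
        # empty-cluster repair: move the worst-scoring subject of any
        # populated cluster into the empty one
        for k in np.flatnonzero(new_alpha.sum(axis=0) == 0):
            assigned = np.argmax(new_alpha, axis=1)
            movable = [
                s for s in range(S) if new_alpha[:, assigned[s]].sum() > 1
            ]
            worst = min(movable, key=lambda s: scores[s, assigned[s]])
            new_alpha[worst] = 0
            new_alpha[worst, k] = 1

        total = float(
            sum(scores[s, int(np.argmax(new_alpha[s]))] for s in range(S))
        )
        log.append({"outer": outer, "objective": total,
                    "n_changed": int((new_alpha != alpha).any(axis=1).sum())})
        stable = np.array_equal(new_alpha, alpha)
        # adopt the trial v for subjects that changed cluster
        for s in range(S):
            k_new = int(np.argmax(new_alpha[s]))
            v_sk[s] = np.asarray(v_trial[s][k_new], dtype=float)
        alpha = new_alpha
        if stable:
            converged = True
            break

    final_scores = np.array(
        [
            penalized_quotient(
                cov_pairs[s], w_k[int(np.argmax(alpha[s]))], v_sk[s], lambda1, lambda2
            )
            for s in range(S)
        ]
    )
    return ClusteredMSModel(
        w_k=[w.copy() for w in w_k],
        v_sk=[v.copy() for v in v_sk],
        alpha=alpha,
        scores=final_scores,
        objective=float(final_scores.sum()),
        log=log,
        converged=converged,
    )


def fit_clmtcsp(
    cov_pairs: list[CovariancePair],
    K: int,
    lambda1: float,
    lambda2: float,
    init: np.ndarray | None = None,
    seed: int = 0,
    max_outer: int = 20,
    newton_opts: dict | None = None,
) -> dict[int, ClusteredMSModel]:
    """Fit clmtCSP for both class directions (independent assignments)."""
    out = {
        1: fit_clmtcsp_direction(
            cov_pairs, K, lambda1, lambda2, init, seed, max_outer, newton_opts
        )
    }
    swapped = [cp.swapped() for cp in cov_pairs]
    out[2] = fit_clmtcsp_direction(
        swapped, K, lambda1, lambda2, init, seed, max_outer, newton_opts
    )
    return out


class ClusteredMultiSubjectCSP:
    """Cluster-based multisubject CSP model.

    Parameters
    ----------
    cov_pairs : list of CovariancePair
        One per subject.
    K : int
        Number of clusters of similar subjects.
    lambda1, lambda2 : float
        Trade-off between cluster-shared and subject-specific filter parts.
    """

    def __init__(self, cov_pairs: list[CovariancePair], K: int,
                 lambda1: float = 0.0, lambda2: float = 0.0):
        self.cov_pairs = list(cov_pairs)
        self.K = int(K)
        self.lambda1 = float(lambda1)
        self.lambda2 = float(lambda2)

    def fit(self, init: np.ndarray | None = None, seed: int = 0,
            max_outer: int = 20) -> "ClusteredMultiSubjectCSPResults":
        models = fit_clmtcsp(self.cov_pairs, self.K, self.lambda1, self.lambda2,
                             init=init, seed=seed, max_outer=max_outer)
        return ClusteredMultiSubjectCSPResults(model=self, directions=models)


@dataclass
class ClusteredMultiSubjectCSPResults:
    model: ClusteredMultiSubjectCSP
    directions: dict[int, ClusteredMSModel]

    @property
    def S(self) -> int:
        return self.directions[1].S

    def subject_filter_matrix(self, s: int) -> np.ndarray:
        """Rows = the class-1 and class-2 filters of subject ``s`` (1-based)."""
        return np.vstack(
            [self.directions[1].effective_filter(s),
             self.directions[2].effective_filter(s)]
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cluster-based multisubject CSP (clmtCSP) results",
            "------------------------------------------------",
            f"subjects: {self.S}   clusters: {m.K}   "
            f"lambda1 = {m.lambda1:g}   lambda2 = {m.lambda2:g}",
        ]
        for c in (1, 2):
            dmod = self.directions[c]
            sizes = dmod.alpha.sum(axis=0)
            lines.append(
                f"class {c} direction: objective {dmod.objective:.6f}  "
                f"cluster sizes {sizes.tolist()}  outer iters {len(dmod.log)}"
            )
        return "\n".join(lines)
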