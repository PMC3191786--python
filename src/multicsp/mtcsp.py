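"""Multisubject CSP (mtCSP): joint global + subject-specific filter learning.

Each subject ``s`` gets an effective spatial filter

    w_s = w0 + v_s,

where ``w0`` is shared across all ``S`` subjects and ``v_s`` is the
subject-specific deviation.  Both are learned at once by maximizing

    R(w) = sum_s  (w_s' S1_s w_s) / (w_s' S2_s w_s + l1 ||w0||^2 + l2 ||v_s||^2)

over the stacked vector ``w = (w0; v1; ...; vS)`` of length ``(S+1) d``.
The trade-off scalars ``l1`` and ``l2`` steer the solution between fully
shared (large ``l2``: v_s forced to zero) and fully subject-specific
(large ``l1``: w0 forced to zero) filters.

With selector matrices ``E_s`` (so that ``E_s w = w0 + v_s``) and the block
projectors ``D_0``, ``D_s`` picking out ``w0`` and ``v_s``, the objective is
a sum of ratios of quadratic forms in ``w``,

    R(w) = sum_s (w' A_s w) / (w' B_s w),
    A_s = E_s S1_s E_s',   B_s = E_s S2_s E_s' + l1 D_0 + l2 D_s,

which is maximized with a safeguarded (damped) Newton method.  R is
homogeneous of degree zero, so the iterate is renormalized to unit norm
after every step and the Newton system is solved with a small Tikhonov
shift to absorb the scale null-direction.  A backtracking line search on R
(step halving until increase) with a gradient-ascent fallback guards
against the nonconvexity of the sum of ratios; a global optimum is not
guaranteed.

Derivatives, with ``r_s = (w'A_s w)/(w'B_s w)`` and denominator
``delta_s = w'B_s w``:

    grad R  = 2 sum_s (A_s w - r_s B_s w) / delta_s
    hess R  = (2/delta_s) sum_s [ A_s - r_s B_s
                                  - (B_s w) g_s' - g_s (B_s w)' ],

where ``g_s = grad r_s``.  Both are validated against finite differences in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import fit_bcsp, fix_sign
from .trials import CovariancePair

__all__ = [
    "StackedFilter",
    "AugmentedProblem",
    "ObjectiveEval",
    "MultiSubjectModel",
    "selector_matrix",
    "penalty_projectors",
    "build_augmented",
    "objective",
    "objective_terms",
    "gradient",
    "hessian",
    "fit_mtcsp_direction",
    "fit_mtcsp",
    "MultiSubjectCSP",
    "MultiSubjectCSPResults",
]


@dataclass
class StackedFilter:
    """Stacked parameter vector ``w = (w0; v1; ...; vS)`` for S subjects.

    ``extract(s)`` returns the effective filter ``w0 + v_s`` of subject
    ``s`` (1-based).
    """

    w: np.ndarray
    S: int
    d: int

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size != (self.S + 1) * self.d:
            raise ValueError(
                f"stacked vector has length {self.w.size}, expected {(self.S + 1) * self.d}"
            )

    @classmethod
    def from_parts(cls, w0: np.ndarray, vs: list[np.ndarray]) -> "StackedFilter":
        w0 = np.asarray(w0, dtype=float).ravel()
        parts = [w0] + [np.asarray(v, dtype=float).ravel() for v in vs]
        return cls(np.concatenate(parts), S=len(vs), d=w0.size)

    @property
    def w0(self) -> np.ndarray:
        return self.w[: self.d]

    def v(self, s: int) -> np.ndarray:
        self._check(s)
        return self.w[s * self.d : (s + 1) * self.d]

    def extract(self, s: int) -> np.ndarray:
        """Effective filter ``w0 + v_s`` of subject ``s`` (1-based)."""
        return self.w0 + self.v(s)

    def _check(self, s: int) -> None:
        if not 1 <= s <= self.S:
            raise IndexError(f"subject index {s} out of range 1..{self.S}")


def selector_matrix(s: int, S: int, d: int) -> np.ndarray:
    """Block row ``E_s = [I, 0, ..., I, ..., 0]`` with ``E_s w = w0 + v_s``."""
    if not 1 <= s <= S:
        raise IndexError(f"subject index {s} out of range 1..{S}")
    E = np.zeros((d, (S + 1) * d))
    E[:, :d] = np.eye(d)
    E[:, s * d : (s + 1) * d] = np.eye(d)
    return E


def penalty_projectors(S: int, d: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Orthogonal projectors onto the ``w0`` block and each ``v_s`` block.

    ``w' D_0 w = ||w0||^2`` and ``w' D_s w = ||v_s||^2``; the projectors are
    idempotent, mutually orthogonal, and sum to the identity.
    """
    if S < 1 or d < 1:
        raise ValueError("S and d must be >= 1")
    n = (S + 1) * d
    D0 = np.zeros((n, n))
    D0[:d, :d] = np.eye(d)
    Ds = []
    for s in range(1, S + 1):
        D = np.zeros((n, n))
        D[s * d : (s + 1) * d, s * d : (s + 1) * d] = np.eye(d)
        Ds.append(D)
    return D0, Ds


@dataclass
class AugmentedProblem:
    """Per-subject quadratic-form matrices of the stacked mtCSP objective.

    ``sigma1_bar[s] = E_s S1_s E_s'`` and
    ``sigma2_bar[s] = E_s S2_s E_s' + l1 D_0 + l2 D_s``; the latter is
    positive definite whenever both trade-off parameters are positive.
    """

    sigma1_bar: list[np.ndarray]
    sigma2_bar: list[np.ndarray]
    S: int
    d: int
    lambda1: float
    lambda2: float

    @property
    def dim(self) -> int:
        return (self.S + 1) * self.d


def build_augmented(
    cov_pairs: list[CovariancePair], lambda1: float, lambda2: float
) -> AugmentedProblem:
    """Lift per-subject covariance pairs into the stacked ``(S+1)d`` space."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("trade-off parameters must be nonnegative")
    S = len(cov_pairs)
    if S == 0:
        raise ValueError("need at least one subject")
    d = cov_pairs[0].d
    if any(cp.d != d for cp in cov_pairs):
        raise ValueError("all subjects must share the channel count d")
    D0, Ds = penalty_projectors(S, d)
    s1bar, s2bar = [], []
    for s, cp in enumerate(cov_pairs, start=1):
        E = selector_matrix(s, S, d)
        s1bar.append(E.T @ cp.sigma1 @ E)
        s2bar.append(E.T @ cp.sigma2 @ E + lambda1 * D0 + lambda2 * Ds[s - 1])
    return AugmentedProblem(s1bar, s2bar, S, d, lambda1, lambda2)


@dataclass
class ObjectiveEval:
    """Objective value with per-subject breakdown and derivatives."""

    value: float
    ratios: np.ndarray
    denominators: np.ndarray
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None


def _as_vector(w, ap: AugmentedProblem) -> np.ndarray:
    if isinstance(w, StackedFilter):
        w = w.w
    w = np.asarray(w, dtype=float).ravel()
    if w.size != ap.dim:
        raise ValueError(f"stacked vector length {w.size}, expected {ap.dim}")
    return w


def objective_terms(w, ap: AugmentedProblem) -> ObjectiveEval:
    """Evaluate ``R(w)`` with per-subject ratios and denominators."""
    w = _as_vector(w, ap)
    ratios = np.empty(ap.S)
    denoms = np.empty(ap.S)
    for s in range(ap.S):
        num = float(w @ ap.sigma1_bar[s] @ w)
        den = float(w @ ap.sigma2_bar[s] @ w)
        if den <= 0:
            raise ValueError(
                f"nonpositive denominator for subject {s + 1}; with "
                "lambda1=lambda2=0 this signals a degenerate covariance"
            )
        ratios[s] = num / den
        denoms[s] = den
    return ObjectiveEval(value=float(ratios.sum()), ratios=ratios, denominators=denoms)


def objective(w, ap: AugmentedProblem) -> float:
    """Sum of per-subject penalized Rayleigh quotients ``R(w)``."""
    return objective_terms(w, ap).value


def gradient(w, ap: AugmentedProblem) -> np.ndarray:
    """Analytic gradient ``2 sum_s (A_s w - r_s B_s w) / delta_s``."""
    w = _as_vector(w, ap)
    ev = objective_terms(w, ap)
    g = np.zeros(ap.dim)
    for s in range(ap.S):
        g += 2.0 * (ap.sigma1_bar[s] @ w - ev.ratios[s] * (ap.sigma2_bar[s] @ w)) / ev.denominators[s]
    return g


def hessian(w, ap: AugmentedProblem) -> np.ndarray:
    """Analytic Hessian of ``R``; symmetric by construction."""
    w = _as_vector(w, ap)
    ev = objective_terms(w, ap)
    H = np.zeros((ap.dim, ap.dim))
    for s in range(ap.S):
        A, B = ap.sigma1_bar[s], ap.sigma2_bar[s]
        r, den = ev.ratios[s], ev.denominators[s]
        Bw = B @ w
        gs = 2.0 * (A @ w - r * Bw) / den
        H += (2.0 / den) * (A - r * B) - (2.0 / den) * (
            np.outer(Bw, gs) + np.outer(gs, Bw)
        )
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Safeguarded Newton maximization
# ---------------------------------------------------------------------------

_TIKHONOV = 1e-8  # relative curvature floor absorbing the scale null-direction


def _ascent_direction(H: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, str]:
    """Safeguarded Newton ascent direction ``p = -H~^{-1} g``.

    ``H~`` is ``H`` with its eigenvalues clamped to at most
    ``-_TIKHONOV * ||H||`` (modified Newton): where the Hessian is safely
    negative the true Newton step is taken; nonconcave or flat directions
    — including the scale null-direction of the degree-0 homogeneous
    objective — fall back to curvature-scaled gradient ascent.  The result
    is always an ascent direction (``p'g > 0`` whenever ``g != 0``).
    """
    try:
        evals, evecs = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        return g.copy(), "gradient"
    scale = max(float(np.abs(evals).max()), 1e-300)
    clamped = np.minimum(evals, -_TIKHONOV * scale)
    p = -evecs @ ((evecs.T @ g) / clamped)
    kind = "newton" if np.all(evals < 0) else "modified-newton"
    return p, kind


@dataclass
class MultiSubjectModel:
    """Fitted mtCSP solution for one class direction.

    Attributes
    ----------
    w0 : ndarray
        Global filter part (from the unit-norm stacked solution).
    v : list of ndarray
        Subject-specific parts.
    objective : float
        Achieved sum of penalized quotients.
    ratios : ndarray
        Per-subject achieved quotients.
    log : list of dict
        Per-iteration convergence record (objective, step norm, step type).
    converged : bool
    """

    w0: np.ndarray
    v: list[np.ndarray]
    objective: float
    ratios: np.ndarray
    log: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def S(self) -> int:
        return len(self.v)

    @property
    def d(self) -> int:
        return self.w0.size

    def effective_filter(self, s: int) -> np.ndarray:
        """``w_s = w0 + v_s`` for subject ``s`` (1-based)."""
        return self.w0 + self.v[s - 1]

    @property
    def stacked(self) -> StackedFilter:
        return StackedFilter.from_parts(self.w0, self.v)


def default_init(
    cov_pairs: list[CovariancePair], kind: str = "bcsp_mean"
) -> StackedFilter:
    """Initial stacked filter for the Newton iteration.

    ``bcsp_mean``: per-subject bCSP filters (ridge-jittered), sign-aligned
    to the first subject's filter, ``w0`` their normalized mean and
    ``v_s = f_s - w0``.  ``zeros+eps``: small constant vector, mainly for
    probing sensitivity to initialization.
    """
    d = cov_pairs[0].d
    S = len(cov_pairs)
    if kind == "zeros+eps":
        w = np.full((S + 1) * d, 1e-3)
        return StackedFilter(w, S=S, d=d)
    if kind != "bcsp_mean":
        raise ValueError(f"unknown init '{kind}'")
    filters = []
    for cp in cov_pairs:
        fs = fit_bcsp(cp, n_per_class=1, ridge=True)
        filters.append(fs.for_class(1)[0])
    ref = filters[0]
    aligned = [f if f @ ref >= 0 else -f for f in filters]
    w0 = np.mean(aligned, axis=0)
    nrm = np.linalg.norm(w0)
    if nrm < 1e-12:  # pathological cancellation; fall back to the reference
        w0 = ref.copy()
    else:
        w0 = w0 / nrm
    vs = [f - w0 for f in aligned]
    return StackedFilter.from_parts(w0, vs)


def fit_mtcsp_direction(
    cov_pairs: list[CovariancePair],
    lambda1: float,
    lambda2: float,
    init: StackedFilter | np.ndarray | str | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MultiSubjectModel:
    """Maximize the mtCSP objective for one class direction.

    ``init`` may be a stacked vector/:class:`StackedFilter`, one of the
    named schemes of :func:`default_init`, or ``None`` (= ``bcsp_mean``).
    The iterate is renormalized to unit norm each step; convergence is a
    step norm below ``tol``.
    """
    ap = build_augmented(cov_pairs, lambda1, lambda2)
    if init is None:
        init = "bcsp_mean"
    if isinstance(init, str):
        sf = default_init(cov_pairs, kind=init)
    elif isinstance(init, StackedFilter):
        sf = init
    else:
        sf = StackedFilter(np.asarray(init, dtype=float), S=ap.S, d=ap.d)
    w = sf.w / np.linalg.norm(sf.w)

    ev = objective_terms(w, ap)
    log: list[dict] = []
    converged = False
    for it in range(max_iter):
        g = gradient(w, ap)
        H = hessian(w, ap)
        p, step_type = _ascent_direction(H, g)

        # line search on R: halve until increase, then expand while the
        # objective keeps improving (guards against both overshooting and
        # crawling on badly scaled problems)
        def evaluate(t):
            cand = w + t * p
            nrm = np.linalg.norm(cand)
            if nrm == 0:
                return None, None
            cand = cand / nrm
            try:
                return cand, objective_terms(cand, ap)
            except ValueError:
                return None, None

        t = 1.0
        new_w = None
        new_ev = None
        while t > 1e-14:
            cand, cand_ev = evaluate(t)
            if cand_ev is not None and cand_ev.value >= ev.value:
                new_w, new_ev = cand, cand_ev
                break
            t *= 0.5
        if new_w is not None and t == 1.0:
            while t < 2.0**40:
                cand, cand_ev = evaluate(2.0 * t)
                if cand_ev is None or cand_ev.value <= new_ev.value:
                    break
                t *= 2.0
                new_w, new_ev = cand, cand_ev
        if new_w is None:
            converged = True  # no ascent possible along p: stationary
            log.append({"iter": it, "objective": ev.value, "step_norm": 0.0,
                        "step": step_type, "t": 0.0})
            break
        if not np.isfinite(new_ev.value):
            raise FloatingPointError(
                f"mtCSP diverged at iteration {it}: objective is not finite; "
                f"log so far: {log}"
            )
        step_norm = float(np.linalg.norm(new_w - w))
        assert new_ev.value >= ev.value - 1e-12 * (1.0 + abs(ev.value))
        w, ev = new_w, new_ev
        log.append({"iter": it, "objective": ev.value, "step_norm": step_norm,
                    "step": step_type, "t": t})
        if step_norm < tol:
            converged = True
            break

    sf = StackedFilter(w, S=ap.S, d=ap.d)
    return MultiSubjectModel(
        w0=sf.w0.copy(),
        v=[sf.v(s).copy() for s in range(1, ap.S + 1)],
        objective=ev.value,
        ratios=ev.ratios,
        log=log,
        converged=converged,
    )


def fit_mtcsp(
    cov_pairs: list[CovariancePair],
    lambda1: float,
    lambda2: float,
    init: StackedFilter | np.ndarray | str | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict[int, MultiSubjectModel]:
    """Fit mtCSP for both class directions.

    Two independent maximizations are run — class 1 over class 2, and the
    swap — producing one filter per class per subject.  Returns a dict
    ``{1: model, 2: model}`` keyed by the variance-maximized class.
    """
    out = {
        1: fit_mtcsp_direction(cov_pairs, lambda1, lambda2, init, tol, max_iter)
    }
    swapped = [cp.swapped() for cp in cov_pairs]
    out[2] = fit_mtcsp_direction(swapped, lambda1, lambda2, init, tol, max_iter)
    return out


class MultiSubjectCSP:
    """Multisubject CSP model over several subjects' class covariances.

    Parameters
    ----------
    cov_pairs : list of CovariancePair
        One per subject, all sharing the channel count.
    lambda1, lambda2 : float
        Trade-off between global (``w0``) and subject-specific (``v_s``)
        filter parts; large ``lambda1`` suppresses ``w0``, large
        ``lambda2`` suppresses the ``v_s``.
    """

    def __init__(self, cov_pairs: list[CovariancePair], lambda1: float = 0.0,
                 lambda2: float = 0.0):
        self.cov_pairs = list(cov_pairs)
        self.lambda1 = float(lambda1)
        self.lambda2 = float(lambda2)

    def fit(self, init=None, tol: float = 1e-8, max_iter: int = 200
            ) -> "MultiSubjectCSPResults":
        models = fit_mtcsp(self.cov_pairs, self.lambda1, self.lambda2,
                           init=init, tol=tol, max_iter=max_iter)
        return MultiSubjectCSPResults(model=self, directions=models)


@dataclass
class MultiSubjectCSPResults:
    """Fitted mtCSP for both class directions, with per-subject filters."""

    model: MultiSubjectCSP
    directions: dict[int, MultiSubjectModel]

    @property
    def S(self) -> int:
        return self.directions[1].S

    def subject_filters(self, s: int) -> FilterPair:
        """The two effective filters of subject ``s`` (1-based)."""
        return FilterPair(
            class1=self.directions[1].effective_filter(s),
            class2=self.directions[2].effective_filter(s),
        )

    def subject_filter_matrix(self, s: int) -> np.ndarray:
        fp = self.subject_filters(s)
        return np.vstack([fp.class1, fp.class2])

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multisubject CSP (mtCSP) results",
            "--------------------------------",
            f"subjects: {self.S}   channels: {self.directions[1].d}",
            f"lambda1 = {m.lambda1:g}   lambda2 = {m.lambda2:g}",
        ]
        for c in (1, 2):
            d = self.directions[c]
            lines.append(
                f"class {c} direction: objective {d.objective:.6f} "
                f"({len(d.log)} iterations, converged={d.converged})"
            )
            lines.append(f"  ||w0|| = {np.linalg.norm(d.w0):.4f}   "
                         f"mean ||v_s|| = {np.mean([np.linalg.norm(v) for v in d.v]):.4f}")
            for s in range(1, d.S + 1):
                lines.append(f"  subject {s}: quotient {d.ratios[s - 1]:.4f}")
        return "\n".join(lines)


@dataclass
class FilterPair:
    class1: np.ndarray
    class2: np.ndarray

    def as_list(self) -> list[np.ndarray]:
        return [self.class1, self.class2]
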