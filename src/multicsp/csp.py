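"""Basic Common Spatial Patterns (bCSP) via the generalized eigenproblem.

A CSP spatial filter ``w`` maximizes the Rayleigh quotient

    w' S1 w / w' S2 w

between the two class covariance matrices; its maximizer is the top
generalized eigenvector of ``(S1, S2)`` and the achieved ratio is the
corresponding generalized eigenvalue.  Filters for the second class come
from the same problem with the class roles swapped.

Filters are defined only up to sign and scale; here they are normalized to
unit Euclidean norm with the sign fixed so the largest-magnitude component
is positive, making results reproducible across eigensolvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .trials import CovariancePair, TrialSet, class_covariances

__all__ = ["FilterSet", "rayleigh_ratio", "fit_bcsp", "BasicCSP", "BasicCSPResults"]


@dataclass
class FilterSet:
    """A collection of spatial filters with the class each one targets.

    ``filters[i]`` is a unit-norm d-vector maximizing the variance of class
    ``target_class[i]`` relative to the other class, achieving Rayleigh
    quotient ``ratios[i]``.
    """

    filters: list[np.ndarray]
    target_class: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.filters = [np.asarray(w, dtype=float) for w in self.filters]
        self.target_class = np.asarray(self.target_class, dtype=int)
        self.ratios = np.asarray(self.ratios, dtype=float)
        for w in self.filters:
            n = np.linalg.norm(w)
            if not np.isfinite(n) or n == 0:
                raise ValueError("filters must have finite nonzero norm")
        if np.any(self.ratios < 0):
            raise ValueError("Rayleigh ratios must be nonnegative")

    def for_class(self, label: int) -> list[np.ndarray]:
        return [w for w, c in zip(self.filters, self.target_class) if c == label]

    def as_matrix(self) -> np.ndarray:
        """Filters stacked as rows, ``(n_filters, d)``."""
        return np.vstack(self.filters)


def rayleigh_ratio(w: np.ndarray, cp: CovariancePair) -> float:
    """Generalized Rayleigh quotient ``(w' S1 w) / (w' S2 w)``.

    Invariant to the sign and scale of ``w``.  Raises if the denominator is
    not strictly positive.
    """
    w = np.asarray(w, dtype=float)
    denom = float(w @ cp.sigma2 @ w)
    if denom <= 0:
        raise ValueError("denominator w' sigma2 w is not positive")
    return float(w @ cp.sigma1 @ w) / denom


def fix_sign(w: np.ndarray) -> np.ndarray:
    """Flip ``w`` so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def _top_filters(
    num: np.ndarray, den: np.ndarray, n: int, ridge: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    den_use = den
    if ridge:
        den_use = den + 1e-10 * np.trace(den) * np.eye(den.shape[0])
    try:
        vals, vecs = scipy.linalg.eigh(num, den_use)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "denominator covariance is singular; pass ridge=True to add a "
            "small regularizing jitter"
        ) from exc
    order = np.argsort(vals)[::-1][:n]
    filters = []
    for j in order:
        w = vecs[:, j]
        w = fix_sign(w / np.linalg.norm(w))
        filters.append(w)
    return filters, np.clip(vals[order], 0.0, None)


def fit_bcsp(cp: CovariancePair, n_per_class: int = 1, ridge: bool = False) -> FilterSet:
    """Fit basic CSP filters from a class-covariance pair.

    Returns ``n_per_class`` filters maximizing the class-1/class-2 variance
    ratio and ``n_per_class`` maximizing the swapped ratio.  Each achieved
    ratio equals the corresponding generalized eigenvalue.

    Parameters
    ----------
    cp : CovariancePair
    n_per_class : int
        Number of filters per class direction.
    ridge : bool
        Add a jitter of ``1e-10 * trace * I`` to the denominator matrix,
        allowing singular covariances.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    f1, r1 = _top_filters(cp.sigma1, cp.sigma2, n_per_class, ridge)
    f2, r2 = _top_filters(cp.sigma2, cp.sigma1, n_per_class, ridge)
    return FilterSet(
        filters=f1 + f2,
        target_class=np.array([1] * n_per_class + [2] * n_per_class),
        ratios=np.concatenate([r1, r2]),
    )


class BasicCSP:
    """Basic CSP as a fit-able model over one subject's trials.

    Parameters
    ----------
    data : TrialSet or CovariancePair
        Raw trials (covariances are estimated with
        :func:`~multicsp.trials.class_covariances`) or precomputed class
        covariances.
    normalize : bool
        Per-trial trace normalization when estimating covariances.
    """

    def __init__(self, data: TrialSet | CovariancePair, normalize: bool = False):
        if isinstance(data, TrialSet):
            self.cov_pair = class_covariances(data, normalize=normalize)
        elif isinstance(data, CovariancePair):
            self.cov_pair = data
        else:
            raise TypeError("data must be a TrialSet or CovariancePair")

    def fit(self, n_per_class: int = 1, ridge: bool = False) -> "BasicCSPResults":
        fs = fit_bcsp(self.cov_pair, n_per_class=n_per_class, ridge=ridge)
        return BasicCSPResults(model=self, filter_set=fs)


@dataclass
class BasicCSPResults:
    model: BasicCSP
    filter_set: FilterSet

    @property
    def filters(self) -> list[np.ndarray]:
        return self.filter_set.filters

    @property
    def ratios(self) -> np.ndarray:
        return self.filter_set.ratios

    def summary(self) -> str:
        lines = ["Basic CSP results", "-----------------"]
        for w, c, r in zip(
            self.filter_set.filters,
            self.filter_set.target_class,
            self.filter_set.ratios,
        ):
            head = np.array2string(w, precision=4, max_line_width=70)
            lines.append(f"class {c}: ratio {r:.6g}  filter {head}")
        return "\n".join(lines)
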