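"""End-to-end motor-imagery evaluation pipeline.

Standard CSP classification chain: band-pass filter the trials (8-30 Hz by
default, the mu+beta band carrying event-related (de)synchronization),
reduce to a 22-electrode montage, spatially filter, take log-variance
features, and classify with two-class LDA.  The trade-off parameters of
the multisubject methods are selected on a grid by stratified k-fold
cross-validation, scoring each grid point by the accuracy averaged over
all subjects and folds.  The chance level for a test set of given size is
the normal-approximation binomial threshold at level alpha under 50%
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .clmtcsp import fit_clmtcsp
from .csp import fit_bcsp
from .mtcsp import fit_mtcsp
from .trials import TrialSet, class_covariances

__all__ = [
    "DEFAULT_MONTAGE_22",
    "bandpass",
    "select_channels",
    "log_variance_features",
    "LDAModel",
    "lda_fit",
    "lda_predict",
    "CVResult",
    "cross_validate",
    "chance_level",
]

# Frontal-to-occipital 22-electrode subset of the extended 10-20 system
# used to keep the stacked optimization dimension manageable.
DEFAULT_MONTAGE_22 = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
]


def bandpass(ts: TrialSet, low_hz: float, high_hz: float,
             fs: float | None = None, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass of every trial, per channel.

    Applied forward-backward (``filtfilt``), so the passband amplitude is
    preserved without phase distortion and DC is removed.
    """
    fs = fs if fs is not None else ts.sample_rate
    if fs is None:
        raise ValueError("sampling rate unknown; pass fs")
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"invalid band {low_hz}-{high_hz} Hz for fs={fs} Hz"
        )
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass",
                              fs=fs, output="sos")
    filtered = [scipy.signal.sosfiltfilt(sos, t, axis=1) for t in ts.trials]
    return TrialSet(filtered, ts.labels, channel_names=ts.channel_names,
                    sample_rate=fs)


def select_channels(ts: TrialSet, montage: list[str] | None = None) -> TrialSet:
    """Restrict a TrialSet to the named channels, in the requested order."""
    if ts.channel_names is None:
        raise ValueError("TrialSet has no channel names")
    montage = montage if montage is not None else DEFAULT_MONTAGE_22
    name_to_idx = {n: i for i, n in enumerate(ts.channel_names)}
    missing = [n for n in montage if n not in name_to_idx]
    if missing:
        raise KeyError(f"channels not present: {missing}")
    idx = [name_to_idx[n] for n in montage]
    return TrialSet(
        [t[idx] for t in ts.trials],
        ts.labels,
        channel_names=list(montage),
        sample_rate=ts.sample_rate,
    )


def log_variance_features(ts: TrialSet, filters: list[np.ndarray]) -> np.ndarray:
    """Per-trial log band-power features ``log var(w_j' X)``.

    Returns ``(n_trials, n_filters)``; invariant to the sign of any filter.
    """
    W = np.vstack([np.asarray(w, dtype=float).ravel() for w in filters])
    feats = np.empty((ts.n_trials, W.shape[0]))
    for i, t in enumerate(ts.trials):
        proj = W @ t
        var = np.mean(proj ** 2, axis=1)
        if np.any(var <= 0):
            raise ValueError(f"zero variance projection in trial {i}")
        feats[i] = np.log(var)
    return feats


# ---------------------------------------------------------------------------
# Two-class LDA with pooled covariance and equal priors
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Linear discriminant ``w = S_pooled^-1 (mu1 - mu2)`` with the
    equal-prior midpoint threshold."""

    weights: np.ndarray
    bias: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights - self.bias


def lda_fit(features: np.ndarray, labels: np.ndarray,
            ridge: float | None = None) -> LDAModel:
    """Fit two-class LDA (pooled covariance, equal priors).

    ``ridge`` adds ``ridge * mean(diag) * I`` to the pooled covariance; if
    the unmodified pooled covariance is singular an error asks for it.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {1, 2}:
        raise ValueError("labels must contain both classes 1 and 2")
    X1, X2 = X[y == 1], X[y == 2]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    n1, n2 = X1.shape[0], X2.shape[0]
    S = np.zeros((X.shape[1], X.shape[1]))
    for Xi, mui in ((X1, mu1), (X2, mu2)):
        C = Xi - mui
        S += C.T @ C
    dof = max(n1 + n2 - 2, 1)
    S /= dof
    if ridge is not None:
        S = S + ridge * max(np.trace(S) / S.shape[0], 1e-300) * np.eye(S.shape[0])
    try:
        w = np.linalg.solve(S, mu1 - mu2)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass a ridge value"
        ) from exc
    bias = float(w @ (mu1 + mu2) / 2.0)
    return LDAModel(weights=w, bias=bias)


def lda_predict(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels in {1, 2} (ties go to class 1)."""
    return np.where(model.decision(features) >= 0, 1, 2)


# ---------------------------------------------------------------------------
# Cross-validation over the trade-off grid
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-4, 5))


@dataclass
class CVResult:
    """Accuracy grid over (lambda1, lambda2) with the selected parameters.

    ``grid`` has columns lambda1, lambda2, accuracy; ``best_params`` is the
    grid maximizer (ties to smallest lambda1, then lambda2);
    ``fold_accuracies[(l1, l2)]`` is the (k, S) per-fold per-subject table.
    """

    grid: pd.DataFrame
    best_params: tuple[float, float]
    fold_accuracies: dict[tuple[float, float], np.ndarray]
    k: int
    seed: int

    @property
    def best_accuracy(self) -> float:
        m = self.grid
        row = m[(m.lambda1 == self.best_params[0]) & (m.lambda2 == self.best_params[1])]
        return float(row.accuracy.iloc[0])

    def accuracy_surface(self) -> pd.DataFrame:
        """Grid pivoted to a lambda1 x lambda2 accuracy surface."""
        return self.grid.pivot(index="lambda1", columns="lambda2",
                               values="accuracy")

    def summary(self) -> str:
        l1, l2 = self.best_params
        return "\n".join([
            f"{self.k}-fold cross-validation (seed {self.seed})",
            f"best parameters: lambda1 = {l1:g}, lambda2 = {l2:g} "
            f"(accuracy {self.best_accuracy:.4f})",
            self.accuracy_surface().to_string(float_format=lambda x: f"{x:.3f}"),
        ])


def _method_filters(
    method: str,
    train_sets: list[TrialSet],
    lambda1: float,
    lambda2: float,
    K: int | None,
    seed: int,
) -> list[list[np.ndarray]]:
    """Per-subject [class-1 filter, class-2 filter] for the chosen method."""
    cov_pairs = [class_covariances(ts) for ts in train_sets]
    S = len(cov_pairs)
    if method == "bcsp":
        out = []
        for cp in cov_pairs:
            fs = fit_bcsp(cp, n_per_class=1, ridge=True)
            out.append([fs.for_class(1)[0], fs.for_class(2)[0]])
        return out
    if method == "mtcsp":
        models = fit_mtcsp(cov_pairs, lambda1, lambda2)
        return [
            [models[1].effective_filter(s), models[2].effective_filter(s)]
            for s in range(1, S + 1)
        ]
    if method == "clmtcsp":
        if K is None:
            raise ValueError("clmtcsp needs the number of clusters K")
        models = fit_clmtcsp(cov_pairs, K, lambda1, lambda2, seed=seed)
        return [
            [models[1].effective_filter(s), models[2].effective_filter(s)]
            for s in range(1, S + 1)
        ]
    raise ValueError(f"unknown method '{method}'")


def cross_validate(
    datasets: list[TrialSet],
    method: str = "mtcsp",
    lambda1_grid=DEFAULT_LAMBDA_GRID,
    lambda2_grid=DEFAULT_LAMBDA_GRID,
    k: int = 5,
    seed: int = 0,
    K: int | None = None,
) -> CVResult:
    """Grid cross-validation of a (multisubject) CSP + LDA pipeline.

    Folds are stratified by class within each subject, all subjects
    sharing one fold seed so the joint methods see aligned folds.  For
    every (lambda1, lambda2) the method is fitted on the training folds of
    all subjects jointly, each subject gets its two filters, and the LDA
    accuracy on the held-out fold is averaged over subjects and folds.
    """
    if not datasets:
        raise ValueError("need at least one subject")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    subject_folds = []
    for ts in datasets:
        counts = np.bincount(ts.labels, minlength=3)
        if counts[1] < k or counts[2] < k:
            raise ValueError(
                f"subject with {counts[1]}/{counts[2]} trials per class "
                f"cannot be split into {k} stratified folds"
            )
        subject_folds.append(list(skf.split(np.zeros(ts.n_trials), ts.labels)))

    rows = []
    fold_acc: dict[tuple[float, float], np.ndarray] = {}
    for l1 in sorted(lambda1_grid):
        for l2 in sorted(lambda2_grid):
            acc = np.empty((k, len(datasets)))
            for f in range(k):
                train_sets = [
                    ts.subset(subject_folds[i][f][0]) for i, ts in enumerate(datasets)
                ]
                filters = _method_filters(method, train_sets, l1, l2, K, seed)
                for i, ts in enumerate(datasets):
                    tr_idx, te_idx = subject_folds[i][f]
                    Xtr = log_variance_features(ts.subset(tr_idx), filters[i])
                    Xte = log_variance_features(ts.subset(te_idx), filters[i])
                    model = lda_fit(Xtr, ts.labels[tr_idx], ridge=1e-8)
                    pred = lda_predict(model, Xte)
                    acc[f, i] = float(np.mean(pred == ts.labels[te_idx]))
            fold_acc[(l1, l2)] = acc
            rows.append({"lambda1": l1, "lambda2": l2,
                         "accuracy": float(acc.mean())})
    grid = pd.DataFrame(rows)
    best_idx = None
    best_val = -np.inf
    for i, row in grid.iterrows():  # sorted by l1 then l2: ties keep smallest
        if row.accuracy > best_val + 1e-12:
            best_val = row.accuracy
            best_idx = i
    best = grid.loc[best_idx]
    return CVResult(
        grid=grid,
        best_params=(float(best.lambda1), float(best.lambda2)),
        fold_accuracies=fold_acc,
        k=k,
        seed=seed,
    )


def masked_mean_accuracy(acc: pd.DataFrame, chance_pct: int) -> pd.Series:
    """Column means over subjects where at least one method beats chance.

    ``acc`` has one row per subject and one column per method, accuracies
    in [0, 1]; ``chance_pct`` is a whole-percent chance level (e.g. from
    :func:`chance_level`).  Subjects where no method exceeds the chance
    level are excluded from every column's mean, the convention used when
    summarizing per-subject accuracy tables.
    """
    mask = (acc > chance_pct / 100.0).any(axis=1)
    return acc[mask].mean(axis=0)


def chance_level(n_test_trials: int, alpha: float = 0.05) -> int:
    """Chance-level accuracy (whole percent) for an n-trial test set.

    Normal approximation to Binomial(n, 1/2): the smallest accuracy
    unlikely (level ``alpha``) under random guessing, computed as
    ``k = floor(n/2 + z_{1-alpha} sqrt(n)/2)`` correct trials and reported
    as ``floor(100 k / n)`` percent.
    """
    if n_test_trials < 1:
        raise ValueError("need at least one test trial")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = scipy.stats.norm.ppf(1.0 - alpha)
    kk = int(np.floor(n_test_trials / 2.0 + z * np.sqrt(n_test_trials) / 2.0))
    return int(np.floor(100.0 * kk / n_test_trials))
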