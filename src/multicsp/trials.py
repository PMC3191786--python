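"""Labeled multichannel trial data and per-class spatial covariance estimation.

A :class:`TrialSet` holds the epoched trials of one subject (or one task of a
simulated benchmark): each trial is a ``channels x samples`` matrix with a
binary class label in ``{1, 2}``.  CSP and its multisubject extensions only
ever see the per-class spatial covariance matrices, computed here.

Band-passed EEG is treated as zero mean, so the per-trial scatter is
``X @ X.T / n_samples`` without mean subtraction.  An optional per-trial trace
normalization guards against amplitude outliers; it is off by default and
both conventions are exposed because neither is universal in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TrialSet",
    "CovariancePair",
    "class_covariances",
    "save_trialset",
    "load_trialset",
]


@dataclass
class TrialSet:
    """Epoched trials of a single subject with binary class labels.

    Parameters
    ----------
    trials : sequence of ndarray
        Each trial is a ``(d, n_samples)`` real matrix; all trials must share
        the channel count ``d``.
    labels : array-like of int
        Per-trial class label, each in ``{1, 2}``.
    channel_names : sequence of str, optional
        Electrode names, length ``d``.
    sample_rate : float, optional
        Sampling rate in Hz.
    """

    trials: Sequence[np.ndarray]
    labels: np.ndarray
    channel_names: Sequence[str] | None = None
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.trials) != self.labels.size:
            raise ValueError(
                f"{len(self.trials)} trials but {self.labels.size} labels"
            )
        if len(self.trials) == 0:
            raise ValueError("TrialSet needs at least one trial")
        bad = set(self.labels.tolist()) - {1, 2}
        if bad:
            raise ValueError(f"labels must be in {{1, 2}}; found {sorted(bad)}")
        d = self.trials[0].shape[0]
        for i, t in enumerate(self.trials):
            if t.ndim != 2:
                raise ValueError(f"trial {i} is not a 2-D matrix")
            if t.shape[0] != d:
                raise ValueError(
                    f"trial {i} has {t.shape[0]} channels, expected {d}"
                )
        if self.channel_names is not None and len(self.channel_names) != d:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def class_trials(self, label: int) -> list[np.ndarray]:
        """Trials belonging to class ``label`` (1 or 2), in stored order."""
        return [t for t, y in zip(self.trials, self.labels) if y == label]

    def subset(self, indices: Sequence[int]) -> "TrialSet":
        """A new TrialSet restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return TrialSet(
            [self.trials[i] for i in idx],
            self.labels[idx],
            channel_names=self.channel_names,
            sample_rate=self.sample_rate,
        )


@dataclass
class CovariancePair:
    """Per-class spatial covariance matrices of one subject.

    ``sigma1`` and ``sigma2`` are the ``d x d`` symmetric positive
    semidefinite covariance matrices of class-1 and class-2 trials.
    Matrices are symmetrized on construction and tiny negative eigenvalues
    (down to ``-1e-10``, numerical noise) are clipped to zero.
    """

    sigma1: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.sigma1 = _validate_cov(np.asarray(self.sigma1, dtype=float), "sigma1")
        self.sigma2 = _validate_cov(np.asarray(self.sigma2, dtype=float), "sigma2")
        if self.sigma1.shape != self.sigma2.shape:
            raise ValueError("sigma1 and sigma2 must have the same shape")

    @property
    def d(self) -> int:
        return self.sigma1.shape[0]

    def swapped(self) -> "CovariancePair":
        """The pair with class roles exchanged."""
        return CovariancePair(self.sigma2, self.sigma1)


def _validate_cov(m: np.ndarray, name: str) -> np.ndarray:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-8 * (1.0 + np.abs(m).max())):
        raise ValueError(f"{name} is not symmetric")
    m = 0.5 * (m + m.T)
    w = np.linalg.eigvalsh(m)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"{name} has negative eigenvalue {w.min():g}; not PSD")
    if w.min() < 0:
        # clip numerical-noise negatives to zero
        vals, vecs = np.linalg.eigh(m)
        m = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        m = 0.5 * (m + m.T)
    return m


def trial_scatter(trial: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Spatial scatter ``X @ X.T / n_samples`` of one trial.

    With ``normalize`` the scatter is divided by its trace, which removes
    per-trial amplitude scale.
    """
    trial = np.asarray(trial, dtype=float)
    n = trial.shape[1]
    if n == 0:
        raise ValueError("trial has zero samples")
    s = trial @ trial.T / n
    if normalize:
        tr = np.trace(s)
        if tr <= 0:
            raise ValueError("cannot trace-normalize an all-zero trial")
        s = s / tr
    return s


def class_covariances(ts: TrialSet, normalize: bool = False) -> CovariancePair:
    """Average per-class spatial covariance matrices of a trial set.

    For each class ``c`` the covariance is the mean over that class's trials
    of the per-trial scatter ``X @ X.T / n_samples`` (trace-normalized per
    trial iff ``normalize``).

    Raises
    ------
    ValueError
        If either class has no trials, or a trial has zero samples.
    """
    sigmas = []
    for label in (1, 2):
        members = ts.class_trials(label)
        if not members:
            raise ValueError(f"no trials for class {label}")
        sigmas.append(
            np.mean([trial_scatter(t, normalize=normalize) for t in members], axis=0)
        )
    return CovariancePair(sigmas[0], sigmas[1])


# ---------------------------------------------------------------------------
# On-disk container: one directory per subject with an .npz matrix container
# (trials tensor + labels + channel names) and a JSON metadata sidecar.
# ---------------------------------------------------------------------------

def save_trialset(ts: TrialSet, directory: str | Path, meta: dict | None = None) -> Path:
    """Write a TrialSet to ``directory`` (created if missing).

    All trials must share a common sample count so they can be stored as a
    single ``(n_trials, d, n_samples)`` tensor.  Extra run metadata (seeds,
    resolved configuration) goes into ``meta.json`` alongside.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lengths = {t.shape[1] for t in ts.trials}
    if len(lengths) != 1:
        raise ValueError("on-disk container requires equal-length trials")
    data = np.stack(ts.trials)
    names = (
        np.array(list(ts.channel_names), dtype="U32")
        if ts.channel_names is not None
        else np.array([], dtype="U32")
    )
    np.savez(
        directory / "trials.npz",
        data=data,
        labels=ts.labels,
        channel_names=names,
        sample_rate=np.array(
            [-1.0 if ts.sample_rate is None else float(ts.sample_rate)]
        ),
    )
    (directory / "meta.json").write_text(json.dumps(meta or {}, indent=2))
    return directory


def load_trialset(directory: str | Path) -> TrialSet:
    """Read a TrialSet written by :func:`save_trialset` (exact round trip)."""
    directory = Path(directory)
    with np.load(directory / "trials.npz") as f:
        data = f["data"]
        labels = f["labels"]
        names = f["channel_names"]
        sr = float(f["sample_rate"][0])
    return TrialSet(
        list(data),
        labels,
        channel_names=list(names) if names.size else None,
        sample_rate=None if sr < 0 else sr,
    )
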