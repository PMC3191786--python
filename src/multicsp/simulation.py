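"""Synthetic source-mixing benchmark for multisubject CSP.

Two clusters of similar "tasks" are generated.  Every task observes
two-dimensional data points x = A s + e, where the source s is zero-mean
Gaussian with a condition-dependent diagonal covariance (diag(5, 1) for
condition 1, diag(1, 5) for condition 2 — the same for all tasks), the
mixing matrix A has its columns drawn around the cluster's fixed mean
mixing matrix with small isotropic perturbation, and e is isotropic sensor
noise.  A spatial filter that unmixes a source should make the filtered
variance differ strongly between the two conditions; the quality measure
is therefore the per-source variance ratio

    max(var_1, var_2) / min(var_1, var_2)

of the filtered test data, sorted from high to low so the two methods'
best (and worst) sources are compared like with like.  Perfect unmixing
approaches a ratio of 5 for both sources.

The benchmark is fully reproducible: one master seed spawns independent
per-task streams, so adding tasks does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .clmtcsp import fit_clmtcsp
from .csp import fit_bcsp
from .trials import CovariancePair

__all__ = [
    "A1_DEFAULT",
    "A2_DEFAULT",
    "SimulationConfig",
    "SimTask",
    "sample_mixing",
    "generate_benchmark",
    "task_cov_pair",
    "variance_ratios",
    "wilcoxon_signed_rank",
    "run_toy_comparison",
    "ToyComparisonResult",
]

# Fixed cluster-mean mixing matrices of the two task clusters.
A1_DEFAULT = np.array([[0.3500, 0.6062], [-1.0392, 0.6000]])
A2_DEFAULT = np.array([[0.6657, 0.2163], [-0.3708, 1.1413]])


@dataclass
class SimulationConfig:
    """Parameters of the two-cluster source-mixing benchmark.

    Defaults are the benchmark's study conditions: source covariances
    diag(5, 1) and diag(1, 5), mixing-column perturbation variance 1e-4,
    sensor-noise variance 1e-3, 20 tasks per cluster, 15 training and 285
    test points per condition.
    """

    source_cov_1: np.ndarray = field(default_factory=lambda: np.diag([5.0, 1.0]))
    source_cov_2: np.ndarray = field(default_factory=lambda: np.diag([1.0, 5.0]))
    mixing_means: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (A1_DEFAULT.copy(), A2_DEFAULT.copy())
    )
    mixing_column_var: float = 1e-4
    noise_var: float = 1e-3
    tasks_per_cluster: int = 20
    n_train_per_condition: int = 15
    n_test_per_condition: int = 285
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mixing_column_var", "noise_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for m in (self.source_cov_1, self.source_cov_2):
            if np.any(np.diag(m) <= 0):
                raise ValueError("source variances must be positive")


@dataclass
class SimTask:
    """One simulated task: its mixing matrix and train/test point clouds.

    ``train[c]`` and ``test[c]`` are ``(n, 2)`` arrays of observed points
    for condition ``c`` in {1, 2}; by construction each observation is
    ``mixing @ source + noise``.
    """

    cluster_id: int
    mixing: np.ndarray
    train: dict[int, np.ndarray]
    test: dict[int, np.ndarray]


def sample_mixing(
    cluster_mean: np.ndarray, column_var: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a mixing matrix: each column Gaussian around the mean column
    with isotropic covariance ``column_var * I``."""
    cluster_mean = np.asarray(cluster_mean, dtype=float)
    if column_var < 0:
        raise ValueError("column_var must be nonnegative")
    d = cluster_mean.shape[0]
    A = np.empty_like(cluster_mean)
    for j in range(cluster_mean.shape[1]):
        A[:, j] = cluster_mean[:, j] + np.sqrt(column_var) * rng.standard_normal(d)
    return A


def _draw_points(
    n: int, source_cov: np.ndarray, mixing: np.ndarray, noise_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    sd = np.sqrt(np.diag(source_cov))
    sources = rng.standard_normal((n, 2)) * sd
    obs = sources @ mixing.T
    obs += np.sqrt(noise_var) * rng.standard_normal(obs.shape)
    return obs


def generate_benchmark(cfg: SimulationConfig) -> list[SimTask]:
    """Generate the full two-cluster benchmark (cluster 1 tasks first)."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.tasks_per_cluster)
    tasks = []
    covs = {1: cfg.source_cov_1, 2: cfg.source_cov_2}
    for i, child in enumerate(children):
        cluster = 1 if i < cfg.tasks_per_cluster else 2
        rng = np.random.default_rng(child)
        A = sample_mixing(cfg.mixing_means[cluster - 1], cfg.mixing_column_var, rng)
        train = {
            c: _draw_points(cfg.n_train_per_condition, covs[c], A, cfg.noise_var, rng)
            for c in (1, 2)
        }
        test = {
            c: _draw_points(cfg.n_test_per_condition, covs[c], A, cfg.noise_var, rng)
            for c in (1, 2)
        }
        tasks.append(SimTask(cluster_id=cluster, mixing=A, train=train, test=test))
    return tasks


def task_cov_pair(task: SimTask, which: str = "train") -> CovariancePair:
    """Per-condition scatter matrices ``X'X / n`` of a task's point clouds."""
    data = getattr(task, which)
    sig = {c: data[c].T @ data[c] / data[c].shape[0] for c in (1, 2)}
    return CovariancePair(sig[1], sig[2])


def variance_ratios(filters: list[np.ndarray], task: SimTask,
                    which: str = "test") -> np.ndarray:
    """Condition-variance ratios of the two estimated sources, sorted
    descending.

    For each filter ``w_i`` the estimated source is ``w_i' x``; its ratio
    is ``max(var_1, var_2) / min(var_1, var_2)`` over the two conditions.
    Invariant to rescaling either filter.
    """
    if len(filters) != 2:
        raise ValueError("variance_ratios expects exactly two filters")
    data = getattr(task, which)
    ratios = []
    for w in filters:
        w = np.asarray(w, dtype=float).ravel()
        var = {c: float(np.mean((data[c] @ w) ** 2)) for c in (1, 2)}
        lo = min(var.values())
        if lo <= 0:
            raise ValueError("zero variance of a filtered condition")
        ratios.append(max(var.values()) / lo)
    return np.sort(ratios)[::-1]


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    diffs: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on a difference sample.

    Zero differences are dropped.  The p-value comes from the exact null
    distribution of the positive-rank sum for n <= 25 (untied ranks), and
    from the normal approximation (with tie correction, no continuity
    correction) otherwise.  ``alternative`` is ``two-sided`` (default),
    ``greater`` (median difference > 0) or ``less``.  Returns
    ``(W_plus, p)``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative '{alternative}'")
    d = np.asarray(diffs, dtype=float).ravel()
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= 25 and not has_ties:
        # exact: DP over the 2^n sign assignments of ranks 1..n
        total = n * (n + 1) // 2
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in range(1, n + 1):
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r]
            counts = counts + shifted
        counts /= 2.0 ** n
        w = int(round(w_plus))
        cdf = counts[: w + 1].sum()  # P(W <= w)
        sf = counts[w:].sum()        # P(W >= w)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif alternative == "greater":
            p = sf
        else:
            p = cdf
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        if alternative == "two-sided":
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = scipy.stats.norm.sf(z)
        else:
            p = scipy.stats.norm.cdf(z)
    return w_plus, float(p)


# ---------------------------------------------------------------------------
# Toy comparison: bCSP per task vs clmtCSP across tasks
# ---------------------------------------------------------------------------

@dataclass
class ToyComparisonResult:
    """Outcome of the toy bCSP-vs-clmtCSP comparison.

    ``ratios_bcsp`` / ``ratios_clmt`` are ``(n_tasks, 2)`` arrays of sorted
    variance ratios (column 0 = higher source).  ``assignment_accuracy`` is
    the fraction of tasks whose recovered cluster matches the generating
    one, averaged over the two class directions.  ``table`` summarizes the
    per-cluster, per-source paired comparison.
    """

    ratios_bcsp: np.ndarray
    ratios_clmt: np.ndarray
    true_clusters: np.ndarray
    assignments: dict[int, np.ndarray]
    assignment_accuracy: float
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Toy benchmark: bCSP vs clmtCSP variance ratios",
            "----------------------------------------------",
            f"tasks: {self.true_clusters.size}   "
            f"cluster recovery: {100 * self.assignment_accuracy:.1f}%",
            self.table.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


def run_toy_comparison(
    cfg: SimulationConfig | None = None,
    lambda1: float = 1e-3,
    lambda2: float = 1e-1,
    block_init: bool = True,
    tasks: list[SimTask] | None = None,
) -> ToyComparisonResult:
    """Fit bCSP per task and clmtCSP across tasks; compare variance ratios.

    clmtCSP uses K=2 with the block initialization (first half of the
    tasks in cluster 1, second half in cluster 2) so cluster recovery can
    be read off directly, unless ``block_init`` is False (seeded
    clustering of bCSP filters instead).  Ratios are sorted per task and
    paired highest-with-highest and lowest-with-lowest; the paired
    Wilcoxon signed-rank test is run per generating cluster and source.
    """
    cfg = cfg or SimulationConfig()
    if tasks is None:
        tasks = generate_benchmark(cfg)
    n = len(tasks)
    true = np.array([t.cluster_id - 1 for t in tasks])
    cov_pairs = [task_cov_pair(t) for t in tasks]

    ratios_b = np.vstack(
        [
            variance_ratios(
                fit_bcsp(cp, n_per_class=1, ridge=True).filters, t
            )
            for cp, t in zip(cov_pairs, tasks)
        ]
    )

    init = true if block_init else None
    models = fit_clmtcsp(cov_pairs, K=2, lambda1=lambda1, lambda2=lambda2,
                         init=init, seed=cfg.seed)
    ratios_c = np.vstack(
        [
            variance_ratios(
                [models[1].effective_filter(s + 1), models[2].effective_filter(s + 1)],
                tasks[s],
            )
            for s in range(n)
        ]
    )

    assignments = {c: models[c].labels for c in (1, 2)}
    acc = float(np.mean([np.mean(assignments[c] == true) for c in (1, 2)]))

    rows = []
    for cluster in (1, 2):
        mask = true == cluster - 1
        for source in (0, 1):
            db = ratios_b[mask, source]
            dc = ratios_c[mask, source]
            _, p = wilcoxon_signed_rank(dc - db)
            rows.append(
                {
                    "cluster": cluster,
                    "source": "high" if source == 0 else "low",
                    "median_bcsp": float(np.median(db)),
                    "median_clmtcsp": float(np.median(dc)),
                    "wilcoxon_p": p,
                }
            )
    table = pd.DataFrame(rows)
    return ToyComparisonResult(
        ratios_bcsp=ratios_b,
        ratios_clmt=ratios_c,
        true_clusters=true,
        assignments=assignments,
        assignment_accuracy=acc,
        table=table,
    )
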