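# multicsp

Multisubject Common Spatial Patterns (CSP) for two-class motor-imagery
brain-computer interfaces.

## The problem

CSP is the standard spatial-filtering step in motor-imagery BCIs: given
band-passed EEG trials of two classes with average spatial covariance
matrices Σ¹ and Σ², it finds the filter **w** maximizing the Rayleigh
quotient

    J(w) = w'Σ¹w / w'Σ²w,

i.e. the top generalized eigenvector of (Σ¹, Σ²).  CSP is supervised,
so every new subject needs calibration trials.  This package implements
multisubject (multitask) extensions that borrow strength across
subjects to cut that calibration cost:

- **bCSP** — basic per-subject CSP via the generalized eigenproblem.
- **mtCSP** — every subject's filter is decomposed into a shared global
  part plus a subject-specific deviation, `w_s = w0 + v_s`, learned
  jointly for all S subjects by maximizing the sum of penalized
  quotients

      Σ_s (w_s'Σ¹_s w_s) / (w_s'Σ²_s w_s + λ1‖w0‖² + λ2‖v_s‖²)

  with a safeguarded Newton method on the stacked vector
  (w0; v1; …; vS).  λ1 and λ2 trade off shared against
  subject-specific structure.
- **Filter clustering** — k-means-style clustering of filters on the
  unit hypersphere under the sign/scale-invariant squared-sine angle
  metric, with principal-eigenvector centroids.
- **clmtCSP** — cluster-based multisubject CSP: one shared filter per
  cluster of similar subjects (`w_sk = w_k + v_sk`), alternating a
  penalized-quotient cluster assignment with per-cluster mtCSP refits.

Around the core sit a synthetic source-mixing benchmark with
variance-ratio evaluation and paired Wilcoxon comparison, and a full
evaluation pipeline (8–30 Hz band-pass, 22-electrode montage,
log-variance features, equal-prior LDA, λ-grid cross-validation, chance
levels).  See `docs/methods.md` for the model details and numerical
choices.

## Worked example

Fit mtCSP to three simulated tasks and inspect the shared/specific
decomposition:

```python
from multicsp import MultiSubjectCSP, SimulationConfig, generate_benchmark
from multicsp.simulation import task_cov_pair

tasks = generate_benchmark(SimulationConfig(seed=1, tasks_per_cluster=3))
cov_pairs = [task_cov_pair(t) for t in tasks[:3]]
results = MultiSubjectCSP(cov_pairs, lambda1=1e-3, lambda2=0.1).fit()
print(results.summary())
```

```
Multisubject CSP (mtCSP) results
--------------------------------
subjects: 3   channels: 2
lambda1 = 0.001   lambda2 = 0.1
class 1 direction: objective 18.025366 (7 iterations, converged=True)
  ||w0|| = 0.9488   mean ||v_s|| = 0.1794
  subject 1: quotient 5.8399
  subject 2: quotient 4.4815
  subject 3: quotient 7.7040
class 2 direction: objective 11.799970 (10 iterations, converged=True)
  ||w0|| = 0.9840   mean ||v_s|| = 0.0913
  subject 1: quotient 5.4408
  subject 2: quotient 3.0134
  subject 3: quotient 3.3458
```

The objective is the sum over subjects of the achieved penalized
variance quotients (one maximization per class direction).  Most of the
unit-norm solution sits in the shared filter `w0` — the three tasks come
from the same mixing cluster — while small `v_s` absorb each task's
mixing perturbation.

The full toy comparison (40 tasks in two clusters, basic CSP per task
versus clmtCSP with K=2):

```python
from multicsp import SimulationConfig, run_toy_comparison
print(run_toy_comparison(SimulationConfig(seed=1)).summary())
```

```
Toy benchmark: bCSP vs clmtCSP variance ratios
----------------------------------------------
tasks: 40   cluster recovery: 100.0%
 cluster source  median_bcsp  median_clmtcsp  wilcoxon_p
       1   high        4.978           4.979   8.202e-05
       1    low        4.275            4.29    2.67e-05
       2   high        5.022           5.036   1.335e-05
       2    low        4.154           4.164   1.907e-06
```

Variance ratios close to 5 mean near-perfect unmixing of the planted
sources (whose condition variances differ by a factor of five); the
clustered multisubject fit edges out the per-task fit on both sources in
both clusters, and the paired Wilcoxon test over the 20 tasks per
cluster rejects equality.

The same functionality is scriptable from the shell:

```bash
multicsp simulate --seed 1 --out bench/
multicsp toy-compare --in bench/ --out comparison.tsv
multicsp fit --method mtcsp --in subj1/ --in subj2/ --lambda2 0.1 --out filters.npz
multicsp cv --method mtcsp --in subj1/ --in subj2/ --k 5 --seed 7
```

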