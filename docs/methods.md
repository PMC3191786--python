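# Methods

## Problem setting

Two-class motor-imagery BCIs discriminate imagined movements through the
spatial distribution of band power (8–30 Hz) over sensorimotor cortex.
The Common Spatial Patterns (CSP) method learns a spatial filter
`w ∈ R^d` (d = number of electrodes) maximizing the Rayleigh quotient

    J(w) = w' Σ¹ w / w' Σ² w,

where `Σ¹`, `Σ²` are the average per-class spatial covariance matrices of
the band-passed trials.  The maximizer is the top generalized eigenvector
of `(Σ¹, Σ²)`; the filter for the second class comes from the swapped
problem.  Because CSP is supervised, a new subject needs calibration
trials; the multisubject extensions below reduce that need by borrowing
strength across subjects.

## Multisubject CSP (mtCSP)

Each subject `s = 1..S` receives an effective filter decomposed into a
shared and a specific part, `w_s = w0 + v_s`, learned jointly by
maximizing

    R = Σ_s  (w_s' Σ¹_s w_s) / (w_s' Σ²_s w_s + λ1‖w0‖² + λ2‖v_s‖²).

λ1 penalizes the shared part (λ1 → ∞ forces `w0 → 0`, fully
subject-specific filters); λ2 penalizes the deviations (λ2 → ∞ forces
`v_s → 0`, one shared filter).  Both large acts as ordinary shrinkage.
Stacking `w = (w0; v1; …; vS)` and lifting the covariances with selector
matrices `E_s` (`E_s w = w0 + v_s`) and block projectors `D_0`, `D_s`
turns `R` into a sum of ratios of quadratic forms,

    R(w) = Σ_s (w'A_s w)/(w'B_s w),
    A_s = E_s Σ¹_s E_s',  B_s = E_s Σ²_s E_s' + λ1 D_0 + λ2 D_s,

with gradient `∇R = 2 Σ_s (A_s w − r_s B_s w)/δ_s` (`r_s` the s-th ratio,
`δ_s = w'B_s w`) and Hessian

    ∇²R = Σ_s (2/δ_s) [ A_s − r_s B_s − (B_s w) g_s' − g_s (B_s w)' ],

where `g_s = ∇r_s`.  Both derivatives are exercised against central
finite differences in the test suite.

### Optimization

`R` is nonconvex (a sum of convex-to-convex ratios), so only a stationary
point is guaranteed.  We maximize with a safeguarded Newton method:

- **Modified-Newton direction.**  The Hessian is eigendecomposed and its
  eigenvalues clamped to at most `−1e-8·‖H‖`; the step
  `p = −H̃⁻¹∇R` is then always an ascent direction, takes the true
  Newton step where the curvature is safely negative, and degrades to
  curvature-scaled gradient ascent in nonconcave or flat directions.  A
  plain Newton step with a constant Tikhonov shift and a unit-step
  gradient fallback was found to stall on badly scaled problems (e.g.
  λ ≈ 1e6, where curvatures span many orders of magnitude); the clamped
  direction removes that failure mode.
- **Line search.**  Backtracking (step halving) until `R` increases,
  followed by step doubling while `R` keeps increasing.  The expansion
  matters on ill-conditioned problems where the unit step is far too
  short.
- **Scale handling.**  `R` is homogeneous of degree zero, so the Hessian
  is singular along `w` (`Hw = −∇R`, `w'∇R = 0`).  The iterate is
  renormalized to unit norm after every step; the eigenvalue clamp
  absorbs the scale null-direction.
- **Stopping.**  Step norm below `tol = 1e-8` (after renormalization) or
  200 iterations; the objective is asserted non-decreasing across
  accepted steps and every iteration is logged (objective, step type,
  step norm, step length).

**Initialization** (`bcsp_mean`, the default): per-subject basic-CSP
filters (ridge-jittered), sign-aligned to the first subject,
`w0` = their normalized mean, `v_s = f_s − w0`.  A `zeros+eps` scheme is
available for probing initialization sensitivity.  With λ1 = λ2 = 0 the
default initialization is already optimal (each `w0 + v_s` is the
subject's own top generalized eigenvector), which the oracle tests
exploit.

Per-class filters are two independent maximizations — class 1 over
class 2, and the swap — mirroring the one-filter-per-class design used
throughout the package.

## Clustering spatial filters

CSP filters are defined up to sign and scale, so they live on the unit
hypersphere with antipodes identified.  The metric is the squared sine of
the angle, `d(v1,v2) = 1 − (v1'v2)²/((v1'v1)(v2'v2))` ∈ [0,1].
Clustering alternates nearest-center assignment (ties to the lowest
cluster index) with a center update: the center of a cluster is the
principal eigenvector of `Σ_{s∈cluster} v_s v_s'`, the maximizer of the
within-cluster squared-cosine sum.  The loop stops when assignments
stabilize; the objective is monotone non-decreasing and asserted so.

Numerical choices (the loop's stopping rule and degenerate-case policies
are genuinely open):

- **Empty clusters** are reseeded with the filter farthest (angle metric)
  from its current center, drawn from a cluster with >1 member.
- **Random initialization** seeds centers with K distinct filters; by
  default 8 seeded restarts are run and the best objective kept, because
  the alternating scheme only finds local optima.  With an explicit
  initial assignment the run is single-shot and fully deterministic.
- Eigen-ties resolve by the deterministic LAPACK ordering; centers carry
  a fixed sign convention (largest-magnitude component positive).

## Cluster-based multisubject CSP (clmtCSP)

One shared filter per cluster: `w_sk = w_k + v_sk`, with binary
memberships α_sk (rows summing to one).  The fit alternates:

1. **Assignment** — each subject joins the cluster maximizing its
   penalized quotient
   `(w_sl'Σ¹_s w_sl)/(w_sl'Σ²_s w_sl + λ1‖w_l‖² + λ2‖v_sl‖²)`.  For
   non-member clusters `v_sl` is first optimized from zero with `w_l`
   held fixed — a damped-Newton solve restricted to the `v` block of the
   stacked single-subject problem (no renormalization there: fixing
   `w_l` breaks scale invariance).
2. **Refit** — mtCSP on each cluster's members, warm-started from the
   current `w_k`, `v_sk`.

Initialization clusters the per-subject basic-CSP filters on the
hypersphere (centers → `w_k`, sign-aligned differences → `v_sk`); an
explicit initial assignment (e.g. the toy benchmark's block split) is
honored exactly.  Outer iterations stop when assignments stabilize, with
a cap of 20.  An empty cluster is repaired by moving in the
worst-scoring subject from a populated cluster.  Subjects that change
cluster adopt the `v` optimized during the assignment test, so the
subsequent refit starts at least as high as the assignment-step score
and the outer objective is non-decreasing.  The two class directions are
fitted independently, each with its own assignments (whether they should
be shared is undetermined; independent fits are the weaker assumption,
and the choice is documented here).

## Synthetic benchmark

The generator emulates a transfer-learning situation with two families
of similar tasks.  Each of 2×20 tasks observes 2-D points
`x = A s + e`: sources `s ~ N(0, Σ^(c))` with condition-dependent
covariances `Σ^(1) = diag(5,1)`, `Σ^(2) = diag(1,5)` (same for all
tasks); mixing matrix columns drawn around the cluster's fixed mean
(`A1 = [[0.3500, 0.6062], [−1.0392, 0.6000]]`,
`A2 = [[0.6657, 0.2163], [−0.3708, 1.1413]]`) with isotropic variance
1e-4; sensor noise variance 1e-3.  Each task gets 15 training and 285
test points per condition.  One master `SeedSequence` spawns per-task
streams, so enlarging the benchmark leaves earlier tasks untouched.

Filter quality is measured on the test points as the per-source
condition-variance ratio `max(σ̂²₁, σ̂²₂)/min(σ̂²₁, σ̂²₂)`, sorted
descending per task so methods are compared best-with-best and
worst-with-worst (source order is arbitrary).  Perfect unmixing
approaches 5 for both sources.  The toy comparison fits basic CSP per
task and clmtCSP (K = 2, block initialization: first 20 tasks in cluster
1) across tasks, then runs a paired Wilcoxon signed-rank test per
generating cluster and source.  The trade-off defaults for this
comparison are λ1 = 1e-3, λ2 = 0.1, with a documented ladder
λ2 ∈ {0.1, 1, 10} over which the clmtCSP advantage is expected to hold
at at least one point per replicate.

What the generator does **not** emulate: real EEG nonstationarity,
artifacts, volume conduction with more sources than sensors, non-Gaussian
sources, or channel counts beyond 2 (the evaluation tests lift tasks to
22 channels with a random orthogonal embedding, which preserves the
planted two-dimensional structure exactly — real head geometry is far
less kind).  Passing the synthetic benchmark shows the optimization and
clustering machinery recover planted structure; it does not predict
real-data accuracy.

The Wilcoxon test uses the exact null distribution of the positive-rank
sum (dynamic programming over sign assignments) for n ≤ 25 without ties,
and the tie-corrected normal approximation (no continuity correction)
otherwise; zero differences are dropped.

## Evaluation pipeline

Band-pass: 4th-order Butterworth, 8–30 Hz, applied forward-backward
(zero phase, DC removed).  Montage: a fixed 22-electrode subset
(Fp1 … O2) keeps the stacked optimization dimension manageable.
Features: `log var(w'X)` per trial and filter (two filters per subject,
one per class).  Classifier: two-class LDA with pooled covariance and
equal priors (`w = S⁻¹(μ₁−μ₂)`, midpoint threshold), with an optional
ridge on the pooled covariance.  λ selection: stratified 5-fold
cross-validation per subject with one shared fold seed; for each grid
point (default λ1, λ2 ∈ {1e-4 … 1e4}) the joint methods are refitted on
the training folds of all subjects and scored by accuracy averaged over
subjects and folds; grid ties resolve to the smallest λ1, then λ2.
Summary tables can mask subjects for which no method beats the chance
level, computed from the normal approximation to Binomial(n, ½):
`k = floor(n/2 + z_{1−α}√n/2)` correct trials, reported as
`floor(100k/n)` percent — giving 56% at n = 180 and 60% at n = 60 at
α = 0.05.  (The rule is an assumption; it is the simplest computation
reproducing both reference values.)

## Known limitations and numerical notes

- The mtCSP objective is nonconvex; different initializations can reach
  different stationary points.  All oracle comparisons in the tests use
  problems where the optimum is identifiable (single subject, planted
  structure, or penalty limits).
- When the optimal shared part is nearly zero (large λ1, or small λ2
  with λ1 > 0), the split of the unit-norm solution between `w0` and the
  `v_s` is nearly degenerate: the sum `Σ_s‖v_s‖²` at computed optima is
  only approximately monotone in λ2 (wiggles of order 1e-3 at tight
  tolerance, occasionally larger when the solution branch switches).
  The λ → 1e6 limits themselves are sharp: ‖v_s‖ (resp. ‖w0‖) fall
  below 1e-3.
- Per-trial covariances are `XX'/n` without mean subtraction (band-passed
  signals are zero-mean); optional per-trial trace normalization (off by
  default) guards against amplitude outliers.  Covariances are
  symmetrized and eigenvalues below −1e-10 rejected, smaller negatives
  clipped to zero.  Singular denominators accept a ridge jitter of
  `1e-10·trace·I` when requested.
- Problem sizes in the tests and the acceptance script (40 two-channel
  tasks, 3–5 subjects at up to 22 channels, five toy replicates) were
  chosen so the full suite completes in well under a minute while every
  planted effect is still detected at its stated threshold.
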