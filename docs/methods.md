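# Methods

## The model

Extended redundancy analysis (ERA) regresses a continuous response on
K components, each a weighted composite of one block of predictors:

```
y_i = Σ_k b_k f_ik + e_i,    f_ik = Σ_p x_ikp w_kp,    or    y = X W b + e,
```

where `W` is the P × K block-diagonal weight matrix and `F = X W` the
N × K component-score matrix. The parameters minimize the least-squares
objective `φ = SS(y − X W b)` subject to the identification constraint
`diag(F'F) = N·I`; without it the scale split between `w_k` and `b_k`
is arbitrary. Candidate models may add component-level interaction
(`f_k · f_l`) and quadratic (`f_k²`) terms; the weights remain attached
to blocks, the extra terms only enter the regression design.

In-sample fit is summarized by `FIT = 1 − φ/SS(y_c)` (an R²-type index
in [0, 1]) and by the training RMSE `sqrt(φ/N)`.

### Standardization conventions

Predictors are standardized to mean 0 and variance 1 **with divisor N**,
so a standardized column has sum of squares exactly N — the same scale
the constraint imposes on component scores. The response is centered on
its training mean (the model has no intercept; centering makes `b = 0`
a meaningful null, so FIT ∈ [0, 1] at any solution), and the mean is
added back at prediction time. Held-out data are always transformed
with the *training* means/SDs; nothing is refit on validation rows.

### ALS estimation

Fitting alternates two least-squares sub-steps until the relative
decrease of φ falls below `tol` (default 1e-8) or `max_iter` (default
500) cycles elapse:

1. **Coefficient step.** Given the current components, all term
   coefficients `b` are re-estimated jointly by OLS of the centered
   response on the term design.
2. **Weight step.** For each block in turn, the partial residual
   (response minus all term contributions not involving that block's
   component) is regressed on the block's contribution, which is linear
   in `w_k` for linear and interaction terms; a quadratic term in the
   block's own component is linearized at the current scores. The
   updated `w_k` is rescaled so `SS(Z_k w_k) = N` and the scale is
   absorbed into the affected coefficients (squared for quadratics).
   Because the linearized quadratic step is not guaranteed to descend,
   a candidate update that would increase φ is rejected; the recorded
   objective trace is therefore non-increasing for every model class.

Initialization is deterministic (`w_k ∝ 1`, renormalized) by default;
uniform-random starts with a seed, and multiple restarts, are available.
Sign indeterminacy of each `(w_k, b)` pair is resolved at exit by making
the first nonzero weight of every block positive. A rank-deficient block
is fit by minimum-norm least squares with a warning. Non-convergence
within `max_iter` sets a flag rather than raising.

For purely linear models the objective is bilinear and each sub-step is
an exact coordinate minimization; in practice ALS reaches the same
objective as a generic constrained optimizer with many restarts (the
test suite verifies this to 1e-6 relative on small instances). **With an
interaction term the problem is no longer bilinear and ALS guarantees
only a stationary point**: on rare small instances the default
(all-positive) initializations converge to a local solution a fraction
of a percent above the global optimum, which is itself an ALS fixed
point reachable by warm-starting. This is a known limitation of
alternating schemes on nonconvex objectives; random restarts
(`FitOptions(init="random", n_restarts=...)`) mitigate it.

## Prediction-error estimators

Predictive performance uses squared-error loss reported as RMSE. The
**apparent (training) error** `sqrt(φ/N)` is downward-biased for
generalization error ("optimism"). Five out-of-sample estimators are
provided; each refits the full pipeline — standardization included —
on every learning set:

* **c-fold CV**: random near-equal partition; the estimate is the
  unweighted mean of per-fold RMSEs (macro average). For **LOOCV**
  (c = N) the singleton-fold RMSE is the absolute error of the held-out
  observation, so the estimate is the *mean absolute* leave-one-out
  error — a deliberate consequence of the macro-average convention,
  stated here prominently because it sits on a lower scale than the
  other estimators (mean |e| < RMSE). Comparisons *across candidate
  models within* LOOCV are unaffected.
* **OOB bootstrap**: B with-replacement draws of size N (draws whose
  out-of-bag set is empty are redrawn); fit in-bag, score out-of-bag,
  average over draws. Defaults: B = 50, c = 10.
* **0.632**: `0.632·ErrTrain + 0.368·Err_OOB`.
* **0.632+**: `ω·ErrTrain + (1 − ω)·Err_OOB` with
  `ω = 0.632/(1 − 0.368·R)`,
  `R = (Err_OOB − ErrTrain)/(γ − ErrTrain)` clipped to [0, 1], and the
  no-information error rate `γ = sqrt(mean_{i,j}(y_i − ŷ_j)²)` (all
  pairs of observed responses and full-data fitted values, on the RMSE
  scale).

Two notes on the 0.632 family. First, the weighting convention here
places ω on ErrTrain; the classical presentation of the 0.632 estimator
weights the out-of-bag term by 0.632 instead. The convention used is
internally consistent — at R = 0 the 0.632+ estimator reduces exactly
to the 0.632 estimator — but at R = 1 it weights the training error
fully, so the two conventions disagree most where overfitting is
severe; users comparing against other software should check which
convention it uses. Second, R is clipped to [0, 1] so that sampling
noise cannot push ω outside [0.632, 1].

Per-fold and per-draw errors are aggregated by an order-invariant mean
(sorted before summation), so an estimate depends only on the partition,
not on fold labelling; this makes LOOCV and N-fold CV agree bit for bit.
Resample fits that fail (e.g., a constant in-bag column) are skipped
with a warning; more than 10% failures is an error. Model selection
(`select_model`) takes the candidate with the smallest estimate,
breaking exact ties toward the model with fewer terms.

## The synthetic population

The generator emulates a two-component ERA population: per block,
raw weights are drawn i.i.d. from U(0.8, 1) and normalized to unit
Euclidean norm; predictors are mutually uncorrelated standard normals
(so each component has variance exactly 1 and the components are
uncorrelated); `b₁ = 0.3` and total explained variance `R² = 0.4` fix
`b₂ = sqrt(R² − b₁²) = 0.5568` (the exact value is used, not its
two-decimal rounding); the error variance is `1 − R²`. The implied joint
covariance is `Σ_xx = I`, `Σ_xy = W b`, `Σ_yy = 1`, and datasets are
i.i.d. draws from MVN(0, Σ). Weights are sampled once per study cell
(one Σ per condition); replications redraw data only.

Identity within-block covariance is the simplest choice consistent with
unit-variance predictors and uncorrelated unit-variance components; real
survey blocks have correlated indicators, non-normal margins and missing
data, none of which the generator emulates — results here demonstrate
estimator behavior under the stated population, not robustness to those
features.

Candidate models: `f0 = {b₁f₁}` (under-specified; its block spec simply
omits the second block's columns), `f1` the generating model,
`f2 = f1 + interaction`, `f3 = f2 + both quadratics`. In the studies the
candidates are fit warm-started along this nested chain, which makes
FIT non-decreasing in model size by construction — the cleanest way to
exhibit that FIT can never favor the smaller true model.

Closed-form anchors used by the tests: the expected test RMSE of the
correctly specified fit approaches `sqrt(1 − R²) = 0.7746` at large N,
and of the under-specified fit `sqrt(1 − b₁²) = 0.9539`.

## The studies

* **Optimism study**: per replication, fit all candidates, record FIT,
  apparent RMSE, and a Monte-Carlo estimate of the expected test error
  (mean RMSE over fresh test sets of the training size).
* **Estimator comparison**: per replication and candidate, compute the
  apparent error, CV at c ∈ {3, 5, 10}, LOOCV, and the OOB/0.632/0.632+
  trio (one set of bootstrap fits per B); summaries report mean, SD and
  bias against the Monte-Carlo truth, plus per-estimator selection
  frequencies (argmin across candidates).

Default configuration is the full design (N ∈ {50, 100, 200, 500, 1000},
Np ∈ {2, 4, 6, 8}, 1,000 replications, 1,000 test sets).
`StudyConfig.scaled()` is the routine profile used by the test suite:
one cell at N = 100, Np = 2 with 200 replications and 200 test sets,
sizes at which the qualitative findings (positive optimism for every
candidate; every out-of-sample estimator minimized at f1; LOOCV least
variable; 0.632 ≈ 0.632+ for the true model) are stable and a full run
completes in minutes on one core. A master seed drives a
`SeedSequence` spawn tree (cell → truth + replications), so any cell or
replication can be regenerated independently and identical seeds give
identical results to the last bit.

## Numerical and degenerate-input policy

* Constant predictor columns, N < 3, and zero-variance responses raise
  typed errors naming the offending column where applicable.
* CV folds that leave fewer than (terms + 2) training rows raise an
  infeasible-fold error before any fitting.
* `relative_overfitting` returns 0 when γ ≤ ErrTrain or
  Err_OOB ≤ ErrTrain (no measurable overfitting).
* The ALS convergence test is relative (`Δφ < tol·φ`), so very small
  objectives do not stall the stopping rule; for high-precision
  comparisons (e.g., against a reference optimizer) tighten `tol`.

## Known limitations

* Single continuous response; squared-error loss only (no
  classification losses), no missing-data handling, no regularized or
  tree-based ERA variants.
* Only the macro-averaged CV convention is implemented (no pooled
  residual variant), and the 0.632 combinations are formed on the RMSE
  scale only.
* ALS global optimality is not guaranteed for models with interaction
  or quadratic terms (see above).
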