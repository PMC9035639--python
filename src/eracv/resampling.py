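"""Out-of-sample prediction-error estimators for ERA models.

Implements the apparent (training) error plus five resampling estimators of
generalization error on the RMSE scale:

* c-fold cross-validation (``cv_error``) and its c = N limit, leave-one-out
  CV (``loocv_error``);
* the out-of-bag (OOB) bootstrap (``oob_error``);
* the 0.632 estimator, ``0.632 * ErrTrain + 0.368 * Err_OOB``;
* the 0.632+ estimator, which adapts the weight via the relative
  overfitting coefficient R and the no-information error rate gamma:
  ``omega = 0.632 / (1 - 0.368 R)``.

Every learning set (CV complement or bootstrap in-bag sample) is
re-standardized on its own rows, and held-out data are transformed with
those training parameters, so no information leaks from validation to
training.  Per-fold/per-draw errors are aggregated by an order-invariant
mean (values are sorted before averaging) so that estimates depend only on
the partition, not on fold labelling; in particular N-fold CV and LOOCV
agree bit for bit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ERAError,
    FitOptions,
    ModelSpec,
    fit_era,
    predict,
    rmse,
)

__all__ = [
    "InfeasibleFoldError",
    "FoldPlan",
    "BootstrapPlan",
    "EstimatorResult",
    "make_cv_folds",
    "make_bootstrap",
    "apparent_error",
    "cv_error",
    "loocv_error",
    "oob_error",
    "bootstrap_estimates",
    "no_info_error",
    "relative_overfitting",
    "weight_632plus",
    "err632",
    "err632plus",
    "select_model",
]


class InfeasibleFoldError(ERAError):
    """A CV fold leaves too few observations to fit the model."""


# ---------------------------------------------------------------------------
# Resampling plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Random partition of N observations into c near-equal folds."""

    n: int
    c: int
    assignment: np.ndarray  # fold label in 0..c-1 per observation
    seed: int | None


@dataclass(frozen=True)
class BootstrapPlan:
    """B with-replacement draws of size N and their out-of-bag complements."""

    n: int
    b: int
    in_bag: np.ndarray  # (B, N) int indices
    oob: tuple[np.ndarray, ...]  # per-draw sorted OOB indices, all non-empty
    seed: int | None
    n_redrawn: int = 0


def make_cv_folds(n: int, c: int, seed: int | None = None) -> FoldPlan:
    """Randomly assign n observations to c folds of near-equal size."""
    if c < 2 or c > n:
        raise ERAError(f"fold count must satisfy 2 <= c <= N; got c={c}, N={n}")
    sizes = np.full(c, n // c)
    sizes[: n % c] += 1
    labels = np.repeat(np.arange(c), sizes)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    assignment[rng.permutation(n)] = labels
    return FoldPlan(n=n, c=c, assignment=assignment, seed=seed)


def make_bootstrap(n: int, b: int, seed: int | None = None) -> BootstrapPlan:
    """B bootstrap draws of size n; draws with an empty OOB set are redrawn."""
    if b < 1:
        raise ERAError("need at least one bootstrap replication")
    if n < 2:
        raise ERAError("need at least two observations to bootstrap")
    rng = np.random.default_rng(seed)
    in_bag = np.empty((b, n), dtype=int)
    oob: list[np.ndarray] = []
    n_redrawn = 0
    all_idx = np.arange(n)
    for i in range(b):
        while True:
            draw = rng.integers(0, n, size=n)
            out = np.setdiff1d(all_idx, draw, assume_unique=False)
            if out.size:
                break
            n_redrawn += 1
            warnings.warn("bootstrap draw covered every observation; redrawing", RuntimeWarning)
        in_bag[i] = draw
        oob.append(out)
    return BootstrapPlan(n=n, b=b, in_bag=in_bag, oob=tuple(oob), seed=seed, n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# Estimator results
# ---------------------------------------------------------------------------


@dataclass
class EstimatorResult:
    """One named prediction-error estimate for one candidate model."""

    method: str
    value: float
    settings: dict = field(default_factory=dict)
    per_resample: np.ndarray | None = None
    auxiliary: dict = field(default_factory=dict)
    n_terms: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "value": self.value,
            "settings": {k: v for k, v in self.settings.items()},
            "per_resample": None if self.per_resample is None else list(map(float, self.per_resample)),
            "auxiliary": {k: float(v) for k, v in self.auxiliary.items()},
            "n_terms": self.n_terms,
        }


def _orderless_mean(values: np.ndarray) -> float:
    """Mean that is invariant to the order of its inputs (sorted summation)."""
    return float(np.mean(np.sort(np.asarray(values, dtype=float))))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def apparent_error(
    y: np.ndarray, X: np.ndarray, spec: ModelSpec, opts: FitOptions | None = None
) -> EstimatorResult:
    """In-sample (training) RMSE from a single full-data fit.

    Equals sqrt(phi / N); downward-biased for generalization error
    ("optimism").
    """
    fit = fit_era(y, X, spec, opts)
    value = rmse(y, predict(fit, X))
    return EstimatorResult(
        method="apparent",
        value=value,
        settings={},
        per_resample=None,
        auxiliary={"phi": fit.phi, "fit": fit.fit},
        n_terms=spec.n_terms,
    )


def cv_error(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    plan: FoldPlan,
    opts: FitOptions | None = None,
) -> EstimatorResult:
    """c-fold cross-validation RMSE (unweighted mean of per-fold RMSEs)."""
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if plan.n != y.shape[0]:
        raise ERAError("fold plan does not match data size")
    fold_values = np.empty(plan.c)
    for j in range(plan.c):
        test = plan.assignment == j
        train = ~test
        n_train = int(train.sum())
        if n_train <= spec.n_terms + 1:
            raise InfeasibleFoldError(
                f"fold {j} leaves {n_train} observations for {spec.n_terms} terms"
            )
        fit = fit_era(y[train], X[train], spec, opts)
        fold_values[j] = rmse(y[test], predict(fit, X[test]))
    return EstimatorResult(
        method=f"cv{plan.c}",
        value=_orderless_mean(fold_values),
        settings={"c": plan.c, "seed": plan.seed},
        per_resample=fold_values,
        n_terms=spec.n_terms,
    )


def loocv_error(
    y: np.ndarray, X: np.ndarray, spec: ModelSpec, opts: FitOptions | None = None
) -> EstimatorResult:
    """Leave-one-out CV: the c = N case; deterministic (no randomness).

    With singleton validation folds the per-fold RMSE is the absolute
    prediction error of the held-out observation, so the estimate is the
    mean absolute leave-one-out error.
    """
    n = np.asarray(y).ravel().shape[0]
    plan = FoldPlan(n=n, c=n, assignment=np.arange(n), seed=None)
    res = cv_error(y, X, spec, plan, opts)
    res.method = "loocv"
    res.settings = {}
    return res


def oob_error(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    plan: BootstrapPlan,
    opts: FitOptions | None = None,
) -> EstimatorResult:
    """Out-of-bag bootstrap RMSE, averaged over the B draws.

    The model (including standardization) is refit on each in-bag sample
    and scored on the corresponding OOB rows.  Draws whose fit fails are
    skipped with a warning; more than 10% failures is an error.
    """
    values = _oob_draw_errors(y, X, spec, plan, opts)
    return EstimatorResult(
        method=f"oob{plan.b}",
        value=_orderless_mean(values),
        settings={"B": plan.b, "seed": plan.seed},
        per_resample=values,
        n_terms=spec.n_terms,
    )


def _oob_draw_errors(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    plan: BootstrapPlan,
    opts: FitOptions | None,
) -> np.ndarray:
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if plan.n != y.shape[0]:
        raise ERAError("bootstrap plan does not match data size")
    values: list[float] = []
    n_failed = 0
    for i in range(plan.b):
        ib = plan.in_bag[i]
        out = plan.oob[i]
        try:
            fit = fit_era(y[ib], X[ib], spec, opts)
        except ERAError as exc:
            n_failed += 1
            warnings.warn(f"bootstrap draw {i} skipped: {exc}", RuntimeWarning)
            continue
        values.append(rmse(y[out], predict(fit, X[out])))
    if n_failed > 0.1 * plan.b:
        raise ERAError(f"{n_failed} of {plan.b} bootstrap fits failed")
    return np.asarray(values)


# ---------------------------------------------------------------------------
# 0.632 family
# ---------------------------------------------------------------------------


def no_info_error(y: np.ndarray, y_hat_train: np.ndarray) -> float:
    """No-information error rate gamma on the RMSE scale.

    The all-pairs form: gamma = sqrt( mean_{i,j} (y_i - yhat_j)^2 ), the
    expected loss when predictions are decoupled from responses.
    """
    y = np.asarray(y, float).ravel()
    yh = np.asarray(y_hat_train, float).ravel()
    if y.size == 0 or yh.size == 0:
        raise ERAError("no_info_error of empty vectors is undefined")
    if y.shape != yh.shape:
        raise ERAError("y and y_hat have different lengths")
    # mean_{i,j}(y_i - yh_j)^2 = mean(y^2) - 2 mean(y) mean(yh) + mean(yh^2)
    g2 = float(np.mean(y * y) - 2.0 * y.mean() * yh.mean() + np.mean(yh * yh))
    return float(np.sqrt(max(g2, 0.0)))


def relative_overfitting(err_train: float, err_oob: float, gamma: float) -> float:
    """Relative overfitting R = (Err_OOB - ErrTrain)/(gamma - ErrTrain), in [0, 1].

    Degenerate cases (gamma <= ErrTrain, or no apparent overfitting) give 0;
    values are clipped to [0, 1] against sampling noise.
    """
    if min(err_train, err_oob, gamma) < 0:
        raise ERAError("error inputs must be nonnegative")
    if gamma <= err_train or err_oob <= err_train:
        return 0.0
    return float(np.clip((err_oob - err_train) / (gamma - err_train), 0.0, 1.0))


def weight_632plus(r: float) -> float:
    """0.632+ weight omega = 0.632 / (1 - 0.368 R); omega(0)=0.632, omega(1)=1."""
    if not 0.0 <= r <= 1.0:
        raise ERAError(f"R must lie in [0, 1]; got {r}")
    return 0.632 / (1.0 - 0.368 * r)


def err632(err_train: float, err_oob: float) -> float:
    """The 0.632 estimator: 0.632 * ErrTrain + 0.368 * Err_OOB."""
    if min(err_train, err_oob) < 0:
        raise ERAError("error inputs must be nonnegative")
    return 0.632 * err_train + 0.368 * err_oob


def err632plus(err_train: float, err_oob: float, gamma: float) -> EstimatorResult:
    """The 0.632+ estimator: omega * ErrTrain + (1 - omega) * Err_OOB.

    omega is derived from the relative overfitting R, which depends on the
    no-information error rate gamma.  At R = 0 this reduces to the 0.632
    estimator.  (At R = 1 the printed combination puts full weight on
    ErrTrain; see the package methods note on this convention.)
    """
    r = relative_overfitting(err_train, err_oob, gamma)
    omega = weight_632plus(r)
    value = omega * err_train + (1.0 - omega) * err_oob
    return EstimatorResult(
        method="632plus",
        value=float(value),
        auxiliary={"err_train": err_train, "err_oob": err_oob, "gamma": gamma, "R": r, "omega": omega},
    )


def bootstrap_estimates(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    plan: BootstrapPlan,
    opts: FitOptions | None = None,
) -> dict[str, EstimatorResult]:
    """OOB, 0.632 and 0.632+ estimates sharing one set of bootstrap fits.

    Returns a dict with keys ``"oob"``, ``"632"`` and ``"632plus"``.  The
    apparent error and the no-information rate come from a single
    full-data fit.
    """
    full = fit_era(y, X, spec, opts)
    y_hat = predict(full, X)
    err_train = rmse(y, y_hat)
    gamma = no_info_error(y, y_hat)
    draw_values = _oob_draw_errors(y, X, spec, plan, opts)
    err_oob = _orderless_mean(draw_values)

    oob_res = EstimatorResult(
        method=f"oob{plan.b}",
        value=err_oob,
        settings={"B": plan.b, "seed": plan.seed},
        per_resample=draw_values,
        auxiliary={"err_train": err_train},
        n_terms=spec.n_terms,
    )
    res632 = EstimatorResult(
        method=f"632-{plan.b}",
        value=err632(err_train, err_oob),
        settings={"B": plan.b, "seed": plan.seed},
        auxiliary={"err_train": err_train, "err_oob": err_oob},
        n_terms=spec.n_terms,
    )
    resplus = err632plus(err_train, err_oob, gamma)
    resplus.method = f"632plus-{plan.b}"
    resplus.settings = {"B": plan.b, "seed": plan.seed}
    resplus.n_terms = spec.n_terms
    return {"oob": oob_res, "632": res632, "632plus": resplus}


def select_model(results: Sequence[EstimatorResult]) -> int:
    """Index of the candidate with the smallest estimated prediction error.

    All results must come from the same estimation method; exact ties are
    broken toward the candidate with fewer terms (parsimony).
    """
    if not results:
        raise ERAError("no candidate results to select from")
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ERAError(f"cannot compare estimates from mixed methods: {sorted(methods)}")
    def key(i: int):
        r = results[i]
        nt = r.n_terms if r.n_terms is not None else np.inf
        return (r.value, nt, i)
    return min(range(len(results)), key=key)
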