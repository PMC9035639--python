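"""Population model, data generator, and the two simulation studies.

The generating model is a two-component ERA model: each component is a
unit-norm weighted composite of ``Np`` standard-normal predictors, the
components are uncorrelated with unit variance, and the response is

    y = b1 * f1 + b2 * f2 + e,   Var(e) = 1 - R^2,

with b1 = 0.3 and R^2 = 0.4, giving b2 = sqrt(R^2 - b1^2) = 0.5568 (the
exact value; 0.56 when rounded).  Raw component weights are drawn i.i.d.
from U(0.8, 1) and normalized to unit Euclidean norm per block, so under
the identity within-block predictor covariance each component has variance
exactly 1.  The joint covariance of (predictors, response) is then

    Sigma_xx = I_P,   Sigma_xy = W b,   Sigma_yy = 1,

and datasets are i.i.d. draws from MVN(0, Sigma).

Candidate models probe mis-specification: f0 omits the second component
(under-specified), f1 is the generating model, f2 adds a component
interaction, f3 adds the interaction plus both quadratics
(over-specified).

Two studies are provided:

* :func:`run_optimism_study` quantifies the optimism of the in-sample
  metrics (FIT and apparent RMSE) against a Monte-Carlo estimate of the
  expected test error;
* :func:`run_estimator_comparison` compares the resampling estimators
  (c-fold CV, LOOCV, OOB/0.632/0.632+ bootstrap) across candidates,
  including the model each estimator selects.

All randomness flows from one master seed through ``SeedSequence`` spawns,
so every cell and replication is independently reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    BlockSpec,
    ERAError,
    ERAFitResult,
    FitOptions,
    ModelSpec,
    Term,
    fit_era,
    predict,
    rmse,
)
from .resampling import (
    EstimatorResult,
    apparent_error,
    bootstrap_estimates,
    cv_error,
    loocv_error,
    make_bootstrap,
    make_cv_folds,
    select_model,
)

__all__ = [
    "SimulationTruth",
    "StudyConfig",
    "StudyResult",
    "sample_true_weights",
    "derive_b2",
    "build_sigma",
    "make_truth",
    "generate_dataset",
    "candidate_specs",
    "true_error_mc",
    "run_optimism_study",
    "run_estimator_comparison",
]

CANDIDATES = ("f0", "f1", "f2", "f3")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationTruth:
    """The generating ERA model and its implied covariance."""

    n_components: int
    n_pred_per_comp: int
    weights: tuple[np.ndarray, ...]  # unit-norm per block
    b: np.ndarray
    r_squared: float
    error_var: float
    sigma: np.ndarray  # (P+1) x (P+1); last row/col is the response
    seed: int | None

    @property
    def n_predictors(self) -> int:
        return self.n_components * self.n_pred_per_comp

    def block_spec(self) -> BlockSpec:
        npp = self.n_pred_per_comp
        return BlockSpec(
            (f"block{k + 1}", tuple(range(k * npp, (k + 1) * npp)))
            for k in range(self.n_components)
        )


def sample_true_weights(
    n_pred_per_comp: int, n_components: int, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, ...]:
    """Raw weights ~ U(0.8, 1) i.i.d., normalized to unit norm per block.

    Unit-norm weights make each component's variance exactly 1 when the
    within-block predictor covariance is the identity.
    """
    if n_pred_per_comp < 1 or n_components < 1:
        raise ERAError("need at least one predictor per component and one component")
    rng = seed if hasattr(seed, "uniform") else np.random.default_rng(seed)
    out = []
    for _ in range(n_components):
        w = rng.uniform(0.8, 1.0, size=n_pred_per_comp)
        out.append(w / np.linalg.norm(w))
    return tuple(out)


def derive_b2(b1: float, r_squared: float) -> float:
    """Second coefficient implied by b1 and total R^2 for uncorrelated
    unit-variance components: b2 = sqrt(R^2 - b1^2)."""
    if not r_squared > b1 * b1:
        raise ERAError(
            f"R^2 = {r_squared} must exceed b1^2 = {b1 * b1}; no variance left for b2"
        )
    return float(np.sqrt(r_squared - b1 * b1))


def build_sigma(weights: Sequence[np.ndarray], b: np.ndarray) -> np.ndarray:
    """Joint covariance of (predictors, response) implied by the ERA truth.

    Predictors are mutually uncorrelated with unit variance; the response
    covariance with predictor p in block k is w_kp * b_k; Var(y) = 1.
    """
    b = np.asarray(b, float).ravel()
    if len(weights) != b.shape[0]:
        raise ERAError("one coefficient per component is required")
    r2 = float(b @ b)
    if r2 > 1.0 + 1e-12:
        raise ERAError(f"b'b = {r2} exceeds 1; response variance cannot be 1")
    wb = np.concatenate([w * bk for w, bk in zip(weights, b)])
    p = wb.shape[0]
    sigma = np.eye(p + 1)
    sigma[:p, p] = wb
    sigma[p, :p] = wb
    eig_min = float(np.linalg.eigvalsh(sigma).min())
    if eig_min < -1e-10:
        raise ERAError(f"constructed covariance is not PSD (min eig {eig_min})")
    return sigma


def make_truth(
    n_pred_per_comp: int,
    n_components: int = 2,
    b1: float = 0.3,
    r_squared: float = 0.4,
    seed: int | np.random.Generator | None = None,
) -> SimulationTruth:
    """Sample a ground truth at the study's default parameter values."""
    weights = sample_true_weights(n_pred_per_comp, n_components, seed)
    if n_components == 2:
        b = np.array([b1, derive_b2(b1, r_squared)])
    else:
        # equal split of the remaining explained variance across components
        rest = (r_squared - b1 * b1) / (n_components - 1)
        b = np.array([b1] + [np.sqrt(rest)] * (n_components - 1))
    sigma = build_sigma(weights, b)
    return SimulationTruth(
        n_components=n_components,
        n_pred_per_comp=n_pred_per_comp,
        weights=weights,
        b=b,
        r_squared=r_squared,
        error_var=1.0 - r_squared,
        sigma=sigma,
        seed=seed if isinstance(seed, int) else None,
    )


def generate_dataset(
    sigma: np.ndarray, n: int, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. rows from MVN(0, sigma); last coordinate is the response."""
    rng = seed if hasattr(seed, "standard_normal") else np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, sigma.shape[0]))
    data = z @ chol.T
    return data[:, :-1], data[:, -1]


def candidate_specs(base: BlockSpec) -> dict[str, ModelSpec]:
    """The four mis-specification candidates built on a two-block base.

    f0 drops the second component entirely (its block spec keeps only the
    first block); f1 is the generating structure; f2 adds the component
    interaction; f3 additionally adds both quadratics.
    """
    if base.n_components != 2:
        raise ERAError("candidate suite is defined for exactly two blocks")
    b1, b2 = base.names
    f0 = ModelSpec(base.subset([b1]), [Term("linear", b1)])
    f1 = ModelSpec(base, [Term("linear", b1), Term("linear", b2)])
    f2 = ModelSpec(base, [*f1.terms, Term("interaction", b1, b2)])
    f3 = ModelSpec(base, [*f2.terms, Term("quadratic", b1), Term("quadratic", b2)])
    return {"f0": f0, "f1": f1, "f2": f2, "f3": f3}


def true_error_mc(
    fit: ERAFitResult,
    sigma: np.ndarray,
    n_sets: int,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo expected test error: mean RMSE over independent test sets.

    Generates ``n_sets`` fresh size-``n`` samples from the population and
    averages the RMSE of the fitted model's predictions.
    """
    rng = seed if hasattr(seed, "standard_normal") else np.random.default_rng(seed)
    X, y = generate_dataset(sigma, n_sets * n, rng)
    err = y - predict(fit, X)
    per_set = np.sqrt(np.mean(err.reshape(n_sets, n) ** 2, axis=1))
    return float(per_set.mean())


# ---------------------------------------------------------------------------
# Study configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Settings for the optimism and estimator-comparison studies.

    Defaults reproduce the full study conditions (1,000 replications per
    cell, N in {50, 100, 200, 500, 1000}, Np in {2, 4, 6, 8});
    :meth:`scaled` gives a reduced profile (200 reps, 200 test sets,
    single cell N=100, Np=2) for routine runs.
    """

    n_grid: tuple[int, ...] = (50, 100, 200, 500, 1000)
    np_grid: tuple[int, ...] = (2, 4, 6, 8)
    reps: int = 1000
    cv_folds: tuple[int, ...] = (3, 5, 10)
    include_loocv: bool = True
    boot_reps: tuple[int, ...] = (20, 50, 100)
    n_test_sets: int = 1000
    b1: float = 0.3
    r_squared: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.reps < 1:
            raise ERAError("reps must be >= 1")
        if not self.n_grid or not self.np_grid:
            raise ERAError("sample-size and predictor grids must be non-empty")

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "StudyConfig":
        base = dict(
            n_grid=(100,),
            np_grid=(2,),
            reps=200,
            cv_folds=(3, 5, 10),
            boot_reps=(50,),
            n_test_sets=200,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class StudyResult:
    """Tidy per-replication records plus aggregated summaries."""

    config: StudyConfig
    per_rep: pd.DataFrame  # one row per (N, Np, rep, candidate[, estimator])
    summary: pd.DataFrame  # aggregated per (N, Np, candidate[, estimator])
    selections: pd.DataFrame | None = None  # per (N, Np, estimator, candidate)


def _cell_iter(cfg: StudyConfig):
    idx = 0
    for n in cfg.n_grid:
        for npp in cfg.np_grid:
            yield idx, n, npp
            idx += 1


def _fit_candidates(
    y: np.ndarray, X: np.ndarray, specs: dict[str, ModelSpec]
) -> dict[str, ERAFitResult]:
    """Fit f0..f3 in order, warm-starting each from the previous solution."""
    fits: dict[str, ERAFitResult] = {}
    prev = None
    for name in CANDIDATES:
        fits[name] = fit_era(y, X, specs[name], init_params=prev)
        prev = fits[name].params
    return fits


def run_optimism_study(cfg: StudyConfig) -> StudyResult:
    """In-sample optimism of FIT and apparent RMSE across candidates.

    Per replication, every candidate is fit (warm-started along the nested
    chain f0 -> f3) and its FIT, apparent RMSE and Monte-Carlo expected
    test error are recorded.  The summary reports per-candidate means and
    the mean optimism (Err - apparent RMSE); selection frequencies by the
    FIT criterion (argmax) are also aggregated.
    """
    root = np.random.SeedSequence(cfg.seed)
    cells = list(_cell_iter(cfg))
    cell_seeds = root.spawn(len(cells))
    records = []
    for (idx, n, npp), cell_ss in zip(cells, cell_seeds):
        truth_ss, *rep_seeds = cell_ss.spawn(cfg.reps + 1)
        truth = make_truth(npp, b1=cfg.b1, r_squared=cfg.r_squared,
                           seed=np.random.default_rng(truth_ss))
        specs = candidate_specs(truth.block_spec())
        for rep, rep_ss in enumerate(rep_seeds):
            rng = np.random.default_rng(rep_ss)
            X, y = generate_dataset(truth.sigma, n, rng)
            fits = _fit_candidates(y, X, specs)
            for cand in CANDIDATES:
                fit = fits[cand]
                err = true_error_mc(fit, truth.sigma, cfg.n_test_sets, n, rng)
                records.append(
                    dict(N=n, Np=npp, rep=rep, candidate=cand,
                         fit=fit.fit, rmse_train=fit.rmse_train, err=err)
                )
    per_rep = pd.DataFrame.from_records(records)
    summary = (
        per_rep.groupby(["N", "Np", "candidate"], as_index=False)
        .agg(mean_fit=("fit", "mean"), mean_rmse_train=("rmse_train", "mean"),
             sd_rmse_train=("rmse_train", "std"), mean_err=("err", "mean"))
    )
    summary["optimism"] = summary["mean_err"] - summary["mean_rmse_train"]
    # selection by the in-sample FIT criterion (argmax over candidates)
    sel_rows = []
    for (n, npp, rep), grp in per_rep.groupby(["N", "Np", "rep"]):
        best = grp.loc[grp["fit"].idxmax(), "candidate"]
        sel_rows.append(dict(N=n, Np=npp, estimator="fit", candidate=best))
    selections = (
        pd.DataFrame.from_records(sel_rows)
        .groupby(["N", "Np", "estimator", "candidate"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    selections["frequency"] = selections.groupby(["N", "Np", "estimator"])["count"].transform(
        lambda s: s / s.sum()
    )
    return StudyResult(config=cfg, per_rep=per_rep, summary=summary, selections=selections)


def run_estimator_comparison(cfg: StudyConfig) -> StudyResult:
    """Compare the out-of-sample estimators across candidates.

    Per replication and candidate the study computes the apparent error,
    c-fold CV for each configured c, LOOCV, and the OOB/0.632/0.632+
    trio for each configured B (sharing one set of bootstrap fits per B).
    The summary aggregates mean, SD and bias against the Monte-Carlo
    expected test error; selection frequencies record how often each
    estimator's minimum lands on each candidate.
    """
    root = np.random.SeedSequence(cfg.seed)
    cells = list(_cell_iter(cfg))
    cell_seeds = root.spawn(len(cells))
    records = []
    err_records = []
    for (idx, n, npp), cell_ss in zip(cells, cell_seeds):
        truth_ss, *rep_seeds = cell_ss.spawn(cfg.reps + 1)
        truth = make_truth(npp, b1=cfg.b1, r_squared=cfg.r_squared,
                           seed=np.random.default_rng(truth_ss))
        specs = candidate_specs(truth.block_spec())
        for rep, rep_ss in enumerate(rep_seeds):
            rng = np.random.default_rng(rep_ss)
            X, y = generate_dataset(truth.sigma, n, rng)
            plan_seeds = rng.integers(0, 2**31 - 1, size=len(cfg.cv_folds) + len(cfg.boot_reps))
            fold_plans = [make_cv_folds(n, c, int(s)) for c, s in zip(cfg.cv_folds, plan_seeds)]
            boot_plans = [
                make_bootstrap(n, b, int(s))
                for b, s in zip(cfg.boot_reps, plan_seeds[len(cfg.cv_folds):])
            ]
            for cand in CANDIDATES:
                spec = specs[cand]
                ests: list[EstimatorResult] = [apparent_error(y, X, spec)]
                for plan in fold_plans:
                    ests.append(cv_error(y, X, spec, plan))
                if cfg.include_loocv:
                    ests.append(loocv_error(y, X, spec))
                for plan in boot_plans:
                    trio = bootstrap_estimates(y, X, spec, plan)
                    ests.extend([trio["oob"], trio["632"], trio["632plus"]])
                for est in ests:
                    records.append(
                        dict(N=n, Np=npp, rep=rep, candidate=cand,
                             estimator=est.method, value=est.value)
                    )
                if cfg.n_test_sets > 0:
                    fit = fit_era(y, X, spec)
                    err = true_error_mc(fit, truth.sigma, cfg.n_test_sets, n, rng)
                    err_records.append(dict(N=n, Np=npp, rep=rep, candidate=cand, err=err))
    per_rep = pd.DataFrame.from_records(records)
    summary = (
        per_rep.groupby(["N", "Np", "candidate", "estimator"], as_index=False)
        .agg(mean=("value", "mean"), sd=("value", "std"))
    )
    if err_records:
        errs = (
            pd.DataFrame.from_records(err_records)
            .groupby(["N", "Np", "candidate"], as_index=False)
            .agg(err=("err", "mean"))
        )
        summary = summary.merge(errs, on=["N", "Np", "candidate"], how="left")
        summary["bias"] = summary["mean"] - summary["err"]
    # per-estimator selection frequencies (argmin over candidates, ties to
    # the smaller model)
    n_terms = {"f0": 1, "f1": 2, "f2": 3, "f3": 5}
    sel_rows = []
    for (n, npp, rep, est), grp in per_rep.groupby(["N", "Np", "rep", "estimator"]):
        grp = grp.sort_values("candidate")
        results = [
            EstimatorResult(method=str(est), value=v, n_terms=n_terms[c])
            for c, v in zip(grp["candidate"], grp["value"])
        ]
        best = grp["candidate"].iloc[select_model(results)]
        sel_rows.append(dict(N=n, Np=npp, estimator=est, candidate=best))
    selections = (
        pd.DataFrame.from_records(sel_rows)
        .groupby(["N", "Np", "estimator", "candidate"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    selections["frequency"] = selections.groupby(["N", "Np", "estimator"])["count"].transform(
        lambda s: s / s.sum()
    )
    return StudyResult(config=cfg, per_rep=per_rep, summary=summary, selections=selections)
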