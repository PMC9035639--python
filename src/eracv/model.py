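"""Core extended redundancy analysis (ERA) model.

ERA relates K blocks of predictors to a continuous response by collapsing
each block into a single weighted composite (a *component*),

    y_i = sum_k b_k * f_ik + e_i,        f_ik = sum_p x_ikp * w_kp,

and estimating the component weights ``W`` and regression coefficients ``b``
jointly by least squares, subject to the identification constraint
``diag(F'F) = N I`` (each component score vector has sum of squares N).
Models may additionally contain component-level interaction (f_k * f_l) and
quadratic (f_k^2) terms.

This module provides the model/term specification types, training-sample
standardization, the alternating-least-squares (ALS) fitting routine,
prediction on new data, and the in-sample metrics FIT (an R^2-type index)
and RMSE.

Conventions
-----------
* Predictors are standardized to mean 0, variance 1 with divisor N (not
  N-1), so a unit-variance column has sum of squares exactly N, matching
  the component-scale constraint.
* The response is centered on its training mean; the mean is added back
  at prediction time.  The model itself carries no intercept.
* Sign indeterminacy of each (w_k, b) pair is resolved by forcing the
  first nonzero weight of every block to be positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ERAError",
    "DegenerateColumnError",
    "InsufficientDataError",
    "DegenerateResponseError",
    "RankDeficiencyError",
    "BlockSpec",
    "Term",
    "linear",
    "interaction",
    "quadratic",
    "ModelSpec",
    "StandardizationParams",
    "ERAParameters",
    "FitOptions",
    "ERAFitResult",
    "standardize_fit",
    "apply_standardization",
    "compute_term_scores",
    "era_objective",
    "fit_era",
    "fit_metric",
    "predict",
    "rmse",
]


class ERAError(ValueError):
    """Base class for model-specification and fitting errors."""


class DegenerateColumnError(ERAError):
    """A predictor column is constant and cannot be standardized."""


class InsufficientDataError(ERAError):
    """Too few observations for the requested model."""


class DegenerateResponseError(ERAError):
    """The response has zero variance; FIT is undefined."""


class RankDeficiencyError(ERAError):
    """A block design matrix is singular in a way that prevents fitting."""


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """Ordered assignment of predictor columns to named blocks.

    Parameters
    ----------
    blocks
        Sequence of ``(name, column_indices)`` pairs.  Indices refer to
        columns of the predictor matrix ``X`` and must be distinct across
        blocks.  Under-specified candidate models may legitimately leave
        some columns of ``X`` unassigned; such columns are simply ignored
        by the fit.
    """

    blocks: tuple[tuple[str, tuple[int, ...]], ...]

    def __init__(self, blocks: Iterable[tuple[str, Sequence[int]]]):
        normalized = tuple((str(name), tuple(int(i) for i in idx)) for name, idx in blocks)
        if len(normalized) < 1:
            raise ERAError("BlockSpec requires at least one block")
        seen_names: set[str] = set()
        seen_idx: set[int] = set()
        for name, idx in normalized:
            if name in seen_names:
                raise ERAError(f"duplicate block name {name!r}")
            seen_names.add(name)
            if len(idx) == 0:
                raise ERAError(f"block {name!r} is empty")
            for i in idx:
                if i < 0:
                    raise ERAError(f"block {name!r} has negative column index {i}")
                if i in seen_idx:
                    raise ERAError(f"column index {i} appears in more than one block")
                seen_idx.add(i)
        object.__setattr__(self, "blocks", normalized)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    @property
    def n_components(self) -> int:
        return len(self.blocks)

    def indices(self, name: str) -> tuple[int, ...]:
        for bname, idx in self.blocks:
            if bname == name:
                return idx
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "BlockSpec":
        """Blocks restricted to ``names`` (order preserved)."""
        keep = [b for b in self.blocks if b[0] in set(names)]
        return BlockSpec(keep)


@dataclass(frozen=True)
class Term:
    """One component-level regression term.

    ``kind`` is ``"linear"``, ``"interaction"`` or ``"quadratic"``;
    ``first``/``second`` are block names (``second`` only for interactions).
    """

    kind: str
    first: str
    second: str | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "interaction", "quadratic"):
            raise ERAError(f"unknown term kind {self.kind!r}")
        if (self.kind == "interaction") != (self.second is not None):
            raise ERAError("interaction terms need exactly two blocks")

    @property
    def blocks_involved(self) -> tuple[str, ...]:
        if self.kind == "interaction":
            return (self.first, self.second)  # type: ignore[return-value]
        return (self.first,)

    @property
    def label(self) -> str:
        if self.kind == "interaction":
            return f"interaction:{self.first}*{self.second}"
        return f"{self.kind}:{self.first}"


def linear(block: str) -> Term:
    return Term("linear", block)


def interaction(block_a: str, block_b: str) -> Term:
    return Term("interaction", block_a, block_b)


def quadratic(block: str) -> Term:
    return Term("quadratic", block)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate ERA model: a block map plus component-level terms."""

    block_spec: BlockSpec
    terms: tuple[Term, ...]

    def __init__(self, block_spec: BlockSpec, terms: Iterable[Term]):
        terms = tuple(terms)
        names = set(block_spec.names)
        order = {n: i for i, n in enumerate(block_spec.names)}
        canon: list[Term] = []
        for t in terms:
            for b in t.blocks_involved:
                if b not in names:
                    raise ERAError(f"term {t.label!r} references unknown block {b!r}")
            if t.kind == "interaction":
                if t.first == t.second:
                    raise ERAError(
                        f"interaction of block {t.first!r} with itself; use quadratic"
                    )
                # canonical block order within the interaction
                if order[t.first] > order[t.second]:  # type: ignore[index]
                    t = Term("interaction", t.second, t.first)  # type: ignore[arg-type]
            canon.append(t)
        if len({t.label for t in canon}) != len(canon):
            raise ERAError("duplicate terms in model specification")
        linear_blocks = {t.first for t in canon if t.kind == "linear"}
        missing = names - linear_blocks
        if missing:
            raise ERAError(
                f"every block needs a linear term; missing for {sorted(missing)}"
            )
        object.__setattr__(self, "block_spec", block_spec)
        object.__setattr__(self, "terms", tuple(canon))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationParams:
    """Training-sample means/SDs of predictors and the response mean.

    SDs use divisor N so a standardized column has sum of squares N.
    """

    mean: np.ndarray
    sd: np.ndarray
    y_mean: float

    @property
    def n_predictors(self) -> int:
        return self.mean.shape[0]


def standardize_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, StandardizationParams]:
    """Standardize predictors (mean 0, divisor-N variance 1) and center y.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 observations are supplied.
    DegenerateColumnError
        If any predictor column is constant (names the column index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ERAError("X must be a 2-D array")
    n = X.shape[0]
    if y.shape[0] != n:
        raise ERAError("X and y have different numbers of observations")
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # divisor N
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if bad.size:
        raise DegenerateColumnError(
            f"predictor column(s) {bad.tolist()} are constant and cannot be standardized"
        )
    Z = (X - mean) / sd
    y_mean = float(y.mean())
    y_c = y - y_mean
    return Z, y_c, StandardizationParams(mean=mean, sd=sd, y_mean=y_mean)


def apply_standardization(X_new: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Transform new data with *training* means and SDs (no refitting)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != params.n_predictors:
        raise ERAError(
            f"expected {params.n_predictors} predictor columns, got {X_new.shape[1]}"
        )
    return (X_new - params.mean) / params.sd


# ---------------------------------------------------------------------------
# Parameters and scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ERAParameters:
    """Component weights (per block) and term coefficients.

    ``weights`` maps block name -> weight vector over that block's columns
    (equivalently, the nonzero entries of the block-diagonal P x K weight
    matrix W).  ``b`` is aligned with ``ModelSpec.terms``.
    """

    weights: Mapping[str, np.ndarray]
    b: np.ndarray

    def weight_matrix(self, block_spec: BlockSpec, n_predictors: int) -> np.ndarray:
        """The explicit P x K block-diagonal weight matrix."""
        W = np.zeros((n_predictors, block_spec.n_components))
        for k, (name, idx) in enumerate(block_spec.blocks):
            W[list(idx), k] = self.weights[name]
        return W


def compute_term_scores(
    Z: np.ndarray, params: ERAParameters, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Component scores F (N x K) and term design T (N x n_terms).

    ``Z`` must already be standardized with the training parameters.
    Linear terms copy the component column, interactions are elementwise
    products of two components, quadratics are elementwise squares.
    """
    Z = np.asarray(Z, dtype=float)
    bs = spec.block_spec
    n = Z.shape[0]
    F = np.empty((n, bs.n_components))
    col = {}
    for k, (name, idx) in enumerate(bs.blocks):
        w = np.asarray(params.weights[name], dtype=float)
        if w.shape[0] != len(idx):
            raise ERAError(f"weight vector for block {name!r} has wrong length")
        F[:, k] = Z[:, list(idx)] @ w
        col[name] = k
    T = np.empty((n, spec.n_terms))
    for j, t in enumerate(spec.terms):
        if t.kind == "linear":
            T[:, j] = F[:, col[t.first]]
        elif t.kind == "interaction":
            T[:, j] = F[:, col[t.first]] * F[:, col[t.second]]
        else:
            T[:, j] = F[:, col[t.first]] ** 2
    return F, T


def era_objective(y_c: np.ndarray, T: np.ndarray, b: np.ndarray) -> float:
    """Least-squares objective phi = SS(y_c - T b)."""
    r = np.asarray(y_c, float).ravel() - np.asarray(T, float) @ np.asarray(b, float).ravel()
    return float(r @ r)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error; indifferent to error sign."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size == 0:
        raise ERAError("rmse of empty vectors is undefined")
    if y.shape != y_hat.shape:
        raise ERAError("y and y_hat have different lengths")
    d = y - y_hat
    return float(np.sqrt(np.mean(d * d)))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """ALS control knobs.

    max_iter : maximum number of full (W, b) update cycles.
    tol      : relative decrease in phi below which iteration stops.
    init     : "ones" (deterministic default) or "random" U(0,1) weights.
    seed     : RNG seed for random initialization.
    n_restarts : number of random restarts (best phi kept); only
        meaningful with ``init="random"``.
    """

    max_iter: int = 500
    tol: float = 1e-8
    init: str = "ones"
    seed: int | None = None
    n_restarts: int = 1

    def __post_init__(self):
        if self.max_iter < 1:
            raise ERAError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ERAError("tol must be > 0")
        if self.init not in ("ones", "random"):
            raise ERAError("init must be 'ones' or 'random'")


@dataclass
class ERAFitResult:
    """Everything produced by one ALS fit."""

    spec: ModelSpec
    params: ERAParameters
    std: StandardizationParams
    F: np.ndarray
    term_scores: np.ndarray
    phi: float
    fit: float
    rmse_train: float
    iterations: int
    converged: bool
    objective_trace: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.F.shape[0]


def _normalize_block_weights(Zk: np.ndarray, w: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Rescale w so SS(Zk w) = n; returns (w_scaled, scale s) with w = w_in / s."""
    f = Zk @ w
    s = float(np.sqrt((f @ f) / n))
    if s < 1e-12:
        raise RankDeficiencyError("block scores are numerically zero under this weighting")
    return w / s, s


def _init_weights(
    spec: ModelSpec,
    Zb: Sequence[np.ndarray],
    n: int,
    opts: FitOptions,
    init_params: ERAParameters | None,
    rng: np.random.Generator | None,
) -> list[np.ndarray]:
    ws: list[np.ndarray] = []
    for k, (name, idx) in enumerate(spec.block_spec.blocks):
        w0 = None
        if init_params is not None and name in init_params.weights:
            cand = np.asarray(init_params.weights[name], dtype=float)
            if cand.shape[0] == len(idx):
                w0 = cand.copy()
        if w0 is None:
            if opts.init == "random":
                assert rng is not None
                w0 = rng.uniform(0.0, 1.0, size=len(idx))
            else:
                w0 = np.ones(len(idx))
        try:
            w0, _ = _normalize_block_weights(Zb[k], w0, n)
        except RankDeficiencyError:
            # e.g. ones-weighting of anti-correlated columns: fall back to e1
            w0 = np.zeros(len(idx))
            w0[0] = 1.0
            w0, _ = _normalize_block_weights(Zb[k], w0, n)
        ws.append(w0)
    return ws


def _ols(T: np.ndarray, y_c: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of y_c on T (minimum-norm on rank deficiency)."""
    G = T.T @ T
    try:
        c = np.linalg.cholesky(G)
        b = np.linalg.solve(c.T, np.linalg.solve(c, T.T @ y_c))
        return b
    except np.linalg.LinAlgError:
        b, *_ = np.linalg.lstsq(T, y_c, rcond=None)
        return b


def _als_single(
    y_c: np.ndarray,
    Zb: list[np.ndarray],
    spec: ModelSpec,
    opts: FitOptions,
    w_init: list[np.ndarray],
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """One ALS run from a given initialization.

    Alternates (i) joint OLS update of all term coefficients b given the
    current components, and (ii) per-block weight updates by least squares
    of the block's partial residual on its (linearized) contribution,
    renormalizing each updated block and absorbing the scale into the
    affected coefficients.  Weight updates that would increase phi (possible
    only when a block carries a quadratic term, whose update is linearized)
    are rejected, so the recorded objective trace is non-increasing.
    """
    n = y_c.shape[0]
    names = spec.block_spec.names
    col = {name: k for k, name in enumerate(names)}
    terms = spec.terms

    # per-block list of (term_index, role) where role in {lin, int_other_k, quad}
    involving: list[list[int]] = [[] for _ in names]
    for j, t in enumerate(terms):
        for bname in set(t.blocks_involved):
            involving[col[bname]].append(j)

    ws = [w.copy() for w in w_init]

    def scores() -> tuple[np.ndarray, np.ndarray]:
        F = np.empty((n, len(names)))
        for k in range(len(names)):
            F[:, k] = Zb[k] @ ws[k]
        T = np.empty((n, len(terms)))
        for j, t in enumerate(terms):
            if t.kind == "linear":
                T[:, j] = F[:, col[t.first]]
            elif t.kind == "interaction":
                T[:, j] = F[:, col[t.first]] * F[:, col[t.second]]
            else:
                T[:, j] = F[:, col[t.first]] ** 2
        return F, T

    F, T = scores()
    b = _ols(T, y_c)
    phi = era_objective(y_c, T, b)
    trace = [phi]

    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # (ii) weight updates, block by block
        for k in range(len(names)):
            inv = involving[k]
            if not inv:
                continue
            mask = np.ones(len(terms), bool)
            mask[inv] = False
            r = y_c - T[:, mask] @ b[mask]
            G = np.zeros((n, Zb[k].shape[1]))
            for j in inv:
                t = terms[j]
                if t.kind == "linear":
                    G += b[j] * Zb[k]
                elif t.kind == "interaction":
                    other = t.second if col[t.first] == k else t.first
                    G += b[j] * (F[:, col[other]][:, None] * Zb[k])
                else:  # quadratic, linearized at the current component
                    G += b[j] * (F[:, k][:, None] * Zb[k])
            gnorm = float(np.abs(G).max(initial=0.0))
            if gnorm < 1e-12:
                continue  # all relevant coefficients ~0: weights unidentified
            w_new, *_ = np.linalg.lstsq(G, r, rcond=None)
            f_new = Zb[k] @ w_new
            s = float(np.sqrt((f_new @ f_new) / n))
            if s < 1e-12:
                continue
            w_new = w_new / s
            b_new = b.copy()
            for j in inv:
                b_new[j] *= s * s if terms[j].kind == "quadratic" else s
            ws_old, b_old, F_old, T_old = ws[k], b, F.copy(), T.copy()
            ws[k] = w_new
            F, T = scores()
            phi_cand = era_objective(y_c, T, b_new)
            if phi_cand <= phi:
                b, phi = b_new, phi_cand
            else:  # linearized quadratic step overshot: keep previous weights
                ws[k], b, F, T = ws_old, b_old, F_old, T_old

        # (i) joint coefficient update
        b = _ols(T, y_c)
        phi_new = era_objective(y_c, T, b)
        if phi_new > phi + 1e-12 * max(phi, 1.0):  # numerically impossible; guard
            phi_new = phi
        trace.append(phi_new)
        if (phi - phi_new) < opts.tol * max(phi, 1e-30):
            phi = phi_new
            converged = True
            break
        phi = phi_new

    return ws, b, F, T, trace, it, converged  # type: ignore[return-value]


def fit_era(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    opts: FitOptions | None = None,
    init_params: ERAParameters | None = None,
) -> ERAFitResult:
    """Fit an ERA model by alternating least squares.

    Parameters
    ----------
    y, X
        Raw (unstandardized) response and predictor matrix.  Predictors
        are standardized internally (divisor-N) and the response centered;
        the training parameters are stored on the result and reused by
        :func:`predict`.
    spec
        Block structure and component-level terms.
    opts
        ALS controls; defaults to :class:`FitOptions`.
    init_params
        Optional warm start: blocks present in ``init_params.weights``
        start from those weights (renormalized), others from the default
        initialization.

    Returns
    -------
    ERAFitResult
        Non-convergence within ``max_iter`` is reported via the
        ``converged`` flag, not an exception.
    """
    opts = opts or FitOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n <= spec.n_terms + 1:
        raise InsufficientDataError(
            f"need more than {spec.n_terms + 1} observations for {spec.n_terms} terms, got {n}"
        )
    Z, y_c, std = standardize_fit(X, y)
    ss_y = float(y_c @ y_c)
    if ss_y <= 0:
        raise DegenerateResponseError("response has zero variance in the training sample")

    bs = spec.block_spec
    Zb = [np.ascontiguousarray(Z[:, list(idx)]) for _, idx in bs.blocks]
    for (name, idx), Zk in zip(bs.blocks, Zb):
        if len(idx) > 1 and np.linalg.matrix_rank(Zk) < len(idx):
            warnings.warn(
                f"block {name!r} is rank deficient; weights resolved by least squares",
                RuntimeWarning,
                stacklevel=2,
            )

    rng = np.random.default_rng(opts.seed) if opts.init == "random" else None
    n_starts = max(1, opts.n_restarts) if opts.init == "random" else 1
    best = None
    for _ in range(n_starts):
        w0 = _init_weights(spec, Zb, n, opts, init_params, rng)
        run = _als_single(y_c, Zb, spec, opts, w0)
        if best is None or run[4][-1] < best[4][-1]:
            best = run
    assert best is not None
    ws, b, F, T, trace, iters, converged = best

    # sign convention: first nonzero weight of each block positive
    sigma = np.ones(bs.n_components)
    for k, w in enumerate(ws):
        nz = np.flatnonzero(np.abs(w) > 1e-12)
        lead = w[nz[0]] if nz.size else 1.0
        if lead < 0:
            sigma[k] = -1.0
            ws[k] = -w
            F[:, k] = -F[:, k]
    col = {name: k for k, name in enumerate(bs.names)}
    for j, t in enumerate(spec.terms):
        if t.kind == "linear":
            fac = sigma[col[t.first]]
        elif t.kind == "interaction":
            fac = sigma[col[t.first]] * sigma[col[t.second]]
        else:
            fac = 1.0
        b[j] *= fac
        T[:, j] *= fac

    phi = trace[-1]
    params = ERAParameters(weights={name: ws[k] for k, name in enumerate(bs.names)}, b=b)
    return ERAFitResult(
        spec=spec,
        params=params,
        std=std,
        F=F,
        term_scores=T,
        phi=phi,
        fit=1.0 - phi / ss_y,
        rmse_train=float(np.sqrt(phi / n)),
        iterations=iters,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def fit_metric(result: ERAFitResult, y_c: np.ndarray) -> float:
    """FIT = 1 - phi / SS(y_c), the R^2-type in-sample index (in [0, 1])."""
    y_c = np.asarray(y_c, float).ravel()
    ss = float(y_c @ y_c)
    if ss <= 0:
        raise DegenerateResponseError("SS(y_c) is zero; FIT undefined")
    return 1.0 - result.phi / ss


def predict(result: ERAFitResult, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses for new data, using training standardization.

    New predictors are transformed with the *training* means/SDs, component
    and term scores are built from the trained weights, and the training
    response mean is added back.
    """
    Z_new = apply_standardization(X_new, result.std)
    _, T_new = compute_term_scores(Z_new, result.params, result.spec)
    return T_new @ result.params.b + result.std.y_mean
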