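"""Regression layer: single models, grid search CV and the stacking ensemble.

Families: multiple linear regression (MLR), partial least squares (PLS),
support vector regression (SVR, C fixed at 1), a back-propagation neural
network (BPNN, an MLP regressor), and random forest (RF).  Inputs and the
target are min-max scaled to [-1, 1] on the training fold for the families
that need it (PLS/SVR/BPNN); predictions are inverse-scaled before metrics,
so every reported number is in the target's original units.

Hyperparameters are chosen by exhaustive grid search under seeded 5-fold
cross-validation, selecting on mean R^2 (ties: lower mean RMSE, then grid
order).  The stacking fusion model (SFM) trains PLS/SVR/BPNN bases, builds
the (m, p) out-of-fold prediction matrix over k folds, fits a BPNN
meta-learner on it, and at inference feeds full-data base refits to the meta
model.

An optional audit list records the training indices of every internal fit so
fold hygiene (no estimator ever sees held-out samples) is testable.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "StackSpec",
    "ScalerState",
    "CvResult",
    "FitRecord",
    "kfold_split",
    "regression_metrics",
    "default_grid",
    "fit_base",
    "ModelPipeline",
    "grid_search",
    "StackingModel",
    "stacking_fit",
    "evaluate_variant",
]

FAMILIES = ("MLR", "PLS", "SVR", "BPNN", "RF")
#: families whose inputs/target are min-max scaled to [-1, 1]
_SCALED = {"PLS", "SVR", "BPNN"}

#: default optimizer iteration cap; generous for n ~ 10^2 training sets (the
#: study-scale cap of 15000 can be requested per grid cell via "max_iter")
_BPNN_MAX_ITER = 2_000
_BPNN_ALPHA = 1e-4


# ---------------------------------------------------------------------------
# folds and metrics


def kfold_split(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint seeded index sets covering range(n), sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split n={n} samples into k={k} folds")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """R^2, RMSE and MAPE (as a fraction).

        R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
        RMSE = sqrt(mean (yhat - y)^2)
        MAPE = mean |(yhat - y) / y|

    R^2 is NaN for a constant y; MAPE is NaN when any y is zero.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length 1-D arrays")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    resid = y - yhat
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot < 1e-300 else 1.0 - float((resid**2).sum()) / ss_tot
    rmse = float(np.sqrt((resid**2).mean()))
    mape = float("nan") if np.any(y == 0) else float(np.abs(resid / y).mean())
    return {"R2": r2, "RMSE": rmse, "MAPE": mape}


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerState:
    """Per-column min-max maps onto [-1, 1], fitted on training rows only."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "ScalerState":
        return cls(X.min(axis=0), X.max(axis=0), float(y.min()), float(y.max()))

    @staticmethod
    def _affine(v, lo, hi):
        span = np.where(hi - lo > 1e-15, hi - lo, 1.0)
        return 2.0 * (v - lo) / span - 1.0

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return self._affine(X, self.x_min, self.x_max)

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return self._affine(y, self.y_min, self.y_max)

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min if self.y_max - self.y_min > 1e-15 else 1.0
        return (np.asarray(y_scaled) + 1.0) / 2.0 * span + self.y_min


# ---------------------------------------------------------------------------
# model specs and grids


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: tuple[dict[str, Any], ...] | None = None  # None -> default grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    def cells(self, n_features: int) -> list[dict[str, Any]]:
        if self.grid is not None:
            return [dict(c) for c in self.grid]
        return default_grid(self.family, n_features)


@dataclass(frozen=True)
class StackSpec:
    """Two-layer stack: grid-searched bases feeding a BPNN meta-learner."""

    base_families: tuple[str, ...] = ("PLS", "SVR", "BPNN")
    k: int = 5
    meta_hidden: tuple[int, ...] = (10,)
    meta_activation: str = "identity"
    meta_solver: str = "lbfgs"

    def __post_init__(self) -> None:
        if len(self.base_families) < 2:
            raise ValueError("a stack needs at least 2 base learners")


def default_grid(family: str, n_features: int, full: bool = False) -> list[dict[str, Any]]:
    """Hyperparameter lattice per family (``full`` = study-scale ranges).

    Defaults are compact lattices that contain the optima the study-scale
    search lands on; the full grids trace the literal published ranges and are
    orders of magnitude slower.
    """
    if family == "MLR":
        return [{}]
    if family == "PLS":
        top = max(1, min(10, n_features))
        return [{"n_components": c} for c in range(1, top + 1)]
    if family == "SVR":
        return [
            {"kernel": k, "gamma": g}
            for k in ("linear", "poly", "rbf", "sigmoid")
            for g in ("scale", "auto")
        ]
    if family == "BPNN":
        layers = range(1, 31) if full else (1, 2)
        neurons = range(1, 101) if full else (10, 50)
        solvers = ("lbfgs", "adam", "sgd") if full else ("lbfgs",)
        return [
            {"hidden_layer_sizes": (nn,) * nl, "activation": act, "solver": sol}
            for nl in layers
            for nn in neurons
            for act in ("identity", "logistic", "tanh", "relu")
            for sol in solvers
        ]
    if family == "RF":
        trees = range(10, 101) if full else (10, 40, 70, 100)
        splits = (2, 3, 4, 5) if full else (2, 5)
        leaves = (1, 2, 3, 4, 5) if full else (1, 3, 5)
        return [
            {"n_estimators": t, "min_samples_split": s, "min_samples_leaf": l}
            for t in trees
            for s in splits
            for l in leaves
        ]
    raise ValueError(f"unknown family {family!r}")


def fit_base(family: str, params: dict[str, Any], seed: int = 0) -> BaseEstimator:
    """Construct the (unfitted) estimator for one grid cell."""
    if family == "MLR":
        return LinearRegression()
    if family == "PLS":
        return PLSRegression(n_components=params.get("n_components", 2), scale=False)
    if family == "SVR":
        return SVR(C=1.0, kernel=params.get("kernel", "rbf"), gamma=params.get("gamma", "scale"))
    if family == "BPNN":
        return MLPRegressor(
            hidden_layer_sizes=params.get("hidden_layer_sizes", (10,)),
            activation=params.get("activation", "relu"),
            solver=params.get("solver", "lbfgs"),
            alpha=params.get("alpha", _BPNN_ALPHA),
            max_iter=params.get("max_iter", _BPNN_MAX_ITER),
            random_state=seed,
        )
    if family == "RF":
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", 100),
            min_samples_split=params.get("min_samples_split", 2),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed,
        )
    raise ValueError(f"unknown family {family!r}")


@dataclass
class FitRecord:
    """Audit entry: which samples one internal fit was trained on."""

    component: str
    train_indices: tuple[int, ...]
    fold: int | None = None


class ModelPipeline:
    """Scaling + estimator bundle honoring each family's scaling contract."""

    def __init__(self, family: str, params: dict[str, Any] | None = None, seed: int = 0,
                 estimator: BaseEstimator | None = None, scaled: bool | None = None):
        self.family = family
        self.params = dict(params or {})
        self.seed = seed
        self._proto = estimator  # externally supplied estimator (e.g. in tests)
        self.scaled = (family in _SCALED) if scaled is None else scaled
        self.scaler: ScalerState | None = None
        self.estimator_: BaseEstimator | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModelPipeline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.family == "PLS" and self._proto is None:
            # component count cannot exceed the fold's feature count or n-1
            cap = max(1, min(X.shape[1], len(y) - 1))
            if self.params.get("n_components", 2) > cap:
                self.params = {**self.params, "n_components": cap}
        est = clone(self._proto) if self._proto is not None else fit_base(self.family, self.params, self.seed)
        if self.scaled:
            self.scaler = ScalerState.fit(X, y)
            Xs, ys = self.scaler.transform_x(X), self.scaler.transform_y(y)
        else:
            Xs, ys = X, y
        if self.family == "MLR" and np.linalg.matrix_rank(np.column_stack([Xs, np.ones(len(Xs))])) <= Xs.shape[1]:
            warnings.warn("MLR: singular design matrix; minimum-norm least squares", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, ys)
        self.estimator_ = est
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.estimator_ is None:
            raise RuntimeError("pipeline not fitted")
        X = np.asarray(X, dtype=float)
        Xs = self.scaler.transform_x(X) if self.scaled else X
        pred = np.asarray(self.estimator_.predict(Xs), dtype=float).ravel()
        return self.scaler.inverse_y(pred) if self.scaled else pred


# ---------------------------------------------------------------------------
# grid search


@dataclass
class CvResult:
    variant: str
    family: str
    fold_metrics: list[dict[str, float]]
    oof_predictions: np.ndarray
    chosen_params: Any
    seed: int = 0

    @property
    def mean_r2(self) -> float:
        return float(np.mean([m["R2"] for m in self.fold_metrics]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([m["RMSE"] for m in self.fold_metrics]))

    @property
    def mean_mape(self) -> float:
        return float(np.mean([m["MAPE"] for m in self.fold_metrics]))

    def summary(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "family": self.family,
            "R2": self.mean_r2,
            "RMSE": self.mean_rmse,
            "MAPE": self.mean_mape,
            "params": self.chosen_params,
        }


def _cv_eval_cell(
    make_pipeline,
    fold_data: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    folds: list[np.ndarray],
    n: int,
    audit: list[FitRecord] | None,
    component: str,
    train_index_sets: list[np.ndarray] | None = None,
) -> tuple[list[dict[str, float]], np.ndarray]:
    """Run one grid cell through the fixed folds; return fold metrics + OOF."""
    oof = np.full(n, np.nan)
    fold_metrics = []
    for f, ((X_tr, y_tr, X_te, y_te), test_idx) in enumerate(zip(fold_data, folds)):
        pipe = make_pipeline()
        pipe.fit(X_tr, y_tr)
        if audit is not None and train_index_sets is not None:
            audit.append(FitRecord(component, tuple(map(int, train_index_sets[f])), fold=f))
        pred = pipe.predict(X_te)
        fold_metrics.append(regression_metrics(y_te, pred))
        oof[test_idx] = pred
    return fold_metrics, oof


def grid_search(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    audit: list[FitRecord] | None = None,
    variant: str = "",
) -> tuple[dict[str, Any], CvResult]:
    """Exhaustive grid traversal under seeded k-fold CV.

    Selection: highest mean R^2, ties broken by lower mean RMSE, then first in
    grid order.  Folds are fixed across cells so cells are comparable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cells = spec.cells(X.shape[1])
    if not cells:
        raise ValueError("empty hyperparameter grid")
    folds = kfold_split(n, k, seed)
    train_sets = [np.setdiff1d(np.arange(n), f) for f in folds]
    fold_data = [(X[tr], y[tr], X[te], y[te]) for tr, te in zip(train_sets, folds)]

    best = None  # (neg_r2, rmse, order, cell, fold_metrics, oof)
    failures = []
    for order, cell in enumerate(cells):
        try:
            fm, oof = _cv_eval_cell(
                lambda: ModelPipeline(spec.family, cell, spec.seed),
                fold_data, folds, n, audit, f"{spec.family}{cell}", train_sets,
            )
        except Exception as exc:  # keep searching; report if everything fails
            failures.append((cell, repr(exc)))
            continue
        key = (-np.mean([m["R2"] for m in fm]), np.mean([m["RMSE"] for m in fm]), order)
        if best is None or key < best[0]:
            best = (key, cell, fm, oof)
    if best is None:
        raise RuntimeError(f"all grid cells failed: {failures}")
    _, cell, fm, oof = best
    result = CvResult(
        variant=variant,
        family=spec.family,
        fold_metrics=fm,
        oof_predictions=oof,
        chosen_params=cell,
        seed=seed,
    )
    return cell, result


# ---------------------------------------------------------------------------
# stacking


class StackingModel:
    """Fitted two-layer stacking fusion model."""

    def __init__(self, stack: StackSpec, seed: int = 0):
        self.stack = stack
        self.seed = seed
        self.base_params: list[dict[str, Any]] = []
        self.base_pipelines_: list[ModelPipeline] = []
        self.base_names: list[str] = []
        self.meta_: ModelPipeline | None = None
        self.oof_matrix_: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.meta_ is None:
            raise RuntimeError("stack not fitted")
        meta_X = np.column_stack([p.predict(X) for p in self.base_pipelines_])
        return self.meta_.predict(meta_X)


def _base_spec_list(stack: StackSpec, seed: int,
                    bases: Sequence[Any] | None) -> list[tuple[str, Any]]:
    """Resolve base definitions to (name, ModelSpec-or-estimator) pairs."""
    if bases is None:
        return [(fam, ModelSpec(fam, seed=seed)) for fam in stack.base_families]
    out = []
    for i, b in enumerate(bases):
        if isinstance(b, ModelSpec):
            out.append((b.family, b))
        elif isinstance(b, str):
            out.append((b, ModelSpec(b, seed=seed)))
        else:  # prebuilt estimator (cloned per fit), e.g. in leakage tests
            out.append((f"base{i}_{type(b).__name__}", b))
    return out


def stacking_fit(
    X: np.ndarray,
    y: np.ndarray,
    stack: StackSpec = StackSpec(),
    seed: int = 0,
    audit: list[FitRecord] | None = None,
    bases: Sequence[Any] | None = None,
    sample_indices: np.ndarray | None = None,
) -> StackingModel:
    """Fit the stacking fusion model on training data.

    Per base: hyperparameters are grid searched on (X, y); the base is then
    trained k times on fold complements to fill its out-of-fold (OOF) column.
    The meta BPNN is trained on the (m, p) OOF matrix; for inference the bases
    are refit on all of (X, y).  ``sample_indices`` (defaults to 0..n-1) is
    only used for audit records.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * stack.k:
        raise ValueError(f"stacking needs n >= 2k (= {2 * stack.k}); got n={n}")
    idx = np.arange(n) if sample_indices is None else np.asarray(sample_indices)

    model = StackingModel(stack, seed=seed)
    resolved = _base_spec_list(stack, seed, bases)
    folds = kfold_split(n, stack.k, seed)
    train_sets = [np.setdiff1d(np.arange(n), f) for f in folds]

    oof = np.empty((n, len(resolved)))
    for col, (name, base) in enumerate(resolved):
        if isinstance(base, ModelSpec):
            try:
                params, _ = grid_search(base, X, y, k=stack.k, seed=seed, audit=None)
            except Exception as exc:
                raise RuntimeError(f"stacking base {name!r} failed: {exc}") from exc
            make = lambda: ModelPipeline(base.family, params, base.seed)
            model.base_params.append(params)
        else:
            make = lambda: ModelPipeline("MLR", estimator=base, scaled=False)
            model.base_params.append({})
        model.base_names.append(name)
        for tr, te in zip(train_sets, folds):
            pipe = make()
            try:
                pipe.fit(X[tr], y[tr])
            except Exception as exc:
                raise RuntimeError(f"stacking base {name!r} failed: {exc}") from exc
            if audit is not None:
                audit.append(FitRecord(f"stack-base:{name}", tuple(map(int, idx[tr]))))
            oof[te, col] = pipe.predict(X[te])
        # inference-time base: refit on all training data
        full_pipe = make()
        full_pipe.fit(X, y)
        if audit is not None:
            audit.append(FitRecord(f"stack-base-full:{name}", tuple(map(int, idx))))
        model.base_pipelines_.append(full_pipe)

    model.oof_matrix_ = oof
    meta = ModelPipeline(
        "BPNN",
        {
            "hidden_layer_sizes": stack.meta_hidden,
            "activation": stack.meta_activation,
            "solver": stack.meta_solver,
        },
        seed=seed,
    )
    meta.fit(oof, y)
    if audit is not None:
        audit.append(FitRecord("stack-meta", tuple(map(int, idx))))
    model.meta_ = meta
    return model


# ---------------------------------------------------------------------------
# variant-level evaluation


def evaluate_variant(
    table,
    y: np.ndarray,
    variant_name: str,
    family: str,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.7,
    stack: StackSpec = StackSpec(),
    grids: dict[str, tuple[dict[str, Any], ...]] | None = None,
    audit: list[FitRecord] | None = None,
    paper_mode_selectors: bool = False,
) -> CvResult:
    """Cross-validated metrics for one (input variant, model family) cell.

    ``family`` is one of the five single families or ``"SFM"``.  Selectors
    (correlation screen / PCA) and scalers are refit inside each training fold
    by default; ``paper_mode_selectors=True`` fits them once on all rows first
    (the discipline described in the source study).  Metrics are computed on
    each held-out fold in original target units; hyperparameters for single
    families are chosen by grid search on mean CV R^2 over the same folds.
    """
    from .select import VariantBuilder

    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = kfold_split(n, k, seed)
    for f in folds:
        if len(f) < 2:
            raise ValueError("every fold needs at least 2 test samples")
    train_sets = [np.setdiff1d(np.arange(n), f) for f in folds]

    # per-fold design matrices via fold-local (or paper-mode global) selectors
    fold_data = []
    if paper_mode_selectors:
        vb = VariantBuilder(variant_name, threshold=threshold).fit(table, y)
        if audit is not None:
            audit.append(FitRecord(f"selector:{variant_name}(paper-mode)", tuple(range(n))))
    for tr, te in zip(train_sets, folds):
        if not paper_mode_selectors:
            vb = VariantBuilder(variant_name, threshold=threshold).fit(table.iloc[tr], y[tr])
            if audit is not None:
                audit.append(FitRecord(f"selector:{variant_name}", tuple(map(int, tr))))
        X_tr = vb.transform(table.iloc[tr]).X
        X_te = vb.transform(table.iloc[te]).X
        fold_data.append((X_tr, y[tr], X_te, y[te]))

    if family == "SFM":
        oof = np.full(n, np.nan)
        fold_metrics, chosen = [], []
        for f, ((X_tr, y_tr, X_te, y_te), te, tr) in enumerate(zip(fold_data, folds, train_sets)):
            sfm = stacking_fit(X_tr, y_tr, stack=stack, seed=seed, audit=audit, sample_indices=tr)
            pred = sfm.predict(X_te)
            fold_metrics.append(regression_metrics(y_te, pred))
            oof[te] = pred
            chosen.append(sfm.base_params)
        return CvResult(variant_name, "SFM", fold_metrics, oof, chosen, seed=seed)

    grid = None
    if grids and family in grids:
        grid = tuple(grids[family])
    spec = ModelSpec(family, grid=grid, seed=seed)
    cells = spec.cells(fold_data[0][0].shape[1])

    best = None
    for order, cell in enumerate(cells):
        fm, oof = _cv_eval_cell(
            lambda: ModelPipeline(family, cell, seed),
            fold_data, folds, n, audit, f"{family}{cell}", train_sets,
        )
        key = (-np.mean([m["R2"] for m in fm]), np.mean([m["RMSE"] for m in fm]), order)
        if best is None or key < best[0]:
            best = (key, cell, fm, oof)
    _, cell, fm, oof = best
    return CvResult(variant_name, family, fm, oof, cell, seed=seed)
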