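"""Minimal cross-validated convex ensemble ("super learner").

All nuisance regressions in the package go through :func:`fit_ensemble`:
candidate learners are fit on inner-CV training folds, their held-out
predictions are stacked, and a convex weight vector minimizing the
held-out risk is solved on the probability simplex. The ensemble's
held-out risk can never exceed the best single learner's (the vertex is
always a fallback candidate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "EnsembleFit",
    "fit_ensemble",
    "predict_ensemble",
    "default_library",
    "EnsembleFitError",
]

PROB_CLIP = (0.001, 0.999)

FAMILIES = ("mean", "linear", "tree", "bagged_trees", "knn")


class EnsembleFitError(RuntimeError):
    """Raised when every candidate learner fails to fit."""


@dataclass(frozen=True)
class LearnerSpec:
    """A named candidate learner: family plus hyperparameters."""

    name: str
    family: str
    params: tuple = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")

    @classmethod
    def make(cls, name: str, family: str, **params) -> "LearnerSpec":
        return cls(name, family, tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


class _MeanLearner:
    """Predicts the training mean. Works for both losses (mean of a binary
    response is its event probability)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


def _build_estimator(spec: LearnerSpec, binary: bool, seed: int):
    p = spec.param_dict
    if spec.family == "mean":
        return _MeanLearner()
    if spec.family == "linear":
        if binary:
            return LogisticRegression(max_iter=1000, C=p.get("C", 1e6))
        return LinearRegression()
    if spec.family == "tree":
        cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
        return cls(
            max_depth=p.get("max_depth", 4),
            min_samples_leaf=p.get("min_samples_leaf", 10),
            random_state=seed,
        )
    if spec.family == "bagged_trees":
        base_cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
        bag_cls = BaggingClassifier if binary else BaggingRegressor
        return bag_cls(
            estimator=base_cls(
                max_depth=p.get("max_depth", None),
                min_samples_leaf=p.get("min_samples_leaf", 5),
            ),
            n_estimators=p.get("n_estimators", 25),
            random_state=seed,
        )
    if spec.family == "knn":
        cls = KNeighborsClassifier if binary else KNeighborsRegressor
        return cls(n_neighbors=p.get("n_neighbors", 10))
    raise ValueError(spec.family)  # pragma: no cover


def default_library() -> list[LearnerSpec]:
    """Mean, linear, shallow tree, and bagged trees — the desk-scale default."""
    return [
        LearnerSpec.make("mean", "mean"),
        LearnerSpec.make("linear", "linear"),
        LearnerSpec.make("tree_d4", "tree", max_depth=4),
        LearnerSpec.make("bagged_trees", "bagged_trees", n_estimators=25),
    ]


@dataclass
class EnsembleFit:
    learners: list[LearnerSpec]
    weights: np.ndarray
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    inner_V: int
    loss: str
    models: list = field(repr=False, default_factory=list)
    binary: bool = False
    n_features: int = 0


def _predict_one(model, X: np.ndarray, binary: bool) -> np.ndarray:
    if binary and hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        # column for class 1; degenerate single-class fits fall back below
        classes = list(getattr(model, "classes_", [0, 1]))
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(len(X))
    return np.asarray(model.predict(X), dtype=float)


def _risk(pred: np.ndarray, y: np.ndarray, loss: str) -> float:
    if loss == "squared":
        return float(np.mean((pred - y) ** 2))
    p = np.clip(pred, *PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solve_weights(Z: np.ndarray, y: np.ndarray, loss: str) -> np.ndarray:
    """Convex weights on the simplex minimizing held-out risk.

    Squared error: non-negative least squares then normalization. Binary
    log-likelihood: simplex-constrained minimization. Either way the best
    single learner (a simplex vertex) is kept if it beats the solved
    combination, so the oracle inequality holds by construction.
    """
    L = Z.shape[1]
    single = np.array([_risk(Z[:, j], y, loss) for j in range(L)])
    best_vertex = np.zeros(L)
    best_vertex[int(np.argmin(single))] = 1.0
    if L == 1:
        return best_vertex

    if loss == "squared":
        # Standardize by the response moments before NNLS so the solved
        # weights are exactly invariant to affine rescaling of y (every
        # equivariant learner's column transforms with y).
        mu, sd = float(np.mean(y)), float(np.std(y))
        if sd < 1e-12:
            return best_vertex
        w, _ = nnls((Z - mu) / sd, (y - mu) / sd)
        total = w.sum()
        cand = w / total if total > 0 else best_vertex
    else:
        def neg_ll(w):
            return _risk(Z @ w, y, loss)

        res = minimize(
            neg_ll,
            np.full(L, 1.0 / L),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * L,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        cand = np.clip(res.x, 0, None)
        cand = cand / cand.sum() if cand.sum() > 0 else best_vertex

    if _risk(Z @ cand, y, loss) <= _risk(Z @ best_vertex, y, loss):
        return cand
    return best_vertex


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    library: Sequence[LearnerSpec],
    inner_V: int = 5,
    loss: str = "squared",
    seed: int = 0,
) -> EnsembleFit:
    """Fit the convex ensemble by inner cross-validation.

    Parameters
    ----------
    X : (n, d) feature matrix; d may be 0 (replaced by a constant column so
        every learner degenerates to the mean).
    y : response; in {0,1} when ``loss == "nll"``.
    library : candidate learner specs; names must be unique.
    inner_V : inner CV folds used to produce held-out predictions.
    loss : ``"squared"`` or ``"nll"``.
    seed : drives fold shuffling and any stochastic learner.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if n < 2 * inner_V:
        raise ValueError(f"need n >= 2*inner_V rows (n={n}, inner_V={inner_V})")
    if not library:
        raise ValueError("learner library is empty")
    names = [s.name for s in library]
    if len(set(names)) != len(names):
        raise ValueError("learner names must be unique within a library")
    if loss not in ("squared", "nll"):
        raise ValueError(f"unknown loss {loss!r}")

    binary = loss == "nll"
    if X.shape[1] == 0:
        X = np.zeros((n, 1))

    degenerate = binary and len(np.unique(y)) < 2
    L = len(library)
    Z = np.full((n, L), np.nan)
    ok = np.zeros(L, dtype=bool)
    kf = KFold(n_splits=inner_V, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    for j, spec in enumerate(library):
        if degenerate and spec.family != "mean":
            continue
        try:
            col = np.empty(n)
            for tr, te in splits:
                est = _build_estimator(spec, binary, seed)
                est.fit(X[tr], y[tr])
                col[te] = _predict_one(est, X[te], binary)
            Z[:, j] = col
            ok[j] = True
        except Exception as exc:  # noqa: BLE001 — failed learners get weight 0
            logger.warning("learner %r failed during CV: %s", spec.name, exc)

    if degenerate and not ok.any():
        # one-class binary response: fall back to the mean learner
        mean_spec = LearnerSpec.make("mean", "mean")
        m = _MeanLearner().fit(X, y)
        return EnsembleFit(
            learners=[mean_spec],
            weights=np.array([1.0]),
            cv_risks=np.array([_risk(np.full(n, m.mean_), y, loss)]),
            ensemble_cv_risk=_risk(np.full(n, m.mean_), y, loss),
            inner_V=inner_V,
            loss=loss,
            models=[m],
            binary=binary,
            n_features=X.shape[1],
        )
    if not ok.any():
        raise EnsembleFitError("every learner in the library failed to fit")

    idx = np.flatnonzero(ok)
    if binary:
        Z[:, idx] = np.clip(Z[:, idx], *PROB_CLIP)
    w_ok = _solve_weights(Z[:, idx], y, loss)
    weights = np.zeros(L)
    weights[idx] = w_ok
    cv_risks = np.array(
        [_risk(Z[:, j], y, loss) if ok[j] else np.inf for j in range(L)]
    )
    ens_risk = _risk(Z[:, idx] @ w_ok, y, loss)

    models: list = []
    for j, spec in enumerate(library):
        if ok[j]:
            est = _build_estimator(spec, binary, seed)
            est.fit(X, y)
            models.append(est)
        else:
            models.append(None)

    return EnsembleFit(
        learners=list(library),
        weights=weights,
        cv_risks=cv_risks,
        ensemble_cv_risk=ens_risk,
        inner_V=inner_V,
        loss=loss,
        models=models,
        binary=binary,
        n_features=X.shape[1],
    )


def predict_ensemble(fit: EnsembleFit, X: np.ndarray) -> np.ndarray:
    """Weighted sum of base-learner predictions; probabilities are clipped."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[1] == 0:
        X = np.zeros((len(X), 1))
    if X.shape[1] != fit.n_features:
        raise ValueError(
            f"feature count mismatch: fit expects {fit.n_features}, got {X.shape[1]}"
        )
    out = np.zeros(len(X))
    for w, model in zip(fit.weights, fit.models):
        if w == 0 or model is None:
            continue
        pred = _predict_one(model, X, fit.binary)
        if fit.binary:
            pred = np.clip(pred, *PROB_CLIP)
        out += w * pred
    if fit.binary:
        out = np.clip(out, *PROB_CLIP)
    return out
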