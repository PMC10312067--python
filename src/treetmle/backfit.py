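"""Iterative backfitting of E(Y|A,W) = f(A) + h(W) and rule extraction.

``f`` is a single regression tree over the joint exposures, selected by
inner cross-validation from a small hyperparameter grid (winner-take-all:
a blended tree ensemble has no single rule set to read off). ``h`` is an
unrestricted convex ensemble over the covariates. The two are fit
alternately against each other's partial residuals until the combined
fitted values stabilize.

A root-only winning tree is a first-class "no rule found" outcome, not an
error: under no exposure signal the intercept model has the lowest CV risk
and no split survives selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .core_data import MixtureDataset, MixtureRule, Predicate
from .super_learner import EnsembleFit, LearnerSpec, fit_ensemble, predict_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "BackfitModel",
    "ComponentThresholds",
    "SampleTooSmallError",
    "iterative_backfit",
    "extract_rules",
    "select_designated_rule",
    "component_thresholds",
    "DEFAULT_TREE_GRID",
]

MIN_BACKFIT_N = 30

# (max_depth, min leaf fraction) pairs; shallow by design — interpretability
# and positivity both degrade with depth.
DEFAULT_TREE_GRID: tuple[tuple[int, float], ...] = (
    (1, 0.05),
    (1, 0.1),
    (2, 0.05),
    (2, 0.1),
    (3, 0.05),
    (3, 0.1),
)


class SampleTooSmallError(ValueError):
    """Backfitting refuses to run on fewer than MIN_BACKFIT_N rows."""


@dataclass
class BackfitModel:
    """Result of the alternating fit; ``tree is None`` means root-only."""

    tree: DecisionTreeRegressor | None
    tree_params: tuple | None
    h_fit: EnsembleFit | None
    f_constant: float
    n_iterations: int
    risk_trace: list[float]
    converged: bool
    tree_grid: tuple
    best_tree_cv_risk: float
    root_cv_risk: float
    no_rule: bool
    exposure_names: list[str] = field(default_factory=list)
    partial_residual: np.ndarray | None = None  # Y - h(W) on the training sample
    f_values: np.ndarray | None = None
    h_values: np.ndarray | None = None

    def predict_f(self, A: np.ndarray) -> np.ndarray:
        if self.tree is None:
            return np.full(len(A), self.f_constant)
        return self.tree.predict(A)


@dataclass
class ComponentThresholds:
    """Data-adaptive cutpoints for one exposure component.

    ``levels`` tile the line: (-inf, c1], (c1, c2], ..., (ck, +inf).
    The reference level is always the lowest interval.
    """

    variable: str
    cutpoints: list[float]
    levels: list[MixtureRule]
    found: bool

    @property
    def reference(self) -> MixtureRule | None:
        return self.levels[0] if self.levels else None


def _tree_cv_risk(
    A: np.ndarray,
    r: np.ndarray,
    max_depth: int,
    min_leaf_frac: float,
    inner_V: int,
    seed: int,
) -> float:
    n = len(r)
    min_leaf = max(1, int(math.ceil(min_leaf_frac * n)))
    kf = KFold(n_splits=inner_V, shuffle=True, random_state=seed)
    sse = 0.0
    for tr, te in kf.split(A):
        t = DecisionTreeRegressor(
            max_depth=max_depth, min_samples_leaf=min_leaf, random_state=seed
        )
        t.fit(A[tr], r[tr])
        sse += float(np.sum((t.predict(A[te]) - r[te]) ** 2))
    return sse / n


def _root_cv_risk(r: np.ndarray, inner_V: int, seed: int) -> float:
    kf = KFold(n_splits=inner_V, shuffle=True, random_state=seed)
    sse = 0.0
    for tr, te in kf.split(r.reshape(-1, 1)):
        sse += float(np.sum((np.mean(r[tr]) - r[te]) ** 2))
    return sse / len(r)


SELECTION_MARGIN = 0.01  # relative CV-risk improvement a split must deliver


def _select_tree(
    A: np.ndarray,
    r: np.ndarray,
    tree_grid: Sequence[tuple[int, float]],
    inner_V: int,
    seed: int,
) -> tuple[DecisionTreeRegressor | None, tuple | None, float, float]:
    """Winner-take-all over the grid, with the intercept-only model as an
    always-present candidate. A tree is selected only when it beats the
    root's CV risk by a relative margin — under pure noise, CV luck
    otherwise promotes spurious splits. Returns
    (tree, params, best_risk, root_risk)."""
    root_risk = _root_cv_risk(r, inner_V, seed)
    best_risk, best_params = root_risk * (1.0 - SELECTION_MARGIN), None
    for depth, frac in tree_grid:
        risk = _tree_cv_risk(A, r, depth, frac, inner_V, seed)
        if risk < best_risk:
            best_risk, best_params = risk, (depth, frac)
    if best_params is None:
        return None, None, root_risk, root_risk
    depth, frac = best_params
    min_leaf = max(1, int(math.ceil(frac * len(r))))
    tree = DecisionTreeRegressor(
        max_depth=depth, min_samples_leaf=min_leaf, random_state=seed
    )
    tree.fit(A, r)
    if tree.tree_.node_count <= 1:  # grid point produced no split
        return None, None, root_risk, root_risk
    return tree, best_params, best_risk, root_risk


def iterative_backfit(
    data: MixtureDataset,
    tree_grid: Sequence[tuple[int, float]] = DEFAULT_TREE_GRID,
    w_library: Sequence[LearnerSpec] | None = None,
    tol: float | None = None,
    max_iter: int = 10,
    inner_V: int = 5,
    seed: int = 0,
    exposure_subset: Sequence[str] | None = None,
) -> BackfitModel:
    """Alternate tree-on-exposures and ensemble-on-covariates fits.

    Initialization is h == 0, f == mean(Y); each pass fits h to the partial
    residual Y - f(A), then re-selects and refits the tree on Y - h(W).
    Stops when the max absolute change in combined fitted values drops
    below ``tol`` (default 1e-3 * sd(Y)), when ``max_iter`` is reached, or
    when the in-sample risk of the combined fit stops improving (the step
    is then rolled back so the recorded risk trace is non-increasing).
    """
    from .super_learner import default_library

    if data.n < MIN_BACKFIT_N:
        raise SampleTooSmallError(
            f"backfitting needs at least {MIN_BACKFIT_N} rows, got {data.n}"
        )
    if tol is not None and tol <= 0:
        raise ValueError("tol must be positive")
    names = list(exposure_subset) if exposure_subset is not None else data.exposure_names
    unknown = [v for v in names if v not in data.exposure_names]
    if unknown:
        raise KeyError(f"unknown exposure column(s): {unknown}")
    A = data.exposures[names].to_numpy(dtype=float)
    W = data.covariate_matrix()
    y = data.outcome
    if w_library is None:
        w_library = default_library()
    sd_y = float(np.std(y))
    if tol is None:
        tol = 1e-3 * max(sd_y, 1e-12)

    f_vals = np.full(data.n, float(np.mean(y)))
    h_vals = np.zeros(data.n)
    tree: DecisionTreeRegressor | None = None
    tree_params: tuple | None = None
    h_fit: EnsembleFit | None = None
    f_constant = float(np.mean(y))
    best_tree_risk = root_risk = math.inf
    risk_trace: list[float] = []
    converged = False
    n_iter = 0

    state = None  # rollback snapshot
    for it in range(1, max_iter + 1):
        n_iter = it
        prev_fit = f_vals + h_vals
        if data.q > 0:
            h_fit = fit_ensemble(
                W, y - f_vals, w_library, inner_V=inner_V, loss="squared",
                seed=seed + it,
            )
            h_vals = predict_ensemble(h_fit, W)
        r = y - h_vals
        tree, tree_params, best_tree_risk, root_risk = _select_tree(
            A, r, tree_grid, inner_V, seed
        )
        if tree is None:
            f_constant = float(np.mean(r))
            f_vals = np.full(data.n, f_constant)
        else:
            f_vals = tree.predict(A)
        combined = f_vals + h_vals
        risk = float(np.mean((y - combined) ** 2))
        if risk_trace and risk > risk_trace[-1] + 1e-6:
            # step made things worse in-sample: roll back and stop
            (tree, tree_params, h_fit, f_constant, f_vals, h_vals,
             best_tree_risk, root_risk) = state
            n_iter = it - 1
            converged = True
            break
        risk_trace.append(risk)
        state = (tree, tree_params, h_fit, f_constant, f_vals.copy(),
                 h_vals.copy(), best_tree_risk, root_risk)
        if np.max(np.abs(combined - prev_fit)) < tol:
            converged = True
            break
        if data.q == 0:
            converged = True  # nothing to alternate against
            break

    return BackfitModel(
        tree=tree,
        tree_params=tree_params,
        h_fit=h_fit,
        f_constant=f_constant,
        n_iterations=n_iter,
        risk_trace=risk_trace,
        converged=converged,
        tree_grid=tuple(tree_grid),
        best_tree_cv_risk=best_tree_risk,
        root_cv_risk=root_risk,
        no_rule=tree is None,
        exposure_names=names,
        partial_residual=y - h_vals,
        f_values=f_vals,
        h_values=h_vals,
    )


def _leaf_rules(
    tree: DecisionTreeRegressor, names: Sequence[str], provenance: str
) -> list[tuple[int, MixtureRule]]:
    """(leaf node index, merged root-to-leaf rule) pairs, ordered by node index."""
    t = tree.tree_
    out: list[tuple[int, MixtureRule]] = []

    def walk(node: int, bounds: dict[str, tuple[float, float]]):
        if t.children_left[node] == -1:
            preds = [Predicate(v, lo, hi) for v, (lo, hi) in bounds.items()]
            if not preds:  # root-only tree has no path conditions
                return
            out.append((node, MixtureRule(tuple(preds), provenance=provenance)))
            return
        var = names[t.feature[node]]
        thr = float(t.threshold[node])
        lo, hi = bounds.get(var, (-math.inf, math.inf))
        left = dict(bounds)
        left[var] = (lo, min(hi, thr))
        walk(t.children_left[node], left)
        right = dict(bounds)
        right[var] = (max(lo, thr), hi)
        walk(t.children_right[node], right)

    walk(0, {})
    out.sort(key=lambda pair: pair[0])
    return out


def extract_rules(model: BackfitModel, data: MixtureDataset) -> list[MixtureRule]:
    """One rule per leaf of the winning tree; empty for a root-only tree.

    sklearn's split ``x <= thr`` (left) / ``x > thr`` (right) maps directly
    onto the half-open interval convention: left tightens the upper bound,
    right raises the lower bound.
    """
    if model.tree is None:
        return []
    unknown = [v for v in model.exposure_names if v not in data.exposure_names]
    if unknown:
        raise KeyError(f"model/exposure schema mismatch: {unknown}")
    return [r for _, r in _leaf_rules(model.tree, model.exposure_names, "")]


def select_designated_rule(
    model: BackfitModel,
    data: MixtureDataset,
    min_support: float = 0.05,
    provenance: str = "",
) -> MixtureRule | None:
    """The leaf rule used for ATE estimation: largest absolute difference
    between leaf-mean partial residual and the overall mean, among leaves
    holding at least ``min_support`` of the sample (positivity guard).
    Ties break toward the smaller leaf index."""
    if model.tree is None or model.partial_residual is None:
        return None
    A = data.exposures[model.exposure_names].to_numpy(dtype=float)
    leaf_of = model.tree.apply(A)
    r = model.partial_residual
    overall = float(np.mean(r))
    min_n = min_support * data.n
    best: tuple[float, int] | None = None
    best_rule = None
    for node, rule in _leaf_rules(model.tree, model.exposure_names, provenance):
        mask = leaf_of == node
        if mask.sum() < min_n or not mask.any():
            continue
        contrast = abs(float(np.mean(r[mask])) - overall)
        key = (-contrast, node)  # max contrast, tie -> smaller node index
        if best is None or key < best:
            best = key
            best_rule = rule
    return best_rule


def component_thresholds(
    data: MixtureDataset,
    variable: str,
    w_library: Sequence[LearnerSpec] | None = None,
    tree_grid: Sequence[tuple[int, float]] = DEFAULT_TREE_GRID,
    tol: float | None = None,
    max_iter: int = 10,
    inner_V: int = 5,
    seed: int = 0,
) -> ComponentThresholds:
    """Backfit with f restricted to single-variable trees on ``variable``
    and read the winning tree's split values off as ordered cutpoints."""
    if variable not in data.exposure_names:
        raise KeyError(f"{variable!r} is not an exposure column")
    model = iterative_backfit(
        data,
        tree_grid=tree_grid,
        w_library=w_library,
        tol=tol,
        max_iter=max_iter,
        inner_V=inner_V,
        seed=seed,
        exposure_subset=[variable],
    )
    if model.tree is None:
        return ComponentThresholds(variable, [], [], found=False)
    t = model.tree.tree_
    cuts = sorted({float(t.threshold[i]) for i in range(t.node_count)
                   if t.children_left[i] != -1})
    return ComponentThresholds(variable, cuts, levels_from_cutpoints(variable, cuts),
                               found=True)


def levels_from_cutpoints(variable: str, cutpoints: Sequence[float]) -> list[MixtureRule]:
    """Interval rules tiling the line: (-inf,c1], (c1,c2], ..., (ck,inf)."""
    if not cutpoints:
        return []
    edges = [-math.inf, *cutpoints, math.inf]
    return [
        MixtureRule((Predicate(variable, lo, hi),))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
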