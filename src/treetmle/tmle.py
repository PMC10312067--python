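"""Cross-validated targeted estimation of rule-membership ATEs.

Per fold: the designated rule and all nuisance functions are learned on
the parameter-generating sample; the targeted point estimate, efficient
influence curve (EIC), and confidence interval are computed on the
held-out estimation sample. Fold results are pooled under the union of
fold rules with a single fluctuation fit on the stacked estimation
samples. The same machinery is reused for per-component threshold
contrasts against the lowest exposure level.

Continuous outcomes are mapped to [0, 1] (bounds from the parameter-
generating sample, widened 10%) so a logistic fluctuation keeps the
updated outcome regression in range; estimates are mapped back to the
original scale at the end.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .backfit import (
    DEFAULT_TREE_GRID,
    component_thresholds,
    iterative_backfit,
    levels_from_cutpoints,
    select_designated_rule,
)
from .core_data import (
    FoldAssignment,
    MixtureDataset,
    MixtureRule,
    assign_folds,
)
from .super_learner import (
    LearnerSpec,
    default_library,
    fit_ensemble,
    predict_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunSettings",
    "NuisanceFit",
    "ATEResult",
    "FoldRecord",
    "ResultsBundle",
    "PositivityError",
    "fit_nuisance",
    "target_ate",
    "run_fold",
    "pool_folds",
    "component_ates",
    "run_cvtreemle",
]

Q_CLIP = (0.001, 0.999)
MIN_CLASS_COUNT = 5
Z_95 = 1.96


class PositivityError(RuntimeError):
    """Too few observations in one treatment class of the parameter-
    generating sample to fit nuisance functions."""


@dataclass
class RunSettings:
    """Method configuration shared by the fold, pooling, and component runs."""

    V: int = 5
    seed: int = 0
    tree_max_depths: tuple[int, ...] = (1, 2, 3)
    tree_min_leaf_fracs: tuple[float, ...] = (0.05, 0.1)
    backfit_tol: float | None = None
    backfit_max_iter: int = 10
    min_support: float = 0.05
    g_bounds: tuple[float, float] = (0.025, 0.975)
    inner_V: int = 5
    w_library: list[LearnerSpec] = field(default_factory=default_library)
    run_components: bool = True

    def __post_init__(self):
        if self.V < 2:
            raise ValueError("V must be at least 2")
        lo, hi = self.g_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("g_bounds must satisfy 0 < lower < upper < 1")

    @property
    def tree_grid(self) -> tuple[tuple[int, float], ...]:
        return tuple(
            (d, f) for d in self.tree_max_depths for f in self.tree_min_leaf_fracs
        )

    def fold_seed(self, v: int) -> int:
        return self.seed * 1009 + v


@dataclass
class NuisanceFit:
    """Out-of-sample nuisance predictions for one (rule, fold) pair.

    Q0/Q1 are the outcome regression at indicator forced to 0/1 on the
    scaled outcome; g1 is the truncated propensity of indicator 1.
    """

    Q0: np.ndarray
    Q1: np.ndarray
    g1: np.ndarray
    g_bounds: tuple[float, float]
    outcome_scale: tuple[float, float]
    binary_outcome: bool


@dataclass
class ATEResult:
    psi: float
    se: float
    ci_lower: float
    ci_upper: float
    eic: np.ndarray = field(repr=False)
    rule_description: str
    scope: str
    n_effective: int
    epsilon: float = 0.0

    def to_row(self) -> dict:
        return {
            "scope": self.scope,
            "rule": self.rule_description,
            "psi": self.psi,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_effective": self.n_effective,
        }


def _is_binary(y: np.ndarray) -> bool:
    return bool(np.isin(np.unique(y), (0.0, 1.0)).all())


def _outcome_scale(y: np.ndarray) -> tuple[float, float]:
    """Scaling bounds from the parameter-generating sample, widened by 10%
    of the range (5% each side) so held-out outcomes rarely clip."""
    lo, hi = float(np.min(y)), float(np.max(y))
    rng = hi - lo
    if rng <= 0:
        rng = max(abs(lo), 1.0)  # constant outcome: any positive width works
    return lo - 0.05 * rng, hi + 0.05 * rng


def fit_nuisance(
    param_sample: MixtureDataset,
    rule: MixtureRule,
    est_sample: MixtureDataset,
    w_library: Sequence[LearnerSpec] | None = None,
    g_bounds: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
    inner_V: int = 5,
    outcome_scale: tuple[float, float] | None = None,
) -> NuisanceFit:
    """Learn outcome regression and propensity on the parameter-generating
    sample for ``rule``; predict on the estimation sample."""
    d_param = rule.evaluate(param_sample.exposures).astype(float)
    n1 = int(d_param.sum())
    n0 = len(d_param) - n1
    if min(n0, n1) < MIN_CLASS_COUNT:
        raise PositivityError(
            f"rule {rule.description!r}: only {min(n0, n1)} observation(s) in the "
            f"rarer class of the parameter-generating sample (need >= {MIN_CLASS_COUNT})"
        )
    return _fit_nuisance_from_indicator(
        param_sample, d_param, est_sample, w_library, g_bounds, seed, inner_V,
        outcome_scale,
    )


def _fit_nuisance_from_indicator(
    param_sample: MixtureDataset,
    d_param: np.ndarray,
    est_sample: MixtureDataset,
    w_library: Sequence[LearnerSpec] | None,
    g_bounds: tuple[float, float],
    seed: int,
    inner_V: int,
    outcome_scale: tuple[float, float] | None,
) -> NuisanceFit:
    if w_library is None:
        w_library = default_library()
    y = param_sample.outcome
    binary = _is_binary(y)
    if binary:
        scale = (0.0, 1.0)
    else:
        scale = outcome_scale if outcome_scale is not None else _outcome_scale(y)
    lo, hi = scale
    y_s = np.clip((y - lo) / (hi - lo), 0.0, 1.0)

    W_param = param_sample.covariate_matrix()
    W_est = est_sample.covariate_matrix()
    Xq = np.column_stack([d_param, W_param])
    q_loss = "nll" if binary else "squared"
    q_fit = fit_ensemble(
        Xq, y_s, w_library, inner_V=inner_V, loss=q_loss, seed=seed
    )
    m = est_sample.n
    X0 = np.column_stack([np.zeros(m), W_est])
    X1 = np.column_stack([np.ones(m), W_est])
    Q0 = np.clip(predict_ensemble(q_fit, X0), *Q_CLIP)
    Q1 = np.clip(predict_ensemble(q_fit, X1), *Q_CLIP)

    g_fit = fit_ensemble(
        W_param, d_param, w_library, inner_V=inner_V, loss="nll", seed=seed + 1
    )
    g1 = np.clip(predict_ensemble(g_fit, W_est), *g_bounds)

    return NuisanceFit(
        Q0=Q0, Q1=Q1, g1=g1, g_bounds=tuple(g_bounds),
        outcome_scale=scale, binary_outcome=binary,
    )


# ---------------------------------------------------------------------------
# Targeting
# ---------------------------------------------------------------------------

def _solve_epsilon(H: np.ndarray, y_s: np.ndarray, Qa: np.ndarray) -> float:
    """One-dimensional fluctuation MLE: maximize the binomial log-likelihood
    of y_s on the clever covariate H with offset logit(Qa).

    The log-likelihood is concave in epsilon (canonical-link GLM), so
    damped Newton on the score converges to machine precision; the final
    score residual is what makes the post-targeting EIC mean vanish.
    """
    off = logit(np.clip(Qa, *Q_CLIP))
    H2 = H * H

    def score_info(eps: float) -> tuple[float, float]:
        Q = expit(off + eps * H)
        return float(H @ (y_s - Q)), float(H2 @ (Q * (1.0 - Q)))

    eps = 0.0
    for _ in range(200):
        s, info = score_info(eps)
        if not (math.isfinite(s) and math.isfinite(info)):
            logger.warning("non-finite fluctuation likelihood; epsilon set to 0")
            return 0.0
        if info < 1e-14 or abs(s) < 1e-14:
            break
        step = s / info
        step = max(min(step, 2.0), -2.0)  # damp overshoot far from optimum
        eps += step
        if abs(step) < 1e-14:
            break
    if not math.isfinite(eps):
        logger.warning("fluctuation diverged; epsilon set to 0")
        return 0.0
    return eps


def _target_from_arrays(
    a: np.ndarray,
    y_s: np.ndarray,
    Q0: np.ndarray,
    Q1: np.ndarray,
    g1: np.ndarray,
    scale: tuple[float, float],
    scope: str,
    rule_description: str,
) -> ATEResult:
    """Targeting step on (possibly stacked) estimation-sample arrays.

    Updates Q with the fluctuation, evaluates the plug-in ATE and the EIC
    on the original outcome scale, and forms the normal-approximation CI.
    """
    a = np.asarray(a, dtype=float).ravel()
    m = len(a)
    if m < 10:
        raise ValueError(f"need at least 10 estimation rows, got {m}")
    Q0 = np.clip(Q0, *Q_CLIP)
    Q1 = np.clip(Q1, *Q_CLIP)
    Qa = np.where(a == 1.0, Q1, Q0)
    H = a / g1 - (1.0 - a) / (1.0 - g1)
    eps = _solve_epsilon(H, y_s, Qa)

    Q0_star = expit(logit(Q0) - eps / (1.0 - g1))
    Q1_star = expit(logit(Q1) + eps / g1)
    Qa_star = np.where(a == 1.0, Q1_star, Q0_star)

    lo, hi = scale
    width = hi - lo
    psi_s = float(np.mean(Q1_star - Q0_star))
    psi = psi_s * width
    eic = width * (H * (y_s - Qa_star) + Q1_star - Q0_star - psi_s)
    se = float(np.std(eic, ddof=1) / math.sqrt(m))
    return ATEResult(
        psi=psi,
        se=se,
        ci_lower=psi - Z_95 * se,
        ci_upper=psi + Z_95 * se,
        eic=eic,
        rule_description=rule_description,
        scope=scope,
        n_effective=m,
        epsilon=eps,
    )


def target_ate(
    nuisance: NuisanceFit,
    indicator: np.ndarray,
    y: np.ndarray,
    scope: str = "",
    rule_description: str = "",
) -> tuple[float, ATEResult]:
    """Fluctuate the outcome regression along the clever covariate and
    return (epsilon, targeted ATE with EIC-based inference)."""
    lo, hi = nuisance.outcome_scale
    y_s = np.clip((np.asarray(y, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    res = _target_from_arrays(
        indicator, y_s, nuisance.Q0, nuisance.Q1, nuisance.g1,
        nuisance.outcome_scale, scope, rule_description,
    )
    return res.epsilon, res


# ---------------------------------------------------------------------------
# Fold-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    v: int
    status: str  # "ok", "no-rule", or "dropped-positivity"
    rule: MixtureRule | None = None
    result: ATEResult | None = None
    message: str = ""


def run_fold(
    data: MixtureDataset,
    folds: FoldAssignment,
    v: int,
    settings: RunSettings,
) -> FoldRecord:
    """Discover the fold's designated rule on the parameter-generating
    sample and estimate its targeted ATE on the estimation sample."""
    if not 1 <= v <= folds.V:
        raise ValueError(f"fold index {v} outside 1..{folds.V}")
    param = data.subset(folds.parameter_mask(v))
    est = data.subset(folds.estimation_mask(v))
    seed = settings.fold_seed(v)
    model = iterative_backfit(
        param,
        tree_grid=settings.tree_grid,
        w_library=settings.w_library,
        tol=settings.backfit_tol,
        max_iter=settings.backfit_max_iter,
        inner_V=settings.inner_V,
        seed=seed,
    )
    rule = select_designated_rule(
        model, param, min_support=settings.min_support, provenance=f"fold {v}"
    )
    if rule is None:
        return FoldRecord(v=v, status="no-rule")
    try:
        nuis = fit_nuisance(
            param, rule, est,
            w_library=settings.w_library,
            g_bounds=settings.g_bounds,
            seed=seed,
            inner_V=settings.inner_V,
        )
    except PositivityError as exc:
        logger.warning("fold %d dropped: %s", v, exc)
        return FoldRecord(v=v, status="dropped-positivity", rule=rule,
                          message=str(exc))
    a_est = rule.evaluate(est.exposures).astype(float)
    _, result = target_ate(
        nuis, a_est, est.outcome,
        scope=f"fold {v}", rule_description=rule.description,
    )
    return FoldRecord(v=v, status="ok", rule=rule, result=result)


def pool_folds(
    data: MixtureDataset,
    folds: FoldAssignment,
    fold_records: Sequence[FoldRecord],
    settings: RunSettings,
) -> tuple[ATEResult, str]:
    """Pooled estimand across folds: one fluctuation on the stacked
    estimation samples, each fold contributing its own designated-rule
    indicator and nuisances re-learned on a common outcome scale.

    The pooled target is the fold-size-weighted average of the
    fold-specific rule ATEs. Each fold's indicator must come from its own
    rule: any other fold's rule was learned on data that includes this
    fold's estimation rows, so evaluating it here would leak the held-out
    sample into the rule and bias the pooled estimate. The union of fold
    rules is reported as the pooled rule description (the interpretable
    harmonized exposure subspace).
    """
    rules = [r.rule for r in fold_records if r.rule is not None and r.status == "ok"]
    if not rules:
        raise RuntimeError("no fold produced a usable rule; nothing to pool")
    _, union_desc = _union_description(rules)
    binary = _is_binary(data.outcome)
    scale = (0.0, 1.0) if binary else _outcome_scale(data.outcome)

    parts_a, parts_y, parts_q0, parts_q1, parts_g = [], [], [], [], []
    for rec in fold_records:
        if rec.status != "ok":
            continue
        v = rec.v
        param = data.subset(folds.parameter_mask(v))
        est = data.subset(folds.estimation_mask(v))
        d_param = rec.rule.evaluate(param.exposures).astype(float)
        n1 = int(d_param.sum())
        if min(n1, len(d_param) - n1) < MIN_CLASS_COUNT:
            logger.warning("fold %d skipped in pooling (positivity)", v)
            continue
        nuis = _fit_nuisance_from_indicator(
            param, d_param, est,
            settings.w_library, settings.g_bounds,
            settings.fold_seed(v), settings.inner_V, scale,
        )
        a_est = rec.rule.evaluate(est.exposures).astype(float)
        lo, hi = scale
        parts_a.append(a_est)
        parts_y.append(np.clip((est.outcome - lo) / (hi - lo), 0.0, 1.0))
        parts_q0.append(nuis.Q0)
        parts_q1.append(nuis.Q1)
        parts_g.append(nuis.g1)
    if not parts_a:
        raise RuntimeError("all folds dropped during pooling")
    result = _target_from_arrays(
        np.concatenate(parts_a),
        np.concatenate(parts_y),
        np.concatenate(parts_q0),
        np.concatenate(parts_q1),
        np.concatenate(parts_g),
        scale,
        "pooled-mixture",
        union_desc,
    )
    # The stacked-EIC variance treats the fold rules as fixed and can miss
    # the rule-estimation noise (threshold error puts rare large residuals
    # in the estimation samples). Guard with the between-fold spread of the
    # fold-specific estimates, taking whichever se is larger.
    fold_psis = [
        rec.result.psi for rec in fold_records
        if rec.status == "ok" and rec.result is not None
    ]
    if len(fold_psis) > 1:
        spread_se = float(np.std(fold_psis, ddof=1) / math.sqrt(len(fold_psis)))
        if spread_se > result.se:
            result.se = spread_se
            result.ci_lower = result.psi - Z_95 * spread_se
            result.ci_upper = result.psi + Z_95 * spread_se
    return result, union_desc


def _union_description(rules: Sequence[MixtureRule]) -> tuple[list[str], str]:
    seen: list[str] = []
    for r in rules:
        if r.description not in seen:
            seen.append(r.description)
    return seen, " | ".join(f"({d})" for d in seen)


def component_ates(
    data: MixtureDataset,
    folds: FoldAssignment,
    variable: str,
    settings: RunSettings,
) -> tuple[list[ATEResult], list[float]]:
    """Pooled ATEs of each harmonized threshold level of one component
    against the lowest level (rows in other levels are excluded from each
    contrast). Returns ([] , []) when no fold finds a cutpoint."""
    all_cuts: set[float] = set()
    for v in range(1, folds.V + 1):
        param = data.subset(folds.parameter_mask(v))
        ct = component_thresholds(
            param, variable,
            w_library=settings.w_library,
            tree_grid=settings.tree_grid,
            tol=settings.backfit_tol,
            max_iter=settings.backfit_max_iter,
            inner_V=settings.inner_V,
            seed=settings.fold_seed(v),
        )
        all_cuts.update(round(c, 10) for c in ct.cutpoints)
    cuts = sorted(all_cuts)
    if not cuts:
        return [], []
    levels = levels_from_cutpoints(variable, cuts)
    reference = levels[0]
    binary = _is_binary(data.outcome)
    scale = (0.0, 1.0) if binary else _outcome_scale(data.outcome)

    results: list[ATEResult] = []
    for j, level in enumerate(levels[1:], start=1):
        parts_a, parts_y, parts_q0, parts_q1, parts_g = [], [], [], [], []
        for v in range(1, folds.V + 1):
            param = data.subset(folds.parameter_mask(v))
            est = data.subset(folds.estimation_mask(v))
            in_lev_p = level.evaluate(param.exposures).astype(bool)
            in_ref_p = reference.evaluate(param.exposures).astype(bool)
            keep_p = in_lev_p | in_ref_p
            if min(int(in_lev_p.sum()), int(in_ref_p.sum())) < MIN_CLASS_COUNT:
                continue
            sub_param = param.subset(keep_p)
            d_param = in_lev_p[keep_p].astype(float)
            in_lev_e = level.evaluate(est.exposures).astype(bool)
            in_ref_e = reference.evaluate(est.exposures).astype(bool)
            keep_e = in_lev_e | in_ref_e
            if not keep_e.any():
                continue
            sub_est = est.subset(keep_e)
            nuis = _fit_nuisance_from_indicator(
                sub_param, d_param, sub_est,
                settings.w_library, settings.g_bounds,
                settings.fold_seed(v) + 7919 * j, settings.inner_V, scale,
            )
            lo, hi = scale
            parts_a.append(in_lev_e[keep_e].astype(float))
            parts_y.append(np.clip((sub_est.outcome - lo) / (hi - lo), 0.0, 1.0))
            parts_q0.append(nuis.Q0)
            parts_q1.append(nuis.Q1)
            parts_g.append(nuis.g1)
        if not parts_a or sum(len(a) for a in parts_a) < 10:
            continue
        res = _target_from_arrays(
            np.concatenate(parts_a),
            np.concatenate(parts_y),
            np.concatenate(parts_q0),
            np.concatenate(parts_q1),
            np.concatenate(parts_g),
            scale,
            f"component:{variable}",
            f"{level.description} vs {reference.description}",
        )
        results.append(res)
    return results, cuts


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    folds: list[FoldRecord]
    pooled: ATEResult | None
    union_rule: str | None
    components: dict[str, list[ATEResult]]
    component_cutpoints: dict[str, list[float]]
    diagnostics: dict
    V: int
    seed: int

    def to_dict(self) -> dict:
        fold_entries = []
        for rec in self.folds:
            entry = {"fold": rec.v, "status": rec.status}
            if rec.rule is not None:
                entry["rule"] = rec.rule.description
            if rec.result is not None:
                entry.update(
                    psi=rec.result.psi, se=rec.result.se,
                    ci_lower=rec.result.ci_lower, ci_upper=rec.result.ci_upper,
                    n_effective=rec.result.n_effective,
                    epsilon=rec.result.epsilon,
                )
            fold_entries.append(entry)
        pooled = None
        if self.pooled is not None:
            pooled = {
                "rule": self.union_rule,
                "psi": self.pooled.psi, "se": self.pooled.se,
                "ci_lower": self.pooled.ci_lower,
                "ci_upper": self.pooled.ci_upper,
                "n_effective": self.pooled.n_effective,
                "epsilon": self.pooled.epsilon,
            }
        comps = {
            var: [
                {
                    "contrast": r.rule_description, "psi": r.psi, "se": r.se,
                    "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                    "n_effective": r.n_effective,
                }
                for r in results
            ]
            for var, results in self.components.items()
        }
        return {
            "V": self.V,
            "seed": self.seed,
            "folds": fold_entries,
            "pooled": pooled,
            "components": comps,
            "component_cutpoints": self.component_cutpoints,
            "diagnostics": self.diagnostics,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_rows(self) -> list[dict]:
        rows = []
        for rec in self.folds:
            if rec.result is not None:
                rows.append(rec.result.to_row())
        if self.pooled is not None:
            rows.append(self.pooled.to_row())
        for results in self.components.values():
            rows.extend(r.to_row() for r in results)
        return rows


def run_cvtreemle(data: MixtureDataset, settings: RunSettings) -> ResultsBundle:
    """End-to-end run: folds, per-fold rules and targeted ATEs, the pooled
    union-rule ATE, and per-component threshold contrasts.

    "No tree found" anywhere is a reported outcome, never an error.
    """
    folds = assign_folds(data.n, settings.V, settings.seed)
    records = [run_fold(data, folds, v, settings) for v in range(1, folds.V + 1)]
    for rec in records:
        if rec.result is not None:
            logger.info(
                "fold %d: rule=%s n_eff=%d psi=%.4g se=%.4g",
                rec.v, rec.rule.description, rec.result.n_effective,
                rec.result.psi, rec.result.se,
            )
        else:
            logger.info("fold %d: %s", rec.v, rec.status)

    pooled = union_desc = None
    if any(r.status == "ok" for r in records):
        try:
            pooled, union_desc = pool_folds(data, folds, records, settings)
        except RuntimeError as exc:
            logger.warning("pooling failed: %s", exc)

    components: dict[str, list[ATEResult]] = {}
    cutpoints: dict[str, list[float]] = {}
    if settings.run_components:
        for var in data.exposure_names:
            results, cuts = component_ates(data, folds, var, settings)
            components[var] = results
            cutpoints[var] = cuts

    n_contrasts = sum(len(v) for v in components.values()) + (
        1 if pooled is not None else 0
    ) + sum(1 for r in records if r.status == "ok")
    diagnostics = {
        "dropped_folds": [r.v for r in records if r.status == "dropped-positivity"],
        "no_rule_folds": [r.v for r in records if r.status == "no-rule"],
        "n_contrasts": n_contrasts,
        "multiplicity_note": (
            f"{n_contrasts} contrasts reported without multiplicity adjustment"
        ),
    }
    return ResultsBundle(
        folds=records,
        pooled=pooled,
        union_rule=union_desc,
        components=components,
        component_cutpoints=cutpoints,
        diagnostics=diagnostics,
        V=settings.V,
        seed=settings.seed,
    )
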