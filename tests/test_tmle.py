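import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from treetmle.core_data import MixtureDataset, MixtureRule, Predicate, assign_folds
from treetmle.simulate import preset_config, simulate
from treetmle.super_learner import LearnerSpec
from treetmle.tmle import (
    ATEResult,
    FoldRecord,
    PositivityError,
    RunSettings,
    _outcome_scale,
    _solve_epsilon,
    _target_from_arrays,
    component_ates,
    fit_nuisance,
    pool_folds,
    run_cvtreemle,
    run_fold,
    target_ate,
)
from treetmle.tmle import NuisanceFit


def random_instance(rng, m=200):
    a = (rng.uniform(size=m) < 0.4).astype(float)
    g1 = rng.uniform(0.1, 0.9, m)
    Q0 = rng.uniform(0.05, 0.95, m)
    Q1 = rng.uniform(0.05, 0.95, m)
    y = rng.uniform(0, 1, m)
    return a, y, Q0, Q1, g1


def no_covariate_dataset(n, seed, effect=2.0):
    rng = np.random.default_rng(seed)
    A = pd.DataFrame({"a1": rng.uniform(0, 1, n)})
    W = pd.DataFrame(index=range(n))
    y = effect * (A["a1"].to_numpy() > 0.5) + rng.normal(0, 0.5, n)
    return MixtureDataset(exposures=A, covariates=W, outcome=y)


class TestFitNuisance:
    def test_no_covariates_gives_constant_nuisances(self, rng):
        data = no_covariate_dataset(300, 0)
        rule = MixtureRule((Predicate("a1", 0.5),))
        folds = assign_folds(300, 3, 0)
        param = data.subset(folds.parameter_mask(1))
        est = data.subset(folds.estimation_mask(1))
        nuis = fit_nuisance(
            param, rule, est,
            w_library=[LearnerSpec.make("linear", "linear")], seed=0,
        )
        # no covariate information: all predictions are constants
        assert np.ptp(nuis.g1) < 1e-10
        assert np.ptp(nuis.Q0) < 1e-10
        assert np.ptp(nuis.Q1) < 1e-10
        d = rule.evaluate(param.exposures).astype(bool)
        rate = d.mean()
        # logistic intercept carries a whiff of regularization: loose tol
        assert abs(nuis.g1[0] - np.clip(rate, *nuis.g_bounds)) < 1e-4
        # linear regression on the indicator alone reproduces class means
        lo, hi = nuis.outcome_scale
        ys = (param.outcome - lo) / (hi - lo)
        np.testing.assert_allclose(nuis.Q1[0], ys[d].mean(), atol=1e-8)
        np.testing.assert_allclose(nuis.Q0[0], ys[~d].mean(), atol=1e-8)

    def test_no_truncation_at_moderate_rate(self, rng, lean_library):
        data = no_covariate_dataset(400, 1)
        rule = MixtureRule((Predicate("a1", 0.5),))
        folds = assign_folds(400, 4, 1)
        nuis = fit_nuisance(
            data.subset(folds.parameter_mask(1)), rule,
            data.subset(folds.estimation_mask(1)),
            w_library=lean_library, g_bounds=(0.025, 0.975), seed=1,
        )
        lo, hi = nuis.g_bounds
        assert (nuis.g1 > lo).all() and (nuis.g1 < hi).all()

    def test_separable_propensity_hits_bounds(self, lean_library):
        rng = np.random.default_rng(2)
        n = 300
        W = pd.DataFrame({"w1": rng.standard_normal(n)})
        # exposure decided by the covariate: perfectly separable propensity
        A = pd.DataFrame({"a1": (W["w1"] > 0).astype(float) + rng.uniform(0, 0.1, n)})
        y = rng.standard_normal(n)
        data = MixtureDataset(exposures=A, covariates=W, outcome=y)
        rule = MixtureRule((Predicate("a1", 0.5),))
        folds = assign_folds(n, 3, 2)
        nuis = fit_nuisance(
            data.subset(folds.parameter_mask(1)), rule,
            data.subset(folds.estimation_mask(1)),
            w_library=lean_library, seed=2,
        )
        lo, hi = nuis.g_bounds
        assert np.isin(nuis.g1, (lo, hi)).mean() > 0.95

    def test_one_class_raises_positivity(self, lean_library):
        data = no_covariate_dataset(200, 3)
        rule = MixtureRule((Predicate("a1", 2.0),))  # nobody qualifies
        folds = assign_folds(200, 4, 3)
        with pytest.raises(PositivityError):
            fit_nuisance(
                data.subset(folds.parameter_mask(1)), rule,
                data.subset(folds.estimation_mask(1)),
                w_library=lean_library, seed=3,
            )


class TestTargetAte:
    def test_saturated_case_equals_difference_of_means(self):
        # saturated nuisance: class means and the empirical rate solve the
        # score equation at epsilon = 0, so the targeted ATE is the plug-in
        rng = np.random.default_rng(0)
        m = 150
        a = (rng.uniform(size=m) < 0.35).astype(float)
        y = rng.uniform(1.0, 3.0, m)
        lo, hi = _outcome_scale(y)
        ys = (y - lo) / (hi - lo)
        nuis = NuisanceFit(
            Q0=np.full(m, ys[a == 0].mean()),
            Q1=np.full(m, ys[a == 1].mean()),
            g1=np.full(m, a.mean()),
            g_bounds=(0.025, 0.975),
            outcome_scale=(lo, hi),
            binary_outcome=False,
        )
        eps, res = target_ate(nuis, a, y)
        plug_in = y[a == 1].mean() - y[a == 0].mean()
        assert abs(eps) < 1e-12
        assert abs(res.psi - plug_in) < 1e-10

    def test_eic_mean_zero_after_targeting(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, y, Q0, Q1, g1 = random_instance(rng)
            res = _target_from_arrays(a, y, Q0, Q1, g1, (0.0, 1.0), "", "")
            assert abs(res.eic.mean()) < 1e-8

    def test_epsilon_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        for _ in range(20):
            a, y, Q0, Q1, g1 = random_instance(rng, m=80)
            Qa = np.clip(np.where(a == 1, Q1, Q0), 0.001, 0.999)
            H = a / g1 - (1 - a) / (1 - g1)
            off = logit(Qa)
            # brute-force maximizer of the fluctuation log-likelihood
            P = expit(off[None, :] + grid[:, None] * H[None, :])
            P = np.clip(P, 1e-12, 1 - 1e-12)
            ll = (y[None, :] * np.log(P) + (1 - y[None, :]) * np.log(1 - P)).sum(axis=1)
            eps_grid = grid[np.argmax(ll)]
            eps = _solve_epsilon(H, y, Qa)
            assert abs(eps - eps_grid) <= 2e-4

    def test_ci_structure(self):
        rng = np.random.default_rng(3)
        a, y, Q0, Q1, g1 = random_instance(rng)
        res = _target_from_arrays(a, y, Q0, Q1, g1, (0.0, 1.0), "s", "r")
        assert res.ci_lower <= res.psi <= res.ci_upper
        assert abs((res.ci_upper - res.psi) - 1.96 * res.se) < 1e-12
        assert abs(res.eic.mean()) <= 1e-6 * res.eic.std() + 1e-10

    def test_eic_matches_closed_form(self):
        # independent recomputation of the EIC from the updated regressions
        rng = np.random.default_rng(4)
        a, y, Q0, Q1, g1 = random_instance(rng, m=120)
        res = _target_from_arrays(a, y, Q0, Q1, g1, (0.0, 1.0), "", "")
        eps = res.epsilon
        Q0s = expit(logit(np.clip(Q0, 0.001, 0.999)) - eps / (1 - g1))
        Q1s = expit(logit(np.clip(Q1, 0.001, 0.999)) + eps / g1)
        H = a / g1 - (1 - a) / (1 - g1)
        Qas = np.where(a == 1, Q1s, Q0s)
        psi = np.mean(Q1s - Q0s)
        eic = H * (y - Qas) + Q1s - Q0s - psi
        np.testing.assert_allclose(res.eic, eic, atol=1e-12)
        np.testing.assert_allclose(res.psi, psi, atol=1e-12)

    def test_stacking_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a, y, Q0, Q1, g1 = random_instance(rng, m=100)
        base = _target_from_arrays(a, y, Q0, Q1, g1, (0.0, 1.0), "", "")
        perm = rng.permutation(100)
        again = _target_from_arrays(
            a[perm], y[perm], Q0[perm], Q1[perm], g1[perm], (0.0, 1.0), "", ""
        )
        assert abs(base.psi - again.psi) < 1e-12
        assert abs(base.se - again.se) < 1e-12

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            _target_from_arrays(
                np.ones(5), np.ones(5), np.ones(5) * 0.5, np.ones(5) * 0.5,
                np.ones(5) * 0.5, (0.0, 1.0), "", "",
            )


class TestRunFold:
    def test_strong_signal_fold(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 500, 7))
        folds = assign_folds(data.n, 5, 7)
        rec = run_fold(data, folds, 1, lean_settings(7))
        assert rec.status == "ok"
        assert rec.result.n_effective == 100
        assert 3.5 < rec.result.psi < 6.5

    def test_invalid_fold_index(self, lean_settings, small_dataset):
        folds = assign_folds(small_dataset.n, 5, 0)
        with pytest.raises(ValueError):
            run_fold(small_dataset, folds, 9, lean_settings(0))

    def test_no_signal_folds_mostly_empty(self, lean_settings):
        n_rules = n_folds = 0
        for s in range(5):
            data, _ = simulate(preset_config("null", 400, s))
            bundle = run_cvtreemle(data, lean_settings(s))
            n_folds += 5
            n_rules += sum(1 for r in bundle.folds if r.status == "ok")
        assert n_rules / n_folds <= 0.3


class TestPooling:
    def test_pooled_matches_folds_strong_signal(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 500, 11))
        bundle = run_cvtreemle(data, lean_settings(11))
        assert bundle.pooled is not None
        fold_psis = [r.result.psi for r in bundle.folds if r.status == "ok"]
        assert abs(bundle.pooled.psi - np.mean(fold_psis)) < 0.25
        assert bundle.pooled.n_effective == sum(
            r.result.n_effective for r in bundle.folds if r.status == "ok"
        )

    def test_pooled_se_not_larger_than_worst_fold(self, lean_settings):
        # pooling over ~V times more rows: pooled se below the max fold se
        # in the vast majority of strong-signal replicates
        wins = 0
        reps = 10
        for s in range(reps):
            data, _ = simulate(preset_config("interaction-2d", 500, 100 + s))
            bundle = run_cvtreemle(data, lean_settings(100 + s))
            if bundle.pooled is None:
                continue
            fold_ses = [r.result.se for r in bundle.folds if r.status == "ok"]
            wins += bundle.pooled.se <= max(fold_ses)
        assert wins >= int(0.9 * reps)

    def test_dropped_folds_excluded(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 500, 12))
        folds = assign_folds(data.n, 5, 12)
        recs = [run_fold(data, folds, v, lean_settings(12)) for v in range(1, 6)]
        recs[0] = FoldRecord(v=1, status="dropped-positivity", rule=recs[0].rule)
        pooled, _ = pool_folds(data, folds, recs, lean_settings(12))
        assert pooled.n_effective == sum(
            r.result.n_effective for r in recs[1:] if r.status == "ok"
        )

    def test_all_dropped_raises(self, lean_settings, small_dataset):
        folds = assign_folds(small_dataset.n, 5, 0)
        recs = [FoldRecord(v=v, status="no-rule") for v in range(1, 6)]
        with pytest.raises(RuntimeError):
            pool_folds(small_dataset, folds, recs, lean_settings(0))


class TestComponentAtes:
    @staticmethod
    def discrete_step_data(n, seed, base=1.0, top=3.0):
        # discrete exposure levels so every fold finds identical cutpoints
        rng = np.random.default_rng(seed)
        a1 = rng.integers(0, 3, n).astype(float)
        A = pd.DataFrame({"a1": a1, "a2": rng.uniform(0, 1, n)})
        W = pd.DataFrame({"w1": rng.standard_normal(n)})
        y = base * (a1 >= 1) + top * (a1 == 2) + 0.5 * W["w1"].to_numpy() \
            + rng.normal(0, 0.2, n)
        return MixtureDataset(exposures=A, covariates=W, outcome=y)

    def test_three_levels_exclude_intermediate(self, lean_settings):
        data = self.discrete_step_data(600, 0)
        folds = assign_folds(data.n, 5, 0)
        settings = lean_settings(0, tree_max_depths=(1, 2))
        results, cuts = component_ates(data, folds, "a1", settings)
        assert len(cuts) == 2  # thresholds at 0.5 and 1.5
        assert len(results) == 2
        for res in results:
            # intermediate-level rows excluded from each contrast
            assert res.n_effective < data.n
        # level 2 vs reference: effect ~ base; level 3 vs reference ~ base+top
        assert abs(results[0].psi - 1.0) < 0.5
        assert abs(results[1].psi - 4.0) < 0.5

    def test_single_cutpoint_uses_all_rows(self, lean_settings):
        rng = np.random.default_rng(1)
        n = 500
        a1 = rng.integers(0, 2, n).astype(float)
        A = pd.DataFrame({"a1": a1, "a2": rng.uniform(0, 1, n)})
        W = pd.DataFrame({"w1": rng.standard_normal(n)})
        y = 3.0 * a1 + 0.5 * W["w1"].to_numpy() + rng.normal(0, 0.2, n)
        data = MixtureDataset(
            exposures=A, covariates=W, outcome=y.to_numpy()
            if hasattr(y, "to_numpy") else y
        )
        folds = assign_folds(n, 5, 1)
        results, cuts = component_ates(data, folds, "a1", lean_settings(1))
        assert len(cuts) == 1
        assert len(results) == 1
        assert results[0].n_effective == n  # complement equals reference
        assert abs(results[0].psi - 3.0) < 0.4

    def test_step_effect_recovery(self, lean_settings):
        # continuous exposure, no confounding: pooled top-level contrast
        # near the true step size in most replicates
        hits = 0
        reps = 20
        for s in range(reps):
            data, _ = simulate(preset_config("main-effect-1d", 500, 300 + s))
            folds = assign_folds(data.n, 5, 300 + s)
            settings = lean_settings(300 + s, tree_max_depths=(1,))
            results, cuts = component_ates(data, folds, "a1", settings)
            if not results:
                continue
            hits += abs(results[-1].psi - 3.0) <= 0.5
        assert hits >= int(0.9 * reps)

    def test_no_signal_gives_empty(self, lean_settings):
        data, _ = simulate(preset_config("null", 400, 5))
        folds = assign_folds(data.n, 5, 5)
        results, cuts = component_ates(data, folds, "a3", lean_settings(5))
        if not cuts:
            assert results == []


class TestRunEndToEnd:
    def test_bundle_structure(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 400, 21))
        bundle = run_cvtreemle(data, lean_settings(21))
        assert len(bundle.folds) == 5
        assert bundle.pooled is not None
        assert bundle.union_rule
        d = bundle.to_dict()
        assert set(d) >= {"V", "seed", "folds", "pooled", "diagnostics"}

    def test_determinism_byte_identical(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 400, 22))
        a = run_cvtreemle(data, lean_settings(22)).to_json()
        b = run_cvtreemle(data, lean_settings(22)).to_json()
        assert a == b

    def test_affine_outcome_equivariance(self, lean_settings):
        data, _ = simulate(preset_config("interaction-2d", 400, 23))
        scaled = MixtureDataset(
            exposures=data.exposures,
            covariates=data.covariates,
            outcome=10.0 * data.outcome + 3.0,
        )
        b1 = run_cvtreemle(data, lean_settings(23))
        b2 = run_cvtreemle(scaled, lean_settings(23))
        assert b1.pooled is not None and b2.pooled is not None
        assert abs(b2.pooled.psi - 10.0 * b1.pooled.psi) < 1e-6 * max(
            1.0, abs(10.0 * b1.pooled.psi)
        )

    def test_binary_outcome_runs(self, lean_settings):
        data, _ = simulate(preset_config("binary-outcome", 500, 24))
        bundle = run_cvtreemle(data, lean_settings(24))
        for rec in bundle.folds:
            if rec.result is not None:
                assert -1.0 <= rec.result.psi <= 1.0

    def test_debiasing_under_confounding(self, lean_settings):
        # with the true rule fixed, the targeted estimate beats the raw
        # difference in means in nearly all replicates
        wins = 0
        reps = 20
        for s in range(reps):
            cfg = preset_config("confounded-interaction", 500, 400 + s)
            data, _ = simulate(cfg)
            folds = assign_folds(data.n, 5, 400 + s)
            recs = [
                FoldRecord(v=v, status="ok", rule=cfg.true_region,
                           result=None)
                for v in range(1, 6)
            ]
            # fold results are only used for the spread guard; provide them
            for rec in recs:
                rec.result = run_fold_fixed(data, folds, rec.v, cfg.true_region,
                                            lean_settings(400 + s))
            pooled, _ = pool_folds(data, folds, recs, lean_settings(400 + s))
            d = cfg.true_region.evaluate(data.exposures).astype(bool)
            unadj = data.outcome[d].mean() - data.outcome[~d].mean()
            wins += abs(pooled.psi - 5.0) < abs(unadj - 5.0)
        assert wins >= int(0.9 * reps)


def run_fold_fixed(data, folds, v, rule, settings):
    """Targeted fold estimate for a fixed (non-discovered) rule."""
    param = data.subset(folds.parameter_mask(v))
    est = data.subset(folds.estimation_mask(v))
    nuis = fit_nuisance(
        param, rule, est, w_library=settings.w_library,
        g_bounds=settings.g_bounds, seed=settings.fold_seed(v),
        inner_V=settings.inner_V,
    )
    a = rule.evaluate(est.exposures).astype(float)
    _, res = target_ate(nuis, a, est.outcome, scope=f"fold {v}",
                        rule_description=rule.description)
    return res
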