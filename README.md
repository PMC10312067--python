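# treetmle

Data-adaptive discovery of interpretable decision-tree rules over a
multivariate ("mixture") exposure, followed by cross-validated targeted
maximum likelihood estimation (CV-TMLE) of the average treatment effect
(ATE) of membership in the discovered exposure subspace, with efficient-
influence-curve-based inference reported per fold and pooled.

## How it works

1. **V-fold split.** Observations are partitioned into V balanced folds.
   For fold v, the *estimation sample* is fold v and the
   *parameter-generating sample* is everything else.
2. **Rule discovery (per fold).** On the parameter-generating sample, the
   semi-parametric model `E(Y|A,W) = f(A) + h(W)` is fit by iterative
   backfitting: `f` is a shallow regression tree over the joint exposures
   (selected by inner CV from a small depth/leaf-size grid, with the
   intercept-only model as an always-present candidate), `h` is a convex
   "super learner" ensemble over the covariates. The designated rule is
   the leaf with the largest partial-residual contrast, subject to a
   minimum-support (positivity) guard.
3. **Targeted estimation (per fold).** Outcome regression and propensity
   for the rule indicator are learned on the parameter-generating sample
   and predicted on the estimation sample; a one-dimensional logistic
   fluctuation along the clever covariate `H = a/g − (1−a)/(1−g)` debiases
   the plug-in ATE and zeroes the empirical mean of the efficient
   influence curve, which supplies the standard error and 95% CI.
4. **Pooling.** One fluctuation is fit on the stacked estimation samples
   (each fold contributing its own rule's indicator and nuisances), giving
   a pooled ATE for the discovered subspace; the union of fold rules is
   reported as its description. The same machinery produces per-component
   threshold ATEs versus the lowest identified exposure level.

"No tree found" is a first-class outcome, not an error. Continuous
outcomes are scaled to [0, 1] for a bounded-loss fluctuation and mapped
back; binary outcomes use the likelihood directly.

## CLI

Simulate a dataset with known ground truth (presets: `null`,
`main-effect-1d`, `interaction-2d`, `confounded-interaction`,
`binary-outcome`):

```bash
treetmle simulate --preset interaction-2d --n 500 --seed 1 --out data.csv
# writes data.csv and data.truth.json (true region, effect size, true ATE)
```

Run the analysis:

```bash
treetmle fit --data data.csv --config config.yaml --out results/
# writes results.json, results.csv, run.log ; exit 2 on validation errors
```

Minimal `config.yaml`:

```yaml
columns:
  exposures: [a1, a2, a3]
  covariates: [w1, w2]
  outcome: y
V: 5
seed: 1
```

Optional keys: `tree_max_depths`, `tree_min_leaf_fracs`, `backfit_tol`,
`backfit_max_iter`, `min_support`, `g_bounds`, `inner_V`, `learners`
(list of `{name, family, ...hyperparameters}` with families `mean`,
`linear`, `tree`, `bagged_trees`, `knn`), `run_components`. Unknown keys
are rejected.

## Python API

```python
from treetmle import RunSettings, run_cvtreemle, preset_config, simulate

data, truth = simulate(preset_config("interaction-2d", n=500, seed=1))
bundle = run_cvtreemle(data, RunSettings(V=5, seed=1))
print(bundle.pooled.psi, bundle.pooled.ci_lower, bundle.pooled.ci_upper)
print(bundle.union_rule)
```

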