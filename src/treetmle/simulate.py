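"""Seeded mixture simulator with known ground truth.

Structural model:

* W: q independent standard normals.
* A_j = alpha * (c_j . W) + Uniform(low, high), with unit loading vectors
  c_j drawn deterministically from the seed and alpha the confounding
  strength (W shifts exposures, hence rule membership, and the outcome).
* Continuous Y = tau * 1{A in true_region} + beta . W + N(0, noise_sd^2);
  binary Y ~ Bernoulli(expit(of the same linear predictor)).
* beta = alpha * 1/sqrt(q) per covariate.

Because the indicator enters additively, the ATE of the true region is
exactly tau for continuous outcomes at any confounding strength, while
the unadjusted difference in means is not — which is the whole point.
:func:`true_ate` evaluates the covariate-adjusted (g-computation) ATE of
an arbitrary rule by nested Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import MixtureDataset, MixtureRule, parse_rule

__all__ = ["SimConfig", "GroundTruth", "simulate", "true_ate", "PRESETS", "preset_config"]


@dataclass(frozen=True)
class SimConfig:
    n: int
    p: int
    q: int
    true_region: MixtureRule
    effect_size: float
    confounding_strength: float = 0.0
    noise_sd: float = 1.0
    outcome_type: str = "continuous"
    seed: int = 0
    exposure_low: float = 0.0
    exposure_high: float = 1.0

    def __post_init__(self):
        if self.n < 1 or self.p < 1 or self.q < 0:
            raise ValueError("need n >= 1, p >= 1, q >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        unknown = [
            v for v in self.true_region.variables
            if v not in {f"a{j + 1}" for j in range(self.p)}
        ]
        if unknown:
            raise ValueError(f"true_region references unknown exposure(s): {unknown}")


@dataclass
class GroundTruth:
    config: SimConfig
    loadings: np.ndarray  # (p, q) unit rows
    beta: np.ndarray  # (q,)
    region_prevalence: float

    def to_dict(self) -> dict:
        return {
            "true_region": self.config.true_region.description,
            "effect_size": self.config.effect_size,
            "confounding_strength": self.config.confounding_strength,
            "noise_sd": self.config.noise_sd,
            "outcome_type": self.config.outcome_type,
            "region_prevalence": self.region_prevalence,
        }


def _structure(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Loadings and outcome coefficients — deterministic in the seed."""
    struct_rng = np.random.default_rng([config.seed, 715517])
    if config.q == 0:
        return np.zeros((config.p, 0)), np.zeros(0)
    # All-positive loadings keep every exposure positively associated with
    # the (positive-coefficient) covariate effect, so confounding bias is
    # systematic rather than averaging out across seeds.
    c = np.abs(struct_rng.standard_normal((config.p, config.q)))
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    beta = np.full(config.q, config.confounding_strength / np.sqrt(config.q))
    return c, beta


def _draw(
    config: SimConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    c, _ = _structure(config)
    W = rng.standard_normal((n, config.q))
    U = rng.uniform(config.exposure_low, config.exposure_high, size=(n, config.p))
    A = config.confounding_strength * (W @ c.T) + U
    return W, A


def _exposure_frame(A: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(A, columns=[f"a{j + 1}" for j in range(A.shape[1])])


def simulate(config: SimConfig) -> tuple[MixtureDataset, GroundTruth]:
    """Draw one dataset; same config (incl. seed) gives an identical draw."""
    rng = np.random.default_rng(config.seed)
    c, beta = _structure(config)
    W, A = _draw(config, rng, config.n)
    A_df = _exposure_frame(A)
    D = config.true_region.evaluate(A_df).astype(float)
    lin = config.effect_size * D + (W @ beta if config.q else 0.0)
    if config.outcome_type == "continuous":
        y = lin + rng.normal(0.0, config.noise_sd, size=config.n)
    else:
        y = rng.binomial(1, expit(lin)).astype(float)
    data = MixtureDataset(
        exposures=A_df,
        covariates=pd.DataFrame(
            W, columns=[f"w{k + 1}" for k in range(config.q)]
        ),
        outcome=y,
    )
    gt = GroundTruth(
        config=config, loadings=c, beta=beta,
        region_prevalence=float(np.mean(D)),
    )
    return data, gt


def true_ate(
    config: SimConfig,
    rule: MixtureRule | Sequence[MixtureRule],
    mc_n: int = 1_000_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Covariate-adjusted true ATE of rule membership, by Monte Carlo.

    Evaluates E_W[ E(Y | 1{A in rule} = 1, W) - E(Y | 1{A in rule} = 0, W) ]
    under the structural model: for each of m draws of W, K conditional
    exposure draws estimate the two arm means; the reported value averages
    the per-W contrasts and the standard error is their spread / sqrt(m).
    Rows of W where an arm has no draws (near-violated positivity) are
    skipped. For the continuous additive model with rule == true_region
    this is exactly the effect size, with zero Monte-Carlo error.

    ``rule`` may also be a sequence of rules, evaluated as their union
    (the pooled estimand across folds).
    """
    if mc_n < 10_000:
        raise ValueError("mc_n must be at least 10,000")
    rng = np.random.default_rng(config.seed + 86243 if seed is None else seed)
    c, beta = _structure(config)
    K = 500
    m = max(mc_n // K, 200)
    W = rng.standard_normal((m, config.q))
    U = rng.uniform(
        config.exposure_low, config.exposure_high, size=(m, K, config.p)
    )
    A = config.confounding_strength * (W @ c.T)[:, None, :] + U  # (m, K, p)
    flat = _exposure_frame(A.reshape(m * K, config.p))
    rules = [rule] if isinstance(rule, MixtureRule) else list(rule)
    D = np.zeros(m * K, dtype=np.int8)
    for r in rules:
        D |= r.evaluate(flat)
    D = D.reshape(m, K).astype(float)
    T = config.true_region.evaluate(flat).reshape(m, K).astype(float)

    if config.outcome_type == "continuous":
        # E[Y | D=d, W] = tau * P(T=1 | D=d, W) + beta.W  — the beta.W term
        # cancels in the contrast.
        val = config.effect_size * T
        base = np.zeros(m)
    else:
        bw = W @ beta if config.q else np.zeros(m)
        val = expit(config.effect_size * T + bw[:, None])
        base = np.zeros(m)
    n1 = D.sum(axis=1)
    n0 = K - n1
    ok = (n1 > 0) & (n0 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (val * D).sum(axis=1) / n1
        m0 = (val * (1.0 - D)).sum(axis=1) / n0
    contrasts = (m1 - m0 + base)[ok]
    if len(contrasts) == 0:
        raise RuntimeError("rule has one empty arm at every covariate draw")
    ate = float(np.mean(contrasts))
    se = float(np.std(contrasts, ddof=1) / np.sqrt(len(contrasts)))
    return ate, se


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _preset(**kw) -> Callable[[int, int], SimConfig]:
    def make(n: int, seed: int) -> SimConfig:
        return SimConfig(n=n, seed=seed, **kw)

    return make


PRESETS: dict[str, Callable[[int, int], SimConfig]] = {
    "null": _preset(
        p=3, q=2,
        true_region=parse_rule("a1 > 0.5 & a2 > 0.5"),
        effect_size=0.0, confounding_strength=0.2, noise_sd=1.0,
    ),
    "main-effect-1d": _preset(
        p=3, q=2,
        true_region=parse_rule("a1 > 1.0"),
        effect_size=3.0, confounding_strength=0.0, noise_sd=0.2,
        exposure_low=0.0, exposure_high=2.0,
    ),
    "interaction-2d": _preset(
        p=3, q=2,
        true_region=parse_rule("a1 > 0.5 & a2 > 0.5"),
        effect_size=5.0, confounding_strength=0.0, noise_sd=0.2,
    ),
    "confounded-interaction": _preset(
        p=3, q=2,
        true_region=parse_rule("a1 > 0.5 & a2 > 0.5"),
        effect_size=5.0, confounding_strength=0.5, noise_sd=0.2,
    ),
    "binary-outcome": _preset(
        p=3, q=2,
        true_region=parse_rule("a1 > 0.5 & a2 > 0.5"),
        effect_size=1.5, confounding_strength=0.2, noise_sd=1.0,
        outcome_type="binary",
    ),
}


def preset_config(name: str, n: int, seed: int) -> SimConfig:
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name](n, seed)
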