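"""Dataset container, fold assignment, and interval-rule machinery.

The three shared primitives of the package live here:

* :class:`MixtureDataset` — validated (exposures, covariates, outcome) blocks.
* :class:`FoldAssignment` / :func:`assign_folds` — balanced V-fold labels
  splitting the data into parameter-generating and estimation samples.
* :class:`MixtureRule` — a conjunction of half-open interval predicates
  ``lower < a <= upper`` on exposure variables, with a canonical text form.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureDataset",
    "FoldAssignment",
    "MixtureRule",
    "Predicate",
    "RuleParseError",
    "RuleSchemaError",
    "assign_folds",
    "evaluate_rule",
    "rule_union",
    "parse_rule",
    "serialize_rule",
]


class RuleParseError(ValueError):
    """Malformed rule text; carries the character position of the error."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class RuleSchemaError(KeyError):
    """A rule references a variable that is not an exposure column."""


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def _fmt_bound(x: float) -> str:
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return repr(float(x))


@dataclass(frozen=True)
class Predicate:
    """Half-open interval predicate ``lower < a <= upper`` on one variable."""

    var: str
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"empty interval for {self.var!r}: ({self.lower}, {self.upper}]"
            )

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values > self.lower) & (values <= self.upper)

    def text(self) -> str:
        parts = []
        if self.lower != -math.inf:
            parts.append(f"{self.var} > {_fmt_bound(self.lower)}")
        if self.upper != math.inf:
            parts.append(f"{self.var} <= {_fmt_bound(self.upper)}")
        if not parts:  # vacuous predicate still needs a serialization
            parts.append(f"{self.var} > -inf")
        return " & ".join(parts)


@dataclass(frozen=True)
class MixtureRule:
    """Conjunction of interval predicates over exposure variables.

    Predicates are merged per variable on construction (interval
    intersection), stored sorted by variable name so that equal rules
    compare equal and serialize identically.
    """

    predicates: tuple[Predicate, ...]
    provenance: str = ""

    def __post_init__(self):
        if not self.predicates:
            raise ValueError("a rule needs at least one predicate")
        merged: dict[str, Predicate] = {}
        for p in self.predicates:
            if p.var in merged:
                q = merged[p.var]
                merged[p.var] = Predicate(
                    p.var, max(p.lower, q.lower), min(p.upper, q.upper)
                )
            else:
                merged[p.var] = p
        object.__setattr__(
            self, "predicates", tuple(merged[v] for v in sorted(merged))
        )

    @classmethod
    def from_bounds(
        cls, bounds: Iterable[tuple[str, float, float]], provenance: str = ""
    ) -> "MixtureRule":
        return cls(
            tuple(Predicate(v, lo, hi) for v, lo, hi in bounds),
            provenance=provenance,
        )

    @property
    def description(self) -> str:
        return " & ".join(p.text() for p in self.predicates)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(p.var for p in self.predicates)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MixtureRule):
            return NotImplemented
        return self.predicates == other.predicates

    def __hash__(self) -> int:
        return hash(self.predicates)

    def evaluate(self, exposures: pd.DataFrame) -> np.ndarray:
        """Indicator vector: 1 iff a row satisfies every predicate."""
        missing = [p.var for p in self.predicates if p.var not in exposures.columns]
        if missing:
            raise RuleSchemaError(
                f"rule references unknown exposure column(s): {missing}"
            )
        out = np.ones(len(exposures), dtype=np.int8)
        for p in self.predicates:
            out &= p.contains(exposures[p.var].to_numpy(dtype=float)).astype(np.int8)
        return out


_CLAUSE_RE = re.compile(
    r"\s*(?P<var>[A-Za-z_][A-Za-z0-9_.]*)\s*"
    r"(?P<op>>=|<=|>|<)\s*"
    r"(?P<num>[-+]?(?:inf|\d+\.?\d*(?:[eE][-+]?\d+)?|\.\d+(?:[eE][-+]?\d+)?))\s*$"
)


def parse_rule(text: str, provenance: str = "") -> MixtureRule:
    """Parse ``var OP number (& var OP number)*`` into a :class:`MixtureRule`.

    ``>`` and ``>=`` both set the (open) lower bound; ``<`` and ``<=`` both
    set the (closed) upper bound — the interval convention is half-open
    ``(lower, upper]`` throughout, so the four operators collapse to two.
    """
    if not text.strip():
        raise RuleParseError("empty rule text", 0)
    preds: list[Predicate] = []
    pos = 0
    for clause in text.split("&"):
        m = _CLAUSE_RE.match(clause)
        if m is None:
            bad = pos + (len(clause) - len(clause.lstrip()))
            raise RuleParseError(f"cannot parse clause {clause.strip()!r}", bad)
        var, op, num = m.group("var"), m.group("op"), float(m.group("num"))
        if op in (">", ">="):
            preds.append(Predicate(var, lower=num))
        else:
            preds.append(Predicate(var, upper=num))
        pos += len(clause) + 1
    return MixtureRule(tuple(preds), provenance=provenance)


def serialize_rule(rule: MixtureRule) -> str:
    """Canonical text form; ``parse_rule(serialize_rule(r)) == r``."""
    return rule.description


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class MixtureDataset:
    """Complete-case rectangular dataset: exposures A, covariates W, outcome Y.

    Invariants enforced on construction: equal row counts, no missing
    values, numeric exposures with >= 2 distinct values each.
    """

    exposures: pd.DataFrame
    covariates: pd.DataFrame
    outcome: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.exposures = self.exposures.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        n = len(self.exposures)
        if n < 1 or self.exposures.shape[1] < 1:
            raise ValueError("need n >= 1 rows and p >= 1 exposure columns")
        if len(self.covariates) != n or len(self.outcome) != n:
            raise ValueError("exposures, covariates and outcome must have equal n")
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        if len(self.ids) != n or len(np.unique(self.ids)) != n:
            raise ValueError("ids must be length n and unique")
        for col in self.exposures.columns:
            vals = self.exposures[col]
            if not pd.api.types.is_numeric_dtype(vals):
                raise ValueError(f"exposure column {col!r} is not numeric")
            if vals.nunique() < 2:
                raise ValueError(f"exposure column {col!r} has < 2 distinct values")
        if self.exposures.isna().any().any() or self.covariates.isna().any().any():
            raise ValueError("missing values are not allowed")
        if np.isnan(self.outcome).any():
            raise ValueError("missing outcome values are not allowed")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def p(self) -> int:
        return self.exposures.shape[1]

    @property
    def q(self) -> int:
        return self.covariates.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return list(self.exposures.columns)

    def covariate_matrix(self) -> np.ndarray:
        """Covariates as a float matrix (may have zero columns)."""
        return self.covariates.to_numpy(dtype=float).reshape(self.n, -1)

    def subset(self, mask: np.ndarray) -> "MixtureDataset":
        mask = np.asarray(mask, dtype=bool)
        return MixtureDataset(
            self.exposures.loc[mask],
            self.covariates.loc[mask],
            self.outcome[mask],
            self.ids[mask],
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure_cols: Sequence[str],
        covariate_cols: Sequence[str],
        outcome_col: str,
    ) -> "MixtureDataset":
        """Build from a raw frame: drop incomplete rows (logged) and one-hot
        encode categorical covariates."""
        wanted = list(exposure_cols) + list(covariate_cols) + [outcome_col]
        missing = [c for c in wanted if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s) in data: {missing}")
        sub = df[wanted]
        complete = sub.dropna()
        dropped = len(sub) - len(complete)
        if dropped:
            logger.warning("dropped %d incomplete row(s) at load time", dropped)
        expo = complete[list(exposure_cols)].copy()
        for col in exposure_cols:
            if not pd.api.types.is_numeric_dtype(expo[col]):
                raise ValueError(f"exposure column {col!r} is not numeric")
        cov = complete[list(covariate_cols)].copy()
        cat = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
        if cat:
            cov = pd.get_dummies(cov, columns=cat, drop_first=True, dtype=float)
            logger.info("one-hot encoded covariate column(s): %s", cat)
        y = pd.to_numeric(complete[outcome_col], errors="raise").to_numpy(dtype=float)
        return cls(expo, cov, y)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Balanced V-fold labels in 1..V; fold v's estimation sample is
    ``labels == v`` and its parameter-generating sample is the complement."""

    V: int
    labels: np.ndarray
    seed: int

    def estimation_mask(self, v: int) -> np.ndarray:
        return self.labels == v

    def parameter_mask(self, v: int) -> np.ndarray:
        return self.labels != v


def assign_folds(n: int, V: int, seed: int) -> FoldAssignment:
    """Balanced random partition into V folds (sizes differ by at most 1).

    Deterministic in (n, V, seed).
    """
    if V < 2 or V > n:
        raise ValueError(f"invalid fold count V={V} for n={n} (need 2 <= V <= n)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % V + 1
    return FoldAssignment(V=V, labels=labels, seed=seed)


# ---------------------------------------------------------------------------
# Rule operations on datasets
# ---------------------------------------------------------------------------

def evaluate_rule(rule: MixtureRule, data: MixtureDataset) -> np.ndarray:
    return rule.evaluate(data.exposures)


def rule_union(
    rules: Sequence[MixtureRule], data: MixtureDataset
) -> tuple[np.ndarray, str]:
    """Disjunction of rules: indicator 1 iff any rule covers the row."""
    if not rules:
        raise ValueError("rule_union needs at least one rule")
    out = np.zeros(data.n, dtype=np.int8)
    seen: list[str] = []
    for r in rules:
        out |= r.evaluate(data.exposures)
        if r.description not in seen:
            seen.append(r.description)
    desc = " | ".join(f"({d})" for d in seen)
    return out, desc
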