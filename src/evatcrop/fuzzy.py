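"""Quasi-fuzzy input layer: triangular fuzzification, exhaustive rule
groups, product t-norm firing, and normalization into interim vectors.

Each meteorological variable is fuzzified into three linguistic labels
(*low*, *medium*, *high*) by symmetric triangular membership functions
anchored at the training-data minimum ``l``, midpoint ``m = (l + h) / 2``
and maximum ``h``. For an input combination of k variables the rule base
is the *complete* Cartesian product of label assignments (3^k rules) — no
rule selection or pruning, which removes the expert-judgement step of a
classical fuzzy system. Every rule fires on every record via the product
t-norm; the firing strengths, normalized to sum to one, form the *interim
vector* that a downstream neural head consumes in place of a defuzzified
value.

Values outside the fitted ``[l, h]`` range clamp to the nearest extreme
label with full membership, so a rule group can never fire all-zero on
unseen data — the design answer to the out-of-range failure of grid-
partition neuro-fuzzy systems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .weather import VARIABLES, WeatherRecord, WeatherSeries

LABELS: tuple[str, ...] = ("low", "medium", "high")
BASE_PAIR: tuple[str, str] = ("tmin", "tmax")
OPTIONAL_VARS: tuple[str, ...] = ("ws", "rh", "sr")


@dataclass(frozen=True)
class FuzzyPartition:
    """Triangular three-label partition of one variable's data space."""

    variable: str
    l: float
    m: float
    h: float

    def __post_init__(self) -> None:
        if not self.l < self.m < self.h:
            raise ValueError(
                f"{self.variable}: require l < m < h, got ({self.l}, {self.m}, {self.h})"
            )


@dataclass(frozen=True)
class InputCombination:
    """One of the eight supported subsets of meteorological inputs."""

    id: str
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(BASE_PAIR) <= set(self.variables):
            raise ValueError(f"{self.id}: must contain the base pair {BASE_PAIR}")
        canonical = tuple(v for v in VARIABLES if v in self.variables)
        if self.variables != canonical:
            raise ValueError(f"{self.id}: variables must follow order {VARIABLES}")

    @property
    def n_rules(self) -> int:
        return 3 ** len(self.variables)


@dataclass(frozen=True)
class Rule:
    """One label per variable of the combination, in combination order."""

    labels: tuple[str, ...]


@dataclass(frozen=True)
class RuleGroup:
    """The exhaustive, lexicographically ordered rule base for a combination."""

    id: str
    combination: InputCombination
    rules: tuple[Rule, ...]


def standard_combinations() -> tuple[InputCombination, ...]:
    """The eight input combinations C1..C8.

    The temperature pair is the base (always measured together); the other
    seven combinations add every subset of wind speed, relative humidity
    and solar radiation:

    C1 (Tmin,Tmax) · C2 +Ws · C3 +Rh · C4 +Sr · C5 +Ws,Rh · C6 +Ws,Sr ·
    C7 +Rh,Sr · C8 all five.
    """
    extras = [(), ("ws",), ("rh",), ("sr",), ("ws", "rh"), ("ws", "sr"),
              ("rh", "sr"), ("ws", "rh", "sr")]
    out = []
    for i, extra in enumerate(extras, start=1):
        variables = tuple(v for v in VARIABLES if v in BASE_PAIR + extra)
        out.append(InputCombination(id=f"C{i}", variables=variables))
    return tuple(out)


def combination_by_id(cid: str) -> InputCombination:
    for c in standard_combinations():
        if c.id == cid:
            return c
    raise KeyError(f"unknown combination {cid!r}; expected C1..C8")


def enumerate_rule_group(c: InputCombination) -> RuleGroup:
    """All 3^k label assignments over the combination's variables.

    Ordering is lexicographic with the first variable varying slowest and
    label order low < medium < high, so the first rule is all-low and the
    last all-high. The ordering is the contract that aligns interim-vector
    components with neural-head inputs across fit, predict and persistence.
    """
    rules = tuple(Rule(labels=combo)
                  for combo in itertools.product(LABELS, repeat=len(c.variables)))
    rg_id = "RG" + c.id[1:]
    return RuleGroup(id=rg_id, combination=c, rules=rules)


def total_rule_count(combinations: Iterable[InputCombination] | None = None) -> int:
    """Sum of rule-group sizes over the given (default: all eight) combinations."""
    combos = tuple(combinations) if combinations is not None else standard_combinations()
    return sum(c.n_rules for c in combos)


# ---------------------------------------------------------------------------
# Fuzzification
# ---------------------------------------------------------------------------

def fit_partition(series: WeatherSeries, variable: str) -> FuzzyPartition:
    """Anchor a partition at the observed min/max with the medium peak at the
    midpoint. Raises on a constant variable (degenerate triangle)."""
    x = series.frame[variable].dropna().to_numpy()
    if x.size < 2:
        raise ValueError(f"{variable}: need at least two observations")
    l, h = float(x.min()), float(x.max())
    if l == h:
        raise ValueError(f"{variable}: constant variable, cannot partition")
    return FuzzyPartition(variable=variable, l=l, m=(l + h) / 2.0, h=h)


def fit_partitions(series: WeatherSeries,
                   variables: Sequence[str] | None = None) -> dict[str, FuzzyPartition]:
    """One partition per requested (default: every available) variable."""
    variables = tuple(variables) if variables is not None else series.variables
    return {v: fit_partition(series, v) for v in variables}


def membership_degrees(x, p: FuzzyPartition) -> np.ndarray:
    """Degrees (μ_low, μ_medium, μ_high) at value(s) ``x``.

    Triangular: μ_low falls 1→0 over [l, m]; μ_medium rises 0→1 over
    [l, m] then falls 1→0 over [m, h]; μ_high rises 0→1 over [m, h].
    Outside [l, h] the nearest extreme label saturates at 1. The three
    degrees sum to 1 for every x (partition of unity), scalar in → shape
    (3,), array in → shape (..., 3).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo = np.clip((p.m - x) / (p.m - p.l), 0.0, 1.0)
    hi = np.clip((x - p.m) / (p.h - p.m), 0.0, 1.0)
    mid = 1.0 - lo - hi
    out = np.stack([lo, mid, hi], axis=-1)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Rule firing and normalization
# ---------------------------------------------------------------------------

def _label_index_matrix(group: RuleGroup) -> np.ndarray:
    """(n_rules, k) matrix of label indices (low=0, medium=1, high=2)."""
    idx = {lab: i for i, lab in enumerate(LABELS)}
    return np.array([[idx[lab] for lab in r.labels] for r in group.rules], dtype=int)


def fire_rule_group(record: WeatherRecord, group: RuleGroup,
                    partitions: Mapping[str, FuzzyPartition]) -> np.ndarray:
    """Product t-norm firing strength P_i for every rule of the group.

    P_i is the product, over the combination's variables, of the membership
    degree of the rule's label at the record's value. All rules fire (the
    full vector is returned); each P_i lies in [0, 1].
    """
    values = np.array([[record.value(v) for v in group.combination.variables]])
    return _fire_matrix(values, group, partitions)[0]


def _fire_matrix(values: np.ndarray, group: RuleGroup,
                 partitions: Mapping[str, FuzzyPartition]) -> np.ndarray:
    """Vectorised firing: values (n, k) → strengths (n, 3^k)."""
    variables = group.combination.variables
    for v in variables:
        if v not in partitions:
            raise KeyError(f"no partition for variable {v!r}")
    # degrees[j]: (n, 3) membership of variable j
    degrees = [membership_degrees(values[:, j], partitions[v])
               for j, v in enumerate(variables)]
    labels = _label_index_matrix(group)  # (n_rules, k)
    p = np.ones((values.shape[0], labels.shape[0]))
    for j in range(labels.shape[1]):
        p *= degrees[j][:, labels[:, j]]
    return p


def normalize_firings(p: np.ndarray) -> np.ndarray:
    """Interim vector I_i = P_i / Σ P_i; errors on an all-zero firing.

    With the default symmetric triangles Σ P_i is already 1 (the product
    of per-variable partitions of unity distributes over the Cartesian
    rule base), so this is an identity up to round-off; it matters for
    expert-supplied partitions that do not sum to one.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0.0):
        raise ValueError("all rules fired at zero; partitions do not cover the input")
    return p / total


def transform(record: WeatherRecord, c: InputCombination,
              partitions: Mapping[str, FuzzyPartition]) -> np.ndarray:
    """Fuzzify one record for a combination: fire its rule group and
    normalize, giving the length-3^k interim vector."""
    group = enumerate_rule_group(c)
    return normalize_firings(fire_rule_group(record, group, partitions))


def transform_series(series: WeatherSeries, c: InputCombination,
                     partitions: Mapping[str, FuzzyPartition]) -> np.ndarray:
    """Interim vectors for every record: (n, 3^k) design matrix for the
    combination's neural head."""
    for v in c.variables:
        if v not in series.variables:
            raise KeyError(f"combination {c.id} needs variable {v!r}, absent from series")
    group = enumerate_rule_group(c)
    values = series.frame[list(c.variables)].to_numpy()
    return normalize_firings(_fire_matrix(values, group, partitions))
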