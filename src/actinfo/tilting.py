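"""Finite distributions, specificity targets, and exponential tilting.

Active information quantifies how much problem-specific knowledge a search
algorithm infuses: for a target set ``A`` of highly specified states,

    I+ = log P(A) / P0(A)        (nats),

where ``P0`` is the null (no-knowledge) distribution and ``P`` the
distribution of the informed search.  The canonical one-parameter family of
informed searches is obtained by exponentially tilting ``P0`` with a
specificity function ``f``,

    P_theta(x) = e^{theta f(x)} P0(x) / M(theta),

which is an exponential family in the tilting parameter ``theta >= 0``.
This module houses the discrete-distribution container, the specificity /
target machinery, the tilting operation, and the equilibrium active
information I+(theta).
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Callable, Hashable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "FiniteDistribution",
    "SpecificityModel",
    "TiltedFamily",
    "log_normalizer",
    "tilt",
    "target_probability",
    "active_info",
    "functional_info",
    "equilibrium_actinfo_curve",
    "nats_to_bits",
]

#: normalization tolerance for every emitted distribution
NORM_TOL = 1e-12

LN2 = float(np.log(2.0))


def nats_to_bits(x: float) -> float:
    """Convert an information value from nats to bits (display only)."""
    return x / LN2


def _serialize_state(state: Hashable) -> str:
    """Canonical text form of a state label (binary tuples -> '10110')."""
    if isinstance(state, tuple) and all(s in (0, 1) for s in state):
        return "".join(str(int(s)) for s in state)
    return str(state)


@dataclass(frozen=True)
class FiniteDistribution:
    """A probability distribution over an enumerated finite state space.

    Probabilities are stored as natural-log probabilities; the enumeration
    order of ``states`` is part of the value (all matrix operations use it).
    """

    states: tuple
    log_probs: np.ndarray
    # exact linear-scale probabilities, kept when constructed from_probs so
    # that serialization round-trips the decimal text bit-exactly
    _probs: np.ndarray | None = None

    def __post_init__(self):
        states = tuple(self.states)
        if len(set(states)) != len(states):
            raise ValueError("state labels must be unique")
        lp = np.asarray(self.log_probs, dtype=float)
        if lp.shape != (len(states),):
            raise ValueError("log_probs length must match number of states")
        if np.any(np.isnan(lp)):
            raise ValueError("log probabilities must not be NaN")
        total = np.exp(logsumexp(lp))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "log_probs", lp)
        lp.setflags(write=False)

    @classmethod
    def from_probs(cls, states: Iterable[Hashable], probs) -> "FiniteDistribution":
        p = np.asarray(probs, dtype=float).copy()
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        p.setflags(write=False)
        with np.errstate(divide="ignore"):
            return cls(tuple(states), np.log(p), p)

    @classmethod
    def uniform(cls, states: Iterable[Hashable]) -> "FiniteDistribution":
        states = tuple(states)
        return cls(states, np.full(len(states), -np.log(len(states))))

    @classmethod
    def point_mass(cls, states: Iterable[Hashable], at: Hashable) -> "FiniteDistribution":
        states = tuple(states)
        p = np.zeros(len(states))
        p[states.index(at)] = 1.0
        return cls.from_probs(states, p)

    @property
    def probs(self) -> np.ndarray:
        if self._probs is not None:
            return self._probs
        return np.exp(self.log_probs)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def prob(self, state: Hashable) -> float:
        return float(np.exp(self.log_probs[self.states.index(state)]))

    def index(self, state: Hashable) -> int:
        return self.states.index(state)

    # ---- serialization (CSV `state,prob` / JSON) ----------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": [_serialize_state(s) for s in self.states], "prob": self.probs}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        obj = {
            "states": [_serialize_state(s) for s in self.states],
            "probs": [repr(float(p)) for p in self.probs],
        }
        if path is None:
            return json.dumps(obj)
        with open(path, "w") as fh:
            json.dump(obj, fh)
        return None

    @classmethod
    def from_csv(cls, path, parse_binary: bool = True) -> "FiniteDistribution":
        df = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
        states = [_parse_state(s, parse_binary) for s in df["state"]]
        return cls.from_probs(states, df["prob"].to_numpy())

    @classmethod
    def from_json(cls, source, parse_binary: bool = True) -> "FiniteDistribution":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        states = [_parse_state(s, parse_binary) for s in obj["states"]]
        return cls.from_probs(states, [float(p) for p in obj["probs"]])


def _parse_state(text: str, parse_binary: bool) -> Hashable:
    if parse_binary and set(text) <= {"0", "1"} and len(text) > 1:
        return tuple(int(c) for c in text)
    return text


def binary_states(d: int) -> tuple:
    """All binary tuples of length ``d`` in lexicographic order."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return tuple(
        tuple((i >> (d - 1 - j)) & 1 for j in range(d)) for i in range(2**d)
    )


@dataclass(frozen=True)
class SpecificityModel:
    """A specificity function ``f``, a threshold ``f0`` and the target set.

    The target is ``A = {x : f(x) >= f0}`` -- ties sit inside A.  The most
    stringent choice ``f0 = fmax`` reduces A to the set of maximally
    specified states.
    """

    f: Callable[[Hashable], float] | dict
    f0: float
    x0: Hashable | None = None

    def value(self, state: Hashable) -> float:
        v = self.f[state] if isinstance(self.f, dict) else self.f(state)
        v = float(v)
        if not np.isfinite(v):
            raise ValueError(f"specificity f is not finite at state {state!r}")
        return v

    def values(self, states: Sequence[Hashable]) -> np.ndarray:
        return np.array([self.value(s) for s in states])

    def in_target(self, state: Hashable) -> bool:
        return self.value(state) >= self.f0

    def target_mask(self, states: Sequence[Hashable]) -> np.ndarray:
        return self.values(states) >= self.f0

    def target_set(self, states: Sequence[Hashable]) -> tuple:
        return tuple(s for s in states if self.in_target(s))

    def fmax(self, states: Sequence[Hashable]) -> float:
        return float(np.max(self.values(states)))

    @classmethod
    def indicator(cls, target: Iterable[Hashable]) -> "SpecificityModel":
        """Binary specificity f = 1{x in A} with threshold 1 (the LPI case)."""
        target = set(target)
        return cls(f=lambda x: 1.0 if x in target else 0.0, f0=1.0)

    @classmethod
    def from_csv(cls, path, f0: float, parse_binary: bool = True) -> "SpecificityModel":
        df = pd.read_csv(path, dtype={"state": str})
        table = {
            _parse_state(s, parse_binary): float(v)
            for s, v in zip(df["state"], df["f"])
        }
        return cls(f=table, f0=f0)

    def to_csv(self, path, states: Sequence[Hashable]) -> None:
        pd.DataFrame(
            {"state": [_serialize_state(s) for s in states], "f": self.values(states)}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class TiltedFamily:
    """The exponential family ``{P_theta : theta >= 0}`` tilted by ``f``."""

    base: FiniteDistribution
    spec: SpecificityModel
    f_values: np.ndarray = field(init=False)

    def __post_init__(self):
        fv = self.spec.values(self.base.states)
        fv.setflags(write=False)
        object.__setattr__(self, "f_values", fv)

    def mean_f(self, theta: float) -> float:
        """E_Ptheta[f] = M'(theta)/M(theta), the score-centering constant."""
        return float(np.sum(tilt(self, theta).probs * self.f_values))

    def var_f(self, theta: float) -> float:
        p = tilt(self, theta).probs
        m = np.sum(p * self.f_values)
        return float(np.sum(p * (self.f_values - m) ** 2))


def log_normalizer(family: TiltedFamily, theta: float) -> float:
    """log M(theta) of the tilted family, computed by log-sum-exp.

    M(theta) = sum_x e^{theta f(x)} P0(x); M(0) = 1 exactly.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    if theta == 0.0:
        return 0.0
    return float(logsumexp(theta * family.f_values + family.base.log_probs))


def tilt(family: TiltedFamily, theta: float) -> FiniteDistribution:
    """The exponentially tilted member P_theta of the family.

    States with P0(x)=0 keep probability zero.  Negative ``theta`` is
    permitted (useful for oracles) but flagged with a warning since the
    tuning interpretation assumes theta >= 0.
    """
    if theta < 0:
        warnings.warn("tilting with theta < 0: outside the tuning domain",
                      stacklevel=2)
    if theta == 0.0:
        return family.base  # exact: the family member at 0 IS the base
    log_m = log_normalizer(family, theta)
    lp = theta * family.f_values + family.base.log_probs - log_m
    # renormalize away the last-digit drift so invariants hold exactly
    lp = lp - logsumexp(lp)
    return FiniteDistribution(family.base.states, lp)


def target_probability(dist: FiniteDistribution, spec: SpecificityModel) -> float:
    """P(A) = sum over the target set A = {x : f(x) >= f0}."""
    mask = spec.target_mask(dist.states)
    if not mask.any():
        raise ValueError("target set A is empty")
    return float(np.sum(dist.probs[mask]))


def active_info(p_target: float, p0_target: float) -> float:
    """Active information I+ = log(P(A)/P0(A)) in nats.

    P(A)=0 yields -inf with a warning rather than an error, so that
    estimators can report "no evidence" instead of crashing.
    """
    if p0_target <= 0:
        raise ValueError("P0(A) must be positive (functional information "
                         "denominator undefined)")
    if p_target < 0:
        raise ValueError("P(A) must be nonnegative")
    if p_target == 0.0:
        warnings.warn("P(A) = 0: active information is -inf", stacklevel=2)
        return -np.inf
    return float(np.log(p_target / p0_target))


def functional_info(p0_target: float) -> float:
    """Functional information If0 = -log P0(A), the ceiling of I+."""
    if not 0 < p0_target <= 1:
        raise ValueError("P0(A) must lie in (0, 1]")
    return float(-np.log(p0_target))


def equilibrium_actinfo_curve(
    family: TiltedFamily, theta_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """I+(theta) along a sorted nonnegative theta grid.

    Strictly increasing in theta when 0 < P0(A) < 1, starting at 0 for
    theta=0, bounded above by If0 = -log P0(A).
    """
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size and (np.any(grid < 0) or np.any(np.diff(grid) < 0)):
        raise ValueError("theta grid must be nonnegative and sorted")
    p0_a = target_probability(family.base, family.spec)
    if p0_a == 0:
        raise ValueError("P0(A) = 0: active information undefined")
    out = []
    for th in grid:
        p_a = target_probability(tilt(family, float(th)), family.spec)
        out.append((float(th), active_info(p_a, p0_a)))
    return out
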