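"""Metropolis--Hastings and Moran-type kernels; stopped-chain actinfo.

A search algorithm that knows the specificity function ``f`` can be modelled
as a Markov chain whose equilibrium is the tilted distribution P_theta: a
candidate move x -> y from a proposal kernel q is accepted with probability

    mh:          alpha(x,y) = min{1, e^{theta f(y)} P0(y) q(y,x)
                                   / (e^{theta f(x)} P0(x) q(x,y))}
    moran_sqrt:  alpha(x,y) = C * [same ratio]^{1/2},

where for the Moran-type flavor the constant C scales the largest ratio to
acceptance probability one.  Both flavors are reversible with respect to
P_theta, so P_theta is the equilibrium distribution whenever the proposal is
irreducible.

The module also computes the non-equilibrium actinfo trajectory I+(theta,t)
of the iterated chain, and -- by clumping the target set A into a single
absorbing state (a phase-type decomposition) -- the actinfo Is+(theta,t) of
the search that stops on first hitting A, together with the expected hitting
time E(T) via the fundamental matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tilting import (
    NORM_TOL,
    FiniteDistribution,
    SpecificityModel,
    TiltedFamily,
    active_info,
    target_probability,
    tilt,
)

__all__ = [
    "MHKernel",
    "StoppedChainDecomposition",
    "build_kernel",
    "evolve",
    "evolve_to_equilibrium",
    "actinfo_trajectory",
    "stopped_decomposition",
    "stopped_target_prob",
    "actinfo_stopped_trajectory",
    "expected_hitting_time",
    "stationary_distribution",
    "detailed_balance_residual",
    "mh_steps_to_moran_generations",
]

#: convergence threshold (total variation) for equilibrium detection
EQUILIBRIUM_TV_TOL = 1e-12
#: hard cap on iterations when searching for equilibrium
EQUILIBRIUM_MAX_ITER = 10**6


@dataclass(frozen=True)
class MHKernel:
    """A reversible transition kernel targeting the tilted distribution.

    ``transition`` rows sum to one; ``acceptance`` holds alpha(x,y) on
    off-diagonal proposal support; ``rejection`` is the per-state probability
    of staying put because the proposed move was declined (plus any proposal
    self-mass).  ``moran_constant`` is the scaling C of the moran_sqrt flavor
    (None for plain mh).
    """

    base: FiniteDistribution
    spec: SpecificityModel
    theta: float
    flavor: str
    proposal: np.ndarray
    acceptance: np.ndarray
    rejection: np.ndarray
    transition: np.ndarray
    moran_constant: float | None = None

    @property
    def states(self) -> tuple:
        return self.base.states

    @property
    def n_states(self) -> int:
        return self.base.n_states

    def stationary(self) -> FiniteDistribution:
        """The tilted member this kernel was built to equilibrate to."""
        return tilt(TiltedFamily(self.base, self.spec), self.theta)


def _check_stochastic(mat: np.ndarray, what: str, tol: float = NORM_TOL) -> None:
    rows = mat.sum(axis=1)
    if np.any(mat < -tol) or np.any(np.abs(rows - 1.0) > max(tol, 1e-10)):
        raise ValueError(f"{what} rows must be nonnegative and sum to 1")


def build_kernel(
    base: FiniteDistribution,
    spec: SpecificityModel,
    theta: float,
    proposal: np.ndarray,
    flavor: str = "mh",
) -> MHKernel:
    """Assemble the MH-type kernel for a given tilting parameter.

    ``flavor='mh'`` uses the usual min{1, ratio} acceptance; ``'moran_sqrt'``
    uses C*sqrt(ratio), with C = 1/max sqrt(ratio) over ordered pairs whose
    proposal probabilities are positive in both directions (one-sided support
    is rejected loudly -- the scaling constant is undefined there).
    """
    q = np.asarray(proposal, dtype=float)
    n = base.n_states
    if q.shape != (n, n):
        raise ValueError("proposal matrix shape must match the state space")
    _check_stochastic(q, "proposal")
    if flavor not in ("mh", "moran_sqrt"):
        raise ValueError(f"unknown kernel flavor {flavor!r}")

    f = spec.values(base.states)
    logp0 = base.log_probs
    off = ~np.eye(n, dtype=bool)
    support = (q > 0) & off

    # mh ratio undefined if a zero-probability state receives proposal inflow
    if flavor == "mh":
        dead = np.isneginf(logp0)
        if np.any(dead & support.any(axis=0)):
            bad = [base.states[i] for i in np.where(dead & support.any(axis=0))[0]]
            raise ValueError(f"P0(x)=0 at proposed-into states {bad!r}: "
                             "mh acceptance ratio undefined")

    # log ratio  theta f(y) + log P0(y) + log q(y,x) - (same at x, q(x,y))
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log(q)
        w = theta * f + logp0  # log unnormalized P_theta
        # NaN/inf entries off the proposal support are masked out below
        log_ratio = (w[None, :] - w[:, None]) + (logq.T - logq)

    alpha = np.zeros((n, n))
    C = None
    if flavor == "mh":
        alpha[support] = np.exp(np.minimum(0.0, log_ratio[support]))
    else:
        both = support & support.T
        if np.any(support & ~both):
            raise ValueError("moran_sqrt requires q(x,y)>0 iff q(y,x)>0; "
                             "one-sided proposal support found")
        if not both.any():
            raise ValueError("moran_sqrt: proposal has no two-sided support")
        half = 0.5 * log_ratio[both]
        logC = -np.max(half)
        C = float(np.exp(logC))
        alpha[both] = np.exp(logC + half)

    if np.any(alpha > 1 + 1e-12):
        raise AssertionError("acceptance probability exceeded 1")
    alpha = np.clip(alpha, 0.0, 1.0)

    trans = np.where(off, alpha * q, 0.0)
    rejection = 1.0 - trans.sum(axis=1)
    trans[np.arange(n), np.arange(n)] = rejection
    return MHKernel(base, spec, float(theta), flavor, q, alpha, rejection,
                    trans, C)


def detailed_balance_residual(kernel: MHKernel) -> float:
    """max |P_theta(x) pi(x,y) - P_theta(y) pi(y,x)| over x != y."""
    p = kernel.stationary().probs
    flow = p[:, None] * kernel.transition
    res = np.abs(flow - flow.T)
    np.fill_diagonal(res, 0.0)
    return float(res.max())


def evolve(start: FiniteDistribution, kernel: MHKernel, t: int) -> FiniteDistribution:
    """P_t = P_start * Pi^t, the chain's marginal after ``t`` steps."""
    if t < 0:
        raise ValueError("t must be >= 0")
    p = start.probs
    for _ in range(int(t)):
        p = p @ kernel.transition
    p = np.maximum(p, 0.0)
    return FiniteDistribution.from_probs(start.states, p / p.sum())


def evolve_to_equilibrium(
    start: FiniteDistribution,
    kernel: MHKernel,
    tol: float = EQUILIBRIUM_TV_TOL,
    max_iter: int = EQUILIBRIUM_MAX_ITER,
) -> tuple[FiniteDistribution, int, bool]:
    """Iterate until consecutive marginals agree in total variation.

    Returns (distribution, steps, converged).  Periodic chains may
    oscillate; in that case a Cesaro average of the last two iterates is
    tried before giving up, and the ``converged`` flag reports honestly.
    """
    p = start.probs
    for it in range(1, max_iter + 1):
        nxt = p @ kernel.transition
        if 0.5 * np.abs(nxt - p).sum() < tol:
            return FiniteDistribution.from_probs(start.states, nxt / nxt.sum()), it, True
        p = nxt
    avg = 0.5 * (p + p @ kernel.transition)
    warnings.warn("equilibrium not reached within max_iter; returning Cesaro "
                  "average of the last iterates", stacklevel=2)
    return FiniteDistribution.from_probs(start.states, avg / avg.sum()), max_iter, False


def actinfo_trajectory(
    start: FiniteDistribution,
    kernel: MHKernel,
    spec: SpecificityModel,
    t_max: int,
) -> np.ndarray:
    """I+(theta,t) = log[P_t(A)/P_0(A)] for t = 0..t_max.

    Starts at 0 by construction and converges to the equilibrium actinfo
    I+(theta); monotonicity in t is not guaranteed in general and is not
    asserted here.
    """
    p0_a = target_probability(start, spec)
    if p0_a == 0:
        raise ValueError("P0(A) = 0")
    mask = spec.target_mask(start.states)
    out = np.empty(t_max + 1)
    p = start.probs
    for t in range(t_max + 1):
        out[t] = active_info(float(p[mask].sum()), p0_a)
        if t < t_max:
            p = p @ kernel.transition
    return out


@dataclass(frozen=True)
class StoppedChainDecomposition:
    """Phase-type pieces of the chain with the target A made absorbing.

    ``Q_na`` is the transient block over the non-target states Ac, ``exit``
    the per-state probability of jumping into A, and ``start_na`` the
    restriction of the start distribution to Ac.  ``p0_target`` is the start
    mass already inside A (T = 0).
    """

    nonabsorbing_states: tuple
    Q_na: np.ndarray
    exit: np.ndarray
    start_na: np.ndarray
    p0_target: float

    def __post_init__(self):
        rows = self.Q_na.sum(axis=1) + self.exit
        if np.any(np.abs(rows - 1.0) > 1e-10):
            raise ValueError("[Q_na | exit] rows must sum to 1")

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.Q_na))))


def stopped_decomposition(
    kernel: MHKernel, start: FiniteDistribution, spec: SpecificityModel
) -> StoppedChainDecomposition:
    """Clump all target states into one absorbing state and split the kernel."""
    if start.states != kernel.states:
        raise ValueError("start distribution and kernel must share a state space")
    mask = spec.target_mask(kernel.states)
    if not mask.any():
        raise ValueError("target set A is empty")
    if mask.all():
        raise ValueError("A = Omega: no transient part to decompose")
    na = ~mask
    Q_na = kernel.transition[np.ix_(na, na)]
    exit = kernel.transition[np.ix_(na, mask)].sum(axis=1)
    start_na = start.probs[na]
    states_na = tuple(s for s, m in zip(kernel.states, na) if m)
    return StoppedChainDecomposition(
        states_na, Q_na, exit, start_na, float(start.probs[mask].sum())
    )


def stopped_target_prob(dec: StoppedChainDecomposition, t: int) -> float:
    """P(T <= t) = 1 - start_na Q_na^t 1: probability A is hit by time t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    v = dec.start_na.copy()
    for _ in range(int(t)):
        v = v @ dec.Q_na
    return float(np.clip(1.0 - v.sum(), 0.0, 1.0))


def actinfo_stopped_trajectory(
    dec: StoppedChainDecomposition, t_max: int
) -> np.ndarray:
    """Is+(theta,t) = log[P(T<=t)/P0(A)] for t = 0..t_max.

    Nondecreasing in t, always >= the non-stopped I+(theta,t), with limit
    the functional information If0.
    """
    if dec.p0_target == 0:
        raise ValueError("P0(A) = 0")
    # use the same 1 - v.sum() form for the denominator so the t=0 term is
    # exactly zero despite last-ulp differences
    p0_a = float(np.clip(1.0 - dec.start_na.sum(), 0.0, 1.0))
    out = np.empty(t_max + 1)
    v = dec.start_na.copy()
    for t in range(t_max + 1):
        out[t] = active_info(float(np.clip(1.0 - v.sum(), 0.0, 1.0)), p0_a)
        if t < t_max:
            v = v @ dec.Q_na
    return out


def expected_hitting_time(dec: StoppedChainDecomposition) -> float:
    """E(T) = start_na (I - Q_na)^{-1} 1 via the fundamental matrix."""
    n = dec.Q_na.shape[0]
    try:
        sojourn = np.linalg.solve(np.eye(n) - dec.Q_na, np.ones(n))
    except np.linalg.LinAlgError as err:
        raise ValueError("I - Q_na singular: target A unreachable from some "
                         "start mass") from err
    if np.any(sojourn < 0):
        raise ValueError("negative sojourn times: target A unreachable from "
                         "some start mass")
    return float(dec.start_na @ sojourn)


def stationary_distribution(transition: np.ndarray, states=None) -> FiniteDistribution:
    """Unique solution of pi = pi Pi, sum(pi) = 1 for an irreducible chain.

    Solved directly: replace one balance equation with the normalization
    constraint (deterministic, exact to solver tolerance).
    """
    P = np.asarray(transition, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("transition matrix must be square")
    _check_stochastic(P, "transition")
    _check_irreducible(P)
    A = (P.T - np.eye(n))
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = np.linalg.solve(A, rhs)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    if states is None:
        states = tuple(range(n))
    return FiniteDistribution.from_probs(states, pi)


def _check_irreducible(P: np.ndarray) -> None:
    """Reachability check on the adjacency structure (BFS from state 0,
    both directions); raises listing unreachable states."""
    adj = P > 0
    n = P.shape[0]
    for mat in (adj, adj.T):
        seen = np.zeros(n, dtype=bool)
        seen[0] = True
        frontier = [0]
        while frontier:
            nxt = mat[frontier].any(axis=0) & ~seen
            frontier = list(np.where(nxt)[0])
            seen |= nxt
        if not seen.all():
            raise ValueError(
                f"chain is reducible; states unreachable (indices): "
                f"{list(np.where(~seen)[0])}"
            )


def mh_steps_to_moran_generations(steps: float, C: float, mu: float) -> float:
    """Convert MH-type steps to Moran generations: one step ~ C/mu generations.

    Documented conversion only -- no computation in this package uses it.
    """
    if mu <= 0:
        raise ValueError("mutation probability mu must be positive")
    return steps * C / mu
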