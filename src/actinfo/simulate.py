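"""Seeded samplers and synthetic experiments for verifying the estimators.

Everything here is a pure function of its inputs and a seed: i.i.d. draws
from a finite distribution by inverse-CDF over the fixed enumeration order,
independent chain runs (optionally frozen on first entry to the target),
and two experiment harnesses -- the exponential decay of the fine-tuning
test's type-I error (computed from exact binomial tails, since the hit
count is Binomial under the null), and Monte-Carlo checks of the CLT
normality/variance claims.
"""

from __future__ import annotations

from collections.abc import Callable

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .estimation import SampleData, ld_rate_np
from .markov import MHKernel
from .tilting import FiniteDistribution, SpecificityModel

__all__ = [
    "iid_sampler",
    "iid_indices",
    "chain_sampler",
    "significance_decay_experiment",
    "normality_experiment",
]


def iid_indices(dist: FiniteDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. state indices by inverse-CDF over the enumeration order."""
    cdf = np.cumsum(dist.probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="left")


def iid_sampler(dist: FiniteDistribution, n: int, seed: int) -> SampleData:
    """n i.i.d. draws from ``dist``; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = iid_indices(dist, n, rng)
    return SampleData(tuple(dist.states[i] for i in idx))


def chain_sampler(
    kernel: MHKernel,
    start: FiniteDistribution,
    t: int,
    n: int,
    seed: int,
    stop_at: SpecificityModel | None = None,
) -> SampleData:
    """n independent chain runs of length t; optionally stopped on hitting A.

    With ``stop_at`` given, each run freezes on its first entry into the
    target set (the stopped search X_{t ^ T}); without it the plain
    t-step marginal is sampled.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(seed)
    cum_trans = np.cumsum(kernel.transition, axis=1)
    cum_trans[:, -1] = 1.0
    state = iid_indices(start, n, rng)
    frozen = np.zeros(n, dtype=bool)
    if stop_at is not None:
        in_a = stop_at.target_mask(kernel.states)
        frozen = in_a[state]
    for _ in range(int(t)):
        active = ~frozen
        if not active.any():
            break
        u = rng.random(int(active.sum()))
        rows = cum_trans[state[active]]
        state[active] = (rows < u[:, None]).sum(axis=1)
        if stop_at is not None:
            frozen = frozen | in_a[state]
    return SampleData(tuple(kernel.states[i] for i in state))


def significance_decay_experiment(
    p0_A: float,
    i_min: float,
    n_grid,
    reps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Type-I error of the nonparametric FT test along a grid of sample sizes.

    Under the null, the number of hits is Binomial(n, P0(A)), so the level
    P(Ihat+ >= Imin) = P(hits >= ceil(n pmin)) is computed exactly from the
    binomial tail (no sampling).  When ``reps`` and ``seed`` are supplied, a
    Monte-Carlo column is appended for comparison.  Columns: n, level,
    rate = -log(level)/n, plus the closed-form limit C.
    """
    p_min = p0_A * float(np.exp(i_min))
    if p_min > 1:
        raise ValueError("pmin > 1: the test can never reject")
    C = ld_rate_np(p0_A, p_min) if p_min > p0_A else 0.0
    rows = []
    rng = np.random.default_rng(seed) if seed is not None else None
    for n in n_grid:
        k = int(np.ceil(n * p_min - 1e-12))
        level = float(binom.sf(k - 1, n, p0_A))
        rate = -np.log(level) / n if level > 0 else np.inf
        row = {"n": int(n), "level": level, "rate": rate, "C": C}
        if reps is not None and rng is not None:
            hits = rng.binomial(n, p0_A, size=reps)
            mc_level = float(np.mean(hits >= k))
            row["mc_level"] = mc_level
            row["flagged"] = mc_level == 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def normality_experiment(
    draw_i_hat: Callable[[np.random.Generator], float],
    truth: float,
    variance: float,
    n: int,
    reps: int,
    seed: int,
) -> dict:
    """Monte-Carlo check of a sqrt(n)(Ihat+ - I+) -> N(0, V) claim.

    ``draw_i_hat(rng)`` produces one estimate from a fresh synthetic sample
    of size n.  Returns the standardized mean/variance/skewness and the
    coverage of the 95% Wald interval built from the claimed variance.
    """
    rng = np.random.default_rng(seed)
    est = np.array([draw_i_hat(rng) for _ in range(reps)])
    z = np.sqrt(n) * (est - truth)
    sd = np.sqrt(variance)
    zz = z / sd
    half = norm.ppf(0.975) * sd / np.sqrt(n)
    return {
        "mean": float(zz.mean()),
        "variance": float(z.var(ddof=1)),
        "variance_ratio": float(z.var(ddof=1) / variance),
        "skewness": float(((zz - zz.mean()) ** 3).mean() / zz.std(ddof=0) ** 3),
        "coverage": float(np.mean(np.abs(est - truth) <= half)),
        "reps": reps,
        "n": n,
    }
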