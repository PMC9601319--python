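"""Worked models: cosmology, student learning, finite MDPs, Moran machines.

Four concrete systems exercise the active-information machinery:

* **Cosmology** -- a constant of nature with a life-permitting interval
  (a, b); the null is the maximum-entropy exponential law with unknown mean
  xi, and the one-sample estimate uses the xi-maximized interval probability.
* **Student learning** -- test scores follow a normal regression whose mean
  shifts linearly with study time t; actinfo measures how much studying
  raises the pass probability.
* **Reinforcement learning** -- a finite MDP where the specificity of a
  trajectory is its discounted total reward; actinfo compares a deterministic
  policy against a random one via two-sample Monte Carlo.
* **Molecular machines** -- binary strings of d parts evolving by one-bit
  mutations under a Moran-type (square-root acceptance) chain; the null is
  the stationary law of the all-accept mutation chain, and the target is the
  fully functional machine (1,...,1).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .estimation import EstimationResult, empirical_actinfo, variance_np
from .markov import MHKernel, build_kernel, stationary_distribution
from .tilting import (
    FiniteDistribution,
    SpecificityModel,
    TiltedFamily,
    active_info,
    binary_states,
)

__all__ = [
    "CosmologyModel",
    "cosmology_null_prob",
    "cosmology_max_prob",
    "StudentModel",
    "student_pass_prob",
    "student_actinfo",
    "student_fit",
    "FiniteMDP",
    "mdp_from_yaml",
    "mdp_trajectory_reward",
    "sample_trajectories",
    "mdp_actinfo_mc",
    "machine_specificity",
    "machine_proposal",
    "machine_null",
    "machine_family",
    "machine_kernel",
    "moran_fixation",
    "moran_acceptance",
]


# ---------------------------------------------------------------------------
# Example: cosmological fine-tuning (life-permitting interval)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosmologyModel:
    """Life-permitting interval (a, b) for a positive constant of nature.

    The null is exponential with mean xi (the max-ent law on R+ under a
    first-moment constraint).  ``epsilon`` is the relative half-width of the
    interval around its midpoint.
    """

    a: float
    b: float

    def __post_init__(self):
        if not 0 < self.a < self.b:
            raise ValueError("need 0 < a < b")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.a + self.b)

    @property
    def epsilon(self) -> float:
        return (self.b - self.a) / (2 * self.midpoint)


def cosmology_null_prob(model: CosmologyModel, xi: float) -> float:
    """P0xi(A) = e^{-a/xi} - e^{-b/xi}: exponential mass of the interval."""
    if xi <= 0:
        raise ValueError("xi must be positive")
    return float(np.exp(-model.a / xi) - np.exp(-model.b / xi))


def cosmology_max_prob(model: CosmologyModel) -> tuple[float, float]:
    """(P0max(A), xi*): the interval probability maximized over the mean.

    Stationarity of e^{-a/xi} - e^{-b/xi} gives the closed form
    xi* = (b - a)/log(b/a); for a narrow interval xi* ~ midpoint and
    P0max(A) ~ 2 eps e^{-1}.
    """
    xi_star = (model.b - model.a) / np.log(model.b / model.a)
    return cosmology_null_prob(model, xi_star), float(xi_star)


def cosmology_actinfo_bound(model: CosmologyModel) -> float:
    """One-sample actinfo bound Ihat+ = -log P0max(A) (observed universe in A)."""
    p0max, _ = cosmology_max_prob(model)
    return float(-np.log(p0max))


# ---------------------------------------------------------------------------
# Example: student learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudentModel:
    """Normal-regression model of test scores under study-time tuning.

    Covariates Z ~ N(m, Sigma); the score given z after studying t units is
    N(xi0 + xi.z + t (theta0 + theta.z), sigma2).  Unconditionally the score
    is N(mu, V) with mu and V in closed form; passing means score >= f0.
    The null corresponds to t = 0.
    """

    xi: np.ndarray        # (xi0, .., xi_{d-1})
    sigma2: float
    theta: np.ndarray     # (theta0, .., theta_{d-1})
    m: np.ndarray         # covariate means, length d-1
    Sigma: np.ndarray     # covariate covariance, (d-1)x(d-1)
    f0: float

    def __post_init__(self):
        object.__setattr__(self, "xi", np.atleast_1d(np.asarray(self.xi, float)))
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "m", np.atleast_1d(np.asarray(self.m, float)))
        object.__setattr__(self, "Sigma", np.atleast_2d(np.asarray(self.Sigma, float)))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.xi.shape != self.theta.shape:
            raise ValueError("xi and theta must have equal length")
        k = len(self.xi) - 1
        if self.m.shape != (k,) and k > 0:
            raise ValueError("covariate mean length mismatch")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")

    def mean_var(self, t: float) -> tuple[float, float]:
        """Unconditional (mu, V) of the score after study time t."""
        beta = self.xi + t * self.theta        # slopes incl. intercept
        b0, bz = beta[0], beta[1:]
        mu = b0 + float(bz @ self.m) if bz.size else b0
        V = self.sigma2 + (float(bz @ self.Sigma @ bz) if bz.size else 0.0)
        if V <= 0:
            raise ValueError("score variance nonpositive")
        return float(mu), float(V)


def student_pass_prob(model: StudentModel, t: float) -> float:
    """P(score >= f0) = 1 - Phi((f0 - mu)/sqrt(V)) after study time t."""
    mu, V = model.mean_var(t)
    return float(norm.sf((model.f0 - mu) / np.sqrt(V)))


def student_actinfo(model: StudentModel, t: float) -> float:
    """I+(theta, xi, t) = log[P_t(pass)/P_0(pass)]; zero at t = 0."""
    return active_info(student_pass_prob(model, t), student_pass_prob(model, 0.0))


def student_fit(
    t: np.ndarray, z: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit of the joint regression y = xi0 + xi.z + t(theta0 + theta.z).

    Returns (xi_hat incl. intercept, theta_hat incl. intercept, sigma2_hat).
    Requires variation in t (otherwise theta is unidentifiable) and a
    full-rank design (1, z, t, t*z).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[0] != t.shape[0]:
        z = z.T
    n, k = z.shape
    X = np.column_stack([np.ones(n), z, t, t[:, None] * z])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if np.ptp(t) == 0:
            raise ValueError("all study times equal: theta unidentifiable "
                             "(columns t and t*z collinear with 1 and z)")
        raise ValueError("design matrix (1, z, t, t*z) is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    xi_hat = np.concatenate([[coef[0]], coef[1:1 + k]])
    theta_hat = np.concatenate([[coef[1 + k]], coef[2 + k:]])
    return xi_hat, theta_hat, sigma2


# ---------------------------------------------------------------------------
# Example: reinforcement learning on a finite MDP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiniteMDP:
    """A finite MDP with per-action transition and reward matrices.

    ``transition[a][s, s']`` is P(s -> s' | action a) and
    ``reward[a][s, s']`` the instantaneous reward; trajectories run for
    ``horizon + 1`` transitions (actions at times 0..horizon) and rewards
    are discounted by gamma^u.  A trajectory is acceptable when its
    discounted total reward reaches f0.
    """

    transition: np.ndarray   # (q, m, m)
    reward: np.ndarray       # (q, m, m)
    gamma: float
    horizon: int
    f0: float
    start: np.ndarray | None = None   # initial environment law, default uniform

    def __post_init__(self):
        T = np.asarray(self.transition, float)
        R = np.asarray(self.reward, float)
        if T.ndim != 3 or T.shape[1] != T.shape[2] or R.shape != T.shape:
            raise ValueError("transition/reward must be (q, m, m) with equal shape")
        if np.any(np.abs(T.sum(axis=2) - 1) > 1e-10) or np.any(T < 0):
            raise ValueError("each P_a row must be a probability vector")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        start = self.start
        if start is None:
            start = np.full(T.shape[1], 1.0 / T.shape[1])
        start = np.asarray(start, float)
        object.__setattr__(self, "transition", T)
        object.__setattr__(self, "reward", R)
        object.__setattr__(self, "start", start)

    @property
    def n_actions(self) -> int:
        return self.transition.shape[0]

    @property
    def n_envs(self) -> int:
        return self.transition.shape[1]


def mdp_trajectory_reward(
    mdp: FiniteMDP, actions: Sequence[int], envs: Sequence[int]
) -> float:
    """f(x) = sum_u R_{a_u}(s_u, s_{u+1}) gamma^u for one trajectory."""
    actions = list(actions)
    envs = list(envs)
    if len(actions) != mdp.horizon + 1 or len(envs) != mdp.horizon + 2:
        raise ValueError("trajectory length must match the horizon")
    total = 0.0
    for u, a in enumerate(actions):
        if not 0 <= a < mdp.n_actions:
            raise ValueError(f"invalid action index {a}")
        if not (0 <= envs[u] < mdp.n_envs and 0 <= envs[u + 1] < mdp.n_envs):
            raise ValueError("invalid environment index")
        total += mdp.reward[a, envs[u], envs[u + 1]] * mdp.gamma**u
    return float(total)


def mdp_from_yaml(path) -> tuple[FiniteMDP, dict]:
    """Load a FiniteMDP (and any policies) from a YAML config.

    Expected keys: transition (list of per-action matrices), reward (same
    shape), gamma, horizon, f0, optional start, optional policies mapping
    names to either probability vectors or integer action maps.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    mdp = FiniteMDP(
        transition=np.asarray(cfg["transition"], float),
        reward=np.asarray(cfg["reward"], float),
        gamma=float(cfg["gamma"]),
        horizon=int(cfg["horizon"]),
        f0=float(cfg["f0"]),
        start=np.asarray(cfg["start"], float) if "start" in cfg else None,
    )
    policies = {name: np.asarray(p) for name, p in cfg.get("policies", {}).items()}
    return mdp, policies


def _policy_matrix(mdp: FiniteMDP, policy) -> np.ndarray:
    """Normalize a policy to an (m, q) action-probability matrix.

    Accepts a length-q probability vector (random policy, environment
    independent), a length-m integer map s -> a (deterministic), or a full
    (m, q) matrix.
    """
    pol = np.asarray(policy)
    m, q = mdp.n_envs, mdp.n_actions
    if pol.ndim == 1 and pol.shape[0] == q and np.issubdtype(pol.dtype, np.floating):
        if abs(pol.sum() - 1) > 1e-10 or np.any(pol < 0):
            raise ValueError("random policy must be a probability vector")
        return np.tile(pol, (m, 1))
    if pol.ndim == 1 and pol.shape[0] == m and np.issubdtype(pol.dtype, np.integer):
        out = np.zeros((m, q))
        out[np.arange(m), pol] = 1.0
        return out
    if pol.shape == (m, q):
        if np.any(np.abs(pol.sum(axis=1) - 1) > 1e-10):
            raise ValueError("policy rows must sum to 1")
        return np.asarray(pol, float)
    raise ValueError("unrecognized policy format")


def sample_trajectories(
    mdp: FiniteMDP, policy, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate n trajectories under a policy; returns discounted rewards."""
    pol = _policy_matrix(mdp, policy)
    rewards = np.zeros(n)
    s = rng.choice(mdp.n_envs, size=n, p=mdp.start)
    disc = 1.0
    for _ in range(mdp.horizon + 1):
        # vectorized: draw actions per current env, then next envs
        a = np.array([rng.choice(mdp.n_actions, p=pol[si]) for si in s])
        s_next = np.array(
            [rng.choice(mdp.n_envs, p=mdp.transition[ai, si]) for ai, si in zip(a, s)]
        )
        rewards += disc * mdp.reward[a, s, s_next]
        disc *= mdp.gamma
        s = s_next
    return rewards


def exact_acceptable_prob(mdp: FiniteMDP, policy) -> float:
    """P(f(X) >= f0) by exhaustive enumeration of all trajectories.

    Exponential in the horizon; intended as an oracle for small fixtures.
    """
    pol = _policy_matrix(mdp, policy)
    total = 0.0
    stack = [(s, mdp.start[s], 0.0) for s in range(mdp.n_envs) if mdp.start[s] > 0]
    for u in range(mdp.horizon + 1):
        nxt = []
        for s, p, r in stack:
            for a in range(mdp.n_actions):
                pa = pol[s, a]
                if pa == 0:
                    continue
                for s2 in range(mdp.n_envs):
                    pt = mdp.transition[a, s, s2]
                    if pt == 0:
                        continue
                    nxt.append((s2, p * pa * pt,
                                r + mdp.gamma**u * mdp.reward[a, s, s2]))
        stack = nxt
    for _, p, r in stack:
        if r >= mdp.f0:
            total += p
    return total


def mdp_actinfo_mc(
    mdp: FiniteMDP,
    policy_theta,
    policy_xi,
    n: int,
    n0: int,
    seed: int,
) -> EstimationResult:
    """Two-sample Monte-Carlo actinfo of a tuned vs an ignorant policy.

    Simulates n trajectories under the deterministic/tuned policy and n0
    under the random/null one; the nonparametric two-sample estimator gives
    Ihat+ = log(Qhat(A)/P0hat(A)) with binomial variance parts
    V1 + lambda V2 = (1-q)/q + (n/n0)(1-p0)/p0.
    """
    rng = np.random.default_rng(seed)
    r_theta = sample_trajectories(mdp, policy_theta, n, rng)
    r_xi = sample_trajectories(mdp, policy_xi, n0, rng)
    q_hat = float(np.mean(r_theta >= mdp.f0))
    p0_hat = float(np.mean(r_xi >= mdp.f0))
    if p0_hat == 0.0:
        i_hat = np.inf  # denominator sentinel: estimate is an upper-bound flag
        var = np.nan
    else:
        i_hat = empirical_actinfo(q_hat, p0_hat) if q_hat > 0 else -np.inf
        v1 = variance_np(q_hat) if 0 < q_hat < 1 else np.nan
        v2 = variance_np(p0_hat) if 0 < p0_hat < 1 else np.nan
        var = v1 + (n / n0) * v2
    return EstimationResult(i_hat=i_hat, q_hat_A=q_hat, variance=var, n=n,
                            mode="np")


# ---------------------------------------------------------------------------
# Example: molecular machines under Moran-type dynamics
# ---------------------------------------------------------------------------

def machine_specificity(d: int, a: float) -> SpecificityModel:
    """Machine specificity: f = a*|x| off the all-ones state, 1 there.

    ``a <= 1/d`` keeps the fully functional machine strictly most specified;
    negative ``a`` models a cost of carrying parts while the machine as a
    whole does not work.  With f0 = fmax = 1 the target is the single
    all-ones state.
    """
    if a > 1.0 / d:
        raise ValueError("need a <= 1/d so the working machine is most specified")
    ones = tuple([1] * d)

    def f(x):
        return 1.0 if x == ones else a * sum(x)

    return SpecificityModel(f=f, f0=1.0, x0=ones)


def machine_proposal(d: int, b: float) -> np.ndarray:
    """One-bit mutation kernel with beneficial/deleterious rate ratio b.

    From state x, flipping a 0 to 1 (beneficial) has weight b and flipping
    a 1 to 0 (deleterious) weight 1, normalized by |x| + b(d - |x|); only
    Hamming-distance-one moves occur.  Symmetric exactly when b = 1.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    states = binary_states(d)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    for i, x in enumerate(states):
        k = sum(x)
        denom = k + b * (d - k)
        for j in range(d):
            y = list(x)
            y[j] ^= 1
            q[i, idx[tuple(y)]] = (b if x[j] == 0 else 1.0) / denom
    return q


def machine_null(d: int, b: float) -> FiniteDistribution:
    """Null law P0: stationary distribution of the all-accept mutation chain.

    With b = 1 this is uniform 2^{-d}; smaller b makes many-parts states
    rarer, raising the functional information of the working machine.
    """
    return stationary_distribution(machine_proposal(d, b), binary_states(d))


def machine_family(d: int, a: float, b: float) -> TiltedFamily:
    """The tilted family of the machine model (base P0(b), specificity f(a))."""
    return TiltedFamily(machine_null(d, b), machine_specificity(d, a))


def machine_kernel(
    d: int, a: float, b: float, theta: float, flavor: str = "moran_sqrt"
) -> MHKernel:
    """The machine model's evolutionary kernel (Moran-type by default)."""
    return build_kernel(machine_null(d, b), machine_specificity(d, a), theta,
                        machine_proposal(d, b), flavor=flavor)


# ---------------------------------------------------------------------------
# Moran fixation probabilities
# ---------------------------------------------------------------------------

def moran_fixation(s: float, N: int) -> float:
    """Fixation probability beta_N(s) of one mutant with relative fitness s.

    beta_N(s) = (1 - 1/s)/(1 - s^{-N}) for s != 1, and 1/N at s = 1
    (continuous there).
    """
    if s <= 0:
        raise ValueError("fitness s must be positive")
    if N < 1:
        raise ValueError("population size N must be >= 1")
    if N == 1:
        return 1.0
    if s == 1.0:
        return 1.0 / N
    # stable form: (1 - e^{-u})/(1 - e^{-Nu}) with u = log s
    u = np.log(s)
    return float(np.expm1(-u) / np.expm1(-N * u))


def moran_acceptance(
    theta: float, f_x: float, f_y: float, N: int
) -> tuple[float, float]:
    """(exact, approximate) fixation probability of an x -> y mutation.

    With per-capita fitness e^{theta f/N}, the mutant's relative fitness is
    s = e^{theta (f_y - f_x)/N}; the exact value is beta_N(s) and the
    small-difference approximation is (1 + Delta/2)/N with
    Delta = theta (f_y - f_x).  The two agree as Delta -> 0.
    """
    delta = theta * (f_y - f_x)
    s = float(np.exp(delta / N))
    exact = moran_fixation(s, N)
    approx = (1.0 + delta / 2.0) / N
    return exact, approx
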