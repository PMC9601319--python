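"""Estimating active information and testing fine-tuning from i.i.d. draws.

Given n independent outcomes X_1..X_n ~ Q of a search algorithm, the
empirical active information is

    Ihat+ = log( Qhat(A) / P0(A) ),

where Qhat(A) is either the nonparametric hit fraction (requires only
membership in A) or the parametric plug-in P_{theta_hat}(A) at the tilting
maximum-likelihood estimate (requires the full specificity function f).
Fine-tuning is declared when Ihat+ >= Imin for a pre-specified threshold
Imin; under the null the rejection probability decays like e^{-Cn}, with the
large-deviation rate C given in closed form (nonparametric case: a Bernoulli
Kullback-Leibler divergence) or as a Legendre-Fenchel supremum (parametric
case).  When the null itself carries an unknown nuisance parameter xi, a
conservative one-sample bound (via the xi-maximized null probability, with a
nonpositive bias B) or a consistent two-sample estimator (with a second
sample from the null) is available.

Asymptotic variances follow the delta-method / M-estimation sandwich route:
for the parametric one-parameter case V = g'(theta*)^2 * U with
g'(theta) = Cov_Ptheta[f, 1{f>=f0}] / Ptheta(A) and
U = Var_Q[f] / Var_Ptheta*[f]^2.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm

from .tilting import (
    FiniteDistribution,
    SpecificityModel,
    TiltedFamily,
    active_info,
    log_normalizer,
    target_probability,
    tilt,
)

__all__ = [
    "SampleData",
    "FTTestConfig",
    "EstimationResult",
    "nonparametric_target_estimate",
    "empirical_actinfo",
    "mle_tilting",
    "parametric_target_estimate",
    "variance_np",
    "variance_param",
    "ld_rate_np",
    "ld_rate_np_legendre",
    "ld_rate_param",
    "ft_test",
    "bias_bound",
    "estimate_nonparametric",
    "estimate_parametric",
    "theta_for_target_prob",
    "two_sample_estimate",
    "variance_param_nuisance",
    "mle_nuisance",
]

#: tolerance for every 1-D root-finding / optimization problem here
ROOT_TOL = 1e-10
#: central finite-difference step for nuisance-score derivatives
FD_STEP = 1e-5


@dataclass(frozen=True)
class SampleData:
    """i.i.d. draws from the search algorithm, optionally with a null sample."""

    draws: tuple
    null_draws: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "draws", tuple(self.draws))
        if self.null_draws is not None:
            object.__setattr__(self, "null_draws", tuple(self.null_draws))
        if self.n < 1:
            raise ValueError("need at least one draw")

    @property
    def n(self) -> int:
        return len(self.draws)

    @property
    def n0(self) -> int:
        return len(self.null_draws) if self.null_draws is not None else 0

    @property
    def lambda_ratio(self) -> float:
        """n/n0 -- weights the null-estimation variance in the two-sample CLT."""
        if not self.null_draws:
            raise ValueError("no null sample present")
        return self.n / self.n0

    def validate_states(self, states: Sequence) -> None:
        space = set(states)
        for x in self.draws:
            if x not in space:
                raise ValueError(f"draw {x!r} outside the declared state space")
        for x in self.null_draws or ():
            if x not in space:
                raise ValueError(f"null draw {x!r} outside the declared state space")


@dataclass(frozen=True)
class FTTestConfig:
    """Fine-tuning test threshold: reject when Ihat+ >= i_min (inclusive).

    ``p_min = P0(A) e^{i_min}`` is the implied target-probability threshold;
    the test is only meaningful when p_min <= 1.
    """

    i_min: float

    def __post_init__(self):
        if self.i_min <= 0:
            raise ValueError("i_min must be positive")

    def p_min(self, p0_a: float) -> float:
        return p0_a * float(np.exp(self.i_min))


@dataclass(frozen=True)
class EstimationResult:
    """Empirical actinfo with its uncertainty and test decision."""

    i_hat: float
    q_hat_A: float
    variance: float
    n: int
    ld_rate: float | None = None
    reject: bool | None = None
    i_min: float | None = None
    bias_bound: float = 0.0
    theta_star: float | None = None
    xi_star: float | None = None
    boundary: bool = False
    mode: str = "np"

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald interval Ihat+ +/- z sqrt(V/n)."""
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(self.variance / self.n)
        return (self.i_hat - half, self.i_hat + half)

    def asymptotic_level_bound(self) -> float | None:
        """e^{-Cn}: the large-deviation bound on the type-I error."""
        if self.ld_rate is None:
            return None
        return float(np.exp(-self.ld_rate * self.n))


# ---------------------------------------------------------------------------
# nonparametric route
# ---------------------------------------------------------------------------

def nonparametric_target_estimate(sample: SampleData, spec: SpecificityModel) -> float:
    """Hit fraction Qhat(A) = #{X_i in A}/n (uses only membership in A)."""
    hits = sum(1 for x in sample.draws if spec.in_target(x))
    return hits / sample.n


def empirical_actinfo(q_hat_A: float, p0_A: float) -> float:
    """Ihat+ = log(Qhat(A)/P0(A)); -inf sentinel when no draw hit A."""
    return active_info(q_hat_A, p0_A)


def variance_np(q_A: float) -> float:
    """Asymptotic variance (1-Q(A))/Q(A) of the nonparametric Ihat+."""
    if not 0 < q_A < 1:
        raise ValueError("Q(A) must lie strictly in (0, 1)")
    return (1.0 - q_A) / q_A


def ld_rate_np(p0_A: float, p_min: float) -> float:
    """Bernoulli KL rate C = pmin log(pmin/p0) + (1-pmin) log((1-pmin)/(1-p0)).

    Governs the exponential decay e^{-Cn} of the type-I error of the
    nonparametric fine-tuning test with threshold pmin = P0(A) e^{Imin}.
    """
    if not 0 < p0_A < 1:
        raise ValueError("P0(A) must lie in (0, 1)")
    if p_min <= p0_A:
        warnings.warn("p_min <= P0(A): test threshold below the null, rate 0",
                      stacklevel=2)
        return 0.0
    if p_min > 1:
        raise ValueError("p_min must not exceed 1")
    out = p_min * np.log(p_min / p0_A)
    if p_min < 1:
        out += (1 - p_min) * np.log((1 - p_min) / (1 - p0_A))
    return float(out)


def ld_rate_np_legendre(p0_A: float, p_min: float) -> float:
    """Same rate via the Legendre-Fenchel sup over the Bernoulli cumulant.

    C = sup_{phi>0} [phi*pmin - log(1 + p0(e^phi - 1))]; kept as the
    independent numerical route against the closed form.
    """
    if p_min <= p0_A:
        return 0.0

    def neg_obj(phi: float) -> float:
        return -(phi * p_min - np.log1p(p0_A * np.expm1(phi)))

    res = minimize_scalar(neg_obj, bounds=(0.0, 700.0), method="bounded",
                          options={"xatol": 1e-12})
    # the sup has the closed-form stationary point phi* = log odds ratio;
    # polish with it when interior
    if p_min < 1:
        phi_star = np.log(p_min * (1 - p0_A) / (p0_A * (1 - p_min)))
        return float(max(-res.fun, -neg_obj(phi_star)))
    return float(-res.fun)


# ---------------------------------------------------------------------------
# parametric route (scalar tilting parameter)
# ---------------------------------------------------------------------------

def _mean_f_minus(family: TiltedFamily, target: float) -> Callable[[float], float]:
    return lambda th: family.mean_f(th) - target


def mle_tilting(sample: SampleData, family: TiltedFamily) -> float:
    """MLE theta_hat = argmax_{theta>=0} sum_i log P_theta(X_i).

    The score f(x) - E_Ptheta[f] makes the MLE the root of
    E_Ptheta[f] = mean(f(X_i)); E_Ptheta[f] is strictly increasing in theta,
    so a geometric bracket plus Brent's method suffices.  A sample mean at
    or below E_P0[f] gives the boundary estimate 0; a sample mean at fmax
    (attained) diverges and returns +inf with a warning.
    """
    f_vals = np.array([family.spec.value(x) for x in sample.draws])
    return mle_tilting_from_mean(float(f_vals.mean()), family)


def mle_tilting_from_mean(fbar: float, family: TiltedFamily) -> float:
    """Tilting MLE given the sufficient statistic mean(f); see mle_tilting."""
    fv = family.f_values
    if np.ptp(fv[np.isfinite(family.base.log_probs)]) == 0:
        raise ValueError("f constant on the support of P0: theta unidentifiable")
    fmax = float(fv[np.isfinite(family.base.log_probs)].max())
    if fbar >= fmax:
        warnings.warn("sample mean of f at or above fmax: theta_hat diverges",
                      stacklevel=2)
        return np.inf
    if fbar <= family.mean_f(0.0):
        return 0.0  # boundary of theta >= 0
    score = _mean_f_minus(family, fbar)
    hi = 1.0
    while score(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # mean_f -> fmax; numerically saturated
            warnings.warn("tilting MLE beyond 1e8: returning +inf", stacklevel=2)
            return np.inf
    return float(brentq(score, 0.0, hi, xtol=ROOT_TOL))


def parametric_target_estimate(
    family: TiltedFamily, theta_hat: float, spec: SpecificityModel | None = None
) -> float:
    """Plug-in Qhat(A) = P_{theta_hat}(A) (needs the full f, not just A)."""
    spec = spec or family.spec
    if np.isinf(theta_hat):
        # the limit distribution sits on the argmax set of f
        fv = family.f_values
        finite = np.isfinite(family.base.log_probs)
        argmax = finite & (fv >= fv[finite].max() - 0.0)
        if bool(np.all(spec.target_mask(family.base.states)[argmax])):
            return 1.0
        raise ValueError("theta_hat infinite but argmax(f) not inside A")
    return target_probability(tilt(family, theta_hat), spec)


def variance_param(
    family: TiltedFamily,
    theta_star: float,
    q_dist: FiniteDistribution | None = None,
    spec: SpecificityModel | None = None,
) -> float:
    """Delta-method variance of the parametric Ihat+ at pseudo-true theta*.

    V = Cov_Ptheta*[f, 1{f>=f0}]^2 Var_Q[f] / (Ptheta*(A)^2 Var_Ptheta*[f]^2);
    ``q_dist`` is the true data-generating law (defaults to P_theta*, the
    correctly-specified case).
    """
    spec = spec or family.spec
    p_star = tilt(family, theta_star)
    fv = family.f_values
    if np.allclose(fv, fv[0]):
        raise ValueError("degenerate (constant) specificity function")
    w = p_star.probs
    mask = spec.target_mask(family.base.states).astype(float)
    mean_f = float(np.sum(w * fv))
    p_a = float(np.sum(w * mask))
    cov = float(np.sum(w * (fv - mean_f) * (mask - p_a)))
    var_star = float(np.sum(w * (fv - mean_f) ** 2))
    if var_star <= 0:
        raise ValueError("Var_Ptheta*[f] = 0: degenerate family")
    if q_dist is None:
        var_q = var_star
    else:
        qw = q_dist.probs
        mq = float(np.sum(qw * fv))
        var_q = float(np.sum(qw * (fv - mq) ** 2))
    return (cov**2) * var_q / (p_a**2 * var_star**2)


def theta_for_target_prob(family: TiltedFamily, p: float,
                          spec: SpecificityModel | None = None) -> float:
    """Solve P_theta(A) = p for theta >= 0 (unique by monotonicity)."""
    spec = spec or family.spec
    p0_a = target_probability(family.base, spec)
    if not p0_a < p < 1:
        raise ValueError("p must lie strictly between P0(A) and 1")

    def g(th: float) -> float:
        return target_probability(tilt(family, th), spec) - p

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("p outside the attainable range of theta -> P_theta(A)")
    return float(brentq(g, 0.0, hi, xtol=ROOT_TOL))


def ld_rate_param(
    family: TiltedFamily, p_min: float, spec: SpecificityModel | None = None,
    return_maximizer: bool = False,
):
    """Parametric LD rate C = sup_{phi>0} [phi E_Pmin[f] - log M(phi)].

    P_min = P_thetamin with thetamin solving P_theta(A) = p_min.  The
    objective is strictly concave (its second derivative is -Var_Pphi[f]),
    and its stationary point E_Pphi[f] = E_Pmin[f] is phi = thetamin; the
    implementation refines the stationarity root and verifies it against
    the value at thetamin rather than assuming the identity.
    """
    spec = spec or family.spec
    theta_min = theta_for_target_prob(family, p_min, spec)
    mu_min = family.mean_f(theta_min)

    def objective(phi: float) -> float:
        return phi * mu_min - log_normalizer(family, phi)

    # stationarity: E_Pphi[f] = mu_min; same monotone root problem
    score = _mean_f_minus(family, mu_min)
    hi = max(1.0, 2 * theta_min)
    while score(hi) < 0 and hi < 1e8:
        hi *= 2.0
    phi_star = float(brentq(score, 0.0, hi, xtol=ROOT_TOL)) if score(hi) >= 0 else hi
    best_phi = phi_star if objective(phi_star) >= objective(theta_min) else theta_min
    C = float(objective(best_phi))
    if return_maximizer:
        return C, best_phi, theta_min
    return C


# ---------------------------------------------------------------------------
# testing and nuisance parameters
# ---------------------------------------------------------------------------

def ft_test(result: EstimationResult, config: FTTestConfig) -> EstimationResult:
    """Reject fine-tuning's null when Ihat+ >= Imin (inclusive >=)."""
    reject = bool(result.i_hat >= config.i_min)
    return EstimationResult(
        i_hat=result.i_hat, q_hat_A=result.q_hat_A, variance=result.variance,
        n=result.n, ld_rate=result.ld_rate, reject=reject, i_min=config.i_min,
        bias_bound=result.bias_bound, theta_star=result.theta_star,
        xi_star=result.xi_star, boundary=result.boundary, mode=result.mode,
    )


def bias_bound(p0_xi_A: float, p0_max_A: float) -> float:
    """One-sample bias B = log(P0xi(A)/P0max(A)) <= 0.

    Using the xi-maximized null probability in the denominator makes the
    one-sample estimator a conservative lower bound; the LD rate then uses
    pmin e^{-B} in place of pmin, which enlarges it.
    """
    if not 0 < p0_xi_A:
        raise ValueError("P0xi(A) must be positive")
    if p0_xi_A > p0_max_A * (1 + 1e-12):
        raise ValueError("P0xi(A) exceeds P0max(A): contradicts maximality")
    return float(min(0.0, np.log(p0_xi_A / p0_max_A)))


def _result_np(q_hat: float, p0_A: float, n: int,
               config: FTTestConfig | None) -> EstimationResult:
    i_hat = empirical_actinfo(q_hat, p0_A) if q_hat > 0 else -np.inf
    var = variance_np(q_hat) if 0 < q_hat < 1 else np.nan
    rate = reject = i_min = None
    if config is not None:
        p_min = config.p_min(p0_A)
        rate = ld_rate_np(p0_A, min(p_min, 1.0)) if p_min <= 1 else np.inf
        reject = bool(np.isfinite(i_hat) and i_hat >= config.i_min)
        i_min = config.i_min
    return EstimationResult(i_hat=i_hat, q_hat_A=q_hat, variance=var, n=n,
                            ld_rate=rate, reject=reject, i_min=i_min, mode="np")


def estimate_nonparametric(
    sample: SampleData,
    spec: SpecificityModel,
    p0_A: float,
    config: FTTestConfig | None = None,
) -> EstimationResult:
    """Nonparametric empirical actinfo with known null target probability."""
    q_hat = nonparametric_target_estimate(sample, spec)
    return _result_np(q_hat, p0_A, sample.n, config)


def estimate_parametric(
    sample: SampleData,
    family: TiltedFamily,
    config: FTTestConfig | None = None,
) -> EstimationResult:
    """Parametric empirical actinfo via the tilting MLE, null known."""
    spec = family.spec
    p0_A = target_probability(family.base, spec)
    theta_hat = mle_tilting(sample, family)
    q_hat = parametric_target_estimate(family, theta_hat, spec)
    i_hat = empirical_actinfo(q_hat, p0_A)
    boundary = theta_hat == 0.0 or np.isinf(theta_hat)
    var = np.nan
    if not boundary:
        var = variance_param(family, theta_hat)
    rate = reject = i_min = None
    if config is not None:
        p_min = config.p_min(p0_A)
        if p_min < 1:
            rate = ld_rate_param(family, p_min, spec)
        reject = bool(i_hat >= config.i_min)
        i_min = config.i_min
    return EstimationResult(i_hat=i_hat, q_hat_A=q_hat, variance=var,
                            n=sample.n, ld_rate=rate, reject=reject,
                            i_min=i_min, theta_star=theta_hat,
                            boundary=boundary, mode="param")


# ---------------------------------------------------------------------------
# two samples / nuisance null
# ---------------------------------------------------------------------------

def mle_nuisance(
    draws: Sequence,
    null_builder: Callable[[float], FiniteDistribution],
    bracket: tuple[float, float],
) -> float:
    """MLE of a scalar nuisance parameter xi of the null family.

    ``null_builder(xi)`` returns P0xi over a fixed state space; the log
    likelihood is maximized over the ``bracket`` by bounded 1-D search.
    """
    lo, hi = bracket
    ref = null_builder(0.5 * (lo + hi))
    idx = {s: i for i, s in enumerate(ref.states)}
    counts = np.zeros(len(ref.states))
    for x in draws:
        counts[idx[x]] += 1

    def negll(xi: float) -> float:
        lp = null_builder(xi).log_probs
        if np.any(np.isneginf(lp[counts > 0])):
            return np.inf
        return -float(np.sum(counts * lp))

    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x)


def _nuisance_score(
    null_builder: Callable[[float], FiniteDistribution], xi: float
) -> np.ndarray:
    """psi_xi(x) = d log P0xi(x)/dxi by central differences (step FD_STEP)."""
    h = FD_STEP * max(1.0, abs(xi))
    lo, hi = null_builder(xi - h), null_builder(xi + h)
    return (hi.log_probs - lo.log_probs) / (2 * h)


def nuisance_variance_v2(
    null_builder: Callable[[float], FiniteDistribution],
    xi: float,
    spec: SpecificityModel,
) -> float:
    """V2 = E[psi|X in A] I(xi)^{-1} E[psi|X in A] for a scalar nuisance.

    Expectations are exact sums over the finite state space under P0xi;
    I(xi) = E[psi^2] is the Fisher information.
    """
    p0 = null_builder(xi)
    psi = _nuisance_score(null_builder, xi)
    w = p0.probs
    mask = spec.target_mask(p0.states)
    p_a = float(np.sum(w[mask]))
    if p_a == 0:
        raise ValueError("P0xi(A) = 0")
    cond = float(np.sum(w[mask] * psi[mask])) / p_a
    fisher = float(np.sum(w * psi**2))
    if fisher <= 0:
        raise ValueError("xi not identifiable: zero Fisher information")
    return cond**2 / fisher


def two_sample_estimate(
    sample: SampleData,
    null_builder: Callable[[float], FiniteDistribution],
    spec: SpecificityModel,
    bracket: tuple[float, float],
    mode: str = "np",
    config: FTTestConfig | None = None,
) -> EstimationResult:
    """Consistent two-sample actinfo estimate with an estimated null.

    The null nuisance xi is fitted by MLE on the null sample; Ihat+ =
    log(Qhat(A)/P0_{xihat}(A)).  The CLT variance is V1 + lambda V2 with
    lambda = n/n0: V1 from the tuned-sample route (nonparametric hit
    fraction or parametric tilting MLE on base P0_{xihat}), V2 the
    delta-method contribution of xihat.
    """
    if not sample.null_draws:
        raise ValueError("two-sample estimation requires a null sample")
    xi_hat = mle_nuisance(sample.null_draws, null_builder, bracket)
    p0_hat = null_builder(xi_hat)
    p0_A = target_probability(p0_hat, spec)
    lam = sample.lambda_ratio
    v2 = nuisance_variance_v2(null_builder, xi_hat, spec)

    if mode == "np":
        q_hat = nonparametric_target_estimate(sample, spec)
        v1 = variance_np(q_hat) if 0 < q_hat < 1 else np.nan
        theta_hat = None
        boundary = False
    elif mode == "param":
        family = TiltedFamily(p0_hat, spec)
        theta_hat = mle_tilting(sample, family)
        q_hat = parametric_target_estimate(family, theta_hat, spec)
        boundary = theta_hat == 0.0 or np.isinf(theta_hat)
        v1 = np.nan if boundary else variance_param(family, theta_hat)
    else:
        raise ValueError("mode must be 'np' or 'param'")

    i_hat = empirical_actinfo(q_hat, p0_A) if q_hat > 0 else -np.inf
    var = v1 + lam * v2 if np.isfinite(v1) else np.nan
    rate = reject = i_min = None
    if config is not None:
        p_min = config.p_min(p0_A)
        if p_min < 1:
            # two-sample rates carry B = 0 (the nuisance is consistently estimated)
            rate = ld_rate_np(p0_A, p_min) if mode == "np" else ld_rate_param(
                TiltedFamily(p0_hat, spec), p_min, spec)
        reject = bool(np.isfinite(i_hat) and i_hat >= config.i_min)
        i_min = config.i_min
    return EstimationResult(i_hat=i_hat, q_hat_A=q_hat, variance=var,
                            n=sample.n, ld_rate=rate, reject=reject,
                            i_min=i_min, theta_star=theta_hat, xi_star=xi_hat,
                            boundary=False if mode == "np" else boundary,
                            mode=mode)


def variance_param_nuisance(
    builder: Callable[[float, float], FiniteDistribution],
    theta_star: float,
    xi_star: float,
    spec: SpecificityModel,
    q_dist: FiniteDistribution | None = None,
) -> float:
    """Sandwich variance of the parametric Ihat+ with a scalar nuisance.

    ``builder(theta, xi)`` returns P_{theta,xi} over a fixed state space.
    V = g' AsVar(theta_hat, xi_hat) g'^T with g'(theta,xi) =
    E[psi_{theta,xi}(X) | X in A] and the M-estimator sandwich
    AsVar = E[psi']^{-1} E[psi^T psi] E[psi'^T]^{-1}; scores and their
    derivatives come from central finite differences (step FD_STEP), and
    expectations are exact sums under ``q_dist`` (default P_{theta*,xi*}).
    """
    p_star = builder(theta_star, xi_star)
    states = p_star.states
    q = q_dist if q_dist is not None else p_star
    if q.states != states:
        raise ValueError("q_dist must share the builder's state space")

    def log_p(th: float, xi: float) -> np.ndarray:
        return builder(th, xi).log_probs

    h_t = FD_STEP * max(1.0, abs(theta_star))
    h_x = FD_STEP * max(1.0, abs(xi_star))
    # score components psi = (d/dtheta, d/dxi) log P
    psi_t = (log_p(theta_star + h_t, xi_star) - log_p(theta_star - h_t, xi_star)) / (2 * h_t)
    psi_x = (log_p(theta_star, xi_star + h_x) - log_p(theta_star, xi_star - h_x)) / (2 * h_x)
    psi = np.stack([psi_t, psi_x], axis=1)  # (n_states, 2)

    # derivative of the score (expected Hessian of log P) by differencing psi
    def psi_at(th: float, xi: float) -> np.ndarray:
        pt = (log_p(th + h_t, xi) - log_p(th - h_t, xi)) / (2 * h_t)
        px = (log_p(th, xi + h_x) - log_p(th, xi - h_x)) / (2 * h_x)
        return np.stack([pt, px], axis=1)

    dpsi_dt = (psi_at(theta_star + h_t, xi_star) - psi_at(theta_star - h_t, xi_star)) / (2 * h_t)
    dpsi_dx = (psi_at(theta_star, xi_star + h_x) - psi_at(theta_star, xi_star - h_x)) / (2 * h_x)

    w = q.probs
    # a parameter whose score vanishes identically is effectively known:
    # reduce to the active block instead of inverting a singular Hessian
    active = np.array([np.max(np.abs(psi[:, j])) > 1e-12 for j in range(2)])
    if not active.any():
        raise ValueError("both score components vanish: no free parameters")
    psi = psi[:, active]
    E_dpsi = np.column_stack([dpsi_dt.T @ w, dpsi_dx.T @ w])[np.ix_(active, active)]
    E_outer = (psi * w[:, None]).T @ psi
    if psi.shape[1] == 2:
        # collinear scores mean (theta, xi) is not jointly identifiable and
        # the expected Hessian is singular up to finite-difference noise
        sd = np.sqrt(np.sum(w[:, None] * psi**2, axis=0))
        corr = float(np.sum(w * psi[:, 0] * psi[:, 1]) / (sd[0] * sd[1]))
        if abs(corr) > 1 - 1e-8:
            raise ValueError(
                "singular expected-Hessian matrix: the tuning and nuisance "
                "scores are collinear, parameters not jointly identifiable")
    inv = np.linalg.inv(E_dpsi)
    asvar = inv @ E_outer @ inv.T
    asvar = 0.5 * (asvar + asvar.T)  # symmetrize fp noise

    mask = spec.target_mask(states)
    p_w = p_star.probs
    p_a = float(np.sum(p_w[mask]))
    if p_a == 0:
        raise ValueError("P_{theta*,xi*}(A) = 0")
    gprime = (psi[mask] * p_w[mask, None]).sum(axis=0) / p_a
    v = float(gprime @ asvar @ gprime)
    return max(v, 0.0)
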