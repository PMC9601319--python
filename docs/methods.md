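# Methods

## Model and quantities

All information quantities are in nats (the CLI offers a bits conversion
for display only).  A problem instance consists of a finite state space Ω
with a fixed enumeration order (binary-string spaces are enumerated
lexicographically as tuples over {0,1}; the order is serialized with every
distribution, since all matrix algebra depends on it), a null distribution
P₀, a specificity function f and a threshold f₀.  The target is
A = {x : f(x) ≥ f₀}; ties at the threshold are inside A.  Active
information is I⁺ = log P(A)/P₀(A) and functional information
I_f₀ = −log P₀(A).

The informed-search family is the exponential tilt
P_θ(x) = e^{θf(x)} P₀(x)/M(θ).  Because {P_θ} is an exponential family,
E_{P_θ}[f] = M′(θ)/M(θ) is strictly increasing in θ (its derivative is
Var_{P_θ}[f]), which the estimators exploit throughout: the tilting MLE is
the root of the moment equation E_{P_θ}[f] = mean of f over the sample,
and P_θ(A) is strictly increasing in θ, so inverse problems such as
"find θ with P_θ(A) = p" have unique, bracketable roots.

## Markov dynamics

Two acceptance rules build a reversible chain with equilibrium P_θ over a
proposal kernel q:

* `mh` — α(x,y) = min{1, ratio} with
  ratio = e^{θf(y)}P₀(y)q(y,x) / (e^{θf(x)}P₀(x)q(x,y));
* `moran_sqrt` — α(x,y) = C·ratio^{1/2} with C chosen so the largest
  acceptance over ordered pairs with two-sided proposal support equals 1.
  Pairs with one-sided support (q(x,y) > 0 but q(y,x) = 0) make the
  builder fail loudly: the scaling constant is undefined for them.

Both satisfy detailed balance with respect to P_θ to ~1e−15 in practice
(the test suite requires < 1e−12).  Proposals may carry self-mass
q(x,x) > 0; the rejection probability is computed as one minus the
accepted off-diagonal flow and added to the diagonal.

Non-equilibrium actinfo I⁺(θ,t) applies the kernel t times to P₀ (one
step = one kernel application; the correspondence "one Moran-type step ≈
C/μ generations" is exposed as the documented helper
`mh_steps_to_moran_generations`, never baked into a computation).
Monotonicity of I⁺(θ,t) in t is plausible but not guaranteed in general,
so the trajectory reports the sequence without asserting it.  Equilibrium
detection uses total-variation distance between consecutive iterates
below 1e−12 with a hard cap of 10⁶ iterations; for periodic chains a
Cesàro average of the final iterates is returned with an honest
`converged=False` flag.

The stopped search clumps A into one absorbing state.  With Q_na the
transient block, P(T ≤ t) = 1 − P₀|_{Ac} Q_naᵗ 1, the stopped actinfo is
I_s⁺(θ,t) = log[P(T ≤ t)/P₀(A)] (non-decreasing, dominating I⁺(θ,t),
converging to I_f₀), and E(T) comes from the fundamental matrix
(I − Q_na)^{-1}.  `stationary_distribution` solves the singular balance
system directly with one equation replaced by the normalization row —
deterministic and exact to solver tolerance, in preference to power
iteration.

## Estimation and testing

Nonparametric: Q̂(A) is the hit fraction (needs only membership in A);
asymptotic variance of Î⁺ is (1−Q(A))/Q(A).  Parametric: Q̂(A) = P_θ̂(A)
at the tilting MLE (needs all of f); the delta-method variance is
V = g′(θ*)²·U with g′(θ) = Cov_{P_θ}[f, 1{f≥f₀}]/P_θ(A) and
U = Var_Q[f]/Var_{P_θ*}[f]².  With an indicator specificity and correct
specification the two variances — and the two large-deviation rates —
coincide, which the suite checks to 1e−9.

The fine-tuning test rejects when Î⁺ ≥ I_min (inclusive), with I_min a
required user input — no default significance threshold is imposed.  Its
type-I error decays like e^{−Cn}: nonparametrically C is the Bernoulli
KL divergence between p_min = P₀(A)e^{I_min} and P₀(A) (verified to
1e−10 against a numerical Legendre–Fenchel supremum of the Bernoulli
cumulant); parametrically C = sup_φ [φ·E_{P_min}[f] − log M(φ)] where
P_min = P_{θ_min} solves P_θ(A) = p_min.  The supremum's stationary point
is θ_min itself; the implementation refines the stationarity root and
cross-checks it against the value at θ_min rather than assuming the
identity.

A hit fraction of zero yields a −∞ sentinel with a warning (and never a
rejection); no continuity correction is applied.  The MLE of θ is clamped
to the boundary 0 when the sample mean of f falls below the null mean,
and results are flagged `boundary=True` there since the CLT variance
formulas assume an interior optimum; a sample mean at the attained
maximum of f returns a +∞ sentinel.

Unknown null nuisance ξ: with one sample, Î⁺ = log Q̂(A)/P₀^max(A) using
the ξ-maximized null probability, a conservative lower bound whose bias
B = log P₀ξ(A)/P₀^max(A) ≤ 0 enlarges the LD rate (p_min e^{−B} replaces
p_min).  With a second, null sample, ξ is estimated by maximum likelihood
and the estimator is consistent; the CLT variance is V₁ + λV₂ with
λ = n/n₀ and V₂ = E[ψ_ξ|X∈A]² / I(ξ) for a scalar nuisance (Fisher
information I(ξ), score ψ_ξ by central finite differences with step 1e−5
on log-probabilities).  The joint (θ, ξ) sandwich variance uses the same
finite-difference scores with exact enumeration of all expectations over
the finite state space; collinear score components (e.g. the machine
model at a = 0.2, d = 5, where f is exactly linear in |x| so tilting and
mutation-bias directions coincide) are detected by score correlation and
raise, since the parameters are not jointly identifiable there.  A
component whose score vanishes identically is treated as known (block
reduction).

All 1-D root-finding and maximization uses bracketing grown geometrically
from [0, 1] plus Brent refinement at tolerance 1e−10; every objective
involved is monotone or strictly concave by exponential-family structure.

## Worked models

* **Cosmology** — P₀ξ(A) = e^{−a/ξ} − e^{−b/ξ} for a life-permitting
  interval (a, b) under an exponential null with mean ξ.  The maximizer
  has the closed form ξ* = (b−a)/log(b/a) (stationarity of the interval
  mass), used instead of a numeric search; a grid search backs it in the
  tests.  For narrow intervals P₀^max(A) ≈ 2εe^{−1} with ε the relative
  half-width.
* **Student learning** — scores are normal with mean and variance linear
  resp. quadratic in the study-time-shifted regression slopes; the pass
  probability is a normal tail.  `student_fit` is ordinary least squares
  on the design (1, z, t, t·z) and requires variation in t, otherwise the
  tuning slopes are unidentifiable (a named error).
* **Finite MDP** — the specificity of a trajectory is its discounted
  total reward; actinfo of a tuned vs a random policy is estimated by
  two-sample Monte Carlo with binomial variance parts, against an
  exhaustive-enumeration oracle on a shipped 2-environment, 2-action
  fixture (the enumeration is exponential in the horizon and intended
  only for small fixtures).
* **Molecular machine** — states {0,1}^d, f(x) = a|x| except f = 1 at the
  all-ones state, with a ≤ 1/d enforced and a < 0 allowed (carrying
  nonfunctional parts is costly).  The proposal flips one bit, weight b
  for 0→1 and 1 for 1→0, normalized by |x| + b(d−|x|).  The null is the
  stationary law of the all-accept chain: uniform at b = 1, and at d = 1
  the normalization absorbs b entirely so the null is uniform for every b.
  The Moran fixation probability β_N(s) = (1−s^{−1})/(1−s^{−N}) is
  evaluated in the numerically stable expm1 form and matches the
  (1 + Δ/2)/N small-difference approximation to < 1e−4 at Δ = 0.01,
  N = 100.

The qualitative ordering "equilibrium actinfo decreases in b" holds over
the moderate-θ range where the curves are usually displayed but is not
pointwise at very small θ for a = −0.2; the property tests check it on
θ ∈ {2, 4, 8}.

## Synthetic data

Samplers are pure functions of (inputs, seed): i.i.d. draws use
inverse-CDF over the enumeration order, chain runs simulate each replicate
independently and can freeze on first entry to A.  The significance-decay
experiment computes the exact binomial tail (the hit count is Binomial
under the null) rather than sampling; a Monte-Carlo column is optional
and rows with zero observed rejections are flagged, not failed.  What the
generators emulate is exactly the i.i.d./Markov sampling the estimators
assume; they do not model real-data features such as dependence between
runs, misspecified state spaces, or measurement error in f — passing
tests certify the estimators under their stated assumptions, not
robustness beyond them.

## Problem sizes and test design

The test suite uses the d = 5 machine (32 states) throughout, 200
replicates of n = 10⁴ for tilting-MLE recovery, 10⁴ replicates of
n = 5000 for the variance-formula checks, 300 replicates of
n = n₀ = 5000 for two-sample coverage, and stopped-chain horizons up to
t = 2·10⁴ (the slowest configuration, a = −0.2, b = 0.5, has transient
spectral radius ≈ 0.99913, so reaching P(T > t) < 10⁻⁶ needs
t ≈ 1.6·10⁴).  These sizes keep every Monte-Carlo band at or below the
tolerances asserted while running the whole suite in about two minutes.

## Limitations

Continuous state spaces are supported only through the two closed-form
models (cosmology, student); there is no generic numerical-integration
layer.  Dense matrices limit kernels to roughly 2^14 states.  The
evolutionary-programming population model (N individuals tracked
separately) is out of scope; under the small-mutation fixed-state
assumption it reduces to the machine model implemented here.  Rarity-
weighted specificities, functional sequence complexity and active
uncertainty reduction are not implemented.
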