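import numpy as np
import pytest

from actinfo import (
    FiniteDistribution,
    SpecificityModel,
    TiltedFamily,
    machine_family,
    machine_kernel,
    machine_null,
    machine_proposal,
    machine_specificity,
)


@pytest.fixture
def two_point_family():
    """Omega = {0, 1}, uniform base, f(x) = x: the simplest tilted family."""
    base = FiniteDistribution.uniform((0, 1))
    spec = SpecificityModel(f=lambda x: float(x), f0=1.0)
    return TiltedFamily(base, spec)


@pytest.fixture(scope="session")
def machine5():
    """The d=5 molecular-machine model at a=0.2, b=1 (uniform null)."""
    d, a, b = 5, 0.2, 1.0
    return {
        "d": d, "a": a, "b": b,
        "null": machine_null(d, b),
        "spec": machine_specificity(d, a),
        "family": machine_family(d, a, b),
        "proposal": machine_proposal(d, b),
    }


def random_instance(rng, n_max=64):
    """A random small state space with random P0 and f s.t. 0 < P0(A) < 1."""
    n = rng.integers(3, n_max + 1)
    p = rng.dirichlet(np.ones(n))
    f = rng.normal(size=n)
    states = tuple(range(n))
    base = FiniteDistribution.from_probs(states, p)
    # threshold at a quantile that leaves both A and Ac nonempty
    f0 = float(np.sort(f)[n // 2])
    spec = SpecificityModel(f=dict(zip(states, f)), f0=f0)
    return TiltedFamily(base, spec)


def random_proposal(rng, n, symmetric=False, self_mass=False):
    """A random dense strictly-positive proposal matrix (irreducible)."""
    w = rng.random((n, n)) + 0.05
    if symmetric:
        w = 0.5 * (w + w.T)
    if not self_mass:
        np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)
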