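"""Shared fixtures and the brute-force likelihood oracle.

The oracle sums the probability of an encounter history over every
hidden-state path explicitly — exponential in the number of occasions,
independent of the forward algorithm it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from trapaware.model_core import ModelSpec, ParameterSet, build_bundle


def brute_force_history_likelihood(codes, params, spec, *, removed=False) -> float:
    """Path-enumeration likelihood of one history, conditional on release."""
    codes = np.asarray(codes, dtype=int)
    K = spec.n_occasions
    nz = np.flatnonzero(codes)
    f = int(nz[0]) + 1
    stop = int(nz[-1]) + 1 if removed else K
    n_s = spec.n_states
    if spec.state_space == "single":
        init = 0
        emit = {0: 1, 1: 0, 2: 0}          # state index -> code
    else:
        init = 0 if codes[f - 1] == 1 else 2
        emit = {0: 1, 1: 0, 2: 2, 3: 0, 4: 0}
    bundles = {t: build_bundle(params, t, spec, first_interval=(t == f))
               for t in range(f, stop)}
    total = 0.0
    for path in itertools.product(range(n_s), repeat=stop - f):
        prob = 1.0
        prev = init
        for step, s in enumerate(path):
            t = f + step
            prob *= bundles[t].Pi[prev, s]
            if prob == 0.0:
                break
            if emit[s] != codes[t]:
                prob = 0.0
                break
            prev = s
        total += prob
    return total


def random_single_params(rng, K, *, transience=True, time_varying=False):
    """Draw a valid random single-state parameter set away from boundaries."""
    def draw(size=None):
        return rng.uniform(0.05, 0.95, size=size)
    shape = (K - 1,) if time_varying else None
    return ParameterSet(
        phi=draw(shape),
        phi1=draw(shape) if transience else None,
        p=draw(shape),
        p_prime=draw(shape),
    )


def random_two_state_params(rng, K, *, time_varying=False):
    def draw(size=None):
        return rng.uniform(0.05, 0.95, size=size)
    shape = (K - 1,) if time_varying else None
    return ParameterSet(
        phi=(draw(shape), draw(shape)),
        p=(draw(shape), draw(shape)),
        p_prime=(draw(shape), draw(shape)),
        psi12=float(draw()),
        psi21=float(draw()),
        pi1=float(draw()),
    )


def all_single_patterns(K, release=1):
    """Every observable single-state pattern for a release at ``release``."""
    pats = []
    for tail in itertools.product((0, 1), repeat=K - release):
        pattern = [0] * K
        pattern[release - 1] = 1
        pattern[release:] = tail
        pats.append(tuple(pattern))
    return pats


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def trap_happy_data():
    """Moderate simulated dataset with a strong trap-happy response."""
    from trapaware.simulator import SimulationScenario, simulate

    scn = SimulationScenario(
        n_occasions=8, n_released_per_cohort=80,
        params=ParameterSet(phi=0.85, phi1=0.6, p=0.4, p_prime=0.7), seed=42,
    )
    data, _ = simulate(scn)
    return data
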