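"""Simulation of encounter histories under the trap-awareness process.

Individuals are released trap-aware at their cohort occasion and then
evolve by the exact per-interval factors of the model: survive (S), move
between states of interest (T, two-state only), and resolve awareness
through capture (P).  Observation codes follow the error-free event
matrix: a capture is recorded as 1 (or 2 in state 2), anything else as 0.

Transients — newly marked animals that permanently leave the study area
— are a mixture at release: with probability ``transient_fraction`` an
individual never survives its first interval, so the apparent
first-interval survival is (1 - transient_fraction) * phi, reproducing
the familiar phi1 < phi2 pattern.  Alternatively, explicit ``phi1`` in
the parameter set plays the same role directly.

Randomness is reproducible: one generator per scenario, consumed in a
documented fixed order — per-individual transient and initial-state
draws first, then a single (individuals x intervals x 4) grid of
uniforms read individual-major, occasion-minor, with slots (survival,
state transition, capture, removal).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data import EncounterData
from .model_core import (
    ModelSpec,
    ParameterSet,
    SpecificationError,
    build_bundle,
)


@dataclass
class SimulationScenario:
    """Ground-truth description of one simulated study.

    ``n_released_per_cohort`` gives new releases at occasions 1..K-1; a
    scalar is replicated across cohorts.  ``removal_prob`` is the chance
    that any recapture is a loss on capture (the marking capture itself
    is never a removal).
    """

    n_occasions: int
    n_released_per_cohort: int | Sequence[int]
    params: ParameterSet = field(default_factory=ParameterSet)
    state_space: str = "single"
    transient_fraction: float = 0.0
    removal_prob: float = 0.0
    seed: int = 0

    def releases(self) -> np.ndarray:
        K = self.n_occasions
        r = np.asarray(self.n_released_per_cohort, dtype=int)
        if r.ndim == 0:
            r = np.full(K - 1, int(r))
        if r.shape != (K - 1,) or (r < 0).any():
            raise SpecificationError(
                f"n_released_per_cohort must give {K - 1} non-negative cohort sizes"
            )
        return r

    def model_spec(self) -> ModelSpec:
        return ModelSpec(n_occasions=self.n_occasions, state_space=self.state_space)

    def truth(self) -> dict:
        rec = asdict(self)
        rec["n_released_per_cohort"] = [int(x) for x in self.releases()]
        return rec


def _first_interval_survival(scn: SimulationScenario, t: int, state: int) -> float:
    """Marginal survival over an animal's first interval: the transient
    mixture collapses to (1 - f) * phi1."""
    base = scn.params.phi_at(t, first=True, state=state)
    return (1.0 - scn.transient_fraction) * base


def simulate(scenario: SimulationScenario) -> tuple[EncounterData, dict]:
    """Generate encounter histories; returns the data and the scenario
    record (the truth) for downstream parameter-recovery checks."""
    scn = scenario
    K = scn.n_occasions
    releases = scn.releases()
    two_state = scn.state_space == "two_state"
    if not 0.0 <= scn.transient_fraction <= 1.0:
        raise SpecificationError("transient_fraction must lie in [0, 1]")
    if not 0.0 <= scn.removal_prob <= 1.0:
        raise SpecificationError("removal_prob must lie in [0, 1]")

    n = int(releases.sum())
    release_occ = np.repeat(np.arange(1, K), releases)
    rng = np.random.default_rng(scn.seed)
    u_transient = rng.random(n)
    u_state = rng.random(n)
    u = rng.random((n, K - 1, 4))

    transient = u_transient < scn.transient_fraction
    if two_state:
        state = np.where(u_state < scn.params.pi1, 1, 2)  # state of interest
        psi12, psi21 = scn.params.psi_pair()
    else:
        state = np.ones(n, dtype=int)

    codes = np.zeros((n, K), dtype=np.int8)
    codes[np.arange(n), release_occ - 1] = state if two_state else 1
    removed = np.zeros(n, dtype=bool)
    alive = np.zeros(n, dtype=bool)   # becomes True at release
    aware = np.zeros(n, dtype=bool)

    # per-interval parameter tables: PHI[t-1, first, state-1], PCAP[t-1, aware, state-1]
    n_st = 2 if two_state else 1
    PHI = np.array([[[scn.params.phi_at(t, first=bool(c), state=s + 1)
                      for s in range(n_st)] for c in (0, 1)] for t in range(1, K)])
    PCAP = np.array([[[scn.params.p_at(t + 1, aware=bool(a), state=s + 1)
                       for s in range(n_st)] for a in (0, 1)] for t in range(1, K)])

    for t in range(1, K):
        just_released = release_occ == t
        alive |= just_released
        aware |= just_released
        idx = np.flatnonzero(alive & ~removed & (release_occ <= t))
        if idx.size == 0:
            continue
        s0 = (state[idx] - 1) if two_state else np.zeros(idx.size, dtype=int)
        first = (release_occ[idx] == t).astype(int)
        phi = PHI[t - 1, first, s0 if two_state else 0]
        phi = np.where(transient[idx] & (first == 1), 0.0, phi)
        survive = u[idx, t - 1, 0] < phi
        alive[idx[~survive]] = False
        sv = idx[survive]
        if sv.size == 0:
            continue
        if two_state:
            psi = np.where(state[sv] == 1, psi12, psi21)
            move = u[sv, t - 1, 1] < psi
            state[sv] = np.where(move, 3 - state[sv], state[sv])
        s1 = (state[sv] - 1) if two_state else np.zeros(sv.size, dtype=int)
        pcap = PCAP[t - 1, aware[sv].astype(int), s1 if two_state else 0]
        caught = u[sv, t - 1, 2] < pcap
        aware[sv] = caught
        cz = sv[caught]
        codes[cz, t] = state[cz] if two_state else 1
        removed[cz[u[cz, t - 1, 3] < scn.removal_prob]] = True

    data = EncounterData(codes, counts=np.ones(n, dtype=np.int64), removed=removed)
    return data, scn.truth()


_MAX_ENUM_K = 6


def expected_history_frequencies(
    scenario: SimulationScenario, *, release_occasion: int = 1,
    release_state: int = 1,
) -> dict[tuple[int, ...], float]:
    """Exact probability of every observable history pattern for one
    release cohort, by enumeration over all hidden-state paths.

    Intended as a small-K oracle (K <= 6, no removals); probabilities sum
    to one over the full pattern set.
    """
    scn = scenario
    K = scn.n_occasions
    if K > _MAX_ENUM_K:
        raise SpecificationError(
            f"exact enumeration supported for K <= {_MAX_ENUM_K}, got {K}"
        )
    if scn.removal_prob != 0.0:
        raise SpecificationError("enumeration assumes no removals")
    spec = scn.model_spec()
    two_state = scn.state_space == "two_state"
    f = int(release_occasion)
    if not 1 <= f <= K - 1:
        raise SpecificationError("release occasion must be in 1..K-1")

    # transient mixture folded into the first-interval survival
    def bundle(t):
        b = build_bundle(scn.params, t, spec, first_interval=(t == f))
        if t == f and scn.transient_fraction > 0.0:
            S = b.S.copy()
            for i, s in ((0, 1), (1, 1), (2, 2), (3, 2)):
                if i >= S.shape[0] - 1:
                    break
                phi_eff = _first_interval_survival(scn, t, s)
                live = S[i, :-1]
                tot = live.sum()
                S[i, :-1] = live / tot * phi_eff if tot > 0 else 0.0
                S[i, -1] = 1.0 - phi_eff
            Pi = S @ b.T @ b.P
            return Pi, b.E
        return b.Pi, b.E

    n_s = spec.n_states
    init_idx = 0 if (not two_state or release_state == 1) else 2
    release_code = 1 if (not two_state or release_state == 1) else 2
    # deterministic emission: code of each state
    emit = [int(np.argmax(row)) for row in build_bundle(scn.params, 1, spec).E]

    bundles = [bundle(t) for t in range(f, K)]
    freqs: dict[tuple[int, ...], float] = {}
    for path in itertools.product(range(n_s), repeat=K - f):
        prob = 1.0
        prev = init_idx
        for step, st in enumerate(path):
            prob *= bundles[step][0][prev, st]
            prev = st
        if prob == 0.0:
            continue
        pattern = [0] * K
        pattern[f - 1] = release_code
        for step, st in enumerate(path):
            pattern[f + step] = emit[st]
        key = tuple(pattern)
        freqs[key] = freqs.get(key, 0.0) + prob
    return freqs
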