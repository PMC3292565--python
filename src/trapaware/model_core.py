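"""Operational state spaces and per-occasion matrices for trap-aware capture-recapture.

Immediate trap response is modelled as movement between two operational
states assessed at the end of each capture session: ``A`` (trap aware —
the animal was caught this session) and ``U`` (trap unaware — it was
not), plus the absorbing state ``D`` (dead).  A captured animal is aware
at the next session and is then detected with probability ``p'``; a
missed animal reverts immediately to unaware and is detected with
probability ``p``.  Survival between sessions is ``phi``.

With an additional two-level classification of biological interest
(site, breeding status, ...) the live states become ``A1, U1, A2, U2``
and a between-state transition process with probabilities ``psi12``,
``psi21`` acts between survival and awareness resolution.

State ordering is fixed everywhere as ``(A, U, D)`` for the single-state
model and ``(A1, U1, A2, U2, D)`` for the two-state model, with matrix
rows the state at the end of session t and columns the state at the end
of session t+1.  Time-varying survival is indexed by interval
(interval t spans sessions t to t+1, t = 1..K-1) and time-varying
capture parameters by the occasion at the interval's end (occasions
2..K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

SINGLE_STATES: tuple[str, ...] = ("A", "U", "D")
TWO_STATES: tuple[str, ...] = ("A1", "U1", "A2", "U2", "D")

SINGLE_EVENTS: tuple[str, ...] = ("0", "1")
TWO_STATE_EVENTS: tuple[str, ...] = ("0", "1", "2")


class ParameterError(ValueError):
    """A probability parameter is outside its domain."""


class SpecificationError(ValueError):
    """The model specification is internally inconsistent."""


def _check_prob(value: float, name: str) -> float:
    v = float(value)
    if not np.isfinite(v) or v < 0.0 or v > 1.0:
        raise ParameterError(f"parameter {name!r} must lie in [0, 1], got {value!r}")
    return v


def _as_state_pair(value):
    """Normalize a possibly state-specific parameter to a (state1, state2) pair."""
    if isinstance(value, (tuple, list)) and len(value) == 2 and not np.isscalar(value[0]) is None:
        return value[0], value[1]
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return value[0], value[1]
    return value, value


def _index_time(value, idx0: int, name: str) -> float:
    """Pick entry ``idx0`` from a scalar-or-vector time-varying parameter."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return float(arr[0])
    if idx0 < 0 or idx0 >= arr.size:
        raise ParameterError(
            f"time-varying parameter {name!r} has {arr.size} entries; index {idx0} out of range"
        )
    return float(arr[idx0])


@dataclass
class ParameterSet:
    """Natural-scale parameters of the trap-awareness model.

    Scalars apply to every interval/occasion; vectors are time-varying.
    ``phi`` is indexed by interval (1..K-1 -> positions 0..K-2); capture
    probabilities by occasion (2..K -> positions 0..K-2): the capture
    parameter attached to interval t is the one for occasion t+1.

    ``phi1``, when given, is the apparent survival over an animal's
    first interval after initial marking (depressed by transients);
    ``phi`` then plays the role of the survival of previously marked
    animals.  ``p_prime`` is the capture probability of trap-aware
    animals; if absent it is derived from ``m`` (an additive effect on
    the logit of ``p``) or defaults to ``p`` (no trap response).

    For the two-state model any of ``phi``, ``phi1``, ``p``,
    ``p_prime`` may be a 2-tuple giving state-specific values;
    ``psi12``, ``psi21`` are the between-state transition probabilities
    and ``pi1`` the probability that a new release is in state 1.
    """

    phi: float | Sequence[float] | tuple = 1.0
    p: float | Sequence[float] | tuple = 1.0
    p_prime: float | Sequence[float] | tuple | None = None
    phi1: float | Sequence[float] | tuple | None = None
    m: float | None = None
    psi12: float | None = None
    psi21: float | None = None
    pi1: float = 1.0

    # -- accessors ---------------------------------------------------------
    def phi_at(self, interval: int, *, first: bool = False, state: int = 1) -> float:
        """Survival over ``interval`` (1-based); ``first`` selects the
        newly-marked class when ``phi1`` is set."""
        src = self.phi1 if (first and self.phi1 is not None) else self.phi
        name = "phi1" if (first and self.phi1 is not None) else "phi"
        val = _as_state_pair(src)[state - 1]
        return _check_prob(_index_time(val, interval - 1, name), name)

    def p_at(self, occasion: int, *, aware: bool = False, state: int = 1) -> float:
        """Capture probability at ``occasion`` (2..K) for the unaware
        (default) or aware class."""
        base = _as_state_pair(self.p)[state - 1]
        pv = _index_time(base, occasion - 2, "p")
        if not aware:
            return _check_prob(pv, "p")
        if self.p_prime is not None:
            ppv = _index_time(_as_state_pair(self.p_prime)[state - 1], occasion - 2, "p_prime")
            return _check_prob(ppv, "p_prime")
        if self.m is not None:
            return float(apply_additive_trap_effect(np.array([pv]), self.m)[0])
        return _check_prob(pv, "p")

    def psi_pair(self) -> tuple[float, float]:
        if self.psi12 is None or self.psi21 is None:
            raise SpecificationError(
                "two-state model requires psi12 and psi21 transition probabilities"
            )
        return (_check_prob(self.psi12, "psi12"), _check_prob(self.psi21, "psi21"))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the effects acting on survival and capture.

    ``effects_phi`` may contain ``time`` and/or ``transience``;
    ``effects_p`` may contain ``time``, ``trap`` and/or ``additive``.
    Without ``trap`` the model is the naive CJS (p' == p); ``additive``
    (one shared trap effect on the logit of a time-varying p) requires
    both ``time`` and ``trap``.
    """

    n_occasions: int
    state_space: str = "single"
    effects_phi: frozenset[str] = field(default_factory=frozenset)
    effects_p: frozenset[str] = field(default_factory=frozenset)
    censoring: bool = True

    def __post_init__(self):
        if self.n_occasions < 2:
            raise SpecificationError("need at least 2 capture occasions")
        if self.state_space not in ("single", "two_state"):
            raise SpecificationError(f"unknown state_space {self.state_space!r}")
        object.__setattr__(self, "effects_phi", frozenset(self.effects_phi))
        object.__setattr__(self, "effects_p", frozenset(self.effects_p))
        bad_phi = self.effects_phi - {"time", "transience"}
        bad_p = self.effects_p - {"time", "trap", "additive"}
        if bad_phi:
            raise SpecificationError(f"unknown effects on phi: {sorted(bad_phi)}")
        if bad_p:
            raise SpecificationError(f"unknown effects on p: {sorted(bad_p)}")
        if "additive" in self.effects_p and not {"time", "trap"} <= self.effects_p:
            raise SpecificationError(
                "an additive trap effect requires both 'time' and 'trap' on p"
            )

    @property
    def n_states(self) -> int:
        return 3 if self.state_space == "single" else 5

    @property
    def states(self) -> tuple[str, ...]:
        return SINGLE_STATES if self.state_space == "single" else TWO_STATES

    @property
    def has_trap_effect(self) -> bool:
        return "trap" in self.effects_p


@dataclass
class MatrixBundle:
    """HMM building blocks for one interval.

    ``Pi = S @ T @ P`` maps the state at the end of session t to the
    state at the end of session t+1 (``T`` is the identity for the
    single-state model); ``E`` maps states to observation codes; ``init``
    is the state distribution at an initial release.
    """

    S: np.ndarray
    T: np.ndarray
    P: np.ndarray
    Pi: np.ndarray
    E: np.ndarray
    init: np.ndarray
    states: tuple[str, ...]
    events: tuple[str, ...]

    def to_text(self) -> str:
        """Plain-text dump of all matrices for debugging and audit."""
        out = []
        for name, mat in (("S", self.S), ("T", self.T), ("P", self.P),
                          ("Pi", self.Pi), ("E", self.E)):
            cols = self.events if name == "E" else self.states
            out.append(f"{name} (rows {','.join(self.states)}; cols {','.join(cols)}):")
            for row in mat:
                out.append("  " + "  ".join(f"{v:8.6f}" for v in row))
        out.append("init: " + "  ".join(f"{v:8.6f}" for v in self.init))
        return "\n".join(out)


def apply_additive_trap_effect(p_by_time: np.ndarray, m: float) -> np.ndarray:
    """Aware-class capture probabilities p'_t = expit(logit(p_t) + m).

    ``m`` is the trap effect shared across occasions: positive for
    trap-happiness, negative for trap-shyness, zero for no response.
    """
    p = np.asarray(p_by_time, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ParameterError("additive trap effect needs p strictly inside (0, 1)")
    return expit(logit(p) + float(m))


def build_single_state_bundle(
    params: ParameterSet, occasion: int, *, first_interval: bool = False
) -> MatrixBundle:
    """Matrices for interval ``occasion`` -> ``occasion``+1 of the
    single-state model; ``first_interval`` selects the transient-affected
    survival class phi1 for a newly marked animal."""
    t = int(occasion)
    if t < 1:
        raise ParameterError(f"interval index must be >= 1, got {t}")
    phi = params.phi_at(t, first=first_interval)
    p = params.p_at(t + 1, aware=False)
    pp = params.p_at(t + 1, aware=True)
    S = np.array([[phi, 0.0, 1.0 - phi],
                  [0.0, phi, 1.0 - phi],
                  [0.0, 0.0, 1.0]])
    P = np.array([[pp, 1.0 - pp, 0.0],
                  [p, 1.0 - p, 0.0],
                  [0.0, 0.0, 1.0]])
    T = np.eye(3)
    E = np.array([[0.0, 1.0],   # A: encountered with certainty
                  [1.0, 0.0],   # U: never encountered
                  [1.0, 0.0]])  # D
    init = np.array([1.0, 0.0, 0.0])
    return MatrixBundle(S=S, T=T, P=P, Pi=S @ P, E=E, init=init,
                        states=SINGLE_STATES, events=SINGLE_EVENTS)


def build_two_state_bundle(
    params: ParameterSet, occasion: int, *, first_interval: bool = False
) -> MatrixBundle:
    """Matrices for one interval of the two-state model over
    (A1, U1, A2, U2, D).

    The composite transition factors as survival (S, between t and
    t+1-), between-state movement (T, by the end of the interval) and
    awareness resolution through capture (P, between t+1- and t+1).
    """
    t = int(occasion)
    if t < 1:
        raise ParameterError(f"interval index must be >= 1, got {t}")
    phi1s, phi2s = (params.phi_at(t, first=first_interval, state=s) for s in (1, 2))
    psi12, psi21 = params.psi_pair()
    p1 = params.p_at(t + 1, aware=False, state=1)
    p2 = params.p_at(t + 1, aware=False, state=2)
    pp1 = params.p_at(t + 1, aware=True, state=1)
    pp2 = params.p_at(t + 1, aware=True, state=2)
    pi1 = _check_prob(params.pi1, "pi1")

    S = np.array([
        [phi1s, 0, 0, 0, 1 - phi1s],
        [0, phi1s, 0, 0, 1 - phi1s],
        [0, 0, phi2s, 0, 1 - phi2s],
        [0, 0, 0, phi2s, 1 - phi2s],
        [0, 0, 0, 0, 1],
    ], dtype=float)
    # movement between states of interest preserves the awareness label
    T = np.array([
        [1 - psi12, 0, psi12, 0, 0],
        [0, 1 - psi12, 0, psi12, 0],
        [psi21, 0, 1 - psi21, 0, 0],
        [0, psi21, 0, 1 - psi21, 0],
        [0, 0, 0, 0, 1],
    ], dtype=float)
    # capture at t+1 lands the animal in the aware state of its current
    # state of interest; the capture probability depends on the awareness
    # carried over from session t
    P = np.array([
        [pp1, 1 - pp1, 0, 0, 0],
        [p1, 1 - p1, 0, 0, 0],
        [0, 0, pp2, 1 - pp2, 0],
        [0, 0, p2, 1 - p2, 0],
        [0, 0, 0, 0, 1],
    ], dtype=float)
    # states are read without error at capture: code 1 in state 1, code 2
    # in state 2, code 0 otherwise
    E = np.array([
        [0, 1, 0],
        [1, 0, 0],
        [0, 0, 1],
        [1, 0, 0],
        [1, 0, 0],
    ], dtype=float)
    init = np.array([pi1, 0.0, 1.0 - pi1, 0.0, 0.0])
    return MatrixBundle(S=S, T=T, P=P, Pi=S @ T @ P, E=E, init=init,
                        states=TWO_STATES, events=TWO_STATE_EVENTS)


def build_bundle(params: ParameterSet, occasion: int, spec: ModelSpec,
                 *, first_interval: bool = False) -> MatrixBundle:
    if spec.state_space == "single":
        return build_single_state_bundle(params, occasion, first_interval=first_interval)
    return build_two_state_bundle(params, occasion, first_interval=first_interval)
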