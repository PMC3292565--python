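"""Traditional formulations: split-history CJS and the naive CJS.

The traditional fix for an immediate trap response cuts every capture
history after each capture: each capture releases a new pseudo-animal
whose first post-release occasion carries the aware-class capture
probability p' and whose later occasions carry the unaware-class p.  All
fragments except the terminal one are flagged as losses on capture so
that the never-seen-again tail is counted exactly once.  The product of
fragment likelihoods is algebraically identical to the trap-awareness
state-model likelihood, which is the equivalence this module exists to
verify.

Both fits here are written in the closed product form of the CJS
likelihood (survival terms, capture/miss terms, and a backward
never-seen-again recursion) — deliberately independent of the
hidden-Markov forward algorithm in :mod:`trapaware.inference`, so that
agreement between the two routes is an informative cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import DataError, EncounterData
from .inference import FitResult, ParameterDesign, maximize_likelihood
from .model_core import ModelSpec, ParameterSet

_TINY = 1e-300


@dataclass(frozen=True)
class Fragment:
    """One split sub-history: released by a capture at ``release``, ending
    either at the next capture (``recapture``, a loss on capture) or, for
    the terminal fragment, running to the end of the study."""

    release: int            # 1-based occasion of the opening capture
    recapture: int | None   # next capture occasion, None for terminal fragments
    removed: bool           # True unless the fragment carries the tail
    first: bool             # opened by the animal's first capture (phi1 class)
    source: int             # row index of the source animal
    count: int = 1


@dataclass
class SplitHistorySet:
    fragments: list[Fragment]
    n_occasions: int
    source_digest: str

    def __len__(self) -> int:
        return len(self.fragments)

    def to_encounter_data(self) -> EncounterData:
        """Fragments as full-length histories with loss-on-capture flags —
        the 'specially prepared' dataset users would feed to external CJS
        software."""
        K = self.n_occasions
        hist = np.zeros((len(self.fragments), K), dtype=np.int8)
        counts = np.zeros(len(self.fragments), dtype=np.int64)
        removed = np.zeros(len(self.fragments), dtype=bool)
        for i, fr in enumerate(self.fragments):
            hist[i, fr.release - 1] = 1
            if fr.recapture is not None:
                hist[i, fr.recapture - 1] = 1
            counts[i] = fr.count
            removed[i] = fr.removed
        return EncounterData(hist, counts, removed)

    def reconstruct(self, n_sources: int) -> np.ndarray:
        """Rebuild the source histories from the fragments (losslessness
        audit): every capture of every animal appears in exactly one
        fragment release or recapture."""
        K = self.n_occasions
        hist = np.zeros((n_sources, K), dtype=np.int8)
        for fr in self.fragments:
            hist[fr.source, fr.release - 1] = 1
            if fr.recapture is not None:
                hist[fr.source, fr.recapture - 1] = 1
        return hist


def split_histories(data: EncounterData) -> SplitHistorySet:
    """Cut each single-state history after every capture.

    Each capture opens exactly one fragment; consecutive captures (c_k,
    c_{k+1}) give a fragment removed at c_{k+1}; the last capture opens
    the terminal fragment, which keeps the never-seen-again tail unless
    the animal itself was a loss on capture.
    """
    if data.max_code > 1:
        raise DataError("split-history preparation is defined for single-state data")
    fragments: list[Fragment] = []
    for i in range(data.n_histories):
        caps = np.flatnonzero(data.histories[i] == 1) + 1
        cnt = int(data.counts[i])
        for k, c in enumerate(caps):
            is_first = k == 0
            if k + 1 < len(caps):
                fragments.append(Fragment(int(c), int(caps[k + 1]), True, is_first, i, cnt))
            else:
                fragments.append(Fragment(int(c), None, bool(data.removed[i]), is_first, i, cnt))
    return SplitHistorySet(fragments, data.n_occasions, data.digest())


# ---------------------------------------------------------------------------
# closed-form CJS log-likelihoods
# ---------------------------------------------------------------------------

def _tables(params: ParameterSet, K: int):
    """Flatten a ParameterSet into per-interval/per-occasion lookup lists:
    phi1[t-1], phi2[t-1] for intervals 1..K-1; p[t], pp[t] for occasions
    (index by occasion, entries 0..1 unused)."""
    phi1 = [params.phi_at(t, first=True) for t in range(1, K)]
    phi2 = [params.phi_at(t, first=False) for t in range(1, K)]
    p = [0.0, 0.0] + [params.p_at(t, aware=False) for t in range(2, K + 1)]
    pp = [0.0, 0.0] + [params.p_at(t, aware=True) for t in range(2, K + 1)]
    return phi1, phi2, p, pp


def _fragment_loglik(fr: Fragment, tables, K: int) -> float:
    """CJS log-likelihood of one fragment with the aware class attached to
    the occasion immediately after the fragment's release."""
    phi1, phi2, p, pp = tables
    r = fr.release

    def phi(t):
        return phi1[t - 1] if (fr.first and t == r) else phi2[t - 1]

    def pc(t):
        return pp[t] if t == r + 1 else p[t]

    if fr.recapture is not None:
        s = fr.recapture
        ll = sum(np.log(max(phi(t), _TINY)) for t in range(r, s))
        ll += sum(np.log(max(1.0 - pc(t), _TINY)) for t in range(r + 1, s))
        ll += np.log(max(pc(s), _TINY))
        return float(ll)
    if fr.removed:
        return 0.0  # removal at the opening capture: no subsequent terms
    chi = 1.0
    for t in range(K - 1, r - 1, -1):
        chi = (1.0 - phi(t)) + phi(t) * (1.0 - pc(t + 1)) * chi
    return float(np.log(max(chi, _TINY)))


def _cjs_history_loglik(codes: np.ndarray, removed: bool,
                        tables, K: int) -> float:
    """Textbook CJS log-likelihood of one full history (capture probability
    has no awareness class; transience enters as the two survival classes)."""
    phi1, phi2, p, _ = tables
    caps = np.flatnonzero(codes == 1) + 1
    f, last = int(caps[0]), int(caps[-1])
    capset = set(int(c) for c in caps)

    def phi(t):
        return phi1[t - 1] if t == f else phi2[t - 1]

    ll = sum(np.log(max(phi(t), _TINY)) for t in range(f, last))
    for t in range(f + 1, last + 1):
        pt = p[t]
        ll += np.log(max(pt if t in capset else 1.0 - pt, _TINY))
    if not removed:
        chi = 1.0
        for t in range(K - 1, last - 1, -1):
            chi = (1.0 - phi(t)) + phi(t) * (1.0 - p[t + 1]) * chi
        ll += np.log(max(chi, _TINY))
    return float(ll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _aggregate_fragments(frs: list[Fragment]) -> dict[tuple, int]:
    agg: dict[tuple, int] = {}
    for fr in frs:
        key = (fr.release, fr.recapture, fr.removed, fr.first)
        agg[key] = agg.get(key, 0) + fr.count
    return agg


def fit_split_cjs(
    fragments: SplitHistorySet,
    spec: ModelSpec,
    start=None,
    seed: int = 0,
    *,
    n_restarts: int = 0,
) -> FitResult:
    """Fit the split-history CJS; parameter names match the trap-awareness
    fit of the same :class:`ModelSpec`, so estimates are directly comparable."""
    if spec.state_space != "single":
        raise DataError("the split-history approach is implemented single-state only")
    K = spec.n_occasions
    if fragments.n_occasions != K:
        raise DataError("fragment set and model disagree on the number of occasions")
    design = ParameterDesign(spec)
    agg = _aggregate_fragments(fragments.fragments)

    def nll(theta):
        tables = _tables(design.to_params(theta), K)
        total = 0.0
        for (release, recapture, removed, first), cnt in agg.items():
            fr = Fragment(release, recapture, removed, first, -1, cnt)
            total += cnt * _fragment_loglik(fr, tables, K)
        return -total

    return maximize_likelihood(
        nll, design, model_label="split-history CJS",
        data_digest=fragments.source_digest, start=start, seed=seed,
        n_restarts=n_restarts,
    )


def fit_naive_cjs(
    data: EncounterData,
    spec: ModelSpec,
    start=None,
    seed: int = 0,
    *,
    n_restarts: int = 0,
) -> FitResult:
    """Fit the CJS that ignores trap response (p' == p); any trap effect in
    the given spec is dropped."""
    if data.n_histories == 0:
        raise DataError("empty dataset")
    if data.max_code > 1:
        raise DataError("naive CJS is implemented single-state only")
    naive_spec = replace(
        spec, effects_p=frozenset(spec.effects_p) - {"trap", "additive"}
    )
    K = naive_spec.n_occasions
    design = ParameterDesign(naive_spec)
    agg = data.aggregate()

    caps_cache = [
        (np.flatnonzero(agg.histories[i] == 1) + 1,
         bool(agg.removed[i]) and naive_spec.censoring,
         int(agg.counts[i]))
        for i in range(agg.n_histories)
    ]

    def nll(theta):
        tables = _tables(design.to_params(theta), K)
        total = 0.0
        for i in range(agg.n_histories):
            total += caps_cache[i][2] * _cjs_history_loglik(
                agg.histories[i], caps_cache[i][1], tables, K
            )
        return -total

    return maximize_likelihood(
        nll, design, model_label="naive CJS (no trap effect)",
        data_digest=data.digest(), start=start, seed=seed, n_restarts=n_restarts,
    )
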