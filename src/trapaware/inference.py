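"""Likelihood and maximum-likelihood fitting of trap-awareness models.

The likelihood of an encounter history conditions on the initial release
(the first capture is not modelled, as in the Cormack-Jolly-Seber
tradition) and is computed by the forward algorithm of the hidden Markov
formulation: the state distribution is initialized at the release
occasion, then alternately propagated through the composite transition
matrix Pi and conditioned on the observed code through the event matrix.

All probabilities are estimated on the logit scale; the additive trap
effect ``m`` lives on the identity (logit-difference) scale.  Standard
errors come from the inverse of the observed information (numerical
Hessian at the MLE); confounded parameter combinations are reported via
near-null eigenvectors of the scaled Hessian rather than silently
constrained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .data import DataError, EncounterData
from .model_core import (
    ModelSpec,
    ParameterSet,
    SpecificationError,
    build_bundle,
)

_TINY = 1e-300
_PCLIP = 1e-12  # keep link-scale probabilities strictly inside (0, 1)


# ---------------------------------------------------------------------------
# parameter design: ModelSpec -> named link-scale vector -> ParameterSet
# ---------------------------------------------------------------------------

@dataclass
class ParameterDesign:
    """Maps a link-scale parameter vector to a :class:`ParameterSet`.

    Parameter naming: ``phi`` (or ``phi1``/``phi2`` with transience),
    ``p``, ``pprime``, ``m``; time-varying entries are suffixed ``_i<t>``
    for interval t (survival) and ``_t<t>`` for occasion t (capture);
    two-state parameters are suffixed ``_s1``/``_s2`` and joined by
    ``psi12``, ``psi21`` (and ``pi1`` when estimated).
    """

    spec: ModelSpec
    free_pi1: bool = False
    names: list[str] = field(default_factory=list)
    links: list[str] = field(default_factory=list)
    _blocks: dict = field(default_factory=dict)

    def __post_init__(self):
        spec = self.spec
        K = spec.n_occasions
        states = (1,) if spec.state_space == "single" else (1, 2)
        sfx = {1: "", 2: ""} if spec.state_space == "single" else {1: "_s1", 2: "_s2"}

        def add_block(key, labels, link="logit"):
            start = len(self.names)
            self.names.extend(labels)
            self.links.extend([link] * len(labels))
            self._blocks[key] = slice(start, len(self.names))

        transience = "transience" in spec.effects_phi
        phi_time = "time" in spec.effects_phi
        p_time = "time" in spec.effects_p
        trap = "trap" in spec.effects_p
        additive = "additive" in spec.effects_p

        for s in states:
            classes = ("phi1", "phi2") if transience else ("phi",)
            for cls in classes:
                if phi_time:
                    add_block((cls, s), [f"{cls}{sfx[s]}_i{t}" for t in range(1, K)])
                else:
                    add_block((cls, s), [f"{cls}{sfx[s]}"])
        for s in states:
            if p_time:
                add_block(("p", s), [f"p{sfx[s]}_t{t}" for t in range(2, K + 1)])
            else:
                add_block(("p", s), [f"p{sfx[s]}"])
        if trap and not additive:
            for s in states:
                if p_time:
                    add_block(("pprime", s), [f"pprime{sfx[s]}_t{t}" for t in range(2, K + 1)])
                else:
                    add_block(("pprime", s), [f"pprime{sfx[s]}"])
        if additive:
            add_block(("m", None), ["m"], link="identity")
        if spec.state_space == "two_state":
            add_block(("psi12", None), ["psi12"])
            add_block(("psi21", None), ["psi21"])
            if self.free_pi1:
                add_block(("pi1", None), ["pi1"])

    @property
    def n_params(self) -> int:
        return len(self.names)

    def _nat(self, theta, key):
        block = self._blocks.get(key)
        if block is None:
            return None
        vals = np.clip(expit(theta[block]), _PCLIP, 1.0 - _PCLIP)
        return float(vals[0]) if vals.size == 1 else vals

    def to_params(self, theta: np.ndarray) -> ParameterSet:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise SpecificationError(
                f"expected {self.n_params} parameters ({self.names}), got {theta.shape}"
            )
        spec = self.spec
        states = (1,) if spec.state_space == "single" else (1, 2)
        transience = "transience" in spec.effects_phi

        def per_state(fetch):
            vals = [fetch(s) for s in states]
            return vals[0] if len(vals) == 1 else tuple(vals)

        phi_key = "phi2" if transience else "phi"
        phi = per_state(lambda s: self._nat(theta, (phi_key, s)))
        phi1 = per_state(lambda s: self._nat(theta, ("phi1", s))) if transience else None
        p = per_state(lambda s: self._nat(theta, ("p", s)))
        p_prime = None
        m = None
        if ("pprime", 1) in self._blocks:
            p_prime = per_state(lambda s: self._nat(theta, ("pprime", s)))
        if ("m", None) in self._blocks:
            m = float(theta[self._blocks[("m", None)]][0])
        kwargs = dict(phi=phi, phi1=phi1, p=p, p_prime=p_prime, m=m)
        if spec.state_space == "two_state":
            kwargs["psi12"] = self._nat(theta, ("psi12", None))
            kwargs["psi21"] = self._nat(theta, ("psi21", None))
            kwargs["pi1"] = self._nat(theta, ("pi1", None)) if self.free_pi1 else 0.5
        return ParameterSet(**kwargs)

    def natural(self, theta: np.ndarray) -> dict[str, float]:
        """Back-transform a link-scale vector to named natural-scale values."""
        out = {}
        for name, link, v in zip(self.names, self.links, np.asarray(theta, float)):
            out[name] = float(v) if link == "identity" else float(expit(v))
        return out


# ---------------------------------------------------------------------------
# forward-algorithm likelihood
# ---------------------------------------------------------------------------

def _release_state_index(code: int, spec: ModelSpec) -> int:
    """Index of the (trap-aware) operational state implied by the release code."""
    if spec.state_space == "single":
        return 0  # A
    return 0 if code == 1 else 2  # A1 / A2


def history_log_likelihood(
    history,
    params: ParameterSet,
    spec: ModelSpec,
    *,
    removed: bool = False,
    free_pi1: bool = False,
) -> float:
    """Log-probability of the encounters after first capture, conditional
    on the release in the trap-aware state of the observed release code.

    A removed (loss-on-capture) history contributes no terms after the
    removal occasion.  With ``free_pi1`` the two-state likelihood carries
    the initial-state term pi1 / (1 - pi1); by default the release state
    is observed without error so the term is a constant and is dropped.
    """
    codes = np.asarray(history, dtype=int).ravel()
    K = spec.n_occasions
    if codes.size != K:
        raise DataError(f"history has {codes.size} occasions, model has {K}")
    if spec.state_space == "single" and (codes > 1).any():
        raise DataError("code 2 encountered under a single-state model")
    nz = np.flatnonzero(codes)
    if nz.size == 0:
        raise DataError("history contains no encounter; cannot condition on release")
    f = int(nz[0]) + 1                      # release occasion, 1-based
    stop = int(nz[-1]) + 1 if removed else K

    n_s = spec.n_states
    alpha = np.zeros(n_s)
    alpha[_release_state_index(codes[f - 1], spec)] = 1.0
    ll0 = 0.0
    if spec.state_space == "two_state" and free_pi1:
        pi1 = params.pi1
        ll0 = np.log(max(pi1 if codes[f - 1] == 1 else 1.0 - pi1, _TINY))
    for t in range(f, stop):
        bundle = build_bundle(params, t, spec, first_interval=(t == f))
        alpha = alpha @ bundle.Pi
        alpha = alpha * bundle.E[:, codes[t]]
    return ll0 + float(np.log(max(alpha.sum(), _TINY)))


class _PreparedData:
    """Per-dataset arrays reused across likelihood evaluations."""

    def __init__(self, data: EncounterData, spec: ModelSpec):
        if data.n_histories == 0:
            raise DataError("empty dataset")
        if data.n_occasions != spec.n_occasions:
            raise DataError(
                f"data have {data.n_occasions} occasions, model has {spec.n_occasions}"
            )
        if spec.state_space == "single" and data.max_code > 1:
            raise DataError("code 2 present: fit a two-state model or recode the data")
        agg = data.aggregate()
        self.codes = agg.histories.astype(int)
        self.counts = agg.counts.astype(float)
        self.release = agg.first_capture()
        removed = agg.removed if spec.censoring else np.zeros(agg.n_histories, bool)
        self.stop = np.where(removed, agg.last_capture(), spec.n_occasions)
        self.release_code = self.codes[np.arange(agg.n_histories), self.release - 1]
        self.n = agg.n_histories


def _forward_nll(theta: np.ndarray, prep: _PreparedData, design: ParameterDesign) -> float:
    spec = design.spec
    params = design.to_params(theta)
    K = spec.n_occasions
    n_s = spec.n_states
    bundles_first = [build_bundle(params, t, spec, first_interval=True) for t in range(1, K)]
    bundles_later = [build_bundle(params, t, spec, first_interval=False) for t in range(1, K)]
    E = bundles_later[0].E

    alpha = np.zeros((prep.n, n_s))
    if spec.state_space == "single":
        alpha[:, 0] = 1.0
    else:
        alpha[np.arange(prep.n), np.where(prep.release_code == 1, 0, 2)] = 1.0

    ll0 = 0.0
    if spec.state_space == "two_state" and design.free_pi1:
        pi1 = params.pi1
        init_p = np.where(prep.release_code == 1, pi1, 1.0 - pi1)
        ll0 = float(prep.counts @ np.log(np.maximum(init_p, _TINY)))

    for t in range(1, K):
        active = (prep.release <= t) & (prep.stop >= t + 1)
        if not active.any():
            continue
        prop_f = alpha @ bundles_first[t - 1].Pi
        prop_l = alpha @ bundles_later[t - 1].Pi
        prop = np.where((prep.release == t)[:, None], prop_f, prop_l)
        prop = prop * E.T[prep.codes[:, t]]
        alpha = np.where(active[:, None], prop, alpha)

    ll = prep.counts @ np.log(np.maximum(alpha.sum(axis=1), _TINY))
    if not np.isfinite(ll):
        bad = int(np.flatnonzero(~np.isfinite(np.log(np.maximum(alpha.sum(1), 0))))[0]) \
            if alpha.size else -1
        raise FloatingPointError(f"non-finite likelihood at aggregated history row {bad}")
    return -(ll + ll0)


def dataset_neg_log_likelihood(
    data: EncounterData,
    theta,
    spec: ModelSpec,
    *,
    free_pi1: bool = False,
) -> float:
    """Negative log-likelihood of the whole dataset (count-weighted sum of
    per-history terms) at a link-scale parameter vector."""
    design = ParameterDesign(spec, free_pi1=free_pi1)
    prep = _PreparedData(data, spec)
    return _forward_nll(np.asarray(theta, float), prep, design)


# ---------------------------------------------------------------------------
# fit result and optimizer
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood estimates with Wald uncertainty.

    ``estimates_natural`` holds back-transformed probabilities (the trap
    effect ``m`` stays on the logit-difference scale); ``ci95`` maps each
    parameter to a (lower, upper) natural-scale interval, or ``None``
    when the estimate sits on the boundary and a Wald interval would be
    fabricated.  ``rank_deficient`` lists parameters involved in
    near-null directions of the observed information (intrinsically
    confounded combinations such as the terminal survival x capture
    product of a fully time-dependent model).
    """

    model: str
    names: list[str]
    links: list[str]
    estimates_link: np.ndarray
    estimates_natural: dict[str, float]
    covariance: np.ndarray
    ci95: dict[str, tuple[float, float] | None]
    loglik: float
    aic: float
    n_params: int
    converged: bool
    rank_deficient: list[str]
    boundary: list[str]
    data_digest: str
    message: str = ""

    def report(self) -> str:
        lines = [f"Model: {self.model}",
                 f"log-likelihood: {self.loglik:.4f}   AIC: {self.aic:.4f}   "
                 f"k: {self.n_params}   converged: {self.converged}"]
        lines.append(f"{'parameter':<14}{'estimate':>10}  95% CI")
        for name in self.names:
            est = self.estimates_natural[name]
            ci = self.ci95[name]
            if ci is None:
                lines.append(f"{name:<14}{est:>10.3f}  (boundary)")
            else:
                lines.append(f"{name:<14}{est:>10.3f}  ({ci[0]:.2f}–{ci[1]:.2f})")
        if self.rank_deficient:
            lines.append("rank-deficient directions involve: "
                         + ", ".join(self.rank_deficient))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "names": self.names,
            "estimates_link": [float(v) for v in self.estimates_link],
            "estimates_natural": self.estimates_natural,
            "ci95": {k: (list(v) if v is not None else None) for k, v in self.ci95.items()},
            "covariance": [[float(x) for x in row] for row in self.covariance],
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "rank_deficient": self.rank_deficient,
            "boundary": self.boundary,
            "data_digest": self.data_digest,
            "message": self.message,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _numgrad(fun, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def _numhess(fun, x, h=1e-4):
    k = x.size
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h**2)
    return H


_BOUNDARY_LINK = 12.0  # |logit| beyond this is numerically a boundary estimate


def maximize_likelihood(
    nll,
    design: ParameterDesign,
    *,
    model_label: str,
    data_digest: str,
    start=None,
    seed: int = 0,
    n_restarts: int = 0,
    maxiter: int = 500,
) -> FitResult:
    """Quasi-Newton maximization shared by the HMM and classic fits.

    Starts at 0 on the link scale (0.5 on the probability scale) unless
    ``start`` is given; optional random restarts are drawn from the given
    seed and the best optimum kept.
    """
    k = design.n_params
    starts = [np.zeros(k) if start is None else np.asarray(start, float)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        starts += [rng.normal(scale=1.0, size=k) for _ in range(n_restarts)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, jac=lambda x: _numgrad(nll, x), method="L-BFGS-B",
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res

    # L-BFGS-B sometimes reports an abnormal line search at a point that is
    # already stationary (finite-difference noise); judge convergence by the
    # gradient itself, with a simplex polish as fallback for real failures
    grad_norm = float(np.max(np.abs(_numgrad(nll, best.x))))
    success = bool(best.success) or grad_norm < 1e-4
    if not success:
        polish = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
        )
        if polish.fun <= best.fun:
            best = polish
        grad_norm = float(np.max(np.abs(_numgrad(nll, best.x))))
        success = bool(best.success) or grad_norm < 1e-4

    theta = best.x
    H = _numhess(nll, theta)
    # scale to unit diagonal before the eigen test so the threshold is
    # comparable across parameters of different information content
    d = np.sqrt(np.abs(np.diag(H)))
    d[d == 0] = 1.0
    Hs = H / np.outer(d, d)
    eigval, eigvec = np.linalg.eigh(Hs)
    rank_deficient: list[str] = []
    for lam, vec in zip(eigval, eigvec.T):
        if lam < 1e-6:
            involved = [design.names[i] for i in np.flatnonzero(np.abs(vec) > 0.3)]
            rank_deficient.extend(n for n in involved if n not in rank_deficient)

    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    boundary = [n for n, v, lk in zip(design.names, theta, design.links)
                if lk == "logit" and abs(v) > _BOUNDARY_LINK]
    natural = design.natural(theta)
    ci95: dict[str, tuple[float, float] | None] = {}
    for i, (name, lk) in enumerate(zip(design.names, design.links)):
        if name in boundary or not np.isfinite(se[i]) or cov[i, i] <= 0:
            ci95[name] = None
            continue
        lo, hi = theta[i] - 1.96 * se[i], theta[i] + 1.96 * se[i]
        if lk == "logit":
            ci95[name] = (float(expit(lo)), float(expit(hi)))
        else:
            ci95[name] = (float(lo), float(hi))

    loglik = -float(best.fun)
    converged = bool(success and np.isfinite(loglik))
    return FitResult(
        model=model_label,
        names=list(design.names),
        links=list(design.links),
        estimates_link=theta,
        estimates_natural=natural,
        covariance=cov,
        ci95=ci95,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n_params=k,
        converged=converged,
        rank_deficient=rank_deficient,
        boundary=boundary,
        data_digest=data_digest,
        message=str(best.message),
    )


def fit(
    data: EncounterData,
    spec: ModelSpec,
    start=None,
    seed: int = 0,
    *,
    n_restarts: int = 0,
    free_pi1: bool = False,
    model_label: str | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the trap-awareness (or naive CJS) HMM."""
    design = ParameterDesign(spec, free_pi1=free_pi1)
    prep = _PreparedData(data, spec)
    nll = lambda th: _forward_nll(th, prep, design)
    label = model_label or _default_label(spec)
    return maximize_likelihood(
        nll, design, model_label=label, data_digest=data.digest(),
        start=start, seed=seed, n_restarts=n_restarts,
    )


def _default_label(spec: ModelSpec) -> str:
    phi = "phi" + ("1,phi2" if "transience" in spec.effects_phi else "")
    if "time" in spec.effects_phi:
        phi += "_t"
    p = "p"
    if "time" in spec.effects_p:
        p += "_t"
    if "additive" in spec.effects_p:
        p += "+m"
    elif "trap" in spec.effects_p:
        p += ",p'"
    tag = "two-state " if spec.state_space == "two_state" else ""
    return f"{tag}({phi}, {p})"


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """AIC ranking of fits on the same data: sorted by AIC, ties broken by
    fewer parameters; dAIC relative to the best model."""
    if not fits:
        raise ValueError("no fits to compare")
    digests = {f.data_digest for f in fits}
    if len(digests) > 1:
        raise ValueError("fits were obtained on different datasets")
    rows = sorted(fits, key=lambda f: (f.aic, f.n_params))
    best = rows[0].aic
    return pd.DataFrame({
        "model": [f.model for f in rows],
        "k": [f.n_params for f in rows],
        "loglik": [f.loglik for f in rows],
        "AIC": [f.aic for f in rows],
        "dAIC": [f.aic - best for f in rows],
        "converged": [f.converged for f in rows],
    })
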