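# Methods

## Model

`trapaware` models an *immediate* trap response in open-population
capture–recapture: capture at occasion t changes the capture probability
at t+1 only; an animal that is missed once reverts to its naive state.
The device is an operational state assessed at the end of each capture
session (t⁺): **A** (trap aware ⇔ captured this session), **U** (trap
unaware) and the absorbing **D** (dead). State order is fixed as
(A, U, D) throughout, rows = state at t⁺, columns = state at (t+1)⁺.
The end-of-session convention matters for censoring: a loss on capture
is removed *after* its capture, so its history simply contributes no
terms past the removal occasion, with no special-case arithmetic.

Each interval factors into a survival step S (t⁺ → (t+1)⁻) and an
awareness-resolution step P ((t+1)⁻ → (t+1)⁺):

```
S = [φ 0 1−φ; 0 φ 1−φ; 0 0 1]      P = [p′ 1−p′ 0; p 1−p 0; 0 0 1]
Π = S·P
```

Capture probabilities therefore appear *inside* the transition matrix —
capture genuinely changes the animal's (behavioural) state. The
observation process is degenerate: A emits "encountered" (code 1), U and
D emit "not encountered" (code 0), and the initial state at release is A
with certainty. The likelihood of a history, conditional on its first
capture (CJS-style; the first capture itself is not modelled), is
computed by the forward algorithm: initialize at the release occasion,
then alternate Π-propagation and conditioning on the observed code.
Histories never underflow at realistic K, so no scaling is applied; the
final sum is floored at 1e−300 before the log for optimizer safety.

**Two-state variant.** With a second classification of interest (site,
breeding status) the live states are (A1, U1, A2, U2) plus D, and each
interval factors as S·T·P, where T moves animals between states of
interest (probabilities ψ12, ψ21) while *preserving the awareness
label*, and P resolves awareness within the current state. Events are
error-free: A1 → code 1, A2 → code 2, others → code 0. Because the
release state is observed without error, the initial-state probability
π1 factors out of the conditional likelihood; it is a constant (not
estimated) by default, with `free_pi1=True` adding the π1/(1−π1) term
for users who want it in the objective.

## Parameters, effects and links

| symbol | meaning | default structure |
|---|---|---|
| φ (`phi`) | survival per interval t → t+1 | constant; `time` → one per interval 1..K−1 |
| φ1/φ2 (`phi1`, `phi2`) | survival of newly marked vs previously marked animals | enabled by `transience` on φ |
| p (`p`) | capture probability, trap-unaware, occasions 2..K | constant; `time` → one per occasion |
| p′ (`pprime`) | capture probability, trap-aware | enabled by `trap` on p; without it the model is the naive CJS |
| m (`m`) | additive trap effect: logit p′_t = logit p_t + m | enabled by `additive` (requires `time` and `trap`) |
| ψ12, ψ21 | between-state transitions | two-state only, constant |
| π1 | P(release in state 1) | two-state, constant by default (see above) |

All probabilities are estimated on the logit scale; `m` lives on the
logit-difference (identity-link) scale, so one shared `m` across
occasions is exactly "time and trap effects additive". Transience is
the standard two-class time-since-first-release device: the interval
immediately after an animal's first capture carries φ1, all later
intervals φ2 — transients depress φ1 only. Time-varying survival is
indexed by interval (t spans t⁺ to (t+1)⁻); capture parameters attach to
the occasion at the interval's end (2..K, since occasion-1 captures are
conditioned on).

## Fitting and uncertainty

The negative log-likelihood (aggregated over identical histories,
count-weighted) is minimized by L-BFGS-B with central-difference
gradients (step 1e−6), ftol 1e−13, at most 500 iterations, starting from
0 on the link scale (0.5 on the probability scale); optional random
restarts are drawn N(0,1) from an explicit seed. Convergence is judged
by the gradient (sup-norm < 1e−4) rather than the optimizer's exit flag
alone — L-BFGS-B occasionally reports an abnormal line search at a point
that is already stationary under finite-difference noise; a Nelder-Mead
polish is used as fallback for genuine failures and non-convergence is
always reported, never silently accepted.

Standard errors come from the inverse of the numerical Hessian (central
differences, step 1e−4) at the MLE; 95% intervals are Wald on the link
scale, back-transformed, so they always lie in (0,1) and bracket the
estimate. Estimates with |logit| > 12 are flagged as boundary and their
intervals suppressed rather than fabricated. Intrinsic confounding
(e.g. the terminal φ_{K−1}·p_K product of a fully time-dependent model)
is detected from eigenvalues of the diagonal-scaled Hessian below 1e−6;
the parameters loading on near-null eigenvectors (|loading| > 0.3) are
listed in `rank_deficient` — reported, never silently constrained, also
because the handling of this confounding under additive time+trap
structures differs across existing software.

Model comparison uses AIC = −2ℓ + 2k with ties broken by fewer
parameters; a dataset digest guards against comparing fits on different
data.

## The split-history and naive CJS routes

The traditional treatment cuts each history after every capture: each
capture releases a fragment whose first post-release occasion carries p′
and whose later occasions carry p. Fragments that end at a recapture are
flagged as losses on capture, so the never-seen-again tail appears
exactly once (in the terminal fragment) — with this convention the
product of fragment likelihoods is algebraically identical to the
state-model likelihood. Transience splits accordingly: only the first
interval of an animal's *first* fragment carries φ1. Both the
split-history CJS and the naive CJS are implemented in closed product
form (survival terms, capture/miss terms, backward never-seen-again
recursion) with no shared code with the forward algorithm; numerical
agreement between the two routes (observed at ~1e−9 on estimates, ~1e−13
on log-likelihoods) is therefore an informative cross-check, and is
asserted in the test suite at 1e−4 / 1e−6.

## Test 2.CT

The diagnostic contrasts, at each occasion i = 2..K−2, animals captured
at i with animals not captured at i but known alive (captured before and
after), among those re-encountered after i: does the next encounter come
immediately (i+1) or later? Counts are weighted by history
multiplicities. Conventions, stated because variants circulate across
software:

- each informative 2×2 table contributes a **plain Pearson** chi-square
  component; tables with a zero margin are skipped and do not count
  toward df;
- when any expected cell is below 2 the component switches to Fisher's
  exact test, converted to a chi-square(1) equivalent via the inverse
  survival function;
- overall statistic = Σ components on df = number of informative tables;
- directional statistic z = Σ sign·√component / √df, positive =
  trap-happiness (captured-at-i animals recaptured immediately more
  often); two-sided p-values for both.

The Yates continuity correction is available (`continuity=True`,
`--continuity`) but is **off by default**: under the null (400
replicates, n = 1000, K = 8, φ = 0.8, p = p′ = 0.5) the corrected
version rejected at 1.5% against a nominal 5% while the uncorrected
components were close to nominal (3.25%, mean component ≈ 0.96), so the
uncorrected form is the calibrated default. Whether the directional
statistic should pool tables before or after signing differs across
descriptions of this test family; the convention above is declared, not
asserted to be the historical one, and the per-occasion tables are
printed so users can audit the construction.

## Simulator

The simulator draws from the exact generative process (release in A —
or A1/A2 by π1 — then S, T, P factors each interval; codes from the
degenerate event matrix), so inference tests have literal ground truth.
Transients are a mixture at release: with probability
`transient_fraction` an animal never survives its first interval, giving
apparent first-interval survival (1 − f)·φ; explicit φ1 may be supplied
instead. Removals are coin flips at each *recapture* (the marking
capture is never a removal). Reproducibility: one generator per
scenario, consumed in a fixed documented order — per-individual
transient and initial-state uniforms first, then a single
(individuals × intervals × 4) grid read individual-major,
occasion-minor with slots (survival, transition, capture, removal) —
so identical seeds give byte-identical output files.

What the simulator does **not** emulate: individual heterogeneity in φ
or p beyond the transient mixture, lasting or waning trap effects
(semi-Markov holding times in A — an extension hook, not implemented),
density dependence, covariates, unequal interval lengths, or
state-uncertain observations. Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness
to these departures.

## Numerical and design choices

- Probabilities produced from the link scale are clipped to
  [1e−12, 1 − 1e−12] inside the design transform only, keeping the
  additive-effect logit well-defined at extreme optimizer iterates.
- `expected_history_frequencies` enumerates hidden-state paths exactly
  and is restricted to K ≤ 6 (it exists as an oracle, not a production
  path).
- Degenerate inputs fail loudly: histories without captures, code 2
  under a single-state model, ragged `.inp` records, zero counts,
  duplicate long-CSV cells, K < 4 for Test 2.CT.
- Occasions are 1-based in every user-facing file, report and parameter
  name (`p_t2` is the capture probability at occasion 2).
- Sessions skipped in the field can be encoded by a time-dependent model
  with the corresponding p fixed near zero; a dedicated missing-occasion
  code is deliberately out of the data model.

## Study sizes used in tests and the acceptance script

Monte-Carlo checks use: oracle agreement at K = 4–5 over 50 random
parameter draws; formulation equivalence on one simulated dataset of 800
individuals over 8 occasions (truth φ1 = 0.6, φ2 = 0.85, p = 0.4,
p′ = 0.7); parameter recovery and naive-bias direction over 200
replicates of 500 individuals (truth φ = 0.8, p = 0.4, p′ = 0.7);
Test 2.CT calibration over 400 null replicates and power over 100
trap-happy replicates (p′ = 0.8, p = 0.3, n = 1000). These sizes give
Monte-Carlo errors comfortably below the assertion tolerances while the
whole suite runs in well under a minute on one CPU.

## Known limitations

- Only two states of interest are exposed in the tested surface (the
  S·T·P construction generalizes, but no more states are wired in).
- Wald intervals can be poor near boundaries; profile likelihood is not
  implemented (boundary flags are reported instead).
- The additive trap effect is shared across states in the two-state
  model; state-specific `m` requires supplying explicit p′ vectors.
- Goodness-of-fit is limited to Test 2.CT; the multistate omnibus test
  and the remaining single-site components are out of scope.
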