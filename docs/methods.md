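# Methods

## Model

Agents on an undirected, simple, connected graph accumulate ±1 signals and
synchronously share their full signal sets each step. The ground truth is
fixed internally to `X = +1`; "accuracy" always means positive orientation
(a relabelling flag would only change reporting, never the simulation).
Signals are informative, `p = Prob(s = +1 | X = +1) ∈ (1/2, 1)`; `p ≤ 1/2`
is rejected because the learning problem is only defined for informative
signals. A biased agent rejects each incongruent incoming signal with
probability `q` and stores a congruent one instead; its own stored signals
are never re-distorted — distortion applies to incoming signals only, so the
self-weight in the update is `1/(k_i+1)` for both agent kinds.

Two engines implement the same model:

- **Stochastic** (`run_stochastic`): exact integer signal counts; the number
  of flipped incongruent incoming signals per biased agent per step is an
  exact binomial draw. On a k-regular graph every total count after `t`
  steps is exactly `(k+1)^t`. Counts are tracked exactly up to totals of
  `2^40`; beyond that the engine switches (and logs the switch) to
  real-valued counts with Gaussian-approximated binomial noise of variance
  `q(1−q)M`, which is accurate precisely where the switch happens, since the
  binomial is then conditioned on huge `M`.
- **Deterministic** (`run_deterministic`): the ghost-node DeGroot update.
  The update is evaluated in vectorised sparse form — one adjacency matvec
  per step — and is algebraically identical to multiplying by the explicit
  `(n+2)×(n+2)` matrix from `build_update_matrix` (a test asserts step-level
  equality); the explicit matrix is used for influence-limit computations.

Orientations are recomputed synchronously after each full step, and a biased
agent distorts a step's incoming signals using the orientation it held
*before* the step — the convention that matches the matrix formulation,
where the ghost link in force during a step is the one set at its start.

Degenerate ties `x_i = 1/2` retain the previous orientation and emit a
warning: the model is meant to be run on configurations that exclude exact
ties, so a tie signals a measure-zero degenerate input rather than a state
to silently resolve.

Heterogeneous degrees (Erdős–Rényi, Barabási–Albert, small-world) use each
agent's own degree `k_i` in all weights (closed-neighbourhood averaging).
Generator defaults recorded in output metadata: BA attachment `m = k/2`,
small-world base degree `k` with rewiring probability 0.1, ER edge
probability `k/(n−1)`; `k` is the exact degree for k-regular graphs and the
target mean degree otherwise. Connectivity is enforced by retrying with
derived seeds (up to 100) because the steady-state results assume a single
component. The biased set has exactly `round(f·n)` members rather than
Bernoulli-per-node membership, removing a nuisance variance term from
ensemble statistics.

## Convergence and limits

A deterministic run converges when the max-norm step change falls below
`tol` (default 1e-10) **and** no orientation flipped in the final step;
hitting `max_iter` (default 1e5) flags the result instead of raising.
`t*` is the last step at which any biased agent flipped (0 if none did).
Limiting influence matrices are computed by repeated squaring of the
post-`t*` matrix until successive powers differ by less than 1e-12, which
converges in a few dozen squarings for every matrix this model produces.

## Mean-field layer and its validity

All closed forms are implemented as exact expressions of the stated
formulas. Two approximations matter in practice:

- **Cascade boundaries.** The printed piecewise prediction is: `Ŷ_B(0)`
  inside the boundaries, 1 above the *upper* boundary `1/(2(1−q))`, 0 below
  the *lower* boundary `(1−2q)/(2(1−q))`; for `q ≥ 1/2` the boundaries clip
  to `[0, 1]` and the mixed regime spans the whole interval (biased agents
  then convert at least half of incoming incongruent signals, so neither
  camp can be eradicated). Exactly at `q = 0` the cascade mechanism is
  absent — biased agents carry zero ghost weight, the dynamics is plain
  unbiased averaging, and consensus forms at `x̄(0) = f·Ŷ_B(0) + (1−f)p`
  rather than at 0/1. Phase-diagram scoring therefore treats `q = 0` as a
  degenerate limit outside the formula's domain and scores `q > 0` cells.
- **Individual-mix variance.** `σ² ≈ (f q²/k)·x(1−x)` is the leading term
  of a large-`k` expansion. Simulations at `n = 2000` show the realized
  variance exceeds it by a factor ≈ 1.1–1.3 at `k = 12` and ≈ 1.3–1.8 at
  `k = 6` (with near-zero excess kurtosis — a genuine width correction, not
  outliers), converging toward the formula as `k` grows.
  The `(f,k) → (2f,2k)` invariance is validated deep in the
  formula's regime (`k/f = 120`, `k ∈ {24, 48}`) on mean-centred samples:
  the claim is distributional identity at fixed mean mix, and uncentred
  two-sample tests at `n = 10⁴` mostly detect the ±0.001 run-to-run
  difference in realized initial-signal means.

Expected accuracy (`q > 1/2` regime, where `t* = 0` and the mean-mix
distribution keeps its initial-signal form) integrates the Gaussian accuracy
kernel over `N(p, p(1−p)/(fn))` truncated to `[0, 1]` and renormalized;
truncation keeps accuracy within `[0, 1]` and its error is negligible
whenever `fn·p(1−p) ≫ 1`. Quadrature is adaptive with absolute tolerance
1e-8 and break points at `x = p` and `x = 1/2` (where the kernel's σ → 0
endpoints make the integrand kink). For `q ≤ 1/2` the function raises
rather than silently extrapolating; extending via the cascade map is
possible but not implemented. `f*` is found by bounded golden-section
search on `f ∈ [0.01, 1]` to 1e-3.

## Echo-chamber conventions

A chamber is a connected set of unbiased agents whose external contacts are
all biased. Closure forces chambers to be full connected components of the
unbiased-induced subgraph. Conventions, recorded in report metadata:

- minimum size 2 (an unbiased node fully surrounded by biased agents is
  reported separately as *isolated*);
- non-empty biased boundary (at `f = 0` there are no chambers: chambers
  model biased gatekeeping);
- a chamber comprises **at most half of the unbiased population**. This is
  the finite-graph counterpart of the percolation picture in which chambers
  are finite clusters of the diluted unbiased subgraph and the giant
  component — the open society — is never a chamber. It is what makes the
  enclosed fraction `η_C` increase with `f` (bias fragments the unbiased
  subgraph) and decrease with `k` (connectivity re-knits it); without it,
  `η_C` degenerates to ≈ 1 − (isolated fraction) and trends the opposite
  way. The cost is that a graph whose entire unbiased population is one
  enclosed pocket has, by convention, no chamber.

Detection via connected components is validated against brute-force subset
enumeration of the definition (feasible to ~16 unbiased nodes). The
permeability relation uses the *realized* steady-state mixes of the boundary
agents, not their camp means. Echo-chamber ensemble experiments run near
the percolation threshold of the unbiased subgraph (`(1−f)k ≈ 2.4`, e.g.
`k = 4` at `f = 0.4`), where finite chambers exist in useful numbers; far
above threshold (`k = 6, f = 0.4` at `n = 1000`) chambers are vanishingly
rare.

## Experiment sizes and seeds

All drivers derive per-repetition seeds from a single user seed via
`SeedSequence`, echo them in metadata, and are bit-reproducible. Default
experiment sizes (n = 500–2000, tens to hundreds of repetitions, phase grids
of 11×11×10) were chosen so the full validation battery runs on a laptop in
a few minutes; the reference figure-scale parameterisations (n = 10³–10⁴)
remain available through `ModelConfig`. The variance-amplification and
camp-mix experiments use `k = 10` (their predictions are k-free in the
mean-field limit; the residual excess in the ensemble variance, ≈ 1.1–1.2×,
comes from dispersion in the biased agents' influence weights and shrinks
only slowly with `k`).

## What the synthetic networks do and do not capture

Generated networks are connected, simple, undirected, with uncorrelated
bias placement. They exercise degree heterogeneity (ER/BA/small-world) but
not degree–bias correlation, directed or weighted ties, temporal rewiring,
agent-specific `q`, or signal forgetting — all outside the model. Passing
tests therefore demonstrate internal consistency of dynamics and theory
under the model's assumptions, not fidelity to any particular empirical
social network.

## Known limitations

- The stochastic/deterministic correspondence is exact in expectation only
  in the linear (no-flip) regime; agents whose orientation switches resolve
  differently across stochastic realisations deviate systematically (a
  flipped biased agent locks onto the opposite ghost), and a single
  realisation retains an early-binomial noise floor that synchronous
  averaging never removes. Correspondence checks therefore compare the
  replicate-averaged trajectory and track orientation agreement separately.
- The `q ≤ 1/2` accuracy extension and analytic heterogeneous-degree
  corrections to the variance formulas are not implemented; those regimes
  are covered by simulation only.
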