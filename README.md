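# biasnet

Biased social learning on networks: a minimal agent-based model of how
confirmation bias reshapes the way a connected society aggregates
information, together with its complete analytic layer.

## The model

A network `G` of `n` agents tries to learn a binary ground truth `X = +1`.
At `t = 0` each agent receives an independent signal `s_i = ±1` that is
correct with probability `p > 1/2`. At every step all agents synchronously
share their full accumulated signal sets with their neighbours. An agent's
**signal mix** is `x_i(t) = N_i⁺/(N_i⁺ + N_i⁻)`, and its **orientation**
`y_i(t) = sign(x_i − 1/2)` is its Bayes-naive best guess of the truth.

A fraction `f` of agents is **biased**: each incoming signal incongruent
with their current orientation is rejected with probability `q` and replaced
by a congruent one, which they store and propagate. The stochastic process
converges to a deterministic DeGroot update `x̂(t) = Â(t) x̂(t−1)` on an
`(n+2)×(n+2)` row-stochastic matrix with two **ghost nodes** pinned at mixes
1 and 0: a biased agent down-weights each neighbour to `(1−q)/(k+1)` and
routes the remaining weight `kq/(k+1)` to the ghost matching its current
orientation, re-wiring whenever it switches sides.

The analytic layer provides, in closed form:

- steady-state camp mixes `(x̂_U*, x̂_B+*, x̂_B−*) = (Ŷ_B, (1−q)Ŷ_B + q, (1−q)Ŷ_B)`;
- cascade boundaries `(1−2q)/(2(1−q)) ≤ Ŷ_B(0) ≤ 1/(2(1−q))` separating
  consensus from mixed steady states;
- the `1/f` amplification of the wisdom-of-crowds variance,
  `x̂_U* ~ N(p, p(1−p)/(fn))`;
- the persistent individual-mix variance `σ² ≈ (f q²/k)·x(1−x)` — the
  bias–connectivity trade-off;
- expected polarization `erfc((x̂_U* − 1/2)/(√2 σ))/2` and expected accuracy
  `A = ½∫ P(x) erfc((1/2 − x)/(√2 σ_x)) dx`, which peaks at an interior
  optimal biased fraction `f*`.

An `echo` module detects **echo chambers** — minority pockets of unbiased
agents whose only outside contacts are biased gatekeepers — and tests the
permeability relation `x_C* = q·x_∂C* + (1−q)·x_U*`.

## Worked example

```python
import numpy as np
import biasnet as bn

cfg = bn.ModelConfig(n=1000, k=6, f=0.4, q=0.6, p=0.51, seed=7)
net, signals, state = bn.run_once(cfg)
x_u = np.mean(state.x_star[sorted(net.unbiased)])
print(state.t_star, state.y_biased_frac, x_u, bn.realized_accuracy(state, net))
```

prints (see `examples/01_single_run.py`):

```
converged            : True after 82 steps
last biased flip t*  : 0
Y_B* (biased + frac) : 0.510
mean unbiased mix    : 0.500
unbiased accuracy    : 0.473
unbiased polarization: 0.473
```

With `q > 1/2` no biased agent ever switches (`t* = 0`), the unbiased mix
settles at the biased agents' initial positive fraction (0.510 here — a run
whose 400 biased agents drew signals barely better than a coin flip), and
nearly half the unbiased population ends up on the wrong side: a sharply
polarized steady state despite informative signals. `examples/` contains
one script per capability (mean-field layer, phase diagram, accuracy
optimum `f*`, echo chambers), and the `biasnet` CLI exposes the same
drivers (`biasnet simulate|sweep|ensemble|accuracy|echo|predict`).

## Layout

- `src/biasnet/netgen.py` — network generators, biased-set assignment, signals
- `src/biasnet/dynamics.py` — stochastic engine, ghost-node DeGroot model,
  influence-matrix limits
- `src/biasnet/meanfield.py` — all closed-form predictions
- `src/biasnet/echo.py` — echo-chamber detection and permeability
- `src/biasnet/experiments.py` — seeded ensemble drivers and sweeps
- `src/biasnet/io.py`, `src/biasnet/cli.py` — file formats and the thin CLI
- `docs/methods.md` — model assumptions, conventions and numerical choices
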