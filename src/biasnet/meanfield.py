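"""Closed-form mean-field predictions.

All analytic results of the model live here, as pure functions of the scalar
parameters:

- subpopulation steady-state mixes (x̂_U*, x̂_B+*, x̂_B-*) as functions of the
  settled biased orientation fraction Ŷ_B and q;
- the cascade phase boundaries in Ŷ_B(0)-space and the piecewise prediction
  of the unbiased steady-state mix;
- the variance p(1-p)/(fn) of the ensemble-mean unbiased mix (the f^-1
  amplification of the wisdom-of-crowds variance);
- the individual-mix variance (f q^2 / k) x(1-x) — the bias–connectivity
  trade-off;
- expected polarization and expected accuracy (closed form for f = 0,
  Gaussian-mixture quadrature for f > 0) and the accuracy-optimal biased
  fraction f*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats


@dataclass
class MeanFieldPrediction:
    """Bundle of analytic predictions for one parameter set."""

    x_u_star: float
    x_bpos_star: float
    x_bneg_star: float
    lower_boundary: float
    upper_boundary: float
    var_global: float
    var_individual: float
    accuracy: float
    f_star: float | None = None


def subpopulation_mixes(y_biased_frac: float, q: float) -> tuple[float, float, float]:
    """Steady-state mixes (x̂_U*, x̂_B+*, x̂_B-*) given Ŷ_B(t*) and q.

    Unbiased agents settle at the settled biased orientation fraction; the
    positively (negatively) oriented biased camp is pulled distance q towards
    its ghost: ((1-q)Ŷ + q, (1-q)Ŷ).
    """
    if not 0.0 <= y_biased_frac <= 1.0 or not 0.0 <= q <= 1.0:
        raise ValueError("y_biased_frac and q must lie in [0, 1]")
    y = y_biased_frac
    return (y, (1.0 - q) * y + q, (1.0 - q) * y)


def cascade_boundaries(q: float) -> tuple[float, float]:
    """Cascade thresholds in Ŷ_B(0)-space, clipped to [0, 1].

    Between the boundaries the two biased camps coexist and the unbiased mix
    tracks Ŷ_B(0); outside them the majority camp converts the minority and
    the network cascades to consensus. For q >= 1/2 the mixed region is the
    whole interval: biased agents then convert at least half of the
    incongruent signals they receive, so neither camp can be eradicated.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if q >= 1.0:
        return (0.0, 1.0)
    lower = max(0.0, (1.0 - 2.0 * q) / (2.0 * (1.0 - q)))
    upper = min(1.0, 1.0 / (2.0 * (1.0 - q)))
    return (lower, upper)


def predict_unbiased_mix(y_biased_init: float, q: float) -> float:
    """Piecewise steady-state unbiased mix as a function of Ŷ_B(0).

    Returns Ŷ_B(0) inside the cascade boundaries, 1 above the upper boundary
    (positive cascade) and 0 below the lower one (negative cascade).
    """
    if not 0.0 <= y_biased_init <= 1.0:
        raise ValueError("y_biased_init must lie in [0, 1]")
    lower, upper = cascade_boundaries(q)
    if y_biased_init > upper:
        return 1.0
    if y_biased_init < lower:
        return 0.0
    return float(y_biased_init)


def global_mix_variance(p: float, n: int, f: float) -> float:
    """Variance of the ensemble-mean unbiased mix, p(1-p)/(fn).

    A biased fraction f amplifies the unbiased network's wisdom-of-crowds
    variance p(1-p)/n by the factor 1/f: the long-run mix is set by the fn
    initial signals of the biased agents alone. f = 0 returns the unbiased
    value p(1-p)/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    base = p * (1.0 - p) / n
    return base if f == 0.0 else base / f


def individual_mix_variance(x_u_star: float, f: float, q: float, k: float) -> float:
    """Variance of individual unbiased mixes, (f q^2 / k) x(1-x).

    Does not decay with n: polarization persists in the large-n limit.
    Invariant under (f, k) -> (cf, ck) — bias and connectivity trade off.
    """
    if not 0.0 <= x_u_star <= 1.0:
        raise ValueError("x_u_star must lie in [0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    return (f * q * q / k) * x_u_star * (1.0 - x_u_star)


def expected_polarization(x_u_star: float, sigma: float) -> float:
    """Expected minority fraction erfc(|x-1/2| / (sqrt(2) sigma)) / 2.

    Under the Gaussian approximation for individual mixes, the fraction of
    unbiased agents on the minority side of 1/2; 0 at consensus, 0.5 when the
    mean mix sits exactly at 1/2.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return 0.5 if x_u_star == 0.5 else 0.0
    z = float(special.erfc((x_u_star - 0.5) / (np.sqrt(2.0) * sigma)) / 2.0)
    return min(z, 1.0 - z)


def accuracy_unbiased(n: int, p: float) -> float:
    """Expected accuracy of an unbiased network, erfc((1-2p) sqrt(n/2)) / 2.

    An unbiased network reaches consensus on the sign of the initial mean
    mix, so its accuracy is the probability that the mean of n Bernoulli(p)
    signals exceeds 1/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(special.erfc((1.0 - 2.0 * p) * np.sqrt(n / 2.0)) / 2.0)


def _truncated_normal(p: float, n: int, f: float):
    mu = p
    sd = np.sqrt(global_mix_variance(p, n, f))
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def expected_accuracy(n: int, p: float, f: float, q: float, k: float) -> float:
    """Expected fraction of accurate unbiased agents for f > 0, q > 1/2.

    Averages the Gaussian accuracy kernel erfc((1/2 - x)/(sqrt(2) sigma_x))/2
    over the distribution of the mean unbiased mix x ~ N(p, p(1-p)/(fn))
    truncated to [0, 1], with sigma_x^2 = (f q^2/k) x(1-x). Valid in the
    q > 1/2 regime where biased orientations settle immediately (t* = 0) so
    the mean mix keeps its initial-signal distribution.
    """
    if f <= 0.0:
        raise ValueError("expected_accuracy requires f > 0; use accuracy_unbiased")
    if q <= 0.5:
        raise NotImplementedError(
            "expected_accuracy is implemented for q > 1/2 (the t* = 0 regime); "
            "for q <= 1/2 the mean-mix distribution must first be pushed through "
            "the cascade map of the phase boundaries"
        )
    dist = _truncated_normal(p, n, f)
    prefac = np.sqrt(f) * q / np.sqrt(k)

    def integrand(x: float) -> float:
        sig = prefac * np.sqrt(max(x * (1.0 - x), 0.0))
        if sig == 0.0:
            kernel = 2.0 if x > 0.5 else (1.0 if x == 0.5 else 0.0)
        else:
            kernel = special.erfc((0.5 - x) / (np.sqrt(2.0) * sig))
        return 0.5 * kernel * dist.pdf(x)

    val, _ = integrate.quad(
        integrand, 0.0, 1.0, points=[p, 0.5], epsabs=1e-8, limit=200
    )
    return float(min(max(val, 0.0), 1.0))


def optimal_bias_fraction(
    n: int, p: float, q: float, k: float, f_min: float = 0.01
) -> tuple[float, float]:
    """Accuracy-maximizing biased fraction f* and the accuracy it attains.

    Golden-section (bounded scalar) maximization of :func:`expected_accuracy`
    over f in (f_min, 1], to 1e-3 in f.
    """
    res = optimize.minimize_scalar(
        lambda f: -expected_accuracy(n, p, f, q, k),
        bounds=(f_min, 1.0),
        method="bounded",
        options={"xatol": 1e-3},
    )
    f_star = float(res.x)
    return f_star, float(-res.fun)


def predict(n: int, p: float, f: float, q: float, k: float,
            y_biased_init: float | None = None) -> MeanFieldPrediction:
    """Evaluate the full analytic layer for one parameter set."""
    y0 = p if y_biased_init is None else y_biased_init
    x_u = predict_unbiased_mix(y0, q)
    x_u_mix, x_bp, x_bn = subpopulation_mixes(x_u if q > 0.5 else y0, q)
    lower, upper = cascade_boundaries(q)
    var_g = global_mix_variance(p, n, f)
    var_i = individual_mix_variance(x_u, f, q, k)
    acc = accuracy_unbiased(n, p) if f == 0.0 else (
        expected_accuracy(n, p, f, q, k) if q > 0.5 else float("nan")
    )
    return MeanFieldPrediction(
        x_u_star=x_u_mix,
        x_bpos_star=x_bp,
        x_bneg_star=x_bn,
        lower_boundary=lower,
        upper_boundary=upper,
        var_global=var_g,
        var_individual=var_i,
        accuracy=acc,
    )
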