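"""Prior-predictive elicitation of the informative-prior hyperparameters.

The prior predictive density of one future unit-scale observation is the
mixture obtained by integrating the model against the informative prior:

    p(y) = [ a*a1*b1^a1 / (y*(b1 - ln y)^(a1+1))
           + b*a2*b2^a2 / (y*(b2 - ln y)^(a2+1))
           + c*a3*b3^a3 / (y*(b3 - ln y)^(a3+1)) ] / (a + b + c).

Each term has the closed-form antiderivative b^a * (b - ln y)^(-a), so
interval probabilities are exact.  Hyperparameters are elicited by matching
these interval probabilities to expert targets through the relative
squared-error objective  sum_z ((p(z) - p0(z)) / p(z))^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .types import IPHyper

#: Default root seed for the multistart optimizer.
DEFAULT_SEED = 20240406

#: log-space box constraint on every hyperparameter.
HYPER_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class PredictiveInterval:
    """An interval of (0, 1] with an expert-assessed predictive probability."""

    z1: float
    z2: float
    target_prob: float

    def __post_init__(self) -> None:
        if not (0 < self.z1 < self.z2 <= 1):
            raise ValueError(f"need 0 < z1 < z2 <= 1, got ({self.z1}, {self.z2})")
        if not (0 < self.target_prob < 1):
            raise ValueError("target probability must lie in (0, 1)")


def ppd_density(y, hyper: IPHyper):
    """Prior predictive density at unit-scale point(s) ``y`` in (0, 1)."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly in (0, 1)")
    h = hyper
    total = h.a + h.b + h.c
    dens = np.zeros_like(y)
    for w, am, bm in ((h.a, h.a1, h.b1), (h.b, h.a2, h.b2), (h.c, h.a3, h.b3)):
        # am*b^am/(y*(b - ln y)^(am+1)) evaluated in log space to avoid overflow
        log_term = (np.log(am) + am * np.log(bm) - np.log(y)
                    - (am + 1.0) * np.log(bm - np.log(y)))
        dens += w * np.exp(log_term)
    out = dens / total
    return float(out) if out.ndim == 0 else out


def ppd_neglog_density(u, hyper: IPHyper):
    """Prior predictive density of ``U = -ln Y`` at ``u > 0``.

    Equals ``y * ppd_density(y)`` with ``y = exp(-u)`` but remains evaluable
    for ``u`` beyond the underflow range of ``y`` (the predictive law has a
    slow logarithmic tail: a non-negligible share of its mass sits at ``y``
    values smaller than the tiniest positive double).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("u must be > 0")
    h = hyper
    total = h.a + h.b + h.c
    dens = np.zeros_like(u)
    for w, am, bm in ((h.a, h.a1, h.b1), (h.b, h.a2, h.b2), (h.c, h.a3, h.b3)):
        dens += w * am * bm**am * (bm + u) ** (-(am + 1.0))
    out = dens / total
    return float(out) if out.ndim == 0 else out


def _term_cdf(z: float, am: float, bm: float) -> float:
    """P(Y <= z) under one predictive mixture term: b^a * (b - ln z)^(-a)."""
    return np.exp(am * (np.log(bm) - np.log(bm - np.log(z))))


def ppd_interval_probability(z1: float, z2: float, hyper: IPHyper) -> float:
    """Exact predictive probability of ``z1 <= Y <= z2``."""
    if not (0 < z1 < z2 <= 1):
        raise ValueError(f"need 0 < z1 < z2 <= 1, got ({z1}, {z2})")
    h = hyper
    total = h.a + h.b + h.c
    prob = 0.0
    for w, am, bm in ((h.a, h.a1, h.b1), (h.b, h.a2, h.b2), (h.c, h.a3, h.b3)):
        prob += w * (_term_cdf(z2, am, bm) - _term_cdf(z1, am, bm))
    return prob / total


def elicitation_objective(hyper: IPHyper,
                          intervals: list[PredictiveInterval]) -> float:
    """Relative squared error between model and target interval probabilities."""
    total = 0.0
    for iv in intervals:
        p = ppd_interval_probability(iv.z1, iv.z2, hyper)
        if p <= 0:
            raise ValueError(f"zero predictive probability on ({iv.z1}, {iv.z2})")
        total += ((p - iv.target_prob) / p) ** 2
    return total


def _objective_logspace(log_x: np.ndarray,
                        intervals: list[PredictiveInterval],
                        fixed: dict[int, float] | None) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        x = np.exp(log_x)
    if not np.all(np.isfinite(x)):
        return 1e12
    full = list(x)
    if fixed:
        full = []
        it = iter(x)
        for pos in range(9):
            full.append(fixed[pos] if pos in fixed else next(it))
    try:
        hyper = IPHyper.from_tuple(full)
        return elicitation_objective(hyper, intervals)
    except (ValueError, FloatingPointError, OverflowError):
        return 1e12


def elicit_hyperparameters(intervals: list[PredictiveInterval],
                           init: IPHyper | None = None,
                           seed: int = DEFAULT_SEED,
                           n_starts: int = 20,
                           fixed: dict[int, float] | None = None) -> IPHyper:
    """Elicit hyperparameters by multistart Nelder-Mead on the log scale.

    ``init`` is always included among the starts, so the result never has a
    worse objective than ``init``.  ``fixed`` maps positions in the
    nine-vector (a1, b1, a2, b2, a3, b3, a, b, c) to frozen values, enabling
    reduced subproblems.  Deterministic for a given ``seed``.
    """
    if not intervals:
        raise ValueError("intervals list must be nonempty")
    fixed = dict(fixed) if fixed else {}
    free_idx = [pos for pos in range(9) if pos not in fixed]
    ndim = len(free_idx)
    if ndim == 0:
        raise ValueError("at least one hyperparameter must be free")

    rng = np.random.default_rng(seed)
    lo, hi = np.log(HYPER_BOUNDS[0]), np.log(HYPER_BOUNDS[1])
    starts = []
    if init is not None:
        starts.append(np.log(np.asarray(init.as_tuple())[free_idx]))
    starts.append(np.zeros(ndim))  # all-ones default
    while len(starts) < n_starts:
        # modest spread around O(1) values; extreme corners are never optimal
        starts.append(rng.uniform(np.log(0.05), np.log(20.0), size=ndim))

    best_x, best_f = None, np.inf
    for x0 in starts:
        f0 = _objective_logspace(x0, intervals, fixed)
        if f0 < best_f:
            best_x, best_f = np.asarray(x0, dtype=float), f0
        res = minimize(_objective_logspace, x0,
                       args=(intervals, fixed), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10,
                                "fatol": 1e-14, "adaptive": True})
        x = np.clip(res.x, lo, hi)
        f = _objective_logspace(x, intervals, fixed)
        if f < best_f:
            best_x, best_f = x, f
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("elicitation optimizer failed to find a finite objective")

    values = np.exp(best_x)
    full = []
    it = iter(values)
    for pos in range(9):
        full.append(fixed[pos] if pos in fixed else float(next(it)))
    return IPHyper.from_tuple(full)


def reference_intervals() -> list[PredictiveInterval]:
    """The packaged nine elicitation intervals with their target probabilities."""
    limits = [(0.05, 0.15), (0.15, 0.25), (0.25, 0.35), (0.35, 0.45),
              (0.45, 0.55), (0.55, 0.65), (0.65, 0.75), (0.75, 0.85),
              (0.85, 0.95)]
    targets = [0.08, 0.07, 0.06, 0.06, 0.065, 0.07, 0.08, 0.09, 0.10]
    return [PredictiveInterval(z1, z2, t)
            for (z1, z2), t in zip(limits, targets)]
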