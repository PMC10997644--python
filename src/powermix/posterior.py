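"""Exact posterior of the censored 3-component power mixture.

The censored likelihood expands the pooled survival term ``{S(t)}^{n-u}``
into a finite alternating triple sum over indices ``0 <= k <= j <= i <= n-u``.
Under any of the three supported priors each summand is a product of three
gamma kernels (for the shapes) and a Dirichlet kernel (for the weights), so
the posterior is a finite *signed* mixture of Gamma x Gamma x Gamma x
Dirichlet components.  Everything downstream — normalizer, moments, marginal
densities, Bayes estimators — reduces to signed sums over these components,
carried out in log space for stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, xlogy

from .types import (
    CensoredSummary,
    ImproperPosteriorError,
    MixtureParams,
    MomentOrderError,
    NumericalFailureError,
    PARAM_NAMES,
    PriorSpec,
)

logger = logging.getLogger(__name__)

#: Digits-lost threshold for the cancellation guard (in nats): if the signed
#: sum loses more than this much magnitude relative to the larger bucket,
#: the result is numerically meaningless in double precision.
CANCELLATION_GUARD = 30.0


def signed_logsumexp(log_abs: np.ndarray, signs: np.ndarray,
                     *, guard: float | None = CANCELLATION_GUARD) -> tuple[float, float]:
    """Stable signed sum ``sum(sign * exp(log_abs))`` in log space.

    Returns ``(log|S|, sign(S))`` with ``sign(S) = 0`` for an exactly empty
    sum.  Positive and negative terms are accumulated in separate log-sum-exp
    buckets and the difference is formed at the larger bucket's scale.  If
    more than ``guard`` nats of magnitude cancel, raises
    :class:`NumericalFailureError` (silent garbage is worse than failure).
    """
    log_abs = np.asarray(log_abs, dtype=float)
    signs = np.asarray(signs, dtype=float)

    def _lse(x: np.ndarray) -> float:
        if x.size == 0:
            return -np.inf
        hi = np.max(x)
        if not np.isfinite(hi):
            return hi
        return hi + np.log(np.sum(np.exp(x - hi)))

    lp = _lse(log_abs[signs > 0])
    ln = _lse(log_abs[signs < 0])
    if lp == -np.inf and ln == -np.inf:
        return -np.inf, 0.0
    scale = max(lp, ln)
    # difference of the two buckets at the dominant scale
    diff = np.exp(lp - scale) - np.exp(ln - scale)
    if diff == 0.0:
        raise NumericalFailureError(
            "signed sum cancelled to exactly zero in double precision")
    log_total = scale + np.log(abs(diff))
    if guard is not None and np.isfinite(scale) and scale - log_total > guard:
        raise NumericalFailureError(
            f"catastrophic cancellation: lost {scale - log_total:.1f} nats "
            f"(guard {guard}); consider extended precision")
    return log_total, float(np.sign(diff))


def _log_betaln3(a, b, c):
    """log of the trivariate beta function Gamma(a)Gamma(b)Gamma(c)/Gamma(a+b+c)."""
    return gammaln(a) + gammaln(b) + gammaln(c) - gammaln(a + b + c)


@dataclass(frozen=True)
class PosteriorComponent:
    """One (i, j, k) term of the signed posterior mixture."""

    i: int
    j: int
    k: int
    sign: int
    log_abs_weight: float
    A1: float
    A2: float
    A3: float
    B1: float
    B2: float
    B3: float
    A0: float
    B0: float
    C0: float


class SignedMixturePosterior:
    """Exact posterior as a finite signed mixture of Gamma^3 x Dirichlet laws.

    Component arrays are stored columnwise for vectorized signed summation;
    :attr:`components` materializes them as :class:`PosteriorComponent`
    records.  ``log_omega`` is the log of the (strictly positive) normalizer.
    """

    def __init__(self, prior: PriorSpec, summary: CensoredSummary,
                 i: np.ndarray, j: np.ndarray, k: np.ndarray,
                 signs: np.ndarray, log_abs_weight: np.ndarray,
                 shapes: tuple[float, float, float],
                 rates: tuple[np.ndarray, np.ndarray, np.ndarray],
                 dirichlet: tuple[np.ndarray, np.ndarray, np.ndarray],
                 log_omega: float):
        self.prior = prior
        self.summary = summary
        self.i, self.j, self.k = i, j, k
        self.signs = signs
        self.log_abs_weight = log_abs_weight
        self.A = shapes                      # scalar gamma shapes (A1, A2, A3)
        self.B = rates                       # per-component gamma rates
        self.dir_exponents = dirichlet       # per-component (A0, B0, C0)
        self.log_omega = log_omega

    # -- structure ---------------------------------------------------------

    @property
    def n_components(self) -> int:
        return self.signs.size

    @property
    def components(self) -> list[PosteriorComponent]:
        A1, A2, A3 = self.A
        B1, B2, B3 = self.B
        A0, B0, C0 = self.dir_exponents
        return [
            PosteriorComponent(
                int(self.i[v]), int(self.j[v]), int(self.k[v]),
                int(self.signs[v]), float(self.log_abs_weight[v]),
                A1, A2, A3, float(B1[v]), float(B2[v]), float(B3[v]),
                float(A0[v]), float(B0[v]), float(C0[v]))
            for v in range(self.n_components)
        ]

    def normalized_signed_weights(self) -> np.ndarray:
        """Signed component weights scaled to sum to one."""
        return self.signs * np.exp(self.log_abs_weight - self.log_omega)

    # -- signed expectations ----------------------------------------------

    def _signed_expectation(self, log_factor: np.ndarray) -> float:
        """sum over components of sign * |w| * exp(log_factor), over Omega."""
        log_val, sign = signed_logsumexp(self.log_abs_weight + log_factor,
                                         self.signs)
        return sign * np.exp(log_val - self.log_omega)

    def moment_lambda(self, m: int, r: float) -> float:
        """Posterior moment ``E(lambda_m^r)`` for real order ``r``."""
        if m not in (1, 2, 3):
            raise ValueError("component index m must be 1, 2 or 3")
        if r == 0:
            return 1.0
        A = self.A[m - 1]
        if A + r <= 0:
            raise MomentOrderError(
                f"E(lambda{m}^{r}) requires gamma shape + r > 0, but shape is "
                f"{A} under the {self.prior.label} prior")
        B = self.B[m - 1]
        log_factor = gammaln(A + r) - gammaln(A) - r * np.log(B)
        return self._signed_expectation(log_factor)

    def moment_proportion(self, s: int, r: float) -> float:
        """Posterior moment ``E(p_s^r)``; ``s = 3`` addresses ``1 - p1 - p2``."""
        if s not in (1, 2, 3):
            raise ValueError("proportion index s must be 1, 2 or 3")
        if r == 0:
            return 1.0
        A0, B0, C0 = self.dir_exponents
        alpha = (A0, B0, C0)[s - 1]
        total = A0 + B0 + C0
        if np.min(alpha) + r <= 0:
            raise MomentOrderError(
                f"E(p{s}^{r}) requires every Dirichlet exponent + r > 0; "
                f"minimum exponent is {np.min(alpha)} under the "
                f"{self.prior.label} prior")
        log_factor = (gammaln(alpha + r) - gammaln(alpha)
                      + gammaln(total) - gammaln(total + r))
        return self._signed_expectation(log_factor)

    def moment(self, param: str, r: float) -> float:
        """Posterior moment of a named parameter (``lambda1..3``, ``p1..p3``)."""
        if param in ("lambda1", "lambda2", "lambda3"):
            return self.moment_lambda(int(param[-1]), r)
        if param in ("p1", "p2", "p3"):
            return self.moment_proportion(int(param[-1]), r)
        raise ValueError(f"unknown parameter {param!r}")

    # -- marginal densities -------------------------------------------------

    def marginal_pdf(self, param: str, x) -> np.ndarray | float:
        """Marginal posterior density of one parameter at point(s) ``x``.

        A signed mixture of Gamma (shape-rate) pdfs for the lambdas and of
        Beta pdfs for the proportions, with the normalized signed weights.
        """
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        w = self.normalized_signed_weights()
        A0, B0, C0 = self.dir_exponents
        if param in ("lambda1", "lambda2", "lambda3"):
            if np.any(xv <= 0):
                raise ValueError("lambda support is (0, inf)")
            m = int(param[-1])
            A = self.A[m - 1]
            B = self.B[m - 1][:, None]
            logpdf = (A * np.log(B) - gammaln(A)
                      + (A - 1.0) * np.log(xv)[None, :] - B * xv[None, :])
        elif param in ("p1", "p2", "p3"):
            if np.any((xv <= 0) | (xv >= 1)):
                raise ValueError("proportion support is (0, 1)")
            s = int(param[-1])
            alpha = (A0, B0, C0)[s - 1]
            beta = (A0 + B0 + C0) - alpha
            a = alpha[:, None]
            b = beta[:, None]
            logpdf = (xlogy(a - 1.0, xv[None, :]) + xlogy(b - 1.0, 1.0 - xv[None, :])
                      - betaln(a, b))
        else:
            raise ValueError(f"unknown parameter {param!r}")
        dens = w @ np.exp(logpdf)
        return float(dens[0]) if scalar else dens

    # -- reporting ----------------------------------------------------------

    def describe(self) -> dict:
        """Summary dict: component count, normalizer, per-parameter mean/sd."""
        out = {
            "prior": self.prior.label,
            "n_components": self.n_components,
            "log_omega": self.log_omega,
        }
        for name in PARAM_NAMES:
            m1 = self.moment(name, 1)
            m2 = self.moment(name, 2)
            out[f"mean_{name}"] = m1
            out[f"sd_{name}"] = float(np.sqrt(max(m2 - m1 * m1, 0.0)))
        return out


def _prior_offsets(prior: PriorSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gamma shape offsets, gamma rate offsets, Dirichlet offsets) per prior."""
    if prior.family == "uniform":
        return np.ones(3), np.zeros(3), np.ones(3)
    if prior.family == "jeffreys":
        return np.zeros(3), np.zeros(3), np.ones(3)
    h = prior.hyper
    return (np.array([h.a1, h.a2, h.a3]),
            np.array([h.b1, h.b2, h.b3]),
            np.array([h.a, h.b, h.c]))


def build_posterior(summary: CensoredSummary, prior: PriorSpec) -> SignedMixturePosterior:
    """Construct the exact signed-mixture posterior for one prior choice.

    One component per index triple ``0 <= k <= j <= i <= n-u`` (so
    ``C(n-u+3, 3)`` components in total), with gamma shapes
    ``A_m = u_m + shape_offset``, gamma rates
    ``B_m = (index factor) * ln(1/t) + S_m + rate_offset`` and Dirichlet
    exponents ``(i-j+u1, j-k+u2, k+u3)`` plus the prior's Dirichlet offsets.
    """
    d_shape, d_rate, d_dir = _prior_offsets(prior)
    us = np.asarray(summary.us, dtype=float)
    Ss = np.asarray(summary.Ss, dtype=float)
    if prior.family == "jeffreys" and np.any(us < 1):
        raise ImproperPosteriorError(
            "Jeffreys prior requires at least one observed failure per "
            f"component; counts are {summary.us}")

    M = summary.n_censored
    L = summary.log_inv_t
    idx = np.array([(i, j, k)
                    for i in range(M + 1)
                    for j in range(i + 1)
                    for k in range(j + 1)], dtype=int).reshape(-1, 3)
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]

    shapes = tuple(us + d_shape)                      # scalars A1, A2, A3
    B1 = (i - j) * L + Ss[0] + d_rate[0]
    B2 = (j - k) * L + Ss[1] + d_rate[1]
    B3 = k * L + Ss[2] + d_rate[2]
    A0 = i - j + us[0] + d_dir[0]
    B0 = j - k + us[1] + d_dir[1]
    C0 = k + us[2] + d_dir[2]

    for m, (A, B) in enumerate(zip(shapes, (B1, B2, B3)), start=1):
        if A > 0 and np.any(B <= 0):
            raise ImproperPosteriorError(
                f"improper posterior: gamma rate B{m} is zero for some "
                f"component (u{m} = {summary.us[m-1]} with no censoring "
                "contribution and no informative rate)")

    log_binom = (gammaln(M + 1) - gammaln(i + 1) - gammaln(M - i + 1)
                 + gammaln(i + 1) - gammaln(j + 1) - gammaln(i - j + 1)
                 + gammaln(j + 1) - gammaln(k + 1) - gammaln(j - k + 1))
    log_gamma_part = sum(gammaln(A) - A * np.log(B)
                         for A, B in zip(shapes, (B1, B2, B3)))
    log_abs_weight = log_binom + log_gamma_part + _log_betaln3(A0, B0, C0)
    signs = np.where(i % 2 == 0, 1.0, -1.0)

    try:
        log_omega, omega_sign = signed_logsumexp(log_abs_weight, signs)
    except NumericalFailureError as err:
        raise NumericalFailureError(
            f"normalizer cancellation at n-u = {M}: {err}") from err
    if omega_sign <= 0:
        raise NumericalFailureError(
            f"normalizer is non-positive at n-u = {M}; posterior invalid")

    post = SignedMixturePosterior(prior, summary, i, j, k, signs,
                                  log_abs_weight, shapes, (B1, B2, B3),
                                  (A0, B0, C0), log_omega)
    resid = abs(post.normalized_signed_weights().sum() - 1.0)
    # roundoff in the signed sum is amplified by exp(scale gap); allow for it
    scale_gap = float(np.max(log_abs_weight) - log_omega)
    allowed = max(1e-10, 64.0 * signs.size * np.finfo(float).eps * np.exp(scale_gap))
    if resid > allowed:
        raise NumericalFailureError(
            f"normalized signed weights sum to 1 with residual {resid:.2e} "
            f"(allowed {allowed:.2e}) at n-u = {M}")
    return post


def summarize_censored(components, values, t: float, scale: str = "unit") -> CensoredSummary:
    """Reduce labeled lifetimes to the censored-sample sufficient statistics.

    On the unit scale a value is observed iff ``y <= t`` (ties observed) and
    contributes ``ln(1/y)``; values above ``t`` only increment the censored
    count (their labels are ignored, matching the pooled survival term of the
    likelihood).  On the negative-log scale (``x = ln(1/y)``) a value is
    observed iff ``x <= t`` and contributes ``x`` directly, with
    ``log_inv_t = t``.
    """
    components = np.asarray(components, dtype=int)
    values = np.asarray(values, dtype=float)
    if components.shape != values.shape or components.ndim != 1:
        raise ValueError("components and values must be matching 1-d sequences")
    if not np.all(np.isin(components, (1, 2, 3))):
        raise ValueError("component labels must be 1, 2 or 3")

    if scale == "unit":
        if np.any((values <= 0) | (values >= 1)):
            raise ValueError("unit-scale values must lie strictly in (0, 1)")
        if t <= 0:
            raise ValueError("censor time t must be > 0")
        if t >= 1:
            raise ValueError(
                "unit-scale censor time t >= 1 leaves nothing censored; use a "
                "value strictly below 1 instead")
        observed = values <= t
        contrib = np.log(1.0 / values)
        log_inv_t = float(np.log(1.0 / t))
    elif scale == "neglog":
        if np.any(values <= 0):
            raise ValueError("negative-log-scale values must be > 0")
        if t <= 0:
            raise ValueError("censor time t must be > 0")
        observed = values <= t
        contrib = values
        log_inv_t = float(t)
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'unit' or 'neglog'")

    n = values.size
    if np.any(~observed):
        logger.debug("ignoring component labels of %d censored units",
                     int(np.sum(~observed)))
    us, Ss = [], []
    for m in (1, 2, 3):
        mask = observed & (components == m)
        us.append(int(np.sum(mask)))
        Ss.append(float(np.sum(contrib[mask])))
    return CensoredSummary(n=n, log_inv_t=log_inv_t,
                           u1=us[0], u2=us[1], u3=us[2],
                           S1=Ss[0], S2=Ss[1], S3=Ss[2])


def log_likelihood(params: MixtureParams, summary: CensoredSummary) -> float:
    """Exact censored log-likelihood at ``params``.

    Includes the full data-dependent constant (the ``+ S_m`` terms arising
    from ``(lambda_m - 1) * sum ln y``) so AIC/BIC computed from this value
    are well defined.
    """
    L = summary.log_inv_t
    ll = 0.0
    for lam, p, um, sm in zip(params.lambdas, params.weights,
                              summary.us, summary.Ss):
        ll += um * (np.log(p) + np.log(lam)) - (lam - 1.0) * sm
    if summary.n_censored > 0:
        surv = 1.0 - sum(p * np.exp(-lam * L)
                         for lam, p in zip(params.lambdas, params.weights))
        if surv <= 0:
            raise ValueError(
                "mixture survival at the censor time is non-positive")
        ll += summary.n_censored * np.log(surv)
    return float(ll)
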