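"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's signed-mixture expansion: moments are
computed by dense midpoint quadrature of the *unexpanded* censored posterior
kernel on a truncated (lambda1, lambda2, lambda3, p1, p2) box, and small
censored powers are alternatively expanded by brute-force enumeration of the
multinomial product.  Both routes only assume the likelihood itself.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import betaln, gammaln


def _prior_offsets(prior):
    if prior.family == "uniform":
        return np.ones(3), np.zeros(3), np.ones(3)
    if prior.family == "jeffreys":
        return np.zeros(3), np.zeros(3), np.ones(3)
    h = prior.hyper
    return (np.array([h.a1, h.a2, h.a3]),
            np.array([h.b1, h.b2, h.b3]),
            np.array([h.a, h.b, h.c]))


def grid_moments(summary, prior, requests, n_lam=24, n_p=24, span=14.0):
    """Posterior moments by dense quadrature of the unexpanded kernel.

    ``requests`` is an iterable of ``(param, r)`` pairs with param in
    {lambda1..3, p1..3}.  Returns a dict mapping each pair to the moment.
    The kernel at a grid point is

        prod_m lam_m^(u_m + d_m - 1) e^(-lam_m (S_m + b_m))
        * p1^(u1+e1-1) p2^(u2+e2-1) p3^(u3+e3-1)
        * (1 - p1 q1 - p2 q2 - p3 q3)^(n-u),   q_m = exp(-lam_m ln(1/t)),

    i.e. the likelihood times the prior with no series expansion.
    Gauss-Legendre nodes are used per dimension; the weight simplex is
    mapped to the unit square via p1 = x, p2 = (1 - x) v (Jacobian 1 - x).
    """
    d_shape, d_rate, d_dir = _prior_offsets(prior)
    us = np.asarray(summary.us, float)
    Ss = np.asarray(summary.Ss, float)
    M = summary.n_censored
    L = summary.log_inv_t

    shapes = us + d_shape
    rates = Ss + d_rate
    nodes, gl_w = np.polynomial.legendre.leggauss(n_lam)
    # per-dimension grids covering the bulk of each gamma factor
    lam_grids, lam_weights = [], []
    for A, B in zip(shapes, rates):
        hi = (A + span * math.sqrt(max(A, 1.0))) / B
        mid = 0.5 * hi * (nodes + 1.0)
        w = 0.5 * hi * gl_w
        logw = (A - 1.0) * np.log(mid) - B * mid
        logw -= logw.max()
        lam_grids.append(mid)
        lam_weights.append(np.exp(logw) * w)

    nodes_p, gl_wp = np.polynomial.legendre.leggauss(n_p)
    x = 0.5 * (nodes_p + 1.0)
    wx = 0.5 * gl_wp
    X, V = np.meshgrid(x, x, indexing="ij")
    WX, WV = np.meshgrid(wx, wx, indexing="ij")
    p1v = X.ravel()
    p2v = ((1.0 - X) * V).ravel()
    p3v = 1.0 - p1v - p2v
    jac = (1.0 - X).ravel()
    e1, e2, e3 = us + d_dir
    logpw = ((e1 - 1.0) * np.log(p1v) + (e2 - 1.0) * np.log(p2v)
             + (e3 - 1.0) * np.log(p3v))
    logpw -= logpw.max()
    p_weight = np.exp(logpw) * jac * (WX * WV).ravel()

    q1 = np.exp(-lam_grids[0] * L)
    q2 = np.exp(-lam_grids[1] * L)
    q3 = np.exp(-lam_grids[2] * L)

    factors = {
        None: (None, None),
        "lambda1": (0, lam_grids[0]),
        "lambda2": (1, lam_grids[1]),
        "lambda3": (2, lam_grids[2]),
        "p1": (3, p1v), "p2": (3, p2v), "p3": (3, p3v),
    }
    acc = {("__Z__", 0): 0.0}
    for key in requests:
        acc[key] = 0.0

    w12 = np.einsum("a,b->ab", lam_weights[0], lam_weights[1])
    chunk = 64
    for start in range(0, p1v.size, chunk):
        sl = slice(start, min(start + chunk, p1v.size))
        surv = (1.0
                - p1v[sl][None, None, None, :] * q1[:, None, None, None]
                - p2v[sl][None, None, None, :] * q2[None, :, None, None]
                - p3v[sl][None, None, None, :] * q3[None, None, :, None])
        core = surv**M if M else np.ones_like(surv)
        core *= (w12[:, :, None, None] * lam_weights[2][None, None, :, None]
                 * p_weight[sl][None, None, None, :])
        acc[("__Z__", 0)] += core.sum()
        for (param, r) in requests:
            axis, grid = factors[param]
            if axis == 3:
                acc[(param, r)] += np.einsum("abcp,p->", core, grid[sl]**r)
            else:
                vec = grid**r
                sub = "abcp," + "abc"[axis] + "->"
                acc[(param, r)] += np.einsum(sub, core, vec)
    Z = acc.pop(("__Z__", 0))
    return {key: val / Z for key, val in acc.items()}


def enumeration_log_weights(summary, prior):
    """Posterior component weights by brute-force expansion of the censored power.

    ``{1 - p1 q1 - p2 q2 - p3 q3}^M`` is expanded by enumerating all ``4^M``
    factor choices (independent of the binomial-coefficient route), each term
    then integrating analytically against the prior.  Returns a dict mapping
    ``(c1, c2, c3)`` (per-component censor multiplicities) to the *signed*
    weight of that term group, and the total normalizer.
    """
    d_shape, d_rate, d_dir = _prior_offsets(prior)
    us = np.asarray(summary.us, float)
    Ss = np.asarray(summary.Ss, float)
    M = summary.n_censored
    L = summary.log_inv_t

    groups: dict[tuple[int, int, int], float] = {}
    for choice in itertools.product((0, 1, 2, 3), repeat=M):
        c = (choice.count(1), choice.count(2), choice.count(3))
        sign = (-1) ** (c[0] + c[1] + c[2])
        shapes = us + d_shape
        rates = Ss + d_rate + np.array(c) * L
        dirich = us + d_dir + np.array(c)
        log_term = (sum(gammaln(A) - A * math.log(B)
                        for A, B in zip(shapes, rates))
                    + gammaln(dirich[0]) + gammaln(dirich[1]) + gammaln(dirich[2])
                    - gammaln(dirich.sum()))
        groups[c] = groups.get(c, 0.0) + sign * math.exp(log_term)
    return groups, sum(groups.values())


def beta_moment(alpha, beta, r):
    """E(X^r) for X ~ Beta(alpha, beta), any real r > -alpha."""
    return math.exp(betaln(alpha + r, beta) - betaln(alpha, beta))


def gamma_moment(shape, rate, r):
    """E(X^r) for X ~ Gamma(shape, rate), any real r > -shape."""
    return math.exp(gammaln(shape + r) - gammaln(shape) - r * math.log(rate))
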