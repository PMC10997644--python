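"""Bayes estimators and posterior risks under four loss functions.

For a posterior with moments ``E(theta^r)`` the estimators are

=====  =======================  ==================================
loss   Bayes estimate           posterior risk at that estimate
=====  =======================  ==================================
SELF   E(theta)                 Var(theta)
QLF    E(theta^-1)/E(theta^-2)  1 - E(theta^-1)^2 / E(theta^-2)
PLF    sqrt(E(theta^2))         2*sqrt(E(theta^2)) - 2*E(theta)
DLF    E(theta^2)/E(theta)      Var(theta)/E(theta^2)
=====  =======================  ==================================

All moments come from the signed-mixture posterior, so the same code serves
every prior.
"""

from __future__ import annotations

import math

import pandas as pd

from .posterior import SignedMixturePosterior, build_posterior
from .types import CensoredSummary, MomentOrderError, PARAM_NAMES, PriorSpec

LOSS_FUNCTIONS = ("SELF", "QLF", "PLF", "DLF")

#: Moment orders each loss requires.
_LOSS_ORDERS = {
    "SELF": (1, 2),
    "QLF": (-1, -2),
    "PLF": (1, 2),
    "DLF": (1, 2),
}


def _check_loss(loss: str) -> str:
    if loss not in LOSS_FUNCTIONS:
        raise ValueError(f"unknown loss {loss!r}; expected one of {LOSS_FUNCTIONS}")
    return loss


def _moments(post: SignedMixturePosterior, param: str, loss: str) -> dict[float, float]:
    try:
        return {r: post.moment(param, r) for r in _LOSS_ORDERS[loss]}
    except MomentOrderError as err:
        raise MomentOrderError(f"{loss} for {param}: {err}") from err


def bayes_estimate(post: SignedMixturePosterior, param: str, loss: str) -> float:
    """Bayes estimate of ``param`` under ``loss``."""
    _check_loss(loss)
    m = _moments(post, param, loss)
    if loss == "SELF":
        return m[1]
    if loss == "QLF":
        return m[-1] / m[-2]
    if loss == "PLF":
        return math.sqrt(m[2])
    return m[2] / m[1]  # DLF


def posterior_risk(post: SignedMixturePosterior, param: str, loss: str) -> float:
    """Posterior expected loss at the Bayes estimate of the same loss."""
    _check_loss(loss)
    m = _moments(post, param, loss)
    if loss == "SELF":
        return m[2] - m[1] ** 2
    if loss == "QLF":
        return 1.0 - m[-1] ** 2 / m[-2]
    if loss == "PLF":
        return 2.0 * math.sqrt(m[2]) - 2.0 * m[1]
    return (m[2] - m[1] ** 2) / m[2]  # DLF


class EstimateTable:
    """Long-format table of (prior, loss, parameter) -> (estimate, risk).

    Rows whose moment orders are unsatisfiable carry NaN values with the
    failure reason in the ``status`` column — never silent omission.
    """

    COLUMNS = ("prior", "loss", "parameter", "estimate", "posterior_risk", "status")

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def get(self, prior: str, loss: str, param: str) -> tuple[float, float]:
        """(estimate, risk) for one cell; prior given as label (UP/JP/IP)."""
        sel = self.frame[(self.frame["prior"] == prior)
                         & (self.frame["loss"] == loss)
                         & (self.frame["parameter"] == param)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({prior}, {loss}, {param})")
        row = sel.iloc[0]
        return float(row["estimate"]), float(row["posterior_risk"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "EstimateTable":
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def estimate_all(summary: CensoredSummary,
                 priors: list[PriorSpec],
                 losses: list[str]) -> EstimateTable:
    """Bayes estimates and posterior risks for every (prior, loss, parameter)."""
    if not priors:
        raise ValueError("priors list must be nonempty")
    if not losses:
        raise ValueError("losses list must be nonempty")
    for loss in losses:
        _check_loss(loss)
    rows = []
    for prior in priors:
        post = build_posterior(summary, prior)
        for loss in losses:
            for param in PARAM_NAMES:
                try:
                    be = bayes_estimate(post, param, loss)
                    pr = posterior_risk(post, param, loss)
                    rows.append({"prior": prior.label, "loss": loss,
                                 "parameter": param, "estimate": be,
                                 "posterior_risk": pr, "status": "ok"})
                except MomentOrderError as err:
                    rows.append({"prior": prior.label, "loss": loss,
                                 "parameter": param, "estimate": float("nan"),
                                 "posterior_risk": float("nan"),
                                 "status": f"unavailable: {err}"})
    return EstimateTable.from_rows(rows)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC and BIC: ``(2k - 2*loglik, k*ln(n) - 2*loglik)``."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n) - 2.0 * loglik
    return aic, bic
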