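"""Domain types shared across the package.

All inference is parameterized by ``Theta = (lambda1, lambda2, lambda3, p1, p2)``,
the shape parameters and mixing weights of a 3-component mixture of power
distributions on (0, 1), with implied third weight ``p3 = 1 - p1 - p2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class PowermixError(Exception):
    """Base class for all package-specific errors."""


class ImproperPosteriorError(PowermixError):
    """The posterior does not normalize (a gamma rate is zero with positive shape)."""


class NumericalFailureError(PowermixError):
    """Catastrophic cancellation in the alternating-sign summation."""


class MomentOrderError(PowermixError):
    """A requested posterior moment order violates a shape-positivity constraint."""


@dataclass(frozen=True)
class MixtureParams:
    """Parameter vector of the 3-component mixture of power distributions.

    ``lambda1..lambda3`` are the per-component power shapes; ``p1``/``p2`` are
    mixing weights with ``p3 = 1 - p1 - p2`` implied.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("mixing weights p1, p2 must be > 0")
        if self.p1 + self.p2 >= 1:
            raise ValueError("p1 + p2 must be < 1 so that p3 > 0")

    @property
    def p3(self) -> float:
        return 1.0 - self.p1 - self.p2

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


@dataclass(frozen=True)
class CensoredSummary:
    """Sufficient statistics of a labeled type-I right-censored sample.

    ``n`` test units, of which ``u1 + u2 + u3`` failed before the termination
    time and the remaining ``n - u`` are censored.  ``log_inv_t = ln(1/t)`` is
    the termination time on the canonical negative-log scale, and
    ``S_m = sum_w ln(1/y_mw)`` over the observed failures of component ``m``.

    Note: data entered on the negative-log scale (x = ln(1/y), censor at
    ``t_x``) have observed values x <= t_x and hence S_m <= u_m * t_x, while
    unit-scale data (observed y <= t) have S_m >= u_m * ln(1/t).  Both feed
    the same likelihood, so no directional constraint is enforced here.
    """

    n: int
    log_inv_t: float
    u1: int
    u2: int
    u3: int
    S1: float
    S2: float
    S3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("u1", "u2", "u3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.u > self.n:
            raise ValueError(f"u1+u2+u3 = {self.u} exceeds n = {self.n}")
        if self.log_inv_t < 0:
            raise ValueError("log_inv_t must be >= 0")
        for um, sm, name in ((self.u1, self.S1, "S1"),
                             (self.u2, self.S2, "S2"),
                             (self.u3, self.S3, "S3")):
            if sm < 0:
                raise ValueError(f"{name} must be >= 0")
            if (um == 0) != (sm == 0):
                raise ValueError(f"{name} must be zero iff its failure count is zero")

    @property
    def u(self) -> int:
        return self.u1 + self.u2 + self.u3

    @property
    def n_censored(self) -> int:
        return self.n - self.u

    @property
    def us(self) -> tuple[int, int, int]:
        return (self.u1, self.u2, self.u3)

    @property
    def Ss(self) -> tuple[float, float, float]:
        return (self.S1, self.S2, self.S3)


@dataclass(frozen=True)
class IPHyper:
    """Hyperparameters of the informative prior.

    Independent Gamma(a_m, b_m) (shape, rate) priors on the three power
    shapes and a bivariate Beta(a, b, c) (i.e. Dirichlet) prior on
    ``(p1, p2, 1 - p1 - p2)``.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    a3: float
    b3: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "b2", "a3", "b3", "a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be > 0")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a1, self.b1, self.a2, self.b2, self.a3, self.b3,
                self.a, self.b, self.c)

    @classmethod
    def from_tuple(cls, values) -> "IPHyper":
        return cls(*map(float, values))


PRIOR_FAMILIES = ("uniform", "jeffreys", "informative")

#: Short labels used in report tables.
PRIOR_LABELS = {"uniform": "UP", "jeffreys": "JP", "informative": "IP"}


@dataclass(frozen=True)
class PriorSpec:
    """A prior choice: uniform (UP), Jeffreys (JP), or informative (IP).

    UP: flat on all five parameters.  JP: 1/(lambda1*lambda2*lambda3), flat
    on the weights.  IP requires :class:`IPHyper`.
    """

    family: str
    hyper: IPHyper | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise ValueError(
                f"unknown prior family {self.family!r}; expected one of {PRIOR_FAMILIES}")
        if self.family == "informative" and self.hyper is None:
            raise ValueError("informative prior requires hyperparameters")

    @property
    def label(self) -> str:
        return PRIOR_LABELS[self.family]


#: Parameter names in canonical table order.
PARAM_NAMES = ("lambda1", "lambda2", "lambda3", "p1", "p2")
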