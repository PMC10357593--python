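"""Model parameters and their uncertainty distributions.

A cost-effectiveness model's inputs are point estimates (branch
probabilities, health-state utilities, unit costs) each of which may carry
second-order uncertainty expressed as a mean +/- SD with a named
distribution family.  Utilities live on (0, 1) and are given Beta
distributions; costs are positive and given Gamma distributions; branch
probabilities with no stated uncertainty are held fixed.  Distribution
parameters are recovered from the stated moments by the method of moments,
so the fitted analytic mean and SD reproduce the inputs exactly.
"""

from __future__ import annotations

import enum
import math
from fractions import Fraction
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InfeasibleMomentsError, ValidationError


class Family(str, enum.Enum):
    """Supported uncertainty distribution families."""

    GAMMA = "gamma"
    BETA = "beta"
    FIXED = "fixed"


class Role(str, enum.Enum):
    """What kind of model input a parameter is."""

    PROBABILITY = "probability"
    UTILITY = "utility"
    COST = "cost"


def fit_gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, rate) whose analytic mean and SD equal ``mean`` and ``sd``.

    shape = mean^2 / sd^2, rate = mean / sd^2.  Raises
    :class:`ValidationError` unless both moments are strictly positive.
    """
    if not (mean > 0):
        raise ValidationError(f"gamma fit requires mean > 0, got {mean}")
    if not (sd > 0):
        raise ValidationError(f"gamma fit requires sd > 0, got {sd}")
    var = sd * sd
    return mean * mean / var, mean / var


def fit_beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) whose analytic mean and SD equal ``mean`` and ``sd``.

    With k = mean(1-mean)/sd^2 - 1: alpha = mean*k, beta = (1-mean)*k.
    The moments are feasible only when sd^2 < mean(1-mean).
    """
    if not (0 < mean < 1):
        raise ValidationError(f"beta fit requires 0 < mean < 1, got {mean}")
    if not (sd > 0):
        raise ValidationError(f"beta fit requires sd > 0, got {sd}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise InfeasibleMomentsError(
            f"beta moments infeasible: sd^2 = {var:g} >= mean(1-mean) = {bound:g}"
        )
    k = bound / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's uncertainty: family plus (mean, sd) in natural units."""

    family: Family
    mean: float
    sd: float = 0.0
    name: str = ""  # carried along so error messages can name the parameter

    def __post_init__(self) -> None:
        label = f" for '{self.name}'" if self.name else ""
        if not math.isfinite(self.mean) or not math.isfinite(self.sd):
            raise ValidationError(f"non-finite moments{label}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0{label}, got {self.sd}")
        if self.family is Family.FIXED:
            if self.sd != 0:
                raise ValidationError(f"fixed distribution{label} requires sd = 0")
        else:
            fit = (
                fit_gamma_from_moments
                if self.family is Family.GAMMA
                else fit_beta_from_moments
            )
            try:
                fit(self.mean, self.sd)
            except ValidationError as exc:
                if self.name:
                    raise type(exc)(f"parameter '{self.name}': {exc}") from None
                raise

    @property
    def is_fixed(self) -> bool:
        return self.family is Family.FIXED

    def fitted(self) -> tuple[float, ...]:
        """Distribution parameters: (shape, rate), (alpha, beta) or (value,)."""
        if self.family is Family.GAMMA:
            return fit_gamma_from_moments(self.mean, self.sd)
        if self.family is Family.BETA:
            return fit_beta_from_moments(self.mean, self.sd)
        return (self.mean,)

    def analytic_moments(self) -> tuple[float, float]:
        """(mean, sd) implied by the fitted distribution parameters."""
        if self.family is Family.GAMMA:
            shape, rate = self.fitted()
            return shape / rate, math.sqrt(shape) / rate
        if self.family is Family.BETA:
            a, b = self.fitted()
            s = a + b
            return a / s, math.sqrt(a * b / (s * s * (s + 1.0)))
        return self.mean, 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values from the fitted distribution."""
        if n < 1:
            raise ValidationError(f"sample size must be >= 1, got {n}")
        if self.family is Family.GAMMA:
            shape, rate = self.fitted()
            return rng.gamma(shape, 1.0 / rate, size=n)
        if self.family is Family.BETA:
            a, b = self.fitted()
            return rng.beta(a, b, size=n)
        return np.full(n, self.mean)


def sample(spec: DistributionSpec, seed: int, n: int) -> np.ndarray:
    """Seed-reproducible draws from ``spec``'s fitted distribution."""
    return spec.sample(np.random.default_rng(seed), n)


@dataclass(frozen=True)
class Parameter:
    """A named model input with a role and an uncertainty specification."""

    name: str
    role: Role
    spec: DistributionSpec
    units: str = ""

    def __post_init__(self) -> None:
        if self.role is Role.PROBABILITY:
            # Branch probabilities carry no sampling distribution and stay
            # fixed in probabilistic sensitivity analysis.
            if not self.spec.is_fixed:
                raise ValidationError(
                    f"probability parameter '{self.name}' must be fixed, "
                    f"got family={self.spec.family.value}"
                )
            if not (0.0 <= self.spec.mean <= 1.0):
                raise ValidationError(
                    f"probability '{self.name}' outside [0, 1]: {self.spec.mean}"
                )
        elif self.role is Role.UTILITY:
            if not (0.0 <= self.spec.mean <= 1.0):
                raise ValidationError(
                    f"utility '{self.name}' outside [0, 1]: {self.spec.mean}"
                )
        elif self.role is Role.COST:
            if self.spec.mean < 0:
                raise ValidationError(
                    f"cost '{self.name}' must be >= 0: {self.spec.mean}"
                )

    @property
    def value(self) -> float:
        """Base-case (mean) value."""
        return self.spec.mean


def pool_utilities(values: Sequence[float]) -> float:
    """Arithmetic mean of utility scores, used to pool severity-specific
    utilities into a single health-state value.

    Utility scores are reported decimals, so each value is interpreted as
    the decimal its repr prints and the mean is taken in exact rational
    arithmetic, rounded once to float: pooling (0.57, 0.52) gives exactly
    0.545 rather than a result half an ulp off.
    """
    if len(values) == 0:
        raise ValidationError("cannot pool an empty sequence of utilities")
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"utility outside [0, 1]: {v}")
    total = sum(Fraction(repr(float(v))) for v in values)
    return float(total / len(values))


@dataclass(frozen=True)
class MoneyAdjustment:
    """Inflation adjustment and currency conversion of a historical cost.

    ``base_amount`` is in the source currency (e.g. Iranian Rials),
    ``inflation_factor`` the cumulative price multiplier from the base year
    to the target year, and ``exchange_rate`` the units of source currency
    per USD in the target year.
    """

    base_amount: float
    inflation_factor: float
    exchange_rate: float

    def __post_init__(self) -> None:
        if not (self.inflation_factor > 0):
            raise ValidationError(
                f"inflation_factor must be > 0, got {self.inflation_factor}"
            )
        if not (self.exchange_rate > 0):
            raise ValidationError(
                f"exchange_rate must be > 0, got {self.exchange_rate}"
            )


def adjust_cost(adj: MoneyAdjustment) -> float:
    """Adjusted USD amount: base * inflation_factor / exchange_rate."""
    return adj.base_amount * adj.inflation_factor / adj.exchange_rate
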