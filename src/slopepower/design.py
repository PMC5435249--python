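"""Domain types and validation for two-group nonparallel-slopes ANCOVA designs.

The model under study is a pair of simple linear regressions

    Y_1j = b01 + X_1j * b11 + e_1j,   Y_2k = b02 + X_2k * b12 + e_2k,

with iid N(0, sigma^2) errors and stochastic covariates X_1 ~ (theta1, tau1^2),
X_2 ~ (theta2, tau2^2).  The quantity of interest is the slope difference
b1D = b11 - b12, summarised by the standardized effect delta = b1D / sigma.
Every power computation in this package consumes a validated :class:`DesignSpec`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class DesignError(ValueError):
    """Base class for invalid design parameterizations."""


class NonPositiveVarianceError(DesignError):
    """A variance parameter (sigma^2, tau1^2 or tau2^2) is not strictly positive."""


class GroupSizeError(DesignError):
    """A group size is below 2; each group needs a nonzero covariate sum of squares."""


class DegreesOfFreedomError(DesignError):
    """Total sample size leaves no error degrees of freedom (n1 + n2 < 5)."""


class AlphaRangeError(DesignError):
    """Significance level outside the open interval (0, 1)."""


class PowerMethod(str, enum.Enum):
    """Which unconditional power function produced a result."""

    EXACT_KB = "exact_kb"
    APPROX_A = "approx_a"
    DUPONT_PLUMMER = "dupont_plummer"


#: Covariate distribution families supported by the simulation engine.
FAMILIES = ("normal", "beta", "exponential", "gamma", "laplace", "uniform")


@dataclass(frozen=True)
class EffectSpec:
    """Slope pair and error variance defining the interaction effect.

    Parameters
    ----------
    beta11, beta12
        Within-group regression slopes (response units per covariate unit).
    sigma2
        Error variance, strictly positive.
    beta01, beta02
        Group intercepts.  They enter only the data generator: no power
        function depends on them.
    """

    beta11: float
    beta12: float
    sigma2: float = 1.0
    beta01: float = 0.0
    beta02: float = 0.0

    @property
    def beta1d(self) -> float:
        """Slope difference b1D = b11 - b12."""
        return self.beta11 - self.beta12

    @property
    def beta0d(self) -> float:
        return self.beta01 - self.beta02

    @property
    def delta(self) -> float:
        """Standardized effect delta = (b11 - b12) / sigma."""
        return self.beta1d / math.sqrt(self.sigma2)

    @classmethod
    def from_delta(cls, delta: float) -> "EffectSpec":
        """Effect with the given standardized magnitude (b11 = delta, b12 = 0, sigma2 = 1)."""
        return cls(beta11=float(delta), beta12=0.0, sigma2=1.0)


@dataclass(frozen=True)
class CovariateSpec:
    """Stochastic covariate description for the two groups.

    Only the variances ``tau1_sq`` and ``tau2_sq`` enter the power functions;
    the means and the distributional family matter solely for simulation.
    ``family_params`` holds family-native parameters (e.g. the Beta shape
    pair); ``None`` selects the simulation module's defaults.
    """

    tau1_sq: float
    tau2_sq: float
    theta1: float = 0.0
    theta2: float = 0.0
    family: str = "normal"
    family_params: tuple | None = None


@dataclass(frozen=True)
class DesignSpec:
    """Complete parameterization of a two-group slope-heterogeneity design."""

    effect: EffectSpec
    covariates: CovariateSpec
    n1: int
    n2: int
    alpha: float = 0.05

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2

    @property
    def nu(self) -> int:
        """Error degrees of freedom, N - 4 (two intercepts and two slopes estimated)."""
        return self.n1 + self.n2 - 4

    @property
    def kappa1(self) -> int:
        return self.n1 - 1

    @property
    def kappa2(self) -> int:
        return self.n2 - 1

    @property
    def kappa(self) -> int:
        return self.kappa1 + self.kappa2

    @property
    def delta(self) -> float:
        return self.effect.delta


def make_design(
    delta: float | None = None,
    *,
    beta11: float | None = None,
    beta12: float = 0.0,
    sigma2: float = 1.0,
    tau1_sq: float = 1.0,
    tau2_sq: float = 1.0,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    theta1: float = 0.0,
    theta2: float = 0.0,
    family: str = "normal",
) -> DesignSpec:
    """Convenience constructor: build and validate a design from scalars.

    Exactly one of ``delta`` or ``beta11`` must be given; ``delta`` implies
    ``beta11 = delta, beta12 = 0, sigma2 = 1``.
    """
    if (delta is None) == (beta11 is None):
        raise DesignError("specify exactly one of delta or beta11")
    if delta is not None:
        effect = EffectSpec.from_delta(delta)
    else:
        effect = EffectSpec(beta11=beta11, beta12=beta12, sigma2=sigma2)
    cov = CovariateSpec(
        tau1_sq=tau1_sq, tau2_sq=tau2_sq, theta1=theta1, theta2=theta2, family=family
    )
    return validate_design(DesignSpec(effect=effect, covariates=cov, n1=n1, n2=n2, alpha=alpha))


def validate_design(design: DesignSpec) -> DesignSpec:
    """Check every invariant of a design and return it unchanged.

    Raises a specific :class:`DesignError` subclass naming the first violated
    constraint.  Validation is idempotent: validating a validated design is a
    no-op.
    """
    if design.effect.sigma2 <= 0:
        raise NonPositiveVarianceError(f"sigma2 must be > 0, got {design.effect.sigma2}")
    if design.covariates.tau1_sq <= 0 or design.covariates.tau2_sq <= 0:
        raise NonPositiveVarianceError(
            f"covariate variances must be > 0, got "
            f"({design.covariates.tau1_sq}, {design.covariates.tau2_sq})"
        )
    if design.covariates.family not in FAMILIES:
        raise DesignError(f"unknown covariate family {design.covariates.family!r}")
    n1, n2 = design.n1, design.n2
    if int(n1) != n1 or int(n2) != n2:
        raise GroupSizeError(f"group sizes must be integers, got ({n1}, {n2})")
    if n1 < 2 or n2 < 2:
        raise GroupSizeError(f"each group needs at least 2 subjects, got ({n1}, {n2})")
    if n1 + n2 < 5:
        raise DegreesOfFreedomError(
            f"n1 + n2 must be >= 5 for positive error degrees of freedom, got {n1 + n2}"
        )
    if not (0.0 < design.alpha < 1.0):
        raise AlphaRangeError(f"alpha must lie in (0, 1), got {design.alpha}")
    return design


@dataclass(frozen=True)
class PowerResult:
    """A power value tagged with the method and design that produced it."""

    method: PowerMethod
    power: float
    design: DesignSpec
    numeric_detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.power <= 1.0 + 1e-12):
            raise ValueError(f"power outside [0, 1]: {self.power}")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a minimal-sample-size search at a fixed allocation ratio."""

    n1: int
    n2: int
    achieved_power: float
    target_power: float
    ratio: float
    method: PowerMethod
    iterations: int


__all__ = [
    "DesignError",
    "NonPositiveVarianceError",
    "GroupSizeError",
    "DegreesOfFreedomError",
    "AlphaRangeError",
    "PowerMethod",
    "FAMILIES",
    "EffectSpec",
    "CovariateSpec",
    "DesignSpec",
    "PowerResult",
    "SampleSizeResult",
    "make_design",
    "validate_design",
]
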