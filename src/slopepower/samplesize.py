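"""Minimal sample-size determination for a target power at a fixed allocation ratio.

Power is monotone increasing in n1 at a fixed ratio r = n2/n1, so the search
brackets the target by doubling n1 and then bisects.  A linear scan over
n1 = 2, 3, ... is the test oracle for this routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import (
    CovariateSpec,
    DesignError,
    DesignSpec,
    EffectSpec,
    PowerMethod,
    SampleSizeResult,
    validate_design,
)
from .power import QuadratureConfig, compute_power


@dataclass(frozen=True)
class SampleSizeRequest:
    """What to solve for: effect and covariates fixed, group sizes free.

    ``ratio`` is the allocation r = n2/n1; non-integer r*n1 is rounded up so
    the realized second group is never smaller than the requested ratio
    implies.
    """

    effect: EffectSpec
    covariates: CovariateSpec
    target_power: float
    alpha: float = 0.05
    ratio: float = 1.0
    method: PowerMethod = PowerMethod.EXACT_KB
    quad: QuadratureConfig | None = None
    max_n1: int = 10**6

    def __post_init__(self) -> None:
        if not (0.0 < self.target_power < 1.0):
            raise DesignError(f"target power must lie in (0, 1), got {self.target_power}")
        if self.target_power <= self.alpha:
            raise DesignError(
                f"target power {self.target_power} must exceed alpha {self.alpha}; "
                "the search is degenerate otherwise"
            )
        if self.ratio <= 0:
            raise DesignError(f"allocation ratio must be > 0, got {self.ratio}")


class SearchOverflowError(RuntimeError):
    """The target power is unreachable below the configured n1 cap."""


def _n2_for(n1: int, ratio: float) -> int:
    return max(2, math.ceil(ratio * n1 - 1e-9))


def _power_at(req: SampleSizeRequest, n1: int) -> float:
    design = DesignSpec(
        effect=req.effect,
        covariates=req.covariates,
        n1=n1,
        n2=_n2_for(n1, req.ratio),
        alpha=req.alpha,
    )
    return compute_power(validate_design(design), req.method, req.quad).power


def _min_valid_n1(ratio: float) -> int:
    """Smallest n1 with n1 >= 2, n2 >= 2 and n1 + n2 >= 5."""
    n1 = 2
    while n1 + _n2_for(n1, ratio) < 5:
        n1 += 1
    return n1


def find_sample_size(req: SampleSizeRequest) -> SampleSizeResult:
    """Smallest n1 (with n2 = ceil(r * n1)) whose power reaches the target.

    Returns the minimal design in the sense that one allocation step smaller
    (n1 - 1 with its own rounded n2), when valid, falls below the target.
    """
    lo = _min_valid_n1(req.ratio)
    iterations = 0

    # Bracket by doubling.
    hi = lo
    while True:
        iterations += 1
        if _power_at(req, hi) >= req.target_power:
            break
        if hi >= req.max_n1:
            raise SearchOverflowError(
                f"power {req.target_power} not attained by n1 = {req.max_n1}"
            )
        lo = hi + 1
        hi = min(2 * hi, req.max_n1)

    # Invariant: power(hi) >= target and either lo == minimum valid n1 with
    # power possibly >= target, or power(lo - 1) < target.  Bisect on n1.
    while lo < hi:
        mid = (lo + hi) // 2
        iterations += 1
        if _power_at(req, mid) >= req.target_power:
            hi = mid
        else:
            lo = mid + 1

    n1 = lo
    n2 = _n2_for(n1, req.ratio)
    achieved = _power_at(req, n1)
    return SampleSizeResult(
        n1=n1,
        n2=n2,
        achieved_power=achieved,
        target_power=req.target_power,
        ratio=req.ratio,
        method=req.method,
        iterations=iterations,
    )


__all__ = ["SampleSizeRequest", "SearchOverflowError", "find_sample_size"]
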