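"""The heterogeneity-of-slopes t test on raw two-group data.

Fits a separate least-squares line in each group, pools the residual sums of
squares into sigma2_hat = SSE / nu with nu = N - 4, and tests
H0: b11 = b12 with

    T = (b11_hat - b12_hat) / sqrt(sigma2_hat * (1/SSX1 + 1/SSX2)) ~ t(nu).

Fitting the equivalent dummy-variable interaction regression gives identical
slope difference, SSE and degrees of freedom; the separate-fits route is used
because it exposes the per-group quantities directly.  Also provides the
gamma-ratio-corrected unbiased estimator of the standardized effect delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class GroupData:
    """Per-group observations: covariate x and response y, paired by subject."""

    label: int
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 2:
            raise ValueError(f"group {self.label}: need at least 2 observations")
        if np.ptp(x) == 0:
            raise ValueError(f"group {self.label}: covariate is constant (zero SSX)")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class TwoLineFit:
    """Separate per-group OLS fits with pooled error sum of squares."""

    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    ssx: tuple[float, float]
    sse: float
    nu: int

    @property
    def beta1d_hat(self) -> float:
        return self.slopes[0] - self.slopes[1]

    @property
    def sigma2_hat(self) -> float:
        return self.sse / self.nu


@dataclass(frozen=True)
class SlopeTestResult:
    """Full output of the slope-heterogeneity test at level alpha."""

    fit: TwoLineFit
    t_stat: float
    p_value: float
    alpha: float
    reject: bool
    delta_hat_ue: float

    @property
    def nu(self) -> int:
        return self.fit.nu


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, SSX and residual SS of a single least-squares line."""
    xc = x - x.mean()
    ssx = float(xc @ xc)
    slope = float(xc @ y) / ssx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    return slope, intercept, ssx, float(resid @ resid)


def fit_two_lines(g1: GroupData, g2: GroupData) -> TwoLineFit:
    """Fit each group's regression line and pool the residual sums of squares."""
    n = len(g1) + len(g2)
    if n < 5:
        raise ValueError(f"need n1 + n2 >= 5 for positive degrees of freedom, got {n}")
    b1, a1, ssx1, rss1 = _ols_line(g1.x, g1.y)
    b2, a2, ssx2, rss2 = _ols_line(g2.x, g2.y)
    return TwoLineFit(
        slopes=(b1, b2),
        intercepts=(a1, a2),
        ssx=(ssx1, ssx2),
        sse=rss1 + rss2,
        nu=n - 4,
    )


def slope_heterogeneity_test(g1: GroupData, g2: GroupData, alpha: float = 0.05) -> SlopeTestResult:
    """Two-sided t test of equal within-group slopes."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    fit = fit_two_lines(g1, g2)
    se = np.sqrt(fit.sigma2_hat * (1.0 / fit.ssx[0] + 1.0 / fit.ssx[1]))
    t_stat = fit.beta1d_hat / se
    p_value = float(2.0 * stats.t.sf(abs(t_stat), fit.nu))
    t_crit = stats.t.isf(alpha / 2.0, fit.nu)
    return SlopeTestResult(
        fit=fit,
        t_stat=float(t_stat),
        p_value=p_value,
        alpha=alpha,
        reject=bool(abs(t_stat) > t_crit),
        delta_hat_ue=effect_size_unbiased(fit),
    )


def unbias_factor(nu: int | np.ndarray) -> float | np.ndarray:
    """Gamma-ratio correction c(nu) = Gamma(nu/2) / (sqrt(nu/2) Gamma((nu-1)/2)).

    Multiplying beta1d_hat / sigma_hat by c(nu) removes the upward bias of the
    plug-in effect estimate; c(nu) -> 1 as nu grows.  Computed with log-gamma
    differences so large nu does not overflow.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 2):
        raise ValueError("nu must be >= 2 for the first moment of t(nu) to exist")
    out = np.exp(gammaln(nu / 2.0) - gammaln((nu - 1.0) / 2.0)) / np.sqrt(nu / 2.0)
    return float(out) if out.ndim == 0 else out


def effect_size_unbiased(fit: TwoLineFit | SlopeTestResult) -> float:
    """Unbiased estimator of delta: c(nu) * beta1d_hat / sigma_hat."""
    if isinstance(fit, SlopeTestResult):
        fit = fit.fit
    return unbias_factor(fit.nu) * fit.beta1d_hat / np.sqrt(fit.sigma2_hat)


def read_group_csv(path) -> tuple[GroupData, GroupData]:
    """Read per-subject records from CSV with header ``group,x,y``.

    Group labels must be exactly {1, 2}; rows may appear in any order.
    """
    df = pd.read_csv(path)
    required = {"group", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"CSV must have columns {sorted(required)}, found {list(df.columns)}"
        )
    labels = set(df["group"].unique().tolist())
    if labels != {1, 2}:
        raise ValueError(f"group column must contain exactly labels 1 and 2, found {labels}")
    groups = []
    for label in (1, 2):
        sub = df[df["group"] == label]
        groups.append(GroupData(label=label, x=sub["x"].to_numpy(), y=sub["y"].to_numpy()))
    return tuple(groups)


__all__ = [
    "GroupData",
    "TwoLineFit",
    "SlopeTestResult",
    "fit_two_lines",
    "slope_heterogeneity_test",
    "unbias_factor",
    "effect_size_unbiased",
    "read_group_csv",
]
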