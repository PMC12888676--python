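"""Sample size, power and minimum detectable effect for linear regression
with an error-prone exposure.

The design question: a continuous outcome y with marginal variance
``sigma2_outcome`` is regressed on a person's mean of *m* biomarker
measurements.  Classical within-person error shrinks the observable slope by
the validity coefficient squared, rho^2(m), so a study needs n_z = n_x /
rho^2 subjects to retain the power it would have had with error-free
exposure (n_x).  The no-error sample size follows the standard normal-
approximation formula for testing a regression slope, with residual variance
sigma2_outcome - beta^2 * sigma2_between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .error_model import VarianceComponents, validity_coefficient

__all__ = [
    "TestSpec",
    "LinearDesign",
    "CONFIRMATORY",
    "EXPLORATORY",
    "n_no_error",
    "n_with_error",
    "mde_for_n",
    "sample_size_inflation",
    "power_for_design",
]


@dataclass(frozen=True)
class TestSpec:
    """Two-sided Type I error and target power for a slope test."""

    alpha: float = 0.01
    power: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.power <= self.alpha:
            raise ValueError("power must exceed alpha")

    @property
    def z_total(self) -> float:
        """z_{1-alpha/2} + z_{power}: the combined normal-quantile term."""
        return norm.ppf(1.0 - self.alpha / 2.0) + norm.ppf(self.power)


#: Confirmatory-study defaults: a previously suspected association is being
#: evaluated, so a stringent test level and high power are used.
CONFIRMATORY = TestSpec(alpha=0.01, power=0.90)
#: Exploratory-study defaults: conventional screening-level test and power.
EXPLORATORY = TestSpec(alpha=0.05, power=0.80)


@dataclass(frozen=True)
class LinearDesign:
    """A simple linear regression design with error-prone exposure.

    Parameters
    ----------
    sigma2_outcome
        Marginal variance of the continuous outcome (outcome units squared).
    beta
        True (or smallest detectable) slope, outcome units per ln-unit of
        exposure.  May be negative; only its magnitude enters power.
    vc
        Between/within variance components of the exposure biomarker.
    m
        Number of repeated measurements averaged per subject.
    n
        Number of subjects, when fixed (required by :func:`mde_for_n` and
        :func:`power_for_design`).
    """

    sigma2_outcome: float
    beta: float
    vc: VarianceComponents
    m: int = 1
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma2_outcome <= 0:
            raise ValueError("sigma2_outcome must be positive")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.vc.sigma2_between <= 0:
            raise ValueError("sigma2_between must be positive for design work")

    @property
    def residual_variance(self) -> float:
        """sigma2_outcome - beta^2 sigma2_between; must be positive."""
        resid = self.sigma2_outcome - self.beta**2 * self.vc.sigma2_between
        if resid <= 0:
            raise ValueError(
                "beta^2 * sigma2_between must be smaller than sigma2_outcome "
                "(residual outcome variance would be non-positive)"
            )
        return resid


def n_no_error(design: LinearDesign, test: TestSpec) -> float:
    """Subjects needed if exposure were measured without error (real-valued).

    n_x = (z_{1-alpha/2} + z_{power})^2 (sigma2_y - beta^2 sigma2_B)
          / (beta^2 sigma2_B).
    """
    if design.beta == 0:
        raise ValueError("beta must be non-zero for a sample-size calculation")
    effect_var = design.beta**2 * design.vc.sigma2_between
    return test.z_total**2 * design.residual_variance / effect_var


def n_with_error(design: LinearDesign, test: TestSpec) -> int:
    """Subjects needed given m error-prone measurements per subject.

    Inflates the no-error size by 1 / rho^2(m) and rounds half-up to the
    nearest integer.
    """
    rho2 = validity_coefficient(design.vc, design.m) ** 2
    return int(math.floor(n_no_error(design, test) / rho2 + 0.5))


def mde_for_n(design: LinearDesign, test: TestSpec) -> float:
    """Minimum detectable slope magnitude for a fixed-size study.

    The exact inverse of :func:`n_with_error` before rounding:

        beta_min = z_tot sqrt(sigma2_y / (sigma2_B (n rho^2(m) + z_tot^2)))

    Strictly decreasing in both n and m.
    """
    if design.n is None or design.n < 2:
        raise ValueError("mde_for_n requires a fixed n >= 2")
    rho2 = validity_coefficient(design.vc, design.m) ** 2
    z_tot = test.z_total
    return z_tot * math.sqrt(
        design.sigma2_outcome
        / (design.vc.sigma2_between * (design.n * rho2 + z_tot**2))
    )


def sample_size_inflation(icc: float, m: int) -> float:
    """Factor by which measurement error inflates the required sample size.

    n_z / n_x = 1 / rho^2(m) = (m ICC + 1 - ICC) / (m ICC); equals 1 when
    ICC = 1 (no within-person variability) and decreases toward 1 as repeats
    are added.
    """
    if not 0 < icc <= 1:
        raise ValueError(f"icc must be in (0, 1], got {icc}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return (m * icc + 1.0 - icc) / (m * icc)


def power_for_design(design: LinearDesign, alpha: float = 0.05) -> float:
    """Power of the two-sided slope test for a fully specified design.

    Normal approximation consistent with :func:`n_with_error`:
    Phi(|beta| sqrt(n rho^2 sigma2_B / (sigma2_y - beta^2 sigma2_B))
        - z_{1-alpha/2}).
    With beta = 0 this reduces to alpha/2, the probability of rejecting into
    one tail under the null.
    """
    if design.n is None:
        raise ValueError("power_for_design requires a fixed n")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rho2 = validity_coefficient(design.vc, design.m) ** 2
    ncp = abs(design.beta) * math.sqrt(
        design.n * rho2 * design.vc.sigma2_between / design.residual_variance
    )
    return float(norm.cdf(ncp - norm.ppf(1.0 - alpha / 2.0)))
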