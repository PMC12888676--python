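"""Variance-component arithmetic for classical measurement error in exposure.

A biomarker of exposure measured repeatedly on the same person fluctuates
around that person's long-run mean.  Under the classical error model a single
measurement is the true person-level mean plus independent, additive,
zero-mean noise, so the population of measurements decomposes into a
between-person variance ``sigma2_between`` (spread of true means) and a
within-person variance ``sigma2_within`` (spread of repeats around each
mean).  Everything this module computes — reliability of a single
measurement (ICC), validity of a mean of *m* repeats, the attenuation
(regression-dilution) factor, and the inverse solvers for the number of
repeats — is a function of those two variances and *m*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VarianceComponents",
    "ReliabilityQuery",
    "icc",
    "validity_coefficient",
    "repeats_for_validity",
    "attenuation_factor",
    "percent_bias",
    "repeats_for_max_bias",
    "bias_grid",
]

# Tolerance used when taking ceilings of analytically exact ratios, so that
# e.g. a required-repeats value of exactly 1.0 is not bumped to 2 by a last-bit
# rounding error.
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class VarianceComponents:
    """Between- and within-person variances of a (ln-scale) exposure biomarker.

    Parameters
    ----------
    sigma2_between
        Variance of true person-level mean exposures across the population,
        in squared ln-units.
    sigma2_within
        Variance of single measurements around a person's true mean
        (biological fluctuation plus assay noise), in squared ln-units.
    """

    sigma2_between: float
    sigma2_within: float

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma2_between + self.sigma2_within == 0:
            raise ValueError("at least one variance component must be positive")

    @classmethod
    def from_icc(cls, icc: float, sigma2_between: float) -> "VarianceComponents":
        """Build components from an ICC and a between-person variance.

        The within-person variance is derived as
        ``sigma2_between * (1 - icc) / icc``.  This is the parameterization
        used when a study reports a reliability coefficient together with a
        single variance that is taken, best-case, to be entirely
        between-person.
        """
        if not 0 < icc <= 1:
            raise ValueError(f"icc must be in (0, 1], got {icc}")
        if sigma2_between <= 0:
            raise ValueError("sigma2_between must be positive")
        return cls(sigma2_between, sigma2_between * (1.0 - icc) / icc)

    @property
    def icc(self) -> float:
        return icc(self)


@dataclass(frozen=True)
class ReliabilityQuery:
    """A (ICC, desired validity coefficient) pair for the repeats solver.

    Both quantities must lie strictly inside (0, 1): at the boundaries the
    required number of repeats is zero or diverges.
    """

    icc: float
    rho: float

    def __post_init__(self) -> None:
        if not 0 < self.icc < 1:
            raise ValueError(f"icc must be in (0, 1), got {self.icc}")
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")


def icc(vc: VarianceComponents) -> float:
    """Intraclass correlation coefficient: between / (between + within).

    The reliability of a single measurement; 0 when all variance is
    within-person, 1 when there is no within-person variability.
    """
    return vc.sigma2_between / (vc.sigma2_between + vc.sigma2_within)


def validity_coefficient(vc: VarianceComponents, m: float) -> float:
    """Correlation between the true mean and the mean of ``m`` measurements.

    rho(m) = sqrt(sigma2_B / (sigma2_B + sigma2_W / m)); strictly increasing
    in ``m`` and approaching 1 as repeats accumulate.  ``rho(1)**2`` equals
    the ICC.  Fractional ``m`` is accepted so the function is the exact
    algebraic inverse of :func:`repeats_for_validity` before rounding.
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return math.sqrt(
        vc.sigma2_between / (vc.sigma2_between + vc.sigma2_within / m)
    )


def repeats_for_validity(query: ReliabilityQuery) -> tuple[float, int]:
    """Number of repeats needed to reach a desired validity coefficient.

    Uses the reliability identity m = rho^2 (1 - ICC) / (ICC (1 - rho^2))
    (Fleiss).  Returns the real-valued solution together with its ceiling
    (minimum 1), the smallest whole number of samples that meets or exceeds
    the target.
    """
    m_real = (query.rho**2 * (1.0 - query.icc)) / (
        query.icc * (1.0 - query.rho**2)
    )
    m_int = max(1, math.ceil(m_real - _CEIL_EPS))
    return m_real, m_int


def attenuation_factor(vc: VarianceComponents, m: float) -> float:
    """Regression-dilution factor for a mean of ``m`` error-prone measurements.

    lambda = m sigma2_B / (m sigma2_B + sigma2_W).  The expected slope of a
    simple linear regression of the outcome on the measured mean exposure is
    lambda times the true slope; lambda is strictly increasing in ``m`` and
    equals 1 only when there is no within-person variance.
    """
    if vc.sigma2_between <= 0:
        raise ValueError("attenuation is undefined when sigma2_between is 0")
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    mb = m * vc.sigma2_between
    return mb / (mb + vc.sigma2_within)


def percent_bias(vc: VarianceComponents, m: float) -> float:
    """Expected percent attenuation of the regression slope, (1 - lambda) x 100.

    Equals (1 - ICC) x 100 at m = 1; decreases toward 0 as repeats are added.
    Returned as a real number — round only for display.
    """
    return (1.0 - attenuation_factor(vc, m)) * 100.0


def repeats_for_max_bias(vc: VarianceComponents, bias_max: float) -> int:
    """Smallest integer number of repeats keeping expected slope bias at or
    below ``bias_max`` percent.

    Solves (1 - lambda(m)) x 100 <= bias_max for m in closed form,
    m >= sigma2_W (100 - bias_max) / (sigma2_B x bias_max), then takes the
    ceiling.
    """
    if not 0 < bias_max < 100:
        raise ValueError(f"bias_max must be in (0, 100), got {bias_max}")
    if vc.sigma2_between <= 0:
        raise ValueError("attenuation is undefined when sigma2_between is 0")
    m_real = vc.sigma2_within * (100.0 - bias_max) / (
        vc.sigma2_between * bias_max
    )
    return max(1, math.ceil(m_real - _CEIL_EPS))


def bias_grid(
    icc_values: Iterable[float], m_values: Sequence[int]
) -> pd.DataFrame:
    """Expected percent slope bias over a grid of ICC and repeat counts.

    In terms of the ICC alone, bias = (1 - ICC) / (1 - ICC + m x ICC) x 100,
    which agrees with :func:`percent_bias` on any components having that ICC.
    Returns a long-format frame with columns ``icc``, ``m``, ``percent_bias``.
    """
    rows = []
    for icc_val in icc_values:
        if not 0 < icc_val < 1:
            raise ValueError(f"icc values must be in (0, 1), got {icc_val}")
        for m in m_values:
            if m < 1:
                raise ValueError(f"m values must be >= 1, got {m}")
            one_minus = 1.0 - icc_val
            pb = one_minus / (one_minus + m * icc_val) * 100.0
            rows.append({"icc": icc_val, "m": m, "percent_bias": pb})
    return pd.DataFrame(rows, columns=["icc", "m", "percent_bias"])
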