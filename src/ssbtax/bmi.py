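"""Log-normal population BMI model and overweight/obesity prevalence.

Each stratum's BMI distribution is log-normal, parameterized from its mean
and SD by moment matching:

    sigma^2 = ln(1 + sd^2 / mean^2),   mu = ln(mean) - sigma^2 / 2

A tax-induced mean BMI change shifts the distribution (SD preserved by
default; CV-preserving mode available), and prevalence in the overweight
(25 <= BMI < 30) and obese (BMI >= 30) bands is read off the CDF.

``sd = 0`` is accepted as the degenerate point-mass limit (sigma -> 0,
mu -> ln(mean)); it is used for closed-form oracles, not for real strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .demand import CohortStratum

#: WHO thresholds: overweight band lower/upper edge; obese above the upper
DEFAULT_THRESHOLDS: tuple[float, float] = (25.0, 30.0)


@dataclass(frozen=True)
class BMIDistribution:
    """Log-normal BMI distribution with natural-scale moments attached."""

    mean: float
    sd: float
    mu: float
    sigma: float

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "BMIDistribution":
        if mean <= 0:
            raise ValueError("BMI mean must be > 0")
        if sd < 0:
            raise ValueError("BMI sd must be >= 0")
        sigma2 = math.log1p((sd / mean) ** 2)
        sigma = math.sqrt(sigma2)
        mu = math.log(mean) - sigma2 / 2.0
        return cls(mean=mean, sd=sd, mu=mu, sigma=sigma)

    @property
    def implied_mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def implied_sd(self) -> float:
        return self.implied_mean * math.sqrt(math.expm1(self.sigma**2))

    def cdf(self, x: float) -> float:
        """P(X <= x)."""
        if x <= 0:
            return 0.0
        if self.sigma == 0.0:
            return 1.0 if math.log(x) >= self.mu else 0.0
        return float(ndtr((math.log(x) - self.mu) / self.sigma))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.sigma == 0.0:
            raise ValueError("point-mass distribution has no density")
        z = (np.log(x) - self.mu) / self.sigma
        return np.exp(-0.5 * z**2) / (x * self.sigma * math.sqrt(2.0 * math.pi))

    def prevalence_band(self, lo: float, hi: float = math.inf) -> float:
        """P(lo <= X < hi) from the log-normal CDF."""
        if lo >= hi:
            raise ValueError(f"band must have lo < hi, got [{lo}, {hi})")
        upper = 1.0 if math.isinf(hi) else self.cdf(hi)
        return upper - self.cdf(lo)

    def shift(self, delta_bmi: float, preserve: str = "sd") -> "BMIDistribution":
        """Shift the mean by ``delta_bmi``, holding SD (default) or CV fixed."""
        new_mean = self.mean + delta_bmi
        if new_mean <= 0:
            raise ValueError(f"shift {delta_bmi} drives BMI mean to {new_mean} <= 0")
        if preserve == "sd":
            new_sd = self.sd
        elif preserve == "cv":
            new_sd = self.sd * new_mean / self.mean
        else:
            raise ValueError("preserve must be 'sd' or 'cv'")
        return BMIDistribution.from_moments(new_mean, new_sd)


def fit_lognormal(mean: float, sd: float) -> BMIDistribution:
    """Moment-matched log-normal; see :class:`BMIDistribution`."""
    return BMIDistribution.from_moments(mean, sd)


def shift_distribution(
    dist: BMIDistribution, delta_bmi: float, preserve: str = "sd"
) -> BMIDistribution:
    return dist.shift(delta_bmi, preserve=preserve)


def prevalence_band(dist: BMIDistribution, lo: float, hi: float = math.inf) -> float:
    return dist.prevalence_band(lo, hi)


@dataclass(frozen=True)
class WeightStatusChange:
    """Prevalence (pp) and case-count changes; positive = reduction."""

    d_prev_overweight: float
    d_prev_obese: float
    d_cases_overweight: float
    d_cases_obese: float


def weight_status_changes(
    stratum: CohortStratum,
    delta_bmi: float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    preserve: str = "sd",
) -> WeightStatusChange:
    """Overweight/obesity changes from shifting a stratum's BMI distribution.

    Prevalence differences are pre − post in percentage points; case counts
    are population × (pre − post).  Note overweight prevalence can *rise*
    under a downward shift in high-BMI strata (obese crossing down into the
    overweight band); the two bands are computed independently.
    """
    lo, hi = thresholds
    pre = fit_lognormal(stratum.bmi_mean, stratum.bmi_sd)
    post = pre.shift(delta_bmi, preserve=preserve)
    d_ow = pre.prevalence_band(lo, hi) - post.prevalence_band(lo, hi)
    d_ob = pre.prevalence_band(hi) - post.prevalence_band(hi)
    return WeightStatusChange(
        d_prev_overweight=100.0 * d_ow,
        d_prev_obese=100.0 * d_ob,
        d_cases_overweight=stratum.population * d_ow,
        d_cases_obese=stratum.population * d_ob,
    )
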