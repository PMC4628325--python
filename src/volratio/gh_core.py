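"""Closed-form statistics for relative tumour-volume change.

Two volume measurements of the same lesion, :math:`X_1` at a reference
timepoint and :math:`X_2` at follow-up, are modelled as approximately
bivariate normal with means :math:`\\mu_i`, standard deviations
:math:`\\sigma_i`, coefficients of variation :math:`c_i = \\sigma_i/\\mu_i`
and correlation :math:`\\rho`.  Inference on the relative change
:math:`(X_2 - X_1)/X_1` is inference on the ratio :math:`W = X_2/X_1`,
which the Geary-Hinkley transformation

.. math::

    Z = \\frac{W\\mu_1 - \\mu_2}
             {\\sqrt{\\sigma_2^2 - 2W\\rho\\sigma_1\\sigma_2 + W^2\\sigma_1^2}}

maps to an approximately standard-normal deviate.  Inverting the
transformation yields a confidence interval for :math:`\\mu_2/\\mu_1` and,
under the no-change null (:math:`\\mu_1 = \\mu_2`, constant CV ``k``,
:math:`\\rho = 0`), a pair of decision thresholds on the observed ratio:
everything below the lower threshold is a significant decrease (partial
response), everything above the upper one a significant increase
(progressive disease).

With the CT volumetry repeatability documented for lung lesions
(``k = 0.3/1.96``, i.e. a ~15% standard deviation of repeated
measurements) and a 95% level, the thresholds come out at a 35% volume
decrease and a 55% volume increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "DEFAULT_CV",
    "RatioStatistics",
    "ConfidenceInterval",
    "ThresholdSet",
    "TestResult",
    "round_half_away",
    "normal_quantile",
    "gh_transform",
    "ratio_confidence_interval",
    "symmetric_thresholds",
    "pvalue_no_change",
    "power_at_ratio",
    "classify_change",
    "no_change_test",
]

#: Default measurement coefficient of variation: a 95% repeatability
#: half-width of 30% divided by 1.96, i.e. the ~15% standard deviation of
#: repeated CT volume measurements reported for lung lesions.
DEFAULT_CV = 0.3 / 1.96

# Range of CVs over which the normal approximation of Z is considered
# trustworthy; outside it we warn but never refuse to compute.
_CV_VALID_LOW = 0.005
_CV_VALID_HIGH = 0.39


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def normal_quantile(level: float) -> float:
    """Two-sided standard-normal quantile for a confidence ``level``.

    The 95% level returns the conventional 1.96 literally (not
    ``norm.ppf(0.975) = 1.95996...``) so that derived thresholds match the
    numbers clinicians quote; other levels use the exact quantile.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if abs(level - 0.95) < 1e-12:
        return 1.96
    return float(norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class RatioStatistics:
    """First-order statistics of the measurement pair (X1, X2).

    Parameters
    ----------
    mu1, mu2
        Expected volumes (cm^3) at the reference and follow-up timepoints.
    sigma1, sigma2
        Measurement standard deviations (cm^3).
    rho
        Correlation between the two measurement errors (default 0: the
        segmentations at the two timepoints are independent).
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ValueError(
                f"expected volumes must be positive, got mu1={self.mu1}, mu2={self.mu2}"
            )
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"correlation must lie in [-1, 1], got {self.rho}")

    @property
    def c1(self) -> float:
        """Coefficient of variation at the reference timepoint."""
        return self.sigma1 / self.mu1

    @property
    def c2(self) -> float:
        """Coefficient of variation at the follow-up timepoint."""
        return self.sigma2 / self.mu2

    @property
    def valid(self) -> bool:
        """Whether both CVs sit in the range where Z is near-normal."""
        return all(
            _CV_VALID_LOW < c < _CV_VALID_HIGH for c in (self.c1, self.c2)
        )

    def warn_if_outside_validity(self) -> None:
        if not self.valid:
            warnings.warn(
                "coefficients of variation "
                f"(c1={self.c1:.4g}, c2={self.c2:.4g}) fall outside "
                f"({_CV_VALID_LOW}, {_CV_VALID_HIGH}); the normal approximation "
                "of the transformed ratio may be poor",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ConfidenceInterval:
    """Confidence interval for the ratio of expected volumes mu2/mu1."""

    lower: float
    upper: float
    level: float
    t: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"interval limits out of order: [{self.lower}, {self.upper}]"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class ThresholdSet:
    """Decision thresholds on the observed volume ratio W = X2/X1.

    ``lower_ratio``/``upper_ratio`` are the exact critical ratios of the
    no-change test (used internally by every statistical computation);
    ``lower_pct``/``upper_pct`` are the integer percent-change thresholds
    used for reporting and clinical classification.
    """

    lower_ratio: float
    upper_ratio: float
    k: float
    level: float
    lower_pct: int
    upper_pct: int

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_ratio < 1.0 < self.upper_ratio:
            raise ValueError(
                "thresholds must straddle 1: "
                f"({self.lower_ratio}, {self.upper_ratio})"
            )

    @property
    def lower_ratio_rounded(self) -> float:
        """Lower critical ratio implied by the reported integer percent."""
        return 1.0 + self.lower_pct / 100.0

    @property
    def upper_ratio_rounded(self) -> float:
        """Upper critical ratio implied by the reported integer percent."""
        return 1.0 + self.upper_pct / 100.0


@dataclass(frozen=True)
class TestResult:
    """Outcome of the no-change test for one observed ratio."""

    observed_ratio: float
    z: float
    p_value: float
    rejected: bool
    category: str  # decrease | no-change | increase


def gh_transform(w: float, stats: RatioStatistics) -> float:
    """Geary-Hinkley transformation of an observed ratio ``w``.

    Returns the approximately standard-normal deviate
    ``(w*mu1 - mu2) / sqrt(sigma2^2 - 2*w*rho*sigma1*sigma2 + w^2*sigma1^2)``.

    Raises
    ------
    ValueError
        If the radicand of the denominator is not positive, which can only
        happen for extreme correlation/ratio combinations.
    """
    stats.warn_if_outside_validity()
    radicand = (
        stats.sigma2**2
        - 2.0 * w * stats.rho * stats.sigma1 * stats.sigma2
        + w**2 * stats.sigma1**2
    )
    if radicand <= 0.0:
        raise ValueError(
            "Geary-Hinkley denominator is not defined: radicand "
            f"{radicand:.4g} <= 0 for w={w}, rho={stats.rho}"
        )
    return (w * stats.mu1 - stats.mu2) / math.sqrt(radicand)


def ratio_confidence_interval(
    x1: float,
    x2: float,
    c1: float,
    c2: float,
    rho: float = 0.0,
    level: float = 0.95,
) -> ConfidenceInterval:
    """Confidence interval for mu2/mu1 from one measurement pair.

    Inverts the Geary-Hinkley transformation:

    ``(x2/x1) * (1 - t^2*rho*c1*c2 -/+ t*sqrt(c2^2 - 2*rho*c1*c2 + c1^2
    - t^2*c1^2*c2^2*(1-rho^2))) / (1 - t^2*c2^2)``

    where ``t`` is the two-sided normal quantile for ``level``.  With
    ``rho = 0`` and ``c1 = c2 = k`` this collapses to the symmetric form
    used for threshold derivation (see :func:`symmetric_thresholds`).

    Raises
    ------
    ValueError
        If ``t*c2 >= 1`` (the denominator ``1 - t^2*c2^2`` would be
        non-positive) or the radicand is negative.
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError(f"volumes must be positive, got x1={x1}, x2={x2}")
    if c1 < 0 or c2 < 0:
        raise ValueError("coefficients of variation must be non-negative")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    t = normal_quantile(level)
    denominator = 1.0 - t**2 * c2**2
    if denominator <= 0.0:
        raise ValueError(
            f"t*c2 = {t * c2:.4g} >= 1: the denominator 1 - t^2*c2^2 of the "
            "confidence limits is not positive; the follow-up CV is too "
            "large for this confidence level"
        )
    radicand = (
        c2**2
        - 2.0 * rho * c1 * c2
        + c1**2
        - t**2 * c1**2 * c2**2 * (1.0 - rho**2)
    )
    if radicand < 0.0:
        raise ValueError(
            f"negative radicand {radicand:.4g} in the confidence limits "
            f"(c1={c1}, c2={c2}, rho={rho}, t={t})"
        )
    w = x2 / x1
    centre = 1.0 - t**2 * rho * c1 * c2
    half = t * math.sqrt(radicand)
    return ConfidenceInterval(
        lower=w * (centre - half) / denominator,
        upper=w * (centre + half) / denominator,
        level=level,
        t=t,
    )


def symmetric_thresholds(k: float, level: float = 0.95) -> ThresholdSet:
    """Decision thresholds under the symmetric model (rho=0, c1=c2=k).

    The critical ratios of the no-change test are

    ``(1 -/+ t*sqrt(2k^2 - t^2*k^4)) / (1 - t^2*k^2)``

    the sign pattern following the general confidence-interval formula
    (the radical carries ``- t^2 k^4``, the ``+`` sits in front of it).
    They form an exact reciprocal pair: ``lower * upper = 1``.

    The integer percent thresholds exploit that reciprocity: the band is a
    single multiplicative factor ``f`` (``upper = f``, ``lower = 1/f``), so
    the upper percent is rounded half-away-from-zero and the lower percent
    is the change of the exact reciprocal of that rounded upper.  At the
    default ``k = 0.3/1.96`` this yields the (-35%, +55%) pair: a x1.55
    increase and its reciprocal /1.55 decrease.
    """
    if k <= 0:
        raise ValueError(f"coefficient of variation must be positive, got {k}")
    t = normal_quantile(level)
    if t * k >= 1.0:
        raise ValueError(
            f"t*k = {t * k:.4g} >= 1: no finite thresholds exist at this "
            "level; the measurement CV is too large"
        )
    radicand = 2.0 * k**2 - t**2 * k**4
    half = t * math.sqrt(radicand)
    denominator = 1.0 - t**2 * k**2
    lower_ratio = (1.0 - half) / denominator
    upper_ratio = (1.0 + half) / denominator
    upper_pct = round_half_away(100.0 * (upper_ratio - 1.0))
    lower_pct = round_half_away(100.0 * (1.0 / (1.0 + upper_pct / 100.0) - 1.0))
    return ThresholdSet(
        lower_ratio=lower_ratio,
        upper_ratio=upper_ratio,
        k=k,
        level=level,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
    )


def pvalue_no_change(w: float, k: float) -> float:
    """Two-sided p-value of the no-change test for an observed ratio ``w``.

    Under the null mu1 = mu2 with sigma_i = k*mu_i and rho = 0 the
    transformation reduces to ``z0 = (w - 1) / (k * sqrt(1 + w^2))`` and
    ``p = 2 * (1 - Phi(|z0|))``.
    """
    if w <= 0:
        raise ValueError(f"observed ratio must be positive, got {w}")
    if k <= 0:
        raise ValueError(f"coefficient of variation must be positive, got {k}")
    z0 = (w - 1.0) / (k * math.sqrt(1.0 + w * w))
    return float(2.0 * norm.sf(abs(z0)))


def power_at_ratio(
    r: float,
    k: float,
    thresholds: ThresholdSet | None = None,
    level: float = 0.95,
) -> float:
    """Probability of declaring change when the true volume ratio is ``r``.

    ``power(r) = Phi(z(w_L; r)) + 1 - Phi(z(w_U; r))`` where ``w_L, w_U``
    are the exact critical ratios and ``z(w; r) = (w - r)/(k*sqrt(r^2 + w^2))``
    is the transformation evaluated at mu2 = r*mu1, sigma_i = k*mu_i,
    rho = 0.  At r = 1 this is the size of the test (~ the nominal alpha);
    at either critical ratio it is ~50%.
    """
    if r <= 0:
        raise ValueError(f"true ratio must be positive, got {r}")
    if k <= 0:
        raise ValueError(f"coefficient of variation must be positive, got {k}")
    if thresholds is None:
        thresholds = symmetric_thresholds(k, level)

    def z(w: float) -> float:
        return (w - r) / (k * math.sqrt(r * r + w * w))

    return float(
        norm.cdf(z(thresholds.lower_ratio)) + norm.sf(z(thresholds.upper_ratio))
    )


def classify_change(
    w: float, thresholds: ThresholdSet, use_exact: bool = False
) -> str:
    """Categorize an observed ratio as decrease / no-change / increase.

    Clinical classification uses the reported integer-percent thresholds by
    default (e.g. 0.65 and 1.55); pass ``use_exact=True`` for the exact
    critical ratios.  A ratio exactly on a threshold is not a rejection and
    maps to ``"no-change"``.
    """
    if w <= 0:
        raise ValueError(f"observed ratio must be positive, got {w}")
    if use_exact:
        lo, hi = thresholds.lower_ratio, thresholds.upper_ratio
    else:
        lo, hi = thresholds.lower_ratio_rounded, thresholds.upper_ratio_rounded
    if w < lo:
        return "decrease"
    if w > hi:
        return "increase"
    return "no-change"


def no_change_test(w: float, k: float, level: float = 0.95) -> TestResult:
    """Full no-change test: transformed statistic, p-value and category.

    Rejection and category use the exact critical ratios (the open
    rejection region ``{w : w < w_L or w > w_U}``), consistent with the
    p-value falling below ``1 - level`` exactly there.
    """
    thresholds = symmetric_thresholds(k, level)
    z0 = (w - 1.0) / (k * math.sqrt(1.0 + w * w)) if w > 0 else math.nan
    p = pvalue_no_change(w, k)
    category = classify_change(w, thresholds, use_exact=True)
    return TestResult(
        observed_ratio=w,
        z=z0,
        p_value=p,
        rejected=category != "no-change",
        category=category,
    )
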