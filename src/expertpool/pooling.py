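"""Average-type opinion pools for expert probability judgements.

Five unweighted aggregations of a group's best estimates for one claim:

* ``ar_mean`` — the arithmetic mean (the classic linear opinion pool);
* ``median_pool`` — the sample median, robust to outliers;
* ``lo_ar_mean`` — the inverse-logit of the mean of log-odds-transformed
  estimates, which treats errors as symmetric on the log-odds scale;
* ``beta_ar_mean`` — the arithmetic mean pushed away from 0.5 through the
  CDF of a symmetric Beta(a, a) distribution ("extremising"), countering
  the well-known under-confidence of averaged probabilities;
* ``distrib_ar_mean`` — the median of the average of the assessors'
  subjective distributions, where each three-point judgement (L, B, U)
  is read as the 5th / 50th / 95th percentile of a minimally informative
  piecewise-uniform distribution on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .panel import Assessment, clip_probability

__all__ = [
    "BetaTransformSpec",
    "ThreePointDistribution",
    "ar_mean",
    "median_pool",
    "lo_ar_mean",
    "beta_ar_mean",
    "build_three_point_distribution",
    "distrib_ar_mean",
]


@dataclass(frozen=True)
class BetaTransformSpec:
    """Parameters of the extremising Beta CDF transform.

    ``alpha = beta > 1`` extremises symmetrically about 0.5;
    ``alpha = beta = 1`` is the identity.
    """

    alpha: float = 7.0
    beta: float = 7.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")


def _as_array(best_estimates) -> np.ndarray:
    arr = np.asarray(list(best_estimates), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot pool an empty set of estimates")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("best estimates must lie in [0, 1]")
    return arr


def ar_mean(best_estimates: Sequence[float]) -> float:
    """Arithmetic mean of the best estimates (equal-weight linear pool)."""
    return float(np.mean(_as_array(best_estimates)))


def median_pool(best_estimates: Sequence[float]) -> float:
    """Sample median; mean of the two central order statistics for even n."""
    return float(np.median(_as_array(best_estimates)))


def lo_ar_mean(best_estimates: Sequence[float], eps: float = 0.01) -> float:
    """Inverse-logit of the mean of logit-transformed (clipped) estimates."""
    arr = clip_probability(_as_array(best_estimates), eps)
    return float(expit(np.mean(logit(arr))))


def beta_ar_mean(
    best_estimates: Sequence[float], spec: BetaTransformSpec | None = None
) -> float:
    """Beta-CDF-extremised arithmetic mean.

    With ``alpha = beta`` the transform fixes 0, 0.5 and 1, maps (0.5, 1)
    above the identity and (0, 0.5) below it, sharpening the pooled
    probability toward the certainty limits.
    """
    spec = spec or BetaTransformSpec()
    m = ar_mean(best_estimates)
    return float(beta_dist.cdf(m, spec.alpha, spec.beta))


# ---------------------------------------------------------------------------
# distribution pooling


@dataclass(frozen=True)
class ThreePointDistribution:
    """Piecewise-uniform distribution on [0, 1] pinned at three percentiles.

    Mass 0.05 is spread uniformly on [0, q5], 0.45 on [q5, q50], 0.45 on
    [q50, q95] and 0.05 on [q95, 1]; a degenerate sub-interval carries its
    mass as an atom at the shared point, so the CDF is right-continuous
    with CDF(q5) = 0.05, CDF(q50) = 0.50, CDF(q95) = 0.95.
    """

    q5: float
    q50: float
    q95: float

    def __post_init__(self):
        if not 0.0 <= self.q5 <= self.q50 <= self.q95 <= 1.0:
            raise ValueError(
                f"percentiles must satisfy 0 <= q5 <= q50 <= q95 <= 1, got "
                f"({self.q5}, {self.q50}, {self.q95})"
            )

    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([0.0, self.q5, self.q50, self.q95, 1.0])

    _SEGMENT_MASS = (0.05, 0.45, 0.45, 0.05)

    def cdf(self, x) -> np.ndarray:
        """Right-continuous CDF evaluated at scalar or array ``x``."""
        x = np.asarray(x, dtype=float)
        bp = self.breakpoints
        F = np.zeros_like(x)
        for j, mass in enumerate(self._SEGMENT_MASS):
            a, b = bp[j], bp[j + 1]
            if b > a:
                with np.errstate(over="ignore"):  # harmless for sub-ulp segments
                    F = F + mass * np.clip((x - a) / (b - a), 0.0, 1.0)
            else:  # degenerate segment: atom at the shared point
                F = F + mass * (x >= a)
        return F

    def cdf_left(self, x) -> np.ndarray:
        """Left limit of the CDF (excludes the atom at ``x``, if any)."""
        x = np.asarray(x, dtype=float)
        bp = self.breakpoints
        F = np.zeros_like(x)
        for j, mass in enumerate(self._SEGMENT_MASS):
            a, b = bp[j], bp[j + 1]
            if b > a:
                with np.errstate(over="ignore"):  # harmless for sub-ulp segments
                    F = F + mass * np.clip((x - a) / (b - a), 0.0, 1.0)
            else:
                F = F + mass * (x > a)
        return F


def build_three_point_distribution(a: Assessment) -> ThreePointDistribution:
    """Read an assessment's (L, B, U) as the 5/50/95 percentiles."""
    return ThreePointDistribution(a.lower, a.best, a.upper)


def distrib_ar_mean(assessments: Sequence[Assessment]) -> float:
    """Median of the pointwise average of the assessors' CDFs.

    The average CDF is piecewise linear between the union of all
    assessors' percentile breakpoints, with jumps only at breakpoints
    (from degenerate sub-intervals).  The median is the left-continuous
    generalized inverse at 0.5: the smallest x with mean-CDF(x) >= 0.5.
    """
    if len(assessments) == 0:
        raise ValueError("cannot pool an empty set of assessments")
    dists = [build_three_point_distribution(a) for a in assessments]

    knots = np.unique(np.concatenate([d.breakpoints for d in dists]))
    Fbar = np.mean([d.cdf(knots) for d in dists], axis=0)
    Fbar_left = np.mean([d.cdf_left(knots) for d in dists], axis=0)

    k = int(np.searchsorted(Fbar >= 0.5, True))
    if Fbar_left[k] >= 0.5 and k > 0:
        # the 0.5 level is reached inside the linear piece ending at knot k
        x0, x1 = knots[k - 1], knots[k]
        f0, f1 = Fbar[k - 1], Fbar_left[k]
        if f1 > f0:
            return float(x0 + (0.5 - f0) * (x1 - x0) / (f1 - f0))
        return float(x0)  # flat piece already at 0.5: smallest such x
    return float(knots[k])  # a jump at knot k crosses 0.5
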