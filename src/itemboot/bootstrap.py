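"""Bootstrap of items (BSI).

An individual's J item responses are treated as the empirical distribution
of that individual's responding.  Resampling J values with replacement and
summing gives one plausible test score; repeating B times builds a score
distribution standing in for the unknown distribution of repeated
administrations.  Percentile or bias-corrected-and-accelerated (BCa)
intervals are then read off that distribution.

Every bootstrap score is a sum of J values drawn from the observed
responses, so the distribution — and any interval derived from it — can
never leave the attainable score range ``[J*scale_min, J*scale_max]``.

A constant response vector yields a one-point distribution from which no
interval exists; such respondents are *degenerate* and the library raises
:class:`~itemboot.exceptions.DegenerateResponseError` so pipeline callers
can record them as indeterminate and drop them from rate denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateResponseError
from .psychometrics import (
    SIDEDNESS,
    ConfidenceInterval,
    ResponseVector,
    ScaleSpec,
    total_score,
)

__all__ = [
    "BootstrapDistribution",
    "BcaParams",
    "check_degenerate",
    "bootstrap_distribution",
    "percentile_interval",
    "bca_interval",
    "compute_bca_params",
    "bsi_interval",
    "DEFAULT_B",
]

logger = logging.getLogger(__name__)

#: Default number of bootstrap repetitions.
DEFAULT_B = 3000


@dataclass(frozen=True)
class BootstrapDistribution:
    """The B resampled total scores for one response vector.

    ``scores`` is sorted ascending; ``observed`` is the actual total score
    of the vector that generated the distribution.
    """

    scores: np.ndarray
    B: int
    observed: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "scores", np.sort(np.asarray(self.scores)))
        if len(self.scores) != self.B:
            raise ValueError("scores length must equal B")


@dataclass(frozen=True)
class BcaParams:
    """Bias-correction and acceleration terms behind one BCa interval."""

    z0: float
    a: float
    adjusted_lower_percentile: float
    adjusted_upper_percentile: float


def check_degenerate(rv) -> bool:
    """True iff all item responses are identical (constant vector)."""
    values = rv.values if isinstance(rv, ResponseVector) else rv
    arr = np.asarray(values)
    return bool((arr == arr[0]).all())


def bootstrap_distribution(rv: ResponseVector, B: int = DEFAULT_B, *,
                           seed: int) -> BootstrapDistribution:
    """Resample the item responses B times and collect the total scores.

    Each of the B scores is the sum of J values drawn independently, with
    replacement, from ``rv.values``.  The seed is mandatory: BSI results
    must be reproducible and callers own the randomness.

    Raises
    ------
    DegenerateResponseError
        If all responses are identical.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if check_degenerate(rv):
        raise DegenerateResponseError(rv.respondent_id, rv.occasion)
    values = np.asarray(rv.values)
    j = len(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, j, size=(B, j))
    scores = values[idx].sum(axis=1)
    return BootstrapDistribution(scores=scores, B=B,
                                 observed=float(total_score(rv)), seed=seed)


def _quantile(scores: np.ndarray, q) -> np.ndarray:
    # type-7 (linear interpolation between order statistics); with B in the
    # thousands the choice of convention is sub-unit on integer score scales
    return np.quantile(scores, q, method="linear")


def _one_sided_limits(spec: Optional[ScaleSpec], sidedness: str):
    if spec is None:
        raise ValueError(
            "one-sided bootstrap intervals need a ScaleSpec to place the "
            "non-data bound at the scale limit"
        )
    return float(spec.min_score) if sidedness == "upper_only" else float(spec.max_score)


def percentile_interval(
    dist: BootstrapDistribution,
    level: float = 0.95,
    sidedness: str = "two_sided",
    spec: Optional[ScaleSpec] = None,
) -> ConfidenceInterval:
    """Raw percentile interval of the bootstrap score distribution.

    Two-sided: the ``(1-level)/2`` and ``(1+level)/2`` empirical
    percentiles (2.5 / 97.5 at the 95% level).  One-sided: the single
    stated percentile (95th for ``upper_only``, 5th for ``lower_only`` at
    level 0.95), the other bound fixed at the scale limit.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    if sidedness == "two_sided":
        lower, upper = _quantile(dist.scores, [(1 - level) / 2, (1 + level) / 2])
    elif sidedness == "upper_only":
        lower = _one_sided_limits(spec, sidedness)
        upper = float(_quantile(dist.scores, level))
    else:
        lower = float(_quantile(dist.scores, 1 - level))
        upper = _one_sided_limits(spec, sidedness)
    return ConfidenceInterval(
        lower=float(lower), upper=float(upper), level=level,
        sidedness=sidedness, method="BSI_percentile", center=dist.observed,
    )


def compute_bca_params(
    dist: BootstrapDistribution,
    rv: ResponseVector,
    level: float = 0.95,
    sidedness: str = "two_sided",
) -> Optional[BcaParams]:
    """Bias-correction z0, acceleration a, and the adjusted percentiles.

    z0 is the normal quantile of the fraction of bootstrap scores strictly
    below the observed score (strict "<": with integer scores ties at the
    observed value are common and the strict convention is the standard
    formulation).  The acceleration comes from a leave-one-item-out
    jackknife of the mean-rescaled total ``(J/(J-1)) * sum(remaining)``, so
    the jackknife replicates live on the J-item score scale; a is invariant
    to that rescaling but the replicates are interpretable.

    Returns None when z0 is undefined (every bootstrap score on one side of
    the observed score) — callers should fall back to the raw percentile
    interval.
    """
    B = dist.B
    frac_below = float(np.count_nonzero(dist.scores < dist.observed)) / B
    if frac_below <= 0.0 or frac_below >= 1.0:
        return None
    z0 = float(sps.norm.ppf(frac_below))

    values = np.asarray(rv.values, dtype=float)
    j = len(values)
    # leave-one-out totals rescaled to the J-item score scale
    theta_i = (j / (j - 1)) * (values.sum() - values)
    d = theta_i.mean() - theta_i
    denom = float(np.sum(d**2)) ** 1.5
    if denom == 0.0:
        logger.warning("zero jackknife variance; acceleration set to 0")
        a = 0.0
    else:
        a = float(np.sum(d**3)) / (6.0 * denom)

    def adjust(z_k: float) -> float:
        t = z0 + z_k
        return float(sps.norm.cdf(z0 + t / (1.0 - a * t)))

    if sidedness == "two_sided":
        alpha_lo = adjust(float(sps.norm.ppf((1 - level) / 2)))
        alpha_hi = adjust(float(sps.norm.ppf((1 + level) / 2)))
    elif sidedness == "upper_only":
        alpha_lo, alpha_hi = 0.0, adjust(float(sps.norm.ppf(level)))
    else:
        alpha_lo, alpha_hi = adjust(float(sps.norm.ppf(1 - level))), 1.0
    return BcaParams(z0=z0, a=a,
                     adjusted_lower_percentile=alpha_lo,
                     adjusted_upper_percentile=alpha_hi)


def bca_interval(
    dist: BootstrapDistribution,
    rv: ResponseVector,
    level: float = 0.95,
    sidedness: str = "two_sided",
    spec: Optional[ScaleSpec] = None,
) -> ConfidenceInterval:
    """Bias-corrected and accelerated (BCa) bootstrap interval.

    The nominal percentile levels are shifted by the bias correction z0 and
    acceleration a before reading the empirical percentiles off the
    bootstrap distribution.  Falls back to the raw percentile interval
    (with a logged warning) when z0 is undefined because every bootstrap
    score lies on one side of the observed score.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    params = compute_bca_params(dist, rv, level, sidedness)
    if params is None:
        logger.warning(
            "respondent %r: bias correction undefined (all bootstrap scores "
            "on one side of the observed score); using percentile interval",
            rv.respondent_id,
        )
        ci = percentile_interval(dist, level, sidedness, spec)
        return ConfidenceInterval(
            lower=ci.lower, upper=ci.upper, level=level, sidedness=sidedness,
            method="BSI_bca", center=dist.observed,
        )
    if sidedness == "two_sided":
        lower = float(_quantile(dist.scores, params.adjusted_lower_percentile))
        upper = float(_quantile(dist.scores, params.adjusted_upper_percentile))
    elif sidedness == "upper_only":
        lower = _one_sided_limits(spec, sidedness)
        upper = float(_quantile(dist.scores, params.adjusted_upper_percentile))
    else:
        lower = float(_quantile(dist.scores, params.adjusted_lower_percentile))
        upper = _one_sided_limits(spec, sidedness)
    return ConfidenceInterval(
        lower=lower, upper=upper, level=level, sidedness=sidedness,
        method="BSI_bca", center=dist.observed,
    )


def bsi_interval(
    rv: ResponseVector,
    level: float = 0.95,
    sidedness: str = "two_sided",
    B: int = DEFAULT_B,
    method: str = "bca",
    *,
    seed: int,
    spec: Optional[ScaleSpec] = None,
) -> ConfidenceInterval:
    """Degeneracy check -> bootstrap distribution -> chosen interval.

    ``method`` is ``"bca"`` (default) or ``"percentile"``.  The observed
    total score is attached as the interval center.  Propagates
    :class:`DegenerateResponseError` for constant response vectors.
    """
    dist = bootstrap_distribution(rv, B, seed=seed)
    if method == "bca":
        return bca_interval(dist, rv, level, sidedness, spec)
    if method == "percentile":
        return percentile_interval(dist, level, sidedness, spec)
    raise ValueError("method must be 'bca' or 'percentile'")
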