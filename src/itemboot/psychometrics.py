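"""Classical-test-theory quantities.

Inverse-item recoding, total scores, Cronbach's alpha, the shrinkage point
estimate of the true score, the standard error of measurement (SEM), and the
classical "estimating the true score" (ETS) confidence interval that adds
``± z * SEM`` around the shrunken score.

Conventions
-----------
* All variances and standard deviations use the ``n - 1`` denominator,
  consistently in the numerator and denominator of alpha.
* Item indices are 1-based in :class:`ScaleSpec` (as in user-facing files)
  and converted to 0-based positions internally.
* ETS interval limits are deliberately *not* clipped to the attainable score
  range ``[J * scale_min, J * scale_max]``: out-of-range limits are a known
  property of classical intervals and reporting preserves them (with a flag)
  so they can be contrasted with the always-in-range bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import BoundsError, UndefinedAlphaError

__all__ = [
    "ScaleSpec",
    "ResponseVector",
    "ReliabilityStats",
    "ConfidenceInterval",
    "recode_inverse",
    "total_score",
    "cronbach_alpha",
    "estimate_reliability",
    "ets_point_estimate",
    "ets_interval",
    "interval_out_of_range",
]

DIRECTIONS = ("increase", "decrease", "two_sided")
SIDEDNESS = ("two_sided", "lower_only", "upper_only")


@dataclass(frozen=True)
class ScaleSpec:
    """Description of a fixed-format ordinal scale.

    Parameters
    ----------
    n_items:
        Number of items J (>= 2).
    scale_min, scale_max:
        Inclusive response bounds (e.g. 1 and 5 for a five-point Likert
        format).
    inverse_items:
        1-based indices of reverse-keyed items; their responses are reflected
        about the scale midpoint before any scoring.
    direction:
        Expected direction of change after an intervention: ``increase``,
        ``decrease`` or ``two_sided`` (no expectation).
    """

    n_items: int
    scale_min: int
    scale_max: int
    inverse_items: frozenset = field(default_factory=frozenset)
    direction: str = "two_sided"

    def __post_init__(self):
        if self.n_items < 2:
            raise ValueError("a scale needs at least 2 items")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        inv = frozenset(int(i) for i in self.inverse_items)
        if not all(1 <= i <= self.n_items for i in inv):
            raise ValueError("inverse_items must be 1-based indices in [1, n_items]")
        object.__setattr__(self, "inverse_items", inv)

    @property
    def min_score(self) -> int:
        """Lowest attainable total score, J * scale_min."""
        return self.n_items * self.scale_min

    @property
    def max_score(self) -> int:
        """Highest attainable total score, J * scale_max."""
        return self.n_items * self.scale_max


@dataclass(frozen=True)
class ResponseVector:
    """One individual's ordered item responses at one occasion."""

    respondent_id: object
    values: tuple
    occasion: str = "pre"

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))

    def validate(self, spec: ScaleSpec) -> "ResponseVector":
        if len(self.values) != spec.n_items:
            raise BoundsError(
                f"respondent {self.respondent_id!r}: expected {spec.n_items} "
                f"responses, got {len(self.values)}",
                respondent_id=self.respondent_id,
            )
        for j, v in enumerate(self.values, start=1):
            if not (spec.scale_min <= v <= spec.scale_max):
                raise BoundsError(
                    f"respondent {self.respondent_id!r}, item {j}: value {v} "
                    f"outside [{spec.scale_min}, {spec.scale_max}]",
                    respondent_id=self.respondent_id,
                    item=j,
                )
        return self


@dataclass(frozen=True)
class ReliabilityStats:
    """Scale-level estimates feeding the ETS interval.

    ``sem = sd_score * sqrt(1 - alpha)``; when the alpha estimate is
    negative it is clamped to 0 for the SEM (``alpha_clamped`` is then True)
    because the classical error model does not contemplate an error variance
    exceeding the observed-score variance.
    """

    alpha: float
    mean_score: float
    sd_score: float
    sem: float
    n_respondents: int
    alpha_clamped: bool = False


@dataclass(frozen=True)
class ConfidenceInterval:
    """A confidence interval for one individual's score at one occasion.

    ``center`` is the ETS point estimate V' for the classical method and the
    observed total score for the bootstrap methods.  For one-sided intervals
    exactly one bound is derived from data; the other is the scale limit.
    """

    lower: float
    upper: float
    level: float
    sidedness: str
    method: str  # "ETS", "BSI_percentile" or "BSI_bca"
    center: float

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        if self.lower > self.upper:
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def recode_inverse(values, spec: ScaleSpec):
    """Reflect reverse-keyed items about the scale midpoint.

    ``x -> scale_min + scale_max - x`` for every item in
    ``spec.inverse_items``; other items untouched.  Accepts a 1-D response
    sequence or a 2-D (respondents x items) array; returns an ndarray of the
    same shape.  The operation is an involution.
    """
    arr = np.asarray(values)
    if arr.shape[-1] != spec.n_items:
        raise BoundsError(
            f"expected {spec.n_items} items, got {arr.shape[-1]}"
        )
    if ((arr < spec.scale_min) | (arr > spec.scale_max)).any():
        bad = np.argwhere((arr < spec.scale_min) | (arr > spec.scale_max))[0]
        raise BoundsError(
            f"value outside [{spec.scale_min}, {spec.scale_max}] at position "
            f"{tuple(int(i) for i in bad)}",
            item=int(bad[-1]) + 1,
        )
    out = arr.copy()
    cols = [i - 1 for i in sorted(spec.inverse_items)]
    out[..., cols] = spec.scale_min + spec.scale_max - arr[..., cols]
    return out


def total_score(rv) -> int:
    """Sum of the item responses (the test score X)."""
    values = rv.values if isinstance(rv, ResponseVector) else rv
    return int(np.sum(np.asarray(values)))


def _as_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D respondents x items matrix")
    return arr


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``alpha = (J / (J - 1)) * (1 - sum_j var_j / var_total)`` with item and
    total-score variances both computed with the n-1 denominator.

    Raises
    ------
    ValueError
        Fewer than 2 items or fewer than 2 respondents.
    UndefinedAlphaError
        Zero total-score variance.
    """
    arr = _as_matrix(matrix)
    n, j = arr.shape
    if j < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 respondents")
    var_total = float(np.var(arr.sum(axis=1), ddof=1))
    if var_total == 0.0:
        raise UndefinedAlphaError("total-score variance is zero; alpha undefined")
    var_items = float(np.var(arr, axis=0, ddof=1).sum())
    return (j / (j - 1)) * (1.0 - var_items / var_total)


def estimate_reliability(matrix) -> ReliabilityStats:
    """Alpha, mean and SD of total scores, and the SEM, for one administration.

    A negative alpha is reported as estimated but clamped to 0 inside the SEM
    (with ``alpha_clamped=True`` and a warning), so that the SEM never
    exceeds the observed-score SD.
    """
    arr = _as_matrix(matrix)
    alpha = cronbach_alpha(arr)
    totals = arr.sum(axis=1)
    mean = float(np.mean(totals))
    sd = float(np.std(totals, ddof=1))
    clamped = alpha < 0.0
    if clamped:
        warnings.warn(
            f"negative alpha ({alpha:.4f}) clamped to 0 for the SEM",
            RuntimeWarning,
            stacklevel=2,
        )
    sem = sd * float(np.sqrt(1.0 - max(alpha, 0.0)))
    return ReliabilityStats(
        alpha=alpha,
        mean_score=mean,
        sd_score=sd,
        sem=sem,
        n_respondents=arr.shape[0],
        alpha_clamped=clamped,
    )


def ets_point_estimate(score: float, stats: ReliabilityStats) -> float:
    """Shrinkage estimate of the true score: V' = a*X + (1 - a)*mean.

    With a = alpha the observed score X is pulled toward the group mean in
    proportion to the estimated unreliability.
    """
    return stats.alpha * score + (1.0 - stats.alpha) * stats.mean_score


def _z_value(level: float, sidedness: str, paper_rounding: bool) -> float:
    """Standard-normal quantile for the interval, optionally rounded to the
    conventional two-decimal table values 1.96 / 1.64 at the 95% level."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if paper_rounding and abs(level - 0.95) < 1e-12:
        return 1.96 if sidedness == "two_sided" else 1.64
    if sidedness == "two_sided":
        return float(sps.norm.ppf((1.0 + level) / 2.0))
    return float(sps.norm.ppf(level))


def ets_interval(
    score: float,
    stats: ReliabilityStats,
    level: float = 0.95,
    sidedness: str = "two_sided",
    spec: Optional[ScaleSpec] = None,
    paper_rounding: bool = False,
) -> ConfidenceInterval:
    """Classical true-score confidence interval V' +/- z * SEM.

    Two-sided: ``[V' - z*sem, V' + z*sem]`` with z the two-sided quantile.
    One-sided: the single data-derived bound ``V' + z*sem`` (``upper_only``)
    or ``V' - z*sem`` (``lower_only``) with z the one-sided quantile; the
    opposite bound is set to the scale limit (a ``spec`` is then required).
    Limits are not clipped to the attainable score range.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    z = _z_value(level, sidedness, paper_rounding)
    center = ets_point_estimate(score, stats)
    if sidedness == "two_sided":
        lower, upper = center - z * stats.sem, center + z * stats.sem
    else:
        if spec is None:
            raise ValueError("one-sided ETS intervals need a ScaleSpec for the "
                             "non-data bound")
        if sidedness == "upper_only":
            lower, upper = float(spec.min_score), center + z * stats.sem
        else:
            lower, upper = center - z * stats.sem, float(spec.max_score)
        # a far-shrunken center can land outside the fixed scale-limit bound
        lower, upper = min(lower, upper), max(lower, upper)
    return ConfidenceInterval(
        lower=lower, upper=upper, level=level, sidedness=sidedness,
        method="ETS", center=center,
    )


def interval_out_of_range(ci: ConfidenceInterval, spec: ScaleSpec) -> bool:
    """True when a data-derived limit falls outside the attainable score
    range — possible for ETS, impossible for item-bootstrap intervals."""
    lo, hi = float(spec.min_score), float(spec.max_score)
    if ci.sidedness == "upper_only":
        return ci.upper > hi or ci.upper < lo
    if ci.sidedness == "lower_only":
        return ci.lower < lo or ci.lower > hi
    return ci.lower < lo or ci.upper > hi
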