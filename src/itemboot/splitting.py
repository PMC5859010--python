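"""Parallel half-tests from a single administration.

Items are ordered by their sample mean (after recoding reverse-keyed
items) and dealt into two halves with an ABBA pattern: of the two items
with the highest means the first goes to half 1 and the second to half 2;
of the next two, the first goes to half 2 and the second to half 1; and so
on.  The resulting halves have total scores as similar as possible and are
then checked for equal means (paired t test) and equal variances
(Pitman-Morgan test) before being treated as parallel forms.

Item positions are 0-based throughout this module; report writers convert
to 1-based labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .psychometrics import ScaleSpec

__all__ = ["SplitResult", "order_items_by_mean", "abba_assign", "check_parallel"]


@dataclass(frozen=True)
class SplitResult:
    """A partition of the items into two half-tests, with equivalence tests.

    ``half1_items`` / ``half2_items`` are 0-based column indices into the
    original matrix, in assignment order.  ``mean_test_p`` and
    ``variance_test_p`` are filled by :func:`check_parallel`; they are None
    before the check, and NaN when the test is not applicable (zero
    variance of the half-score differences).
    """

    half1_items: tuple
    half2_items: tuple
    mean_test_p: Optional[float] = None
    variance_test_p: Optional[float] = None
    equivalent: Optional[bool] = None


def order_items_by_mean(matrix, spec: Optional[ScaleSpec] = None) -> np.ndarray:
    """Column indices sorted by descending item mean; ties broken by
    ascending original index.  Reverse-keyed items must already be recoded.
    """
    arr = np.asarray(matrix, dtype=float)
    means = arr.mean(axis=0)
    # lexsort: last key is primary; negate means for descending order
    return np.lexsort((np.arange(len(means)), -means))


def abba_assign(ordered: Sequence[int]) -> SplitResult:
    """Deal the mean-ordered items into halves with the repeating pattern
    A,B,B,A over blocks of four; an odd leftover continues the pattern, so
    half sizes differ by at most one (equal when J is even)."""
    ordered = list(ordered)
    if len(ordered) < 2:
        raise ValueError("need at least 2 items to split")
    half1, half2 = [], []
    for pos, item in enumerate(ordered):
        (half1 if pos % 4 in (0, 3) else half2).append(item)
    return SplitResult(half1_items=tuple(half1), half2_items=tuple(half2))


def _pitman_morgan(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value for equality of variances of paired samples.

    Based on the correlation between the sums and differences of the
    pairs: r(x+y, x-y) = 0 iff var(x) = var(y); t = r*sqrt(n-2)/sqrt(1-r^2)
    with n-2 df.
    """
    n = len(x)
    s, d = x + y, x - y
    if np.std(s, ddof=1) == 0.0 or np.std(d, ddof=1) == 0.0:
        return float("nan")
    r = float(np.corrcoef(s, d)[0, 1])
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def check_parallel(matrix, split: SplitResult, alpha_level: float = 0.05) -> SplitResult:
    """Test whether the two halves behave as parallel forms.

    Paired-samples t test on the half-score differences and Pitman-Morgan
    test on the half-score variances; ``equivalent`` is True when neither
    rejects at ``alpha_level``.  With zero variance of the differences the
    tests are not applicable (p = NaN): identical halves are equivalent, a
    constant nonzero offset is not.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 respondents to test parallelism")
    h1 = arr[:, list(split.half1_items)].sum(axis=1)
    h2 = arr[:, list(split.half2_items)].sum(axis=1)
    diff = h1 - h2
    if np.std(diff, ddof=1) == 0.0:
        # degenerate: every respondent has the same half difference
        equivalent = bool(np.all(diff == 0.0))
        return replace(split, mean_test_p=float("nan"),
                       variance_test_p=float("nan"), equivalent=equivalent)
    mean_p = float(sps.ttest_rel(h1, h2).pvalue)
    var_p = _pitman_morgan(h1, h2)
    ok = mean_p > alpha_level and (np.isnan(var_p) or var_p > alpha_level)
    return replace(split, mean_test_p=mean_p, variance_test_p=var_p,
                   equivalent=bool(ok))
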