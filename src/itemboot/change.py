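"""Reliable-change decisions by interval non-overlap, and rate summaries.

A pre/post score difference is declared significant when the two
confidence intervals do not overlap, with strict inequality at shared
bounds (touching intervals overlap, hence no change).  When a direction of
change is expected the rule is applied only in that direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .psychometrics import DIRECTIONS, ConfidenceInterval

__all__ = ["ChangeDecision", "RateSummary", "detect_change", "summarize_rates"]


@dataclass(frozen=True)
class ChangeDecision:
    """Per-individual verdict with both intervals attached.

    ``verdict`` is ``indeterminate`` iff either interval could not be
    computed (degenerate response vector); ``tie`` flags an exact equality
    at the decisive bound, where the strict rule resolves to no change.
    """

    respondent_id: object
    pre: Optional[ConfidenceInterval]
    post: Optional[ConfidenceInterval]
    verdict: str  # significant | not_significant | indeterminate
    direction_tested: str
    tie: bool = False


@dataclass(frozen=True)
class RateSummary:
    """Group-level counts: frequencies (and percentages) of significant
    change, on the evaluated (non-indeterminate) denominator."""

    group_label: str
    method: str
    n_evaluated: int
    n_indeterminate: int
    n_significant: int
    percent_significant: Optional[float]  # one decimal, half-up; None if n=0


def detect_change(
    pre: Optional[ConfidenceInterval],
    post: Optional[ConfidenceInterval],
    direction: str = "two_sided",
    respondent_id: object = None,
) -> ChangeDecision:
    """Apply the strict non-overlap rule to one pre/post interval pair.

    two_sided : significant iff ``pre.lower > post.upper`` or
        ``post.lower > pre.upper``.
    increase  : significant iff ``post.lower > pre.upper``.
    decrease  : significant iff ``pre.lower > post.upper``.

    ``None`` for either interval (degenerate respondent) yields an
    ``indeterminate`` verdict.  Pre and post must come from the same method
    and confidence level.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if pre is None or post is None:
        return ChangeDecision(respondent_id, pre, post, "indeterminate", direction)
    if pre.method != post.method:
        raise ValueError(
            f"mixed interval methods: pre={pre.method}, post={post.method}"
        )
    if pre.level != post.level:
        raise ValueError(
            f"mixed confidence levels: pre={pre.level}, post={post.level}"
        )
    if direction == "two_sided":
        significant = pre.lower > post.upper or post.lower > pre.upper
        tie = pre.lower == post.upper or post.lower == pre.upper
    elif direction == "increase":
        significant = post.lower > pre.upper
        tie = post.lower == pre.upper
    else:  # decrease
        significant = pre.lower > post.upper
        tie = pre.lower == post.upper
    verdict = "significant" if significant else "not_significant"
    return ChangeDecision(respondent_id, pre, post, verdict, direction, tie=tie)


def _round_percent(n_significant: int, n_evaluated: int) -> float:
    pct = Decimal(100 * n_significant) / Decimal(n_evaluated)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_rates(
    decisions: Iterable[ChangeDecision],
    group_label: str = "",
    method: str = "",
) -> RateSummary:
    """Count significant verdicts among the evaluated (non-indeterminate)
    respondents; percentage on the evaluated denominator, one decimal,
    half-up rounding."""
    decisions = list(decisions)
    if not decisions:
        raise ValueError("empty decision collection")
    n_ind = sum(1 for d in decisions if d.verdict == "indeterminate")
    n_eval = len(decisions) - n_ind
    n_sig = sum(1 for d in decisions if d.verdict == "significant")
    pct = _round_percent(n_sig, n_eval) if n_eval > 0 else None
    return RateSummary(
        group_label=group_label,
        method=method,
        n_evaluated=n_eval,
        n_indeterminate=n_ind,
        n_significant=n_sig,
        percent_significant=pct,
    )
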