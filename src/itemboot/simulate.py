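"""Synthetic respondent generator and simulation harness.

The generator emulates bounded ordinal (Likert-type) responding: each
respondent carries a latent trait value theta on the response scale;
their response to an item is ``round(theta + e)`` with item noise
``e ~ Normal(0, item_noise_sd)``, clipped to the scale bounds.  Two
administrations generated from the same theta differ only through the
item noise — the null condition of no real change.  An intervention is a
shift of theta by ``change_delta`` before the second administration.

Studies apply the classical true-score (ETS) intervals and the item
bootstrap (BSI, percentile and BCa) to the same simulated data and return
the rate of significant-change verdicts per method, with a Monte-Carlo
standard error.  Under the null that rate is the false-positive rate and
should not exceed the nominal alpha; under a shift it is the power.

Respondents who answer every item identically on either occasion are
degenerate for the bootstrap; they are recorded as indeterminate and
excluded from the rate denominator of every method, so the methods are
always compared on the same respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .bootstrap import bca_interval, bootstrap_distribution, check_degenerate, percentile_interval
from .change import ChangeDecision, detect_change, summarize_rates
from .exceptions import UndefinedAlphaError
from .psychometrics import (
    ConfidenceInterval,
    ResponseVector,
    ScaleSpec,
    estimate_reliability,
    ets_interval,
)

__all__ = ["SimConfig", "SimResult", "generate_administration",
           "run_null_study", "run_change_study", "run_power_grid", "METHODS"]

METHODS = ("ETS", "BSI_percentile", "BSI_bca")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults describe a 24-item five-point scale answered by 1,000
    respondents whose latent trait is centred mid-scale
    (theta ~ Normal(3, 0.6)) with item noise SD 0.8 — a regime that, like
    half-tests of a long personality inventory, produces realistic
    reliabilities and essentially no degenerate responders.  ``change_delta``
    is the latent shift applied before the second administration (0 under
    the null).
    """

    n_respondents: int = 1000
    n_items: int = 24
    scale_min: int = 1
    scale_max: int = 5
    true_score_mean: float = 3.0
    true_score_sd: float = 0.6
    item_noise_sd: float = 0.8
    change_delta: float = 0.0
    n_replications: int = 1
    B: int = 1000
    level: float = 0.95
    seed: int = 0
    paper_rounding: bool = False
    one_sided_percentile: bool = False

    def __post_init__(self):
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if self.true_score_sd < 0 or self.item_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def spec(self) -> ScaleSpec:
        direction = "two_sided"
        if self.change_delta > 0:
            direction = "increase"
        elif self.change_delta < 0:
            direction = "decrease"
        return ScaleSpec(n_items=self.n_items, scale_min=self.scale_min,
                         scale_max=self.scale_max, direction=direction)


@dataclass(frozen=True)
class SimResult:
    """Significant-change rate for one method under one condition."""

    method: str
    condition: str  # "null" | "change"
    rate_significant: float
    mc_se: float
    n_indeterminate: int
    n_significant: int
    n_evaluated: int
    config_echo: SimConfig


def generate_administration(theta, config: SimConfig, seed) -> np.ndarray:
    """One respondents x items integer response matrix.

    Respondent i's response to item j is ``round(theta_i + e_ij)`` with
    ``e_ij ~ Normal(0, item_noise_sd)``, clipped to the scale bounds;
    independent across items and across calls (occasions).
    """
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.item_noise_sd, size=(len(theta), config.n_items))
    resp = np.rint(theta[:, None] + noise)
    return np.clip(resp, config.scale_min, config.scale_max).astype(np.int64)


def _sided(direction: str):
    """(pre_sidedness, post_sidedness) implementing the directional rule."""
    if direction == "two_sided":
        return "two_sided", "two_sided"
    if direction == "increase":
        # change means post clearly above pre: pre's upper vs post's lower
        return "upper_only", "lower_only"
    return "lower_only", "upper_only"


def _replication_decisions(
    pre: np.ndarray,
    post: np.ndarray,
    config: SimConfig,
    direction: str,
    boot_seeds: np.ndarray,
) -> Dict[str, list]:
    """Per-method ChangeDecision lists for one simulated replication."""
    spec = config.spec
    side_pre, side_post = _sided(direction)
    try:
        # a fully saturated occasion has zero total-score variance and no
        # alpha; ETS is then undefined for the whole replication
        stats_pre = estimate_reliability(pre)
        stats_post = estimate_reliability(post)
    except UndefinedAlphaError:
        stats_pre = stats_post = None
    bsi_method_one_sided = "percentile" if config.one_sided_percentile else "bca"

    decisions: Dict[str, list] = {m: [] for m in METHODS}
    for i in range(pre.shape[0]):
        rv_pre = ResponseVector(i, tuple(pre[i]), "pre")
        rv_post = ResponseVector(i, tuple(post[i]), "post")
        degenerate = check_degenerate(rv_pre) or check_degenerate(rv_post)
        if degenerate:
            for m in METHODS:
                decisions[m].append(
                    ChangeDecision(i, None, None, "indeterminate", direction))
            continue

        if stats_pre is None:
            decisions["ETS"].append(
                ChangeDecision(i, None, None, "indeterminate", direction))
        else:
            ci_pre = ets_interval(sum(rv_pre.values), stats_pre, config.level,
                                  side_pre, spec, config.paper_rounding)
            ci_post = ets_interval(sum(rv_post.values), stats_post, config.level,
                                   side_post, spec, config.paper_rounding)
            decisions["ETS"].append(detect_change(ci_pre, ci_post, direction, i))

        d_pre = bootstrap_distribution(rv_pre, config.B, seed=int(boot_seeds[i, 0]))
        d_post = bootstrap_distribution(rv_post, config.B, seed=int(boot_seeds[i, 1]))
        p_pre = percentile_interval(d_pre, config.level, side_pre, spec)
        p_post = percentile_interval(d_post, config.level, side_post, spec)
        decisions["BSI_percentile"].append(detect_change(p_pre, p_post, direction, i))
        if direction != "two_sided" and bsi_method_one_sided == "percentile":
            b_pre, b_post = p_pre, p_post
            b_pre = replace(b_pre, method="BSI_bca")
            b_post = replace(b_post, method="BSI_bca")
        else:
            b_pre = bca_interval(d_pre, rv_pre, config.level, side_pre, spec)
            b_post = bca_interval(d_post, rv_post, config.level, side_post, spec)
        decisions["BSI_bca"].append(detect_change(b_pre, b_post, direction, i))
    return decisions


def _run_study(config: SimConfig, condition: str) -> Dict[str, SimResult]:
    direction = "two_sided" if condition == "null" else config.spec.direction
    root = np.random.SeedSequence(config.seed)
    rep_seqs = root.spawn(config.n_replications)

    rates = {m: [] for m in METHODS}
    n_ind = {m: 0 for m in METHODS}
    n_sig = {m: 0 for m in METHODS}
    n_eval = {m: 0 for m in METHODS}
    for seq in rep_seqs:
        theta_seq, pre_seq, post_seq, boot_seq = seq.spawn(4)
        rng = np.random.default_rng(theta_seq)
        theta = rng.normal(config.true_score_mean, config.true_score_sd,
                           config.n_respondents)
        pre = generate_administration(theta, config, pre_seq)
        post_theta = theta + (config.change_delta if condition == "change" else 0.0)
        post = generate_administration(post_theta, config, post_seq)
        boot_seeds = np.random.default_rng(boot_seq).integers(
            0, 2**31, size=(config.n_respondents, 2))
        decisions = _replication_decisions(pre, post, config, direction, boot_seeds)
        for m in METHODS:
            summ = summarize_rates(decisions[m], condition, m)
            n_ind[m] += summ.n_indeterminate
            n_sig[m] += summ.n_significant
            n_eval[m] += summ.n_evaluated
            if summ.n_evaluated > 0:
                rates[m].append(summ.n_significant / summ.n_evaluated)

    results = {}
    for m in METHODS:
        rs = np.asarray(rates[m], dtype=float)
        rate = float(rs.mean()) if rs.size else float("nan")
        if rs.size > 1:
            mc_se = float(rs.std(ddof=1) / np.sqrt(rs.size))
        elif n_eval[m] > 0:
            mc_se = float(np.sqrt(rate * (1.0 - rate) / n_eval[m]))
        else:
            mc_se = float("nan")
        results[m] = SimResult(
            method=m, condition=condition, rate_significant=rate, mc_se=mc_se,
            n_indeterminate=n_ind[m], n_significant=n_sig[m],
            n_evaluated=n_eval[m], config_echo=config,
        )
    return results


def run_null_study(config: SimConfig) -> Dict[str, SimResult]:
    """False-positive study: two administrations from the same theta.

    Both occasions are generated from an identical latent trait, so every
    significant verdict is a false positive; two-sided intervals are used
    because no direction of change is expected.  Requires
    ``change_delta == 0``.
    """
    if config.change_delta != 0:
        raise ValueError("null study requires change_delta = 0")
    return _run_study(config, "null")


def run_change_study(config: SimConfig) -> Dict[str, SimResult]:
    """Power study: theta is shifted by ``change_delta`` before the second
    administration and one-sided intervals in the matching direction are
    compared; the returned rate is the detection rate."""
    if config.change_delta == 0:
        raise ValueError("change study requires change_delta != 0; "
                         "use run_null_study for the null condition")
    return _run_study(config, "change")


def run_power_grid(config: SimConfig, deltas: Sequence[float]) -> Dict[float, Dict[str, SimResult]]:
    """Detection rate per method over a grid of latent shifts.

    ``delta == 0`` entries are run through the null study (two-sided rule);
    the same base seed is offset per grid point so conditions are
    independent but the whole grid is reproducible.
    """
    out = {}
    for k, delta in enumerate(deltas):
        cfg = replace(config, change_delta=float(delta),
                      seed=config.seed + 10007 * k)
        out[float(delta)] = run_null_study(cfg) if delta == 0 else run_change_study(cfg)
    return out
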