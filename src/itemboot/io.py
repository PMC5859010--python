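"""Response-file reading, run configuration, and report building.

Input format: comma-separated UTF-8 text with a header row; the first
column is ``id``, remaining columns are item responses as integers.
Missing cells are rejected rather than imputed — the bootstrap resamples
the empirical response set and imputation would silently change that
population.  Item indices in configuration files (``inverse_items``) are
1-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace as dc_replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import DEFAULT_B, bsi_interval
from .change import RateSummary, detect_change, summarize_rates
from .exceptions import DegenerateResponseError, InputFormatError
from .psychometrics import (
    ConfidenceInterval,
    ResponseVector,
    ScaleSpec,
    estimate_reliability,
    ets_interval,
    interval_out_of_range,
    recode_inverse,
    total_score,
)
from .splitting import abba_assign, check_parallel, order_items_by_mean

__all__ = ["RunConfig", "load_config", "read_responses", "run_detect",
           "run_split", "describe_matrix", "write_report", "summary_text",
           "summary_json"]

logger = logging.getLogger(__name__)

INTERVAL_METHODS = ("ETS", "BSI_percentile", "BSI_bca")


def _sided(direction: str) -> Tuple[str, str]:
    """(pre, post) interval sidedness implementing the directional rule."""
    if direction == "two_sided":
        return "two_sided", "two_sided"
    if direction == "increase":
        # change means post clearly above pre: pre's upper vs post's lower
        return "upper_only", "lower_only"
    return "lower_only", "upper_only"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run, echoed into every report."""

    scale: ScaleSpec
    method: str = "both"  # ETS | BSI_percentile | BSI_bca | both
    level: float = 0.95
    B: int = DEFAULT_B
    seed: Optional[int] = None
    paper_rounding: bool = False
    one_sided_percentile: bool = False
    direction: Optional[str] = None  # default: scale.direction
    intersect: bool = False
    parallel_alpha: float = 0.05

    def methods(self) -> Tuple[str, ...]:
        if self.method == "both":
            return ("ETS", "BSI_bca")
        if self.method not in INTERVAL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        return (self.method,)

    def effective_direction(self) -> str:
        return self.direction or self.scale.direction


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML key-value file.

    Expected keys mirror the dataclass; the ``scale`` block holds
    ``n_items``, ``scale_min``, ``scale_max``, optional 1-based
    ``inverse_items`` and ``direction``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "scale" not in raw:
        raise InputFormatError(f"{path}: config must be a mapping with a 'scale' block")
    s = dict(raw["scale"])
    spec = ScaleSpec(
        n_items=int(s["n_items"]),
        scale_min=int(s["scale_min"]),
        scale_max=int(s["scale_max"]),
        inverse_items=frozenset(s.get("inverse_items", ())),
        direction=s.get("direction", "two_sided"),
    )
    kwargs = {k: raw[k] for k in
              ("method", "level", "B", "seed", "paper_rounding",
               "one_sided_percentile", "direction", "intersect",
               "parallel_alpha") if k in raw}
    return RunConfig(scale=spec, **kwargs)


def read_responses(path, spec: ScaleSpec) -> pd.DataFrame:
    """Validated respondents x items matrix, indexed by respondent id.

    Raises :class:`InputFormatError` with the row/column location for any
    missing or non-integer cell, out-of-bounds value, duplicated id or
    column-count mismatch.  Rows are reported 1-based counting the header.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if df.shape[1] != spec.n_items + 1:
        raise InputFormatError(
            f"{path}: expected {spec.n_items + 1} columns (id + "
            f"{spec.n_items} items), found {df.shape[1]}"
        )
    ids = df.iloc[:, 0]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise InputFormatError(
            f"{path}: duplicated respondent id {dup.iloc[0]!r} "
            f"(row {dup.index[0] + 2})"
        )
    values = np.empty((len(df), spec.n_items), dtype=np.int64)
    for c, col in enumerate(df.columns[1:]):
        for r, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                raise InputFormatError(
                    f"{path}: missing value at row {r + 2}, column {col!r}")
            try:
                v = int(cell)
            except ValueError:
                raise InputFormatError(
                    f"{path}: non-integer value {cell!r} at row {r + 2}, "
                    f"column {col!r}") from None
            if not (spec.scale_min <= v <= spec.scale_max):
                raise InputFormatError(
                    f"{path}: value {v} outside [{spec.scale_min}, "
                    f"{spec.scale_max}] at row {r + 2}, column {col!r} "
                    f"(respondent {ids.iloc[r]!r})")
            values[r, c] = v
    return pd.DataFrame(values, index=pd.Index(ids, name="id"),
                        columns=list(df.columns[1:]))


def _interval_pair(
    rv_pre: ResponseVector,
    rv_post: ResponseVector,
    method: str,
    config: RunConfig,
    sides: Tuple[str, str],
    stats_pre,
    stats_post,
    spec_pre: ScaleSpec,
    spec_post: ScaleSpec,
    seed_pair,
) -> Tuple[Optional[ConfidenceInterval], Optional[ConfidenceInterval]]:
    if method == "ETS":
        return (
            ets_interval(total_score(rv_pre), stats_pre, config.level,
                         sides[0], spec_pre, config.paper_rounding),
            ets_interval(total_score(rv_post), stats_post, config.level,
                         sides[1], spec_post, config.paper_rounding),
        )
    kind = "percentile" if method == "BSI_percentile" else "bca"
    if kind == "bca" and config.one_sided_percentile and sides[0] != "two_sided":
        kind = "percentile"
    try:
        pre = bsi_interval(rv_pre, config.level, sides[0], config.B, kind,
                           seed=int(seed_pair[0]), spec=spec_pre)
        post = bsi_interval(rv_post, config.level, sides[1], config.B, kind,
                            seed=int(seed_pair[1]), spec=spec_post)
    except DegenerateResponseError:
        return None, None
    if method == "BSI_bca" and pre.method != "BSI_bca":
        pre, post = dc_replace(pre, method="BSI_bca"), dc_replace(post, method="BSI_bca")
    return pre, post


def _detect_frame(
    pre_arr: np.ndarray,
    post_arr: np.ndarray,
    index,
    config: RunConfig,
    direction: str,
    group_label: str,
    spec_pre: Optional[ScaleSpec] = None,
    spec_post: Optional[ScaleSpec] = None,
    occasion_labels: Tuple[str, str] = ("pre", "post"),
) -> Tuple[pd.DataFrame, Dict[str, RateSummary]]:
    """Per-respondent detection report over already-recoded matrices."""
    spec_pre = spec_pre or config.scale
    spec_post = spec_post or config.scale
    sides = _sided(direction)
    stats_pre = estimate_reliability(pre_arr)
    stats_post = estimate_reliability(post_arr)
    seed = config.seed if config.seed is not None else 0
    seeds = np.random.default_rng(seed).integers(0, 2**31, size=(len(index), 2))

    lab_pre, lab_post = occasion_labels
    rows = []
    decisions: Dict[str, list] = {m: [] for m in config.methods()}
    for i, rid in enumerate(index):
        rv_pre = ResponseVector(rid, tuple(pre_arr[i]), lab_pre).validate(spec_pre)
        rv_post = ResponseVector(rid, tuple(post_arr[i]), lab_post).validate(spec_post)
        row = {
            "id": rid,
            f"{lab_pre}_score": total_score(rv_pre),
            f"{lab_post}_score": total_score(rv_post),
            "degenerate": bool(
                (pre_arr[i] == pre_arr[i][0]).all()
                or (post_arr[i] == post_arr[i][0]).all()),
        }
        for method in config.methods():
            ci_pre, ci_post = _interval_pair(
                rv_pre, rv_post, method, config, sides,
                stats_pre, stats_post, spec_pre, spec_post, seeds[i])
            dec = detect_change(ci_pre, ci_post, direction, rid)
            decisions[method].append(dec)
            p = method.lower()
            if ci_pre is not None:
                row[f"{p}_{lab_pre}_lower"] = round(ci_pre.lower, 4)
                row[f"{p}_{lab_pre}_upper"] = round(ci_pre.upper, 4)
                row[f"{p}_{lab_post}_lower"] = round(ci_post.lower, 4)
                row[f"{p}_{lab_post}_upper"] = round(ci_post.upper, 4)
                if method == "ETS":
                    row["ets_out_of_range"] = (
                        interval_out_of_range(ci_pre, spec_pre)
                        or interval_out_of_range(ci_post, spec_post))
            row[f"{p}_verdict"] = dec.verdict
            row[f"{p}_tie"] = dec.tie
        rows.append(row)
    report = pd.DataFrame(rows)
    summaries = {m: summarize_rates(decisions[m], group_label, m)
                 for m in config.methods()}
    return report, summaries


def run_detect(pre_path, post_path, config: RunConfig):
    """End-to-end pre/post detection from two response files.

    Returns ``(report_df, summaries)``: one report row per respondent
    (scores, interval limits per method, verdict, degeneracy /
    out-of-range / tie flags) and a :class:`RateSummary` per method.
    Respondent ids must match between files; with ``config.intersect`` the
    common subset is kept instead of aborting.
    """
    spec = config.scale
    pre_df = read_responses(pre_path, spec)
    post_df = read_responses(post_path, spec)
    if list(pre_df.index) != list(post_df.index):
        common = pre_df.index.intersection(post_df.index)
        if not config.intersect:
            missing = set(pre_df.index) ^ set(post_df.index)
            raise InputFormatError(
                "respondent ids differ between pre and post files "
                f"(unmatched: {sorted(map(str, missing))[:10]}); rerun with "
                "intersect to keep the common subset")
        pre_df, post_df = pre_df.loc[common], post_df.loc[common]
    pre_arr = recode_inverse(pre_df.to_numpy(), spec)
    post_arr = recode_inverse(post_df.to_numpy(), spec)
    return _detect_frame(pre_arr, post_arr, pre_df.index, config,
                         config.effective_direction(), "detect")


def run_split(single_path, config: RunConfig):
    """Single-administration workflow: recode, ABBA split into parallel
    halves, two-sided non-overlap detection between the half-tests.

    Returns ``(split_result, report_df, summaries)``.  With an odd number
    of items the halves differ by one item (logged; half scores are not
    rescaled) and each half's intervals use its own score bounds.
    """
    spec = config.scale
    df = read_responses(single_path, spec)
    arr = recode_inverse(df.to_numpy(), spec)
    ordered = order_items_by_mean(arr)
    split = abba_assign(ordered)
    split = check_parallel(arr, split, config.parallel_alpha)

    j1, j2 = len(split.half1_items), len(split.half2_items)
    if j1 != j2:
        logger.warning("odd item count %d: halves of %d and %d items",
                       spec.n_items, j1, j2)
    spec1 = ScaleSpec(j1, spec.scale_min, spec.scale_max)
    spec2 = ScaleSpec(j2, spec.scale_min, spec.scale_max)
    half1 = arr[:, list(split.half1_items)]
    half2 = arr[:, list(split.half2_items)]
    # parallel halves carry no expected direction: always two-sided
    report, summaries = _detect_frame(
        half1, half2, df.index, config, "two_sided", "split",
        spec_pre=spec1, spec_post=spec2, occasion_labels=("half1", "half2"))
    return split, report, summaries


def describe_matrix(path, config: RunConfig) -> Dict[str, object]:
    """Scale-level description of one administration: Cronbach's alpha,
    mean and SD of total scores, and the standard error of measurement."""
    df = read_responses(path, config.scale)
    arr = recode_inverse(df.to_numpy(), config.scale)
    st = estimate_reliability(arr)
    return {
        "n_respondents": st.n_respondents,
        "n_items": config.scale.n_items,
        "alpha": st.alpha,
        "mean_score": st.mean_score,
        "sd_score": st.sd_score,
        "sem": st.sem,
        "alpha_clamped": st.alpha_clamped,
    }


def _config_header(config: RunConfig) -> Dict:
    d = asdict(config)
    d["scale"]["inverse_items"] = sorted(config.scale.inverse_items)
    d["itemboot_version"] = __version__
    return d


def write_report(report: pd.DataFrame, path) -> None:
    """Per-respondent report as tab-separated text."""
    report.to_csv(path, sep="\t", index=False)


def summary_text(summaries: Dict[str, RateSummary]) -> str:
    """Human-readable frequencies-and-percentages block."""
    lines = []
    for m, s in summaries.items():
        pct = "--" if s.percent_significant is None else f"{s.percent_significant:.1f}"
        lines.append(
            f"{m}: {s.n_significant} ({pct}) significant of "
            f"{s.n_evaluated} evaluated, {s.n_indeterminate} indeterminate")
    return "\n".join(lines)


def summary_json(summaries: Dict[str, RateSummary], config: RunConfig) -> str:
    """Machine-readable summary with the full run configuration echoed."""
    payload = {
        "config": _config_header(config),
        "summaries": {m: asdict(s) for m, s in summaries.items()},
    }
    return json.dumps(payload, indent=2, default=str)
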