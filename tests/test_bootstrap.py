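"""Item-bootstrap distributions and percentile / BCa intervals."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itemboot import (
    DegenerateResponseError,
    ResponseVector,
    ScaleSpec,
    bootstrap_distribution,
    bsi_interval,
    check_degenerate,
    percentile_interval,
)
from itemboot.bootstrap import BootstrapDistribution, bca_interval, compute_bca_params


def enumerate_resample_scores(values):
    """All J^J equally likely resampled total scores (exact distribution)."""
    return np.array([sum(c) for c in itertools.product(values, repeat=len(values))])


class TestCheckDegenerate:
    @pytest.mark.parametrize("values,expected", [
        ((3, 3, 3, 3), True),
        ((3, 3, 3, 4), False),
        (tuple([2] * 23 + [3]), False),
    ])
    def test_constant_vectors_only(self, values, expected):
        assert check_degenerate(ResponseVector("r", values)) is expected


class TestBootstrapDistribution:
    def test_degenerate_vector_raises_with_id(self):
        with pytest.raises(DegenerateResponseError) as exc:
            bootstrap_distribution(ResponseVector("p8", (2, 2, 2)), 100, seed=1)
        assert exc.value.respondent_id == "p8"

    def test_reproducible_and_sorted(self):
        rv = ResponseVector("r", (1, 2, 3, 4, 5))
        d1 = bootstrap_distribution(rv, 500, seed=11)
        d2 = bootstrap_distribution(rv, 500, seed=11)
        assert (d1.scores == d2.scores).all()
        assert (np.diff(d1.scores) >= 0).all()
        assert d1.observed == 15

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(1, 5), min_size=3, max_size=8).filter(
        lambda v: len(set(v)) > 1), st.integers(0, 2**31 - 1))
    def test_scores_within_observed_value_range(self, values, seed):
        # every resampled score is a sum of J observed values, so it can
        # never leave [J*min(values), J*max(values)]
        d = bootstrap_distribution(ResponseVector("r", values), 200, seed=seed)
        j = len(values)
        assert d.scores.min() >= j * min(values)
        assert d.scores.max() <= j * max(values)

    def test_resampling_moments_match_empirical_distribution(self):
        # mean of a resampled score is J*mean(rv); its variance is
        # J*var_pop(rv) because draws are iid from the empirical distribution
        rv = ResponseVector("r", (1, 2, 3))
        B = 20000
        d = bootstrap_distribution(rv, B, seed=5)
        exact_mean, exact_var = 3 * 2.0, 3 * (2 / 3)
        se_mean = np.sqrt(exact_var / B)
        assert abs(d.scores.mean() - exact_mean) < 4 * se_mean
        assert abs(d.scores.var() - exact_var) < 4 * exact_var * np.sqrt(2 / B)


class TestPercentileInterval:
    def test_two_sided_percentiles_2p5_97p5(self):
        d = bootstrap_distribution(ResponseVector("r", (1, 2, 3, 4, 5)),
                                   3000, seed=2)
        ci = percentile_interval(d, 0.95)
        assert ci.lower == np.quantile(d.scores, 0.025)
        assert ci.upper == np.quantile(d.scores, 0.975)
        assert ci.method == "BSI_percentile"

    def test_enumeration_oracle_j3(self):
        # full 3^3 enumeration of equally likely resample scores
        values = (1, 2, 3)
        exact = enumerate_resample_scores(values)
        d = BootstrapDistribution(scores=exact, B=len(exact), observed=6, seed=0)
        ci = percentile_interval(d, 0.95)
        assert ci.lower == pytest.approx(np.quantile(exact, 0.025), abs=1e-9)
        assert ci.upper == pytest.approx(np.quantile(exact, 0.975), abs=1e-9)

    def test_one_sided_uses_stated_percentile_and_scale_limit(self):
        spec = ScaleSpec(5, 1, 5)
        d = bootstrap_distribution(ResponseVector("r", (1, 2, 3, 4, 5)),
                                   3000, seed=3)
        up = percentile_interval(d, 0.95, "upper_only", spec)
        lo = percentile_interval(d, 0.95, "lower_only", spec)
        assert up.upper == np.quantile(d.scores, 0.95)
        assert up.lower == spec.min_score
        assert lo.lower == np.quantile(d.scores, 0.05)
        assert lo.upper == spec.max_score
        with pytest.raises(ValueError):
            percentile_interval(d, 0.95, "upper_only")  # spec required

    def test_width_non_decreasing_in_level(self):
        d = bootstrap_distribution(ResponseVector("r", (1, 1, 2, 3, 5)),
                                   3000, seed=4)
        widths = [percentile_interval(d, lv).width
                  for lv in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert widths == sorted(widths)


class TestBcaInterval:
    def test_reduces_to_percentile_when_z0_and_a_zero(self):
        # symmetric scores with exactly half strictly below the observed
        # value, and a symmetric response vector (zero jackknife skew)
        rv = ResponseVector("r", (1, 2, 3))
        offsets = np.arange(1, 101)
        scores = np.concatenate([6 - offsets * 0.01, 6 + offsets * 0.01])
        d = BootstrapDistribution(scores=scores, B=200, observed=6.0, seed=0)
        params = compute_bca_params(d, rv, 0.95)
        assert params.z0 == 0.0
        assert params.a == pytest.approx(0.0, abs=1e-15)
        pct = percentile_interval(d, 0.95)
        bca = bca_interval(d, rv, 0.95)
        assert (bca.lower, bca.upper) == (pct.lower, pct.upper)

    def test_z0_zero_at_median_and_strict_tie_convention(self):
        rv = ResponseVector("r", (1, 2, 3, 4))
        scores = np.array([5.0] * 50 + [10.0] * 100 + [15.0] * 50)
        d = BootstrapDistribution(scores=scores, B=200, observed=10.0, seed=0)
        # 50 of 200 strictly below the observed score despite 100 ties at it
        params = compute_bca_params(d, rv, 0.95)
        from scipy.stats import norm
        assert params.z0 == pytest.approx(norm.ppf(0.25))

    def test_fallback_to_percentile_when_z0_undefined(self):
        rv = ResponseVector("r", (1, 2, 3, 4))
        scores = np.full(100, 12.0)
        d = BootstrapDistribution(scores=scores, B=100, observed=10.0, seed=0)
        ci = bca_interval(d, rv, 0.95)
        assert ci.method == "BSI_bca"
        assert ci.lower == ci.upper == 12.0  # percentile of a constant

    def test_matches_independent_reference_implementation(self):
        # Reference: R `boot` package, boot.ci(type="bca"), statistic =
        # sum of resampled items, R = 50,000, for responses (1,1,2,3,5):
        # 95% BCa interval (6, 19).  Computed once and frozen.
        rv = ResponseVector("r", (1, 1, 2, 3, 5))
        ci = bsi_interval(rv, 0.95, B=50000, method="bca", seed=7)
        assert ci.lower == pytest.approx(6.0, abs=1.0)
        assert ci.upper == pytest.approx(19.0, abs=1.0)


class TestBsiInterval:
    def test_degenerate_propagates(self):
        with pytest.raises(DegenerateResponseError):
            bsi_interval(ResponseVector("r", (4, 4, 4, 4)), seed=1)

    def test_reproducibility_contract(self):
        rv = ResponseVector("r", (2, 3, 1, 5, 4))
        a = bsi_interval(rv, B=800, seed=99)
        b = bsi_interval(rv, B=800, seed=99)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.center == 15

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(1, 5), min_size=4, max_size=10).filter(
        lambda v: len(set(v)) > 1),
        st.integers(0, 2**31 - 1),
        st.sampled_from(["bca", "percentile"]))
    def test_bound_property(self, values, seed, method):
        # bootstrap intervals can never leave the attainable score range
        spec = ScaleSpec(len(values), 1, 5)
        ci = bsi_interval(ResponseVector("r", values), B=300, method=method,
                          seed=seed, spec=spec)
        assert spec.min_score <= ci.lower <= ci.upper <= spec.max_score

    def test_heterogeneous_responses_widen_interval(self):
        # equal total scores, different spread: uncertainty (width) is
        # larger for the heterogeneous responder (median over seeds)
        spec = ScaleSpec(4, 1, 5)
        het = ResponseVector("het", (1, 5, 1, 5))
        hom = ResponseVector("hom", (3, 3, 3, 3))
        assert sum(het.values) == sum(hom.values)
        near_hom = ResponseVector("nh", (3, 3, 3, 4))
        w_het = np.median([bsi_interval(het, B=500, seed=s, spec=spec).width
                           for s in range(15)])
        w_hom = np.median([bsi_interval(near_hom, B=500, seed=s, spec=spec).width
                           for s in range(15)])
        assert w_het > w_hom
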