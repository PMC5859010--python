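# Methods

## Model and decision rule

Classical test theory writes an observed score as X = V + e with true
score V and error e. Whether a pre/post difference is *reliable* is
operationalised here as non-overlap of per-occasion confidence intervals
for the score, with strict inequality at shared bounds (touching
intervals overlap, hence no change — ties favour the null). With an
expected direction, only the corresponding pair of bounds is compared:
for an expected increase, the post interval's lower bound against the pre
interval's upper bound; mirrored for a decrease. Two-sided detection
checks both orderings. Directional significance implies two-sided
significance for intervals of matching construction, and nested intervals
are never significant.

Two interval constructions are provided.

**ETS (estimating the true score).** The point estimate shrinks the
observed score toward the group mean in proportion to unreliability,
V' = ρ̂·X + (1−ρ̂)·μ̂, with ρ̂ estimated by Cronbach's alpha and the
standard error of measurement σ̂e = σ̂x·√(1−ρ̂). The interval is
V' ± z·σ̂e (two-sided) or the single bound V' ± z·σ̂e with the opposite
bound at the scale limit (one-sided). Its width 2·z·σ̂e is identical for
every respondent, and its limits may fall outside the attainable score
range — both deliberate: they are known properties of the classical
interval that the bootstrap contrast is meant to expose, so limits are
not clipped and reports carry an `ets_out_of_range` flag instead.

**BSI (bootstrap of items).** The respondent's J responses form an
empirical distribution; B resamples of size J (with replacement, summed)
form the bootstrap score distribution. Intervals are empirical
percentiles of that distribution, either raw or BCa-adjusted. Widths now
vary with the heterogeneity of the individual's responses, and every
bound lies inside [J·scale_min, J·scale_max] by construction. A constant
response vector yields a one-point distribution; no interval exists, the
library raises a typed degeneracy error, and pipelines record the
respondent as indeterminate outside the rate denominator.

## BCa details

z0 = Φ⁻¹(#{bootstrap scores strictly below the observed score}/B). The
strict "<" convention matters with integer scores, where ties at the
observed value are common; it follows the standard BCa formulation and is
covered by a tie-heavy test. When every bootstrap score falls on one side
of the observed score z0 is infinite; the implementation falls back to
the raw percentile interval with a logged warning.

The acceleration a comes from a leave-one-item-out jackknife. The total
score is J times the item mean, so the jackknife statistic is the
mean-rescaled total (J/(J−1))·(sum of the remaining J−1 responses), which
keeps replicates on the J-item score scale; a is invariant to this
rescaling. a = Σ(θ̄−θ₍ᵢ₎)³ / (6·[Σ(θ̄−θ₍ᵢ₎)²]^{3/2}), set to 0 (with a
warning) when the jackknife variance is zero. Adjusted percentile levels
are Φ(z0 + (z0+z_k)/(1−a·(z0+z_k))).

Empirical percentiles use linear interpolation between order statistics
(the type-7 convention); at the default B = 3000 the difference between
quantile conventions is far below one score unit. One-sided bootstrap
intervals apply the same BCa adjustment to the single data-derived bound
by default; a `one_sided_percentile` flag forces raw 5th/95th
percentiles instead.

## z values and conventions

Default z values are exact normal quantiles (1.959964…, 1.644854…); a
`paper_rounding` flag substitutes the conventional two-decimal table
values 1.96/1.64 at the 95% level so textbook arithmetic can be
reproduced digit for digit. All variances and SDs use the n−1
denominator, consistently in both parts of alpha (the convention cancels
in the ratio only if consistent). A negative alpha estimate is reported
as computed but clamped to 0 inside the SEM (flagged and warned): an
error variance exceeding the observed-score variance has no meaning in
the additive model. Reverse-keyed items are reflected about the scale
midpoint, x → scale_min + scale_max − x, before any scoring; item indices
are 1-based in user-facing files and 0-based internally.

## Parallel forms from one administration

When only one administration exists, two half-tests serve as parallel
forms. Items are ordered by descending sample mean (ties broken by
original index — the split, and everything downstream, depends on this
tie-break, so it is fixed and documented) and dealt A,B,B,A in blocks of
four; an odd leftover continues the pattern, leaving halves that differ
by one item (half scores are not rescaled; each half's intervals use its
own score bounds). Equivalence is then checked by a paired-samples t test
on the half-score differences and a Pitman–Morgan test for paired
variances (the correlation between pair sums and differences is zero iff
the variances are equal). With zero variance of the differences both
tests are not applicable (NaN): identical halves count as equivalent, a
constant nonzero offset does not. The mean-ordered ABBA split is chosen
to minimise the half difference, so on exchangeable items its rejection
rate sits *below* the nominal level; test-suite calibration of the paired
test therefore uses a fixed arbitrary split, and the ABBA property is
asserted separately (its half-mean gap is stochastically smaller than
under random splits).

## Synthetic data generator

The generator emulates Likert-type responding from a latent trait:
respondent i draws θᵢ ~ Normal(true_score_mean, true_score_sd) once;
their response to item j at any occasion is round(θᵢ + eᵢⱼ) with
eᵢⱼ ~ Normal(0, item_noise_sd), clipped to the scale bounds, independent
across items and occasions. An intervention shifts θ by `change_delta`
before the second administration. This is the simplest mechanism
producing bounded ordinal responses with controllable heterogeneity and a
shared-trait link between occasions.

Defaults — 1,000 respondents, J = 24 items on a 1–5 scale,
θ ~ Normal(3, 0.6), item noise SD 0.8, B = 1,000, level 0.95 — describe a
mid-scale-centred half-test of a long inventory: they yield realistic
internal consistencies (alpha ≈ 0.9), essentially no degenerate
responders, and enough respondents that a 5% rate is estimated with a
Monte-Carlo SE of about 0.7 points. Rates are computed across respondents
within a replication and averaged over `n_replications`; the Monte-Carlo
SE uses the replication-level variance when there is more than one
replication and the binomial formula otherwise. Degenerate respondents
are excluded from every method's denominator so methods are compared on
identical cases. A fully saturated administration (zero total-score
variance) leaves alpha undefined; ETS verdicts for that replication are
recorded as indeterminate while the bootstrap still runs.

What the generator does *not* emulate: item-specific difficulties or
discriminations (no item-response-theory structure), correlated item
errors, missing data, practice or regression-to-the-mean artifacts, and
test–retest dependence beyond the shared trait. Passing calibration tests
therefore show the decision rules behave correctly under a clean additive
error model, not that real questionnaires meet that model.

## Numerical and design choices

- Seeds are mandatory in the bootstrap API; the CLI auto-generates and
  logs one when omitted. Identical inputs + configuration reproduce every
  report bit for bit.
- The non-overlap rule is conservative by construction: requiring two
  95% intervals to separate is stricter than a 5% test on the difference,
  so null rates fall well below nominal (observed ≈ 0.2–0.8% at the
  default conditions) for both methods. This conservatism is asserted,
  not corrected.
- ETS statistics (alpha, mean, SD) are estimated per administration —
  each occasion uses its own — since pooling assumptions are not part of
  the model; the simulation and detection code paths share this choice.
- Missing responses are rejected, never imputed: the bootstrap resamples
  the empirical response set, and imputation would silently change the
  resampling population.
- Power at large shifts is ceiling-limited: responders pushed to the
  scale maximum become degenerate (indeterminate), capping the detection
  rate below 1. This is a property of bounded scales, not a defect.

## Problem sizes

The shipped validation uses 1,000 respondents × 24 items at B = 1,000 for
the null-calibration and power-grid studies (seconds on one CPU core;
B = 3,000 remains the analysis default), B = 50,000 against exact J^J
enumerations for percentile accuracy, and 1,000 random vectors for the
bound property. The BCa implementation is cross-checked against an
independent reference (R's `boot` package, run once; bounds frozen in the
test fixture) on a fixed five-item vector.
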