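# Methods

## The value model

`trialvalue` implements an additive multi-attribute value model. A trial is
described by seven raw metrics; each is mapped to a partial value in
[0, 100] by a criterion-specific partial value function (PVF); the aggregate
trial value is the weight-share-weighted sum of the partial values,

    V(t) = sum_i (w_i / 100) * v_i(x_i),

so the aggregate lives on the same 0–100 scale as the partial values. This
is the standard weighted-sum MCDA form and assumes preferential independence
between criteria (the value of an overall-survival gain does not depend on
the trial's cost, etc.) and that the elicited weights are swing weights —
i.e. they price the worst-to-best swing of each metric, which is the only
weight semantics under which the weighted sum is meaningful.

## Criteria and scales

The default instrument carries seven criteria. Value direction is encoded
purely by anchor ordering: `unmet_need` is measured as five-year survival of
the target disease and runs *down* (85% survival → value 0, 18% → value 100),
`total_cost` runs from 105 M AUD (value 0) down to 3 M AUD (value 100); the
other continuous criteria run upward. `use_of_results` is ordinal with four
levels (unused → informed research → regulatory approval → informed policy).

`trial_access` is defined on a 1–5 ordinal scale (1 = under 20% of eligible
patients can access the trial, 5 = 100%) but recorded portfolios carry a
percent-of-eligible-patients number. The criterion therefore accepts a
percent by default and bands it with `level = ceil(percent/20)` clamped to
[1, 5] (55% → level 3); direct 1–5 input is a config switch
(`percent_input: false`). The PVF then operates on the level scale.

Out-of-range raw values are accepted with a *warning* and clamped to the
nearer anchor at evaluation time — real validation data contains an
overall-survival gain of 1.3 months against a 3-month floor, and a bounded
instrument must still score such trials. Clamping (rather than linear
extrapolation) is this package's documented choice; it guarantees partial
values, and hence aggregates, stay in [0, 100].

## Weights

Complete survey responses (all four background questions plus all ranks and
weights; a permutation of ranks 1..n with the rank-1 weight fixed at 100)
are classified concordant or discordant. Concordance is read
**non-strictly**: a response is concordant iff, over every criterion pair, a
better (smaller) rank carries a weight greater than *or equal to* the
worse-ranked criterion's weight. Ties in raw weights therefore do not break
concordance — the weakest reading of "rankings match the descending order of
weights", and the only one under which equal-weight responses remain
analysable. The instrument collects non-top weights on 0–99, but the engine
accepts 100 (a tie with the top) rather than discard the response.

Concordant weights are standardised to shares of their total
(`w_i / sum * 100`); discordant responses get reciprocal-of-rank surrogate
weights, `(1/k) / H_n * 100`. The portfolio vector is the unweighted arithmetic mean across
respondents; stratified means by stakeholder background are available via
the results object but are deliberately not the default, since the
instrument is designed around a single pooled preference.

Published weight vectors are rounded to one decimal and may not sum to
exactly 100 (the reference vector sums to 100.2). The valuation layer
accepts such a vector as given and offers a `renormalise_weights` switch
that rescales it to exactly 100; both paths are exercised in the tests.

Survey percentages are reported half-up — completion to the whole percent,
everything else to one decimal — matching conventional survey reporting
(37/80 → 46.3%).

## Partial value functions

For each continuous criterion the bisection interviews yield midpoints (the
raw value judged equal in value to 50); `average_midpoint` takes their
arithmetic mean, and `build_bent_stick` draws the two segments. When the
elicited midpoint sits exactly at the centre of the range the bent stick
degenerates to the single straight line between anchors — a closed-form
identity the tests exploit. Ordinal criteria default to equally spaced level
values (0, 100/3, 200/3, 100 for the four-level `use_of_results`),
overridable in the PVF config.

### Reconstructing a lost PVF set

The original deployment's PVF equations were not published alongside its
validation portfolio, but the six published aggregate scores were. The
`reconstruct` module treats recovery of the PVF parameters as an inverse
problem: free parameters are one midpoint per continuous criterion and each
interior level value of each ordinal criterion (8 parameters for the default
instrument), fitted by `scipy.optimize.least_squares` to the known
aggregates with a weak quadratic pull (0.02 per unit of box-scaled
parameter) toward the neutral defaults, which makes the under-determined
problem well-posed and the solution deterministic (single start at the
defaults; midpoints are kept 1% of the range off the anchors).

The fit is reported, not trusted: `PvfFitReport` carries per-trial
residuals. For the reference portfolio the two-segment family **cannot**
reproduce the published aggregate column exactly — the best attainable fit
leaves about 1.1 points on one trial — which is a structural property of the
bent-stick family, not an optimiser failure: the published gap between
Examples C and F exceeds what any midpoint configuration can produce under
the published weights. The reconstructed instrument does reproduce the
published *ranking* of all six trials (under both the as-published and the
renormalised weight vector) and the published dominance structure (unmet
need the largest contribution in four of six trials), and those two checks —
plus staying within the fit's own reported residual of the published
aggregates — are what the acceptance tests assert. The acceptance script
writes the reconstructed aggregates and the fit's maximum absolute error so
the discrepancy is always visible.

## Synthetic surveys

The simulator emulates the elicitation study's respondent population and is
the test bed for the whole weight pipeline. Defaults are the study's
conditions: 157 respondents, completion probability 80/157, concordance
probability 43/80 among completers, stakeholder backgrounds drawn from the
published complete-responder mix (31% health professionals, 19%
patients/consumers, 18% statisticians, 10% CRA/CRO, 8% scientists, 8% other,
6% health economists), and a latent true weight vector equal to the
published means. Weight noise defaults to sd 8 on the 0–100 standardised
scale — of the order of the between-respondent spread such surveys show,
large enough to scramble adjacent ranks without erasing the consensus
ordering.

Generation per respondent, in fixed draw order (background, affiliation,
experience, completion, concordance, weight noise, discordance swaps,
dropout cut): latent scores are the true weights plus Gaussian noise
(floored at 0.5 so all scores stay positive); ranks are the descending order
of the scores (ties broken by criterion order); raw weights are the scores
scaled to top = 100 and quantised to the instrument's integer scale (top
pinned at 100, others clamped to 0–99). An intended-discordant respondent
then has adjacent (by rank) weight pairs swapped against the ranking — the
minimal, controllable violation of concordance; no generative model of real
discordant behaviour is claimed. Dropouts stop answering partway through the
rank/weight questions. A single integer seed drives everything;
`exact_counts=True` fixes the complete/concordant counts instead of drawing
them Bernoulli, which pins the accounting percentages for reproduction runs.

Because raw weights are quantised to integers, only truth vectors that are
proportional to an integer weight profile (top = 100) are *exactly*
recoverable from noise-free responses; `representable_weights` maps any
vector to the nearest such profile, and the recovery tests use the
representable quantisation of the published means (which differs from them
by at most ~0.13 per criterion). With noise, the estimated mean converges to
a noise-dependent expectation (ranking noise plus the top-pinned
quantisation bias both shift it slightly off the truth), so the recovery
tests compare against that expectation, estimated from an independent large
run (n = 20,000), at n = 500 and n = 5,000 — sizes chosen to give a √10
separation of Monte-Carlo standard errors while keeping the suite quick.

What passing these tests shows — and does not. The generator reproduces the
*statistical structure* the analysis assumes (rank/weight consistency,
dropout, a concordance mixture); it does not model respondent fatigue,
background-dependent preferences or correlated criterion judgements, so the
tests validate the estimation machinery, not the behavioural realism of any
particular survey.

## Numerical and interface choices

- All tables are comma-separated UTF-8 with header rows; criterion columns
  are identified by id (`rank_<id>`, `weight_<id>`), never by position.
- Reports round half-up (aggregates 2 dp, weights 1 dp by default); a
  full-precision companion file is always written so no check depends on
  report rounding.
- Ranking ties are broken lexicographically by trial id and the rule is
  documented; equal-value ties are otherwise meaningful and all tied
  dominant criteria are reported.
- Degenerate inputs fail loudly: all-zero weight vectors, empty response
  subsets, empty elicitation lists and midpoints at or beyond an anchor all
  raise `ValueError` with the offending name in the message.
- The CLI exits non-zero on any such error, logs the filter accounting
  (total → complete → concordant/discordant) at INFO, and logs out-of-range
  raw values as warnings while continuing.

## Known limitations

- The reconstructed PVF set is one deterministic member of a continuum of
  near-optimal solutions; individual midpoints (e.g. for academic impact,
  which the validation trials barely constrain) should not be
  over-interpreted even though the portfolio-level behaviour is pinned.
- Only overall-survival gain is supported as the patient-outcomes metric;
  progression-free survival, QALYs or toxicity endpoints would require
  re-elicitation of weights and are out of scope.
- The sensitivity comparison (weight deltas, aggregate deltas, pairwise rank
  inversions) uses this package's own definitions of those metrics.
- Prospective valuation — scoring trials from forecast rather than observed
  metrics — is not addressed.
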