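# trialvalue

Multi-criteria decision analysis (MCDA) for valuing and prioritising
portfolios of cancer clinical trials.

Clinical trials are expensive and health systems cannot run them all, yet the
established appraisal tools (risk-of-bias scores, the ASCO/ESMO benefit
frameworks) each capture only a narrow slice of what makes a trial worth
running. `trialvalue` implements a seven-criterion MCDA instrument that
aggregates stakeholder preferences over *unmet need* (five-year survival of
the target disease), *size of the target population*, *trial access*,
*patient outcomes* (overall-survival gain), *total trial cost*, *academic
impact* and *use of trial results* into a single 0–100 value per trial. It is
aimed at trial units, funders and health-economics researchers who need a
transparent, reproducible screening score for portfolio decisions.

## The model

Each trial *t* with raw metrics *x₁ … x₇* gets the weighted-sum value

> V(t) = Σᵢ (wᵢ / 100) · vᵢ(xᵢ),  V ∈ [0, 100]

where the **partial value functions** vᵢ are "bent sticks": two linear
segments from the worst anchor (value 0) through the bisection-elicited
midpoint (value 50) to the best anchor (value 100), with out-of-range inputs
clamped. Ordinal criteria map each level to a fixed value.

The **weights** wᵢ come from a swing-weighting survey. Each complete
response is classified *concordant* (stated ranks match the descending order
of stated weights, read non-strictly) or *discordant*. Concordant weights are
standardised to sum to 100,

> wᵢ ← wᵢ / Σⱼ wⱼ × 100,

while discordant responses are replaced by reciprocal-of-rank surrogate
weights, (1/k) / Hₙ × 100 for the criterion ranked k (Hₙ the n-th harmonic
number). The portfolio weight vector is the per-criterion mean over
respondents, either combined or concordant-only.

## Worked example

```python
import trialvalue as tv

# weights elicited from a (synthetic) stakeholder survey
survey = tv.simulate_survey(tv.SurveySimConfig(seed=42))
res = tv.SwingWeightModel(survey).fit(subset="combined")
print(res.summary())

# score the six-trial validation portfolio with the published mean weights
pvfs, report = tv.reconstruct_reference_pvfs()
results = tv.ValueModel(pvfs, tv.reference_weights()).score(tv.reference_portfolio())
print(results.summary())
```

The survey summary prints the filter accounting and the estimated weights
(157 simulated respondents, of whom 79 happened to complete at this seed):

```
Swing-weight model: 79 responses (subset=combined)
responses: 157 total, 79 complete (50%)
concordant: 37 (46.8%), discordant: 42 (53.2%)
...
mean standardised weights:
                  mean_weight     sd   n
criterion
unmet_need              27.37  10.40  79
population_size         13.91   9.94  79
trial_access            11.22   5.72  79
patient_outcomes        18.52  10.07  79
total_cost               7.68   5.83  79
academic_impact          8.12   6.95  79
use_of_results          13.17   8.69  79
```

and the portfolio report ranks the six reference trials:

```
Portfolio of 6 trials, weights: manual (n=80, total=100.2)

           rank  aggregate
trial_id
Example B     1      57.27
Example C     2      50.73
Example A     3      45.83
Example D     4      40.59
Example F     5      33.11
Example E     6      24.53

dominant criterion: unmet_need leads in 4 of 6 trials
```

The aggregate is each trial's total value on the common 0–100 scale; Example
B leads because the disease it targets has very poor five-year survival
(high unmet need) and its results fed regulatory approval, while Example E
scores lowest — its unmet-need and use-of-results contributions are both
zero. `results.contributions_long()` gives a plot-ready decomposition and
`results.plot_contributions()` draws the stacked-bar version.

The same pipeline is available from a shell:

```bash
trialvalue simulate --seed 42 --out survey.csv
trialvalue weights  --survey survey.csv --out weights.yaml
trialvalue value    --trials trials.csv --weights weights.yaml --pvf pvf.yaml --out report.csv
trialvalue sensitivity --survey survey.csv --trials trials.csv --out sens.csv
```

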