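from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trialvalue as tv

from conftest import make_response

IDS = tv.default_criteria_set().ids


def record_at(criteria, position: str, trial_id="t"):
    """A record with every criterion at its worst/best anchor."""
    raw = {}
    for crit in criteria:
        if crit.kind == "continuous":
            v = crit.worst_raw if position == "worst" else crit.best_raw
            if crit.id == "trial_access":  # percent-input scale
                v = 0.0 if position == "worst" else 100.0
            raw[crit.id] = v
        else:
            raw[crit.id] = crit.levels[0] if position == "worst" else crit.levels[-1]
    return tv.TrialRecord(trial_id, raw)


def equal_weights():
    return tv.WeightVector({cid: 100.0 / 7 for cid in IDS}, provenance="manual")


def test_all_best_record_scores_100_and_all_worst_0(criteria):
    pvfs = tv.default_pvf_set(criteria)
    for weights in (equal_weights(), tv.reference_weights().renormalised()):
        assert tv.value_trial(record_at(criteria, "best"), pvfs, weights, criteria).aggregate == pytest.approx(100)
        assert tv.value_trial(record_at(criteria, "worst"), pvfs, weights, criteria).aggregate == pytest.approx(0)


def test_hand_dot_product_with_equal_weights(criteria):
    """Partial values (0, 50, 100, 50, 0, 100, 50) under equal weights -> 50."""
    pvfs = tv.default_pvf_set(
        criteria, level_values={"use_of_results": [0, 50, 50, 100]}
    )
    raw = {
        "unmet_need": 85.0,  # worst -> 0
        "population_size": (0.2 + 1000) / 2,  # mid -> 50
        "trial_access": 100.0,  # level 5 -> 100
        "patient_outcomes": (3 + 36) / 2,  # mid -> 50
        "total_cost": 105.0,  # worst -> 0
        "academic_impact": 1000.0,  # best -> 100
        "use_of_results": "informed_research",  # configured 50
    }
    val = tv.value_trial(tv.TrialRecord("t", raw), pvfs, equal_weights(), criteria)
    assert [val.partial_values[cid] for cid in IDS] == pytest.approx([0, 50, 100, 50, 0, 100, 50])
    assert val.aggregate == pytest.approx(50)
    assert val.aggregate == pytest.approx(sum(val.contributions.values()), abs=1e-9)


def test_coverage_gap_is_named(criteria, ref_weights):
    pvfs = tv.default_pvf_set(criteria)
    del pvfs["total_cost"]
    with pytest.raises(ValueError, match="total_cost"):
        tv.value_trial(record_at(criteria, "best"), pvfs, ref_weights, criteria)


# ---------------------------------------------------------------- properties

raw_record = st.fixed_dictionaries(
    {
        "unmet_need": st.floats(0, 100),
        "population_size": st.floats(0.2, 1000),
        "trial_access": st.floats(0, 100),
        "patient_outcomes": st.floats(0, 40),
        "total_cost": st.floats(0, 120),
        "academic_impact": st.floats(0, 1200),
        "use_of_results": st.sampled_from(
            ["unused", "informed_research", "regulatory_approval", "informed_policy"]
        ),
    }
)
weight_vectors = st.lists(st.floats(0.1, 100), min_size=7, max_size=7).map(
    lambda w: tv.WeightVector(dict(zip(IDS, tv.standardise_weights(w))))
)
mid_fracs = st.lists(st.floats(0.05, 0.95), min_size=6, max_size=6)


def pvfs_from_fracs(criteria, fracs):
    mids, i = {}, 0
    for crit in criteria:
        if crit.kind == "continuous":
            lo, hi = crit.raw_interval()
            mids[crit.id] = lo + fracs[i] * (hi - lo)
            i += 1
    return tv.default_pvf_set(criteria, midpoints=mids)


@given(raw=raw_record, w=weight_vectors, fracs=mid_fracs)
def test_aggregate_bounded_on_random_instances(raw, w, fracs):
    criteria = tv.default_criteria_set()
    pvfs = pvfs_from_fracs(criteria, fracs)
    val = tv.value_trial(tv.TrialRecord("t", raw), pvfs, w, criteria)
    assert 0.0 <= val.aggregate <= 100.0 + 1e-9
    for cid in IDS:
        assert -1e-9 <= val.contributions[cid] <= w[cid] + 1e-9


@given(raw=raw_record, w=weight_vectors, fracs=mid_fracs, step=st.floats(0.01, 1))
def test_improving_one_metric_never_lowers_the_aggregate(raw, w, fracs, step):
    criteria = tv.default_criteria_set()
    pvfs = pvfs_from_fracs(criteria, fracs)
    base = tv.value_trial(tv.TrialRecord("t", raw), pvfs, w, criteria).aggregate
    for crit in criteria:
        better = dict(raw)
        if crit.kind == "continuous":
            x = float(raw[crit.id])
            better[crit.id] = x + step * (
                (100.0 if crit.id == "trial_access" else crit.best_raw) - x
            )
        else:
            idx = crit.levels.index(raw[crit.id])
            better[crit.id] = crit.levels[min(idx + 1, len(crit.levels) - 1)]
        improved = tv.value_trial(tv.TrialRecord("t", better), pvfs, w, criteria).aggregate
        assert improved >= base - 1e-7


@given(
    pv=st.lists(st.fractions(0, 100), min_size=7, max_size=7),
    w=st.lists(st.fractions(Fraction(1, 10), 100), min_size=7, max_size=7),
)
def test_aggregate_matches_exact_rational_oracle(pv, w):
    """Float aggregation agrees with exact Fraction arithmetic on small instances."""
    wsum = sum(w)
    weights = tv.WeightVector(dict(zip(IDS, (float(x / wsum * 100) for x in w))))
    criteria = tv.default_criteria_set()
    pvfs = {
        cid: _FixedPvf(cid, float(v)) for cid, v in zip(IDS, pv)
    }
    raw = {cid: 0.0 for cid in IDS}
    raw["use_of_results"] = "unused"
    val = tv.value_trial(tv.TrialRecord("t", raw), pvfs, weights, criteria)
    oracle = sum((x / wsum) * v for x, v in zip(w, pv))
    assert val.aggregate == pytest.approx(float(oracle), rel=1e-9, abs=1e-9)


class _FixedPvf:
    """Constant PVF used to drive the aggregation layer with exact targets."""

    kind = "continuous"

    def __init__(self, cid, value):
        self.criterion_id = cid
        self.value = value

    def evaluate(self, x):
        return self.value


def test_weight_shift_toward_a_strong_criterion_raises_value(criteria):
    pvfs = tv.default_pvf_set(criteria)
    raw = record_at(criteria, "best").raw_values.copy()
    raw["total_cost"] = 105.0  # score 0 here, 100 elsewhere
    rec = tv.TrialRecord("t", raw)
    w = {cid: 100.0 / 7 for cid in IDS}
    base = tv.value_trial(rec, pvfs, tv.WeightVector(dict(w)), criteria).aggregate
    w["total_cost"] -= 5
    w["unmet_need"] += 5
    shifted = tv.value_trial(rec, pvfs, tv.WeightVector(w), criteria).aggregate
    assert shifted > base


# ---------------------------------------------------------------- portfolio


def test_portfolio_ranking_and_tie_break(criteria, ref_weights):
    pvfs = tv.default_pvf_set(criteria)
    best, worst = record_at(criteria, "best", "zz_best"), record_at(criteria, "worst", "aa_worst")
    twin = tv.TrialRecord("ab_best", best.raw_values)
    ranked = tv.value_portfolio([best, worst, twin], pvfs, ref_weights, criteria)
    assert [v.trial_id for v in ranked] == ["ab_best", "zz_best", "aa_worst"]
    assert ranked[0].aggregate == ranked[1].aggregate

    single = tv.value_portfolio([worst], pvfs, ref_weights, criteria)
    assert single[0].trial_id == "aa_worst"
    with pytest.raises(ValueError):
        tv.value_portfolio([], pvfs, ref_weights, criteria)


def test_dominant_criterion_reporting():
    v1 = tv.TrialValuation("t1", {}, dict(zip(IDS, [24.4, 0, 0, 0, 0, 0, 0])), 24.4)
    assert v1.dominant() == ("unmet_need",)
    v2 = tv.TrialValuation("t2", {}, {cid: 10.0 for cid in IDS}, 70.0)
    assert set(v2.dominant()) == set(IDS)
    per_trial, modal, count = tv.dominant_criterion([v1, v2])
    assert per_trial["t1"] == ("unmet_need",)
    assert count == 2 and "unmet_need" in modal


# ---------------------------------------------------------------- sensitivity


def test_sensitivity_identical_subsets_yield_zero_deltas(criteria, portfolio):
    classified = [
        tv.process_response(make_response((100, 90, 80, 70, 60, 50, 40), respondent_id=f"R{i}"), criteria)
        for i in range(3)
    ]
    pvfs = tv.default_pvf_set(criteria)
    rep = tv.sensitivity_compare(classified, portfolio, pvfs, criteria)
    assert all(d == pytest.approx(0) for d in rep.weight_delta.values())
    assert all(d == pytest.approx(0) for d in rep.aggregate_delta.values())
    assert rep.n_rank_inversions == 0


def test_sensitivity_weight_delta_hand_value(criteria, portfolio):
    conc = tv.process_response(make_response((100,) * 7, respondent_id="R1"), criteria)
    disc = tv.process_response(make_response((100, 40, 90, 70, 60, 50, 30), respondent_id="R2"), criteria)
    pvfs = tv.default_pvf_set(criteria)
    rep = tv.sensitivity_compare([conc, disc], portfolio, pvfs, criteria)
    top = criteria.ids[0]
    assert rep.weight_delta[top] == pytest.approx(26.4266 - 100 / 7, abs=5e-4)
    with pytest.raises(ValueError):
        tv.sensitivity_compare([disc], portfolio, pvfs, criteria)


def test_contribution_plot_stacks_to_the_aggregate(criteria, ref_weights, portfolio):
    import matplotlib

    matplotlib.use("Agg")
    results = tv.ValueModel(tv.default_pvf_set(criteria), ref_weights, criteria).score(portfolio)
    ax = results.plot_contributions()
    heights = np.zeros(len(results.valuations))
    for container in ax.containers:
        heights += [patch.get_height() for patch in container]
    assert heights == pytest.approx([v.aggregate for v in results.valuations])
    long = results.contributions_long()
    assert set(long.columns) == {"trial_id", "criterion", "contribution", "aggregate"}
    assert len(long) == 6 * 7


def test_rank_inversions_counts_discordant_pairs():
    assert tv.rank_inversions(["a", "b", "c"], ["a", "b", "c"]) == 0
    assert tv.rank_inversions(["a", "b", "c"], ["c", "b", "a"]) == 3
    assert tv.rank_inversions(["a", "b", "c"], ["b", "a", "c"]) == 1
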