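from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trialvalue as tv
from trialvalue.weights import CONCORDANT, DISCORDANT, IncompleteResponseError

from conftest import make_response

# ------------------------------------------------------ standardisation


def test_standardise_hand_example():
    out = tv.standardise_weights([100, 70, 50, 40, 30, 20, 10])
    assert out == pytest.approx([31.25, 21.875, 15.625, 12.5, 9.375, 6.25, 3.125])


def test_standardise_equal_weights_split_evenly():
    out = tv.standardise_weights([100] * 7)
    assert out == pytest.approx([100 / 7] * 7)


def test_standardise_rejects_degenerate_input():
    with pytest.raises(ValueError):
        tv.standardise_weights([0, 0, 0])
    with pytest.raises(ValueError):
        tv.standardise_weights([10, -1, 5])


@given(
    w=st.lists(st.floats(0, 100), min_size=2, max_size=9).filter(lambda v: sum(v) > 1e-6),
    c=st.floats(0.01, 50),
)
def test_standardise_sums_idempotent_scale_invariant(w, c):
    out = tv.standardise_weights(w)
    assert sum(out) == pytest.approx(100, abs=1e-9)
    assert tv.standardise_weights(out) == pytest.approx(out, abs=1e-9)
    assert tv.standardise_weights([c * x for x in w]) == pytest.approx(out, abs=1e-6)


# ------------------------------------------------- reciprocal-of-rank


def exact_reciprocal_rank(n):
    """Independent oracle: exact rational arithmetic."""
    h = sum(Fraction(1, j) for j in range(1, n + 1))
    return [Fraction(1, k) / h * 100 for k in range(1, n + 1)]


@pytest.mark.parametrize("n", [1, 2, 3, 4])
def test_reciprocal_rank_matches_exact_rationals(n):
    got = tv.reciprocal_rank_weights(n)
    want = exact_reciprocal_rank(n)
    assert got == pytest.approx([float(f) for f in want], abs=1e-12)


def test_reciprocal_rank_n2_hand_values():
    assert tv.reciprocal_rank_weights(2) == pytest.approx([200 / 3, 100 / 3])


def test_reciprocal_rank_n7_decreasing_and_sums_to_100():
    w = tv.reciprocal_rank_weights(7)
    assert w[0] == pytest.approx(float(Fraction(100 * 140, 363)), abs=1e-12)
    assert all(a > b for a, b in zip(w, w[1:]))
    assert sum(w) == pytest.approx(100, abs=1e-9)


def test_reciprocal_rank_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        tv.reciprocal_rank_weights(0)


# ---------------------------------------------------------------- concordance


@pytest.mark.parametrize(
    "weights_by_rank,expected",
    [
        ((100, 90, 80, 70, 60, 50, 40), CONCORDANT),
        ((100, 40, 90, 70, 60, 50, 30), DISCORDANT),
        ((100, 80, 80, 70, 60, 50, 40), CONCORDANT),  # ties are tolerated
    ],
)
def test_classify_concordance(weights_by_rank, expected, criteria):
    r = make_response(weights_by_rank)
    assert tv.classify_concordance(r, criteria) == expected


def test_tied_weights_satisfy_the_pairwise_rule_everywhere(criteria):
    """Enumerate all 21 criterion pairs: smaller rank never carries smaller weight."""
    r = make_response((100, 80, 80, 70, 60, 50, 40))
    for a, b in combinations(criteria.ids, 2):
        better, worse = (a, b) if r.ranks[a] < r.ranks[b] else (b, a)
        assert r.raw_weights[better] >= r.raw_weights[worse]
    assert tv.classify_concordance(r, criteria) == CONCORDANT


def test_incomplete_response_is_rejected_with_field_names(criteria):
    r = make_response((100, 90, 80, 70, 60, 50, 40), background="")
    with pytest.raises(IncompleteResponseError, match="background"):
        tv.classify_concordance(r, criteria)
    partial = tv.SwingResponse(respondent_id="x", ranks={}, raw_weights={})
    assert not partial.is_complete(criteria)
    assert "rank_unmet_need" in partial.missing_fields(criteria)


# ---------------------------------------------------------------- processing


def test_process_concordant_uses_own_weights(criteria):
    r = make_response((100, 90, 80, 70, 60, 50, 40))
    c = tv.process_response(r, criteria)
    assert c.category == CONCORDANT
    want = tv.standardise_weights({cid: r.raw_weights[cid] for cid in criteria.ids})
    assert c.standardised_weights == pytest.approx(want)


def test_process_discordant_imputes_reciprocal_rank(criteria):
    r = make_response((100, 40, 90, 70, 60, 50, 30))
    c = tv.process_response(r, criteria)
    assert c.category == DISCORDANT
    assert [c.standardised_weights[cid] for cid in criteria.ids] == pytest.approx(
        [38.567, 19.284, 12.856, 9.642, 7.713, 6.428, 5.510], abs=5e-4
    )


def test_discordant_raw_weights_do_not_matter(criteria):
    a = tv.process_response(make_response((100, 40, 90, 70, 60, 50, 30)), criteria)
    b = tv.process_response(make_response((100, 0, 99, 1, 98, 2, 97)), criteria)
    assert a.standardised_weights == pytest.approx(b.standardised_weights)


# ---------------------------------------------------------------- averaging


def test_mean_of_identical_responses_is_the_response(criteria):
    c = tv.process_response(make_response((100, 90, 80, 70, 60, 50, 40)), criteria)
    mv = tv.mean_weight_vector([c, c])
    assert mv.n_responses == 2
    assert {k: mv[k] for k in c.standardised_weights} == pytest.approx(
        dict(c.standardised_weights)
    )


def test_mean_mixes_concordant_and_imputed_vectors(criteria):
    conc = tv.process_response(make_response((100,) * 7), criteria)
    disc = tv.process_response(make_response((100, 40, 90, 70, 60, 50, 30)), criteria)
    mv = tv.mean_weight_vector([conc, disc], "combined")
    top = criteria.ids[0]  # ranked 1 by both
    assert mv[top] == pytest.approx((100 / 7 + 38.5675) / 2, abs=5e-4)
    assert mv.total() == pytest.approx(100, abs=1e-9)
    only = tv.mean_weight_vector([conc, disc], "concordant_only")
    assert only.n_responses == 1
    assert only[top] == pytest.approx(100 / 7)


def test_mean_requires_a_nonempty_subset(criteria):
    disc = tv.process_response(make_response((100, 40, 90, 70, 60, 50, 30)), criteria)
    with pytest.raises(ValueError):
        tv.mean_weight_vector([disc], "concordant_only")
    with pytest.raises(ValueError):
        tv.mean_weight_vector([], "combined")


@given(st.lists(st.lists(st.integers(0, 99), min_size=6, max_size=6), min_size=1, max_size=8))
def test_mean_vector_always_sums_to_100(tails):
    criteria = tv.default_criteria_set()
    classified = [
        tv.process_response(make_response((100, *tail), respondent_id=f"R{i}"), criteria)
        for i, tail in enumerate(tails)
    ]
    mv = tv.mean_weight_vector(classified)
    assert mv.total() == pytest.approx(100, abs=1e-9)


# ---------------------------------------------------------------- summaries & model


def test_summary_all_complete_concordant(criteria):
    rs = [make_response((100, 90, 80, 70, 60, 50, 40), respondent_id=f"R{i}") for i in range(4)]
    s = tv.summarise_survey(rs, criteria)
    assert (s.completion_pct, s.concordant_pct) == (100.0, 100.0)
    assert s.rank1_share_pct[criteria.ids[0]] == 100.0


def test_summary_of_empty_survey_has_no_percentages(criteria):
    s = tv.summarise_survey([], criteria)
    assert s.n_total == 0 and s.completion_pct is None and s.concordant_pct is None


def test_model_fit_from_dataframe_matches_direct_path(criteria):
    responses = [
        make_response((100, 90, 80, 70, 60, 50, 40), respondent_id="R1"),
        make_response((100, 40, 90, 70, 60, 50, 30), respondent_id="R2"),
        tv.SwingResponse(respondent_id="R3"),  # dropout
    ]
    from trialvalue.io import responses_from_frame, survey_to_frame

    df = survey_to_frame(responses, criteria)
    res = tv.SwingWeightModel.from_dataframe(df, criteria).fit()
    direct = tv.mean_weight_vector(
        [tv.process_response(r, criteria) for r in responses[:2]]
    )
    assert {k: res.weights[k] for k in direct.weights} == pytest.approx(dict(direct.weights))
    assert res.survey.n_total == 3 and res.survey.n_complete == 2
    assert "mean standardised weights" in res.summary()
    back = responses_from_frame(df, criteria)
    assert [r.respondent_id for r in back] == ["R1", "R2", "R3"]
    assert not back[2].is_complete(criteria)
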