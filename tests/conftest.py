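import pytest
from hypothesis import HealthCheck, settings

import trialvalue as tv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def criteria():
    return tv.default_criteria_set()


@pytest.fixture(scope="session")
def portfolio():
    return tv.reference_portfolio()


@pytest.fixture(scope="session")
def ref_weights():
    return tv.reference_weights()


@pytest.fixture(scope="session")
def reconstructed():
    """PVF sets fitted to the published validation aggregates, both weight paths."""
    return {
        "printed": tv.reconstruct_reference_pvfs(renormalise_weights=False),
        "renormalised": tv.reconstruct_reference_pvfs(renormalise_weights=True),
    }


def make_response(weights_by_rank, criteria=None, respondent_id="R1", **demo):
    """A complete response whose rank-k criterion (in canonical id order) has
    the k-th weight of ``weights_by_rank``."""
    criteria = criteria or tv.default_criteria_set()
    ids = criteria.ids
    assert len(weights_by_rank) == len(ids)
    fields = dict(
        background="statistician",
        paid_affiliation="no",
        trial_experience="10_plus_years",
        country="Australia",
    )
    fields.update(demo)
    return tv.SwingResponse(
        respondent_id=respondent_id,
        ranks={cid: k + 1 for k, cid in enumerate(ids)},
        raw_weights={cid: float(w) for cid, w in zip(ids, weights_by_rank)},
        **fields,
    )
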