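"""Reference fixtures published with the original seven-criterion instrument.

These are the six-trial validation portfolio, its published aggregate scores,
and the mean stakeholder weights from the original elicitation survey.  They
let every pipeline stage run without any external download and anchor the
regression tests.
"""

from __future__ import annotations

from .criteria import TrialRecord
from .weights import WeightVector

__all__ = [
    "reference_portfolio",
    "reference_weights",
    "reference_aggregates",
    "reference_background_mix",
    "reference_rank1_shares",
]


def reference_portfolio() -> list[TrialRecord]:
    """The six retrospectively scored cancer trials (Examples A-F).

    Values are kept exactly as published, including two overall-survival gains
    below the instrument's 3-month floor (1.3 and 1.7 months, clamped to value
    0 at evaluation) and Example B's population entry of 222.0 per 100,000 —
    flagged because A and B are the same trial yet A records 12.0.
    """
    rows = [
        ("Example A", 8.0, 12.0, 55.0, 1.3, 40.5, 440.0, "informed_research"),
        ("Example B", 8.0, 222.0, 55.0, 1.7, 55.0, 440.0, "regulatory_approval"),
        ("Example C", 35.0, 12.0, 55.0, 14.8, 13.0, 31.0, "informed_policy"),
        ("Example D", 32.0, 8.1, 55.0, 4.5, 40.5, 508.0, "informed_research"),
        ("Example E", 91.0, 65.0, 55.0, 9.4, 27.0, 69.0, "unused"),
        ("Example F", 24.0, 7.8, 55.0, 7.5, 40.5, 40.0, "unused"),
    ]
    keys = (
        "unmet_need",
        "population_size",
        "trial_access",
        "patient_outcomes",
        "total_cost",
        "academic_impact",
        "use_of_results",
    )
    return [
        TrialRecord(trial_id=row[0], raw_values=dict(zip(keys, row[1:])))
        for row in rows
    ]


def reference_weights() -> WeightVector:
    """Published mean standardised weights (they sum to 100.2 after rounding)."""
    return WeightVector(
        weights={
            "unmet_need": 24.4,
            "patient_outcomes": 21.2,
            "use_of_results": 14.4,
            "population_size": 13.2,
            "trial_access": 12.4,
            "total_cost": 7.4,
            "academic_impact": 7.2,
        },
        provenance="manual",
        n_responses=80,
    )


def reference_aggregates() -> dict[str, float]:
    """Published aggregate values of the validation portfolio (0-100 scale)."""
    return {
        "Example A": 45.81,
        "Example B": 57.31,
        "Example C": 51.83,
        "Example D": 40.61,
        "Example E": 24.31,
        "Example F": 32.19,
    }


def reference_background_mix() -> dict[str, float]:
    """Stakeholder-background proportions among the 80 complete survey responses."""
    return {
        "health_professional": 0.31,
        "patient_consumer": 0.19,
        "statistician": 0.18,
        "cra_cro": 0.10,
        "scientist": 0.08,
        "other": 0.08,
        "health_economist": 0.06,
    }


def reference_rank1_shares() -> dict[str, float]:
    """Published share (%) of rank-1 votes each criterion received."""
    return {
        "unmet_need": 43.8,
        "patient_outcomes": 25.0,
        "use_of_results": 13.8,
        "population_size": 8.8,
        "trial_access": 8.8,
        "academic_impact": 0.0,
        "total_cost": 0.0,
    }
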