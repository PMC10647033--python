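"""Swing-weighting engine: from raw survey responses to mean criterion weights.

Respondents rank the seven criteria by the value of swinging each from its
worst to its best outcome (rank 1 = most valuable swing), then weight every
criterion 0-99 relative to the top-ranked one, which is fixed at 100.

A response is *concordant* when the stated ranking matches the descending
order of the stated weights, and its weights are standardised to sum to 100:

    w_i / sum_i(w_i) * 100

A *discordant* response's weights are discarded and replaced by surrogate
reciprocal-of-rank weights driven only by the stated ranks:

    (1/k) / sum_{j=1..n}(1/j) * 100     for the criterion ranked k

The portfolio weight vector is the unweighted mean of the per-respondent
standardised vectors, optionally restricted to the concordant subset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import CriteriaSet, default_criteria_set
from .utils import round_half_up

__all__ = [
    "SwingResponse",
    "ClassifiedResponse",
    "WeightVector",
    "SurveySummary",
    "SwingWeightModel",
    "SwingWeightResults",
    "classify_concordance",
    "standardise_weights",
    "reciprocal_rank_weights",
    "process_response",
    "mean_weight_vector",
    "summarise_survey",
    "BACKGROUNDS",
    "EXPERIENCE_LEVELS",
]

BACKGROUNDS = (
    "health_economist",
    "health_professional",
    "patient_consumer",
    "scientist",
    "statistician",
    "cra_cro",
    "other",
)

EXPERIENCE_LEVELS = ("none", "under_10_years", "10_plus_years", "other")

CONCORDANT = "concordant"
DISCORDANT = "discordant"


class IncompleteResponseError(ValueError):
    """Raised when an operation requiring a complete response receives one that is not."""


@dataclass(frozen=True)
class SwingResponse:
    """One respondent's demographics plus swing ranks and raw weights.

    ``ranks`` and ``raw_weights`` may be partial for respondents who dropped
    out; such responses are incomplete and excluded from all weight analyses.
    """

    respondent_id: str
    background: str = ""
    paid_affiliation: str = ""  # "yes" | "no" | "" (unanswered)
    trial_experience: str = ""
    country: str = ""
    ranks: Mapping[str, int] = field(default_factory=dict)
    raw_weights: Mapping[str, float] = field(default_factory=dict)

    def missing_fields(self, criteria: CriteriaSet) -> list[str]:
        """Names of required answers this response lacks (or gave invalidly)."""
        missing: list[str] = []
        for name in ("background", "paid_affiliation", "trial_experience", "country"):
            if not getattr(self, name):
                missing.append(name)
        for cid in criteria.ids:
            if cid not in self.ranks or self.ranks[cid] is None:
                missing.append(f"rank_{cid}")
            if cid not in self.raw_weights or self.raw_weights[cid] is None:
                missing.append(f"weight_{cid}")
        if missing:
            return missing
        # structural validity enforced by the survey instrument
        rank_values = sorted(int(self.ranks[cid]) for cid in criteria.ids)
        if rank_values != list(range(1, criteria.n + 1)):
            missing.append("ranks (not a permutation of 1..n)")
            return missing
        top = [cid for cid in criteria.ids if int(self.ranks[cid]) == 1][0]
        if float(self.raw_weights[top]) != 100:
            missing.append("weights (top-ranked criterion must weigh 100)")
        for cid in criteria.ids:
            w = float(self.raw_weights[cid])
            # the instrument asks for 0-99, but a tie with the top is analysable
            if cid != top and not 0 <= w <= 100:
                missing.append(f"weight_{cid} (must be 0-100)")
        return missing

    def is_complete(self, criteria: CriteriaSet) -> bool:
        return not self.missing_fields(criteria)


@dataclass(frozen=True)
class ClassifiedResponse:
    """A complete response with its concordance label and standardised weights."""

    response: SwingResponse
    category: str  # CONCORDANT | DISCORDANT
    standardised_weights: Mapping[str, float]


@dataclass(frozen=True)
class WeightVector:
    """Criterion weights on the 0-100 scale (summing to 100 up to reporting rounding)."""

    weights: Mapping[str, float]
    provenance: str = "manual"  # combined | concordant_only | imputed | manual
    n_responses: int = 0

    def total(self) -> float:
        return float(sum(self.weights.values()))

    def renormalised(self) -> "WeightVector":
        """Rescale so the weights sum to exactly 100 (published vectors are rounded)."""
        t = self.total()
        if t <= 0:
            raise ValueError("cannot renormalise a weight vector with non-positive total")
        return replace(self, weights={k: v * 100.0 / t for k, v in self.weights.items()})

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.weights), name="weight")

    def __getitem__(self, criterion_id: str) -> float:
        return float(self.weights[criterion_id])


def standardise_weights(raw_weights):
    """Share-of-total standardisation: each weight becomes its share of the total, x100.

    Accepts a mapping (returns a dict in the same key order) or a sequence
    (returns a list).  Weights must be non-negative and not all zero.
    """
    if isinstance(raw_weights, Mapping):
        keys = list(raw_weights.keys())
        values = [float(raw_weights[k]) for k in keys]
    else:
        keys = None
        values = [float(v) for v in raw_weights]
    if any(v < 0 for v in values):
        raise ValueError("raw weights must be non-negative")
    total = sum(values)
    if total <= 0:
        raise ValueError("degenerate input: all raw weights are zero")
    out = [v / total * 100.0 for v in values]
    if keys is None:
        return out
    return dict(zip(keys, out))


def reciprocal_rank_weights(n: int) -> list[float]:
    """Surrogate weights for ranks 1..n, proportional to 1/k and summing to 100.

    Position ``k-1`` of the result is the weight for rank ``k``; H_n is the
    n-th harmonic number.
    """
    if n < 1:
        raise ValueError(f"criteria count must be >= 1, got {n}")
    h_n = sum(1.0 / j for j in range(1, n + 1))
    return [(1.0 / k) / h_n * 100.0 for k in range(1, n + 1)]


def classify_concordance(response: SwingResponse, criteria: CriteriaSet | None = None) -> str:
    """Label a complete response concordant or discordant.

    Concordant means the stated ranking matches the descending order of the
    stated weights, read non-strictly: a better (smaller) rank must carry a
    weight >= every worse-ranked criterion's weight.  Ties in weights between
    adjacent ranks therefore do not break concordance.
    """
    criteria = criteria or default_criteria_set()
    missing = response.missing_fields(criteria)
    if missing:
        raise IncompleteResponseError(
            f"response {response.respondent_id!r} is incomplete: {', '.join(missing)}"
        )
    by_rank = sorted(criteria.ids, key=lambda cid: int(response.ranks[cid]))
    w = [float(response.raw_weights[cid]) for cid in by_rank]
    for better, worse in zip(w, w[1:]):
        if better < worse:
            return DISCORDANT
    return CONCORDANT


def process_response(response: SwingResponse, criteria: CriteriaSet | None = None) -> ClassifiedResponse:
    """Classify one response and produce its standardised weight vector.

    Concordant responses keep their own standardised weights; discordant
    responses get reciprocal-of-rank surrogate weights, so their raw weights
    have no influence on the result.
    """
    criteria = criteria or default_criteria_set()
    category = classify_concordance(response, criteria)
    if category == CONCORDANT:
        std = standardise_weights({cid: response.raw_weights[cid] for cid in criteria.ids})
    else:
        by_rank = reciprocal_rank_weights(criteria.n)
        std = {cid: by_rank[int(response.ranks[cid]) - 1] for cid in criteria.ids}
    return ClassifiedResponse(response=response, category=category, standardised_weights=std)


def mean_weight_vector(
    classified: Sequence[ClassifiedResponse],
    subset: str = "combined",
) -> WeightVector:
    """Per-criterion arithmetic mean of standardised weights over a subset.

    ``subset`` is ``"combined"`` (all complete responses, concordant weights
    plus imputed discordant ones) or ``"concordant_only"``.
    """
    if subset == "combined":
        pool = list(classified)
    elif subset == "concordant_only":
        pool = [c for c in classified if c.category == CONCORDANT]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not pool:
        raise ValueError(f"degenerate input: no responses in subset {subset!r}")
    ids = list(pool[0].standardised_weights.keys())
    means = {
        cid: float(np.mean([c.standardised_weights[cid] for c in pool])) for cid in ids
    }
    return WeightVector(weights=means, provenance=subset, n_responses=len(pool))


@dataclass(frozen=True)
class SurveySummary:
    """Respondent accounting: completion, concordance split, demographics, rank shares."""

    n_total: int
    n_complete: int
    completion_pct: float | None
    n_concordant: int
    n_discordant: int
    concordant_pct: float | None
    discordant_pct: float | None
    background_counts: Mapping[str, int]
    background_pct: Mapping[str, float]
    affiliation_counts: Mapping[str, int]
    experience_counts: Mapping[str, int]
    rank_position_props: pd.DataFrame  # criteria x rank, proportions over complete
    rank1_share_pct: Mapping[str, float]

    def to_text(self) -> str:
        lines = [
            f"responses: {self.n_total} total, {self.n_complete} complete"
            + (f" ({self.completion_pct:.0f}%)" if self.completion_pct is not None else ""),
        ]
        if self.n_complete:
            lines.append(
                f"concordant: {self.n_concordant} ({self.concordant_pct}%), "
                f"discordant: {self.n_discordant} ({self.discordant_pct}%)"
            )
            lines.append("background (complete responses):")
            for k, v in self.background_counts.items():
                lines.append(f"  {k}: {v} ({self.background_pct[k]}%)")
            lines.append("share of rank-1 votes:")
            for k, v in self.rank1_share_pct.items():
                lines.append(f"  {k}: {v}%")
        return "\n".join(lines)


def summarise_survey(
    responses: Sequence[SwingResponse],
    criteria: CriteriaSet | None = None,
) -> SurveySummary:
    """Counts and percentages describing a survey: the 'who answered what' table.

    Completion is reported to the whole percent, the concordant/discordant
    split and rank-1 shares to one decimal (half-up), matching conventional
    survey reporting.  Percentages are absent (None) when a denominator is 0.
    """
    criteria = criteria or default_criteria_set()
    n_total = len(responses)
    complete = [r for r in responses if r.is_complete(criteria)]
    n_complete = len(complete)
    completion_pct = round_half_up(n_complete / n_total * 100, 0) if n_total else None

    labels = [classify_concordance(r, criteria) for r in complete]
    n_conc = labels.count(CONCORDANT)
    n_disc = n_complete - n_conc
    conc_pct = round_half_up(n_conc / n_complete * 100, 1) if n_complete else None
    disc_pct = round_half_up(n_disc / n_complete * 100, 1) if n_complete else None

    bg = Counter(r.background for r in complete)
    bg_pct = {k: round_half_up(v / n_complete * 100, 1) for k, v in bg.items()} if n_complete else {}
    aff = Counter(r.paid_affiliation for r in complete)
    exp = Counter(r.trial_experience for r in complete)

    counts = np.zeros((criteria.n, criteria.n))
    for r in complete:
        for row, cid in enumerate(criteria.ids):
            counts[row, int(r.ranks[cid]) - 1] += 1.0
    prop = pd.DataFrame(
        counts / n_complete if n_complete else counts,
        index=list(criteria.ids),
        columns=list(range(1, criteria.n + 1)),
    )
    rank1 = {
        cid: round_half_up(float(prop.loc[cid, 1]) * 100, 1) if n_complete else 0.0
        for cid in criteria.ids
    }
    return SurveySummary(
        n_total=n_total,
        n_complete=n_complete,
        completion_pct=completion_pct,
        n_concordant=n_conc,
        n_discordant=n_disc,
        concordant_pct=conc_pct,
        discordant_pct=disc_pct,
        background_counts=dict(bg),
        background_pct=bg_pct,
        affiliation_counts=dict(aff),
        experience_counts=dict(exp),
        rank_position_props=prop,
        rank1_share_pct=rank1,
    )


class SwingWeightModel:
    """Swing-weighting estimator over a set of survey responses.

    Parameters
    ----------
    responses : sequence of SwingResponse
        Raw survey responses; incomplete ones are kept for accounting but
        excluded from weight estimation.
    criteria : CriteriaSet, optional
        The instrument's criteria (defaults to the seven-criterion set).

    ``fit`` classifies every complete response, imputes surrogate weights for
    discordant ones, and averages into a portfolio weight vector.
    """

    def __init__(self, responses: Iterable[SwingResponse], criteria: CriteriaSet | None = None):
        self.responses = list(responses)
        self.criteria = criteria or default_criteria_set()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, criteria: CriteriaSet | None = None) -> "SwingWeightModel":
        """Build from a survey table with rank_<id> and weight_<id> columns."""
        criteria = criteria or default_criteria_set()
        from .io import responses_from_frame  # local import to avoid a cycle

        return cls(responses_from_frame(df, criteria), criteria)

    def fit(self, subset: str = "combined") -> "SwingWeightResults":
        complete = [r for r in self.responses if r.is_complete(self.criteria)]
        classified = [process_response(r, self.criteria) for r in complete]
        summary = summarise_survey(self.responses, self.criteria)
        weights = mean_weight_vector(classified, subset=subset)
        return SwingWeightResults(
            model=self, subset=subset, classified=classified, weights=weights, survey=summary
        )


@dataclass
class SwingWeightResults:
    """Fitted mean weight vector plus the classification and survey accounting behind it."""

    model: SwingWeightModel
    subset: str
    classified: list[ClassifiedResponse]
    weights: WeightVector
    survey: SurveySummary

    def weights_frame(self) -> pd.DataFrame:
        """Per-criterion mean weight with the between-respondent spread."""
        ids = list(self.weights.weights.keys())
        pool = (
            self.classified
            if self.subset == "combined"
            else [c for c in self.classified if c.category == CONCORDANT]
        )
        rows = []
        for cid in ids:
            vals = np.array([c.standardised_weights[cid] for c in pool])
            rows.append(
                {
                    "criterion": cid,
                    "mean_weight": self.weights[cid],
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": len(vals),
                }
            )
        return pd.DataFrame(rows).set_index("criterion")

    def summary(self) -> str:
        head = (
            f"Swing-weight model: {self.weights.n_responses} responses "
            f"(subset={self.subset})\n"
        )
        table = self.weights_frame().round(2).to_string()
        return head + self.survey.to_text() + "\n\nmean standardised weights:\n" + table
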