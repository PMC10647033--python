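"""Weighted-sum aggregation of partial values into trial value scores.

Each trial's raw metrics are passed through the criterion PVFs to partial
values on 0-100; each partial value is multiplied by its criterion's weight
share (weight / 100); the contributions sum to the aggregate trial value,
which therefore also lives on 0-100.  A portfolio is ranked by descending
aggregate, ties broken lexicographically by trial id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .criteria import CriteriaSet, TrialRecord, default_criteria_set
from .pvf import PartialValueFunction
from .weights import (
    CONCORDANT,
    ClassifiedResponse,
    WeightVector,
    mean_weight_vector,
)

__all__ = [
    "TrialValuation",
    "SensitivityReport",
    "ValueModel",
    "PortfolioResults",
    "value_trial",
    "value_portfolio",
    "dominant_criterion",
    "sensitivity_compare",
    "rank_inversions",
]


@dataclass(frozen=True)
class TrialValuation:
    """One trial's partial values, weighted contributions and aggregate value."""

    trial_id: str
    partial_values: Mapping[str, float]
    contributions: Mapping[str, float]
    aggregate: float

    def dominant(self) -> tuple[str, ...]:
        """Criterion(s) contributing the most value (all of them if tied)."""
        best = max(self.contributions.values())
        return tuple(cid for cid, c in self.contributions.items() if c == best)


def _check_coverage(criteria: CriteriaSet, pvfs, weights: WeightVector) -> None:
    for crit in criteria:
        if crit.id not in pvfs:
            raise ValueError(f"no partial value function configured for criterion {crit.id!r}")
        if crit.id not in weights.weights:
            raise ValueError(f"no weight configured for criterion {crit.id!r}")


def value_trial(
    record: TrialRecord,
    pvfs: Mapping[str, PartialValueFunction],
    weights: WeightVector,
    criteria: CriteriaSet | None = None,
) -> TrialValuation:
    """Score one trial: partial values, per-criterion contributions, aggregate."""
    criteria = criteria or default_criteria_set()
    _check_coverage(criteria, pvfs, weights)
    partial: dict[str, float] = {}
    contrib: dict[str, float] = {}
    for crit in criteria:
        if crit.id not in record.raw_values:
            raise ValueError(f"trial {record.trial_id!r} has no value for criterion {crit.id!r}")
        x = crit.prepare_value(record.raw_values[crit.id])
        v = pvfs[crit.id].evaluate(x)
        partial[crit.id] = v
        contrib[crit.id] = weights[crit.id] / 100.0 * v
    return TrialValuation(
        trial_id=record.trial_id,
        partial_values=partial,
        contributions=contrib,
        aggregate=float(sum(contrib.values())),
    )


def value_portfolio(
    records: Sequence[TrialRecord],
    pvfs: Mapping[str, PartialValueFunction],
    weights: WeightVector,
    criteria: CriteriaSet | None = None,
) -> list[TrialValuation]:
    """Score a portfolio and rank it by descending aggregate (ties by trial id)."""
    if not records:
        raise ValueError("empty portfolio")
    vals = [value_trial(r, pvfs, weights, criteria) for r in records]
    return sorted(vals, key=lambda v: (-v.aggregate, v.trial_id))


def dominant_criterion(
    valuations: Sequence[TrialValuation],
) -> tuple[dict[str, tuple[str, ...]], tuple[str, ...], int]:
    """Per-trial dominant criterion plus the modal one across the portfolio.

    Returns ``(per_trial, modal_criteria, modal_count)`` where ``per_trial``
    maps trial id to the tuple of top-contributing criteria (ties reported in
    full) and ``modal_count`` is how many trials the modal criterion leads.
    """
    if not valuations:
        raise ValueError("no valuations given")
    per_trial = {v.trial_id: v.dominant() for v in valuations}
    counts: dict[str, int] = {}
    for doms in per_trial.values():
        for cid in doms:
            counts[cid] = counts.get(cid, 0) + 1
    top = max(counts.values())
    modal = tuple(sorted(cid for cid, c in counts.items() if c == top))
    return per_trial, modal, top


def rank_inversions(order_a: Sequence[str], order_b: Sequence[str]) -> int:
    """Number of trial pairs ordered differently by two rankings (Kendall distance)."""
    pos = {t: i for i, t in enumerate(order_b)}
    inv = 0
    for i, ti in enumerate(order_a):
        for tj in order_a[i + 1:]:
            if pos[ti] > pos[tj]:
                inv += 1
    return inv


@dataclass(frozen=True)
class SensitivityReport:
    """Combined vs concordant-only weights and their effect on the portfolio.

    The comparison metrics are simple and explicit: per-criterion absolute
    weight differences, per-trial absolute aggregate differences, and the
    number of pairwise rank inversions between the two portfolio orderings.
    """

    weights_combined: WeightVector
    weights_concordant_only: WeightVector
    valuations_combined: list[TrialValuation]
    valuations_concordant_only: list[TrialValuation]
    weight_delta: Mapping[str, float]
    aggregate_delta: Mapping[str, float]
    order_combined: tuple[str, ...]
    order_concordant_only: tuple[str, ...]
    n_rank_inversions: int

    def to_frame(self) -> pd.DataFrame:
        agg_c = {v.trial_id: v.aggregate for v in self.valuations_combined}
        agg_k = {v.trial_id: v.aggregate for v in self.valuations_concordant_only}
        return pd.DataFrame(
            {
                "aggregate_combined": pd.Series(agg_c),
                "aggregate_concordant_only": pd.Series(agg_k),
                "abs_delta": pd.Series(self.aggregate_delta),
            }
        ).sort_values("aggregate_combined", ascending=False)


def sensitivity_compare(
    classified: Sequence[ClassifiedResponse],
    records: Sequence[TrialRecord],
    pvfs: Mapping[str, PartialValueFunction],
    criteria: CriteriaSet | None = None,
) -> SensitivityReport:
    """Re-value a portfolio under combined vs concordant-only mean weights."""
    if not any(c.category == CONCORDANT for c in classified):
        raise ValueError("degenerate input: no concordant responses")
    w_comb = mean_weight_vector(classified, "combined")
    w_conc = mean_weight_vector(classified, "concordant_only")
    v_comb = value_portfolio(records, pvfs, w_comb, criteria)
    v_conc = value_portfolio(records, pvfs, w_conc, criteria)
    agg_conc = {v.trial_id: v.aggregate for v in v_conc}
    order_c = tuple(v.trial_id for v in v_comb)
    order_k = tuple(v.trial_id for v in v_conc)
    return SensitivityReport(
        weights_combined=w_comb,
        weights_concordant_only=w_conc,
        valuations_combined=v_comb,
        valuations_concordant_only=v_conc,
        weight_delta={
            cid: abs(w_comb[cid] - w_conc[cid]) for cid in w_comb.weights
        },
        aggregate_delta={
            v.trial_id: abs(v.aggregate - agg_conc[v.trial_id]) for v in v_comb
        },
        order_combined=order_c,
        order_concordant_only=order_k,
        n_rank_inversions=rank_inversions(order_c, order_k),
    )


class ValueModel:
    """The assembled MCDA instrument: criteria, PVFs and a weight vector.

    ``score`` applies it to a portfolio of trial records and returns a
    :class:`PortfolioResults` with the ranked valuations.
    """

    def __init__(
        self,
        pvfs: Mapping[str, PartialValueFunction],
        weights: WeightVector,
        criteria: CriteriaSet | None = None,
        renormalise_weights: bool = False,
    ):
        self.criteria = criteria or default_criteria_set()
        self.pvfs = dict(pvfs)
        self.weights = weights.renormalised() if renormalise_weights else weights
        _check_coverage(self.criteria, self.pvfs, self.weights)

    def score(self, records: Sequence[TrialRecord]) -> "PortfolioResults":
        return PortfolioResults(self, value_portfolio(records, self.pvfs, self.weights, self.criteria))


@dataclass
class PortfolioResults:
    """Ranked trial valuations produced by a :class:`ValueModel`."""

    model: ValueModel
    valuations: list[TrialValuation]

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(v.trial_id for v in self.valuations)

    def aggregates(self) -> dict[str, float]:
        return {v.trial_id: v.aggregate for v in self.valuations}

    def to_frame(self) -> pd.DataFrame:
        """Wide report: one row per trial with partial values, contributions, aggregate."""
        rows = []
        for rank, v in enumerate(self.valuations, start=1):
            row: dict = {"trial_id": v.trial_id, "rank": rank, "aggregate": v.aggregate}
            for cid in self.model.criteria.ids:
                row[f"value_{cid}"] = v.partial_values[cid]
                row[f"contribution_{cid}"] = v.contributions[cid]
            rows.append(row)
        return pd.DataFrame(rows).set_index("trial_id")

    def contributions_long(self) -> pd.DataFrame:
        """Long-format table (trial, criterion, contribution) for stacked-bar plots."""
        rows = [
            {"trial_id": v.trial_id, "criterion": cid, "contribution": c, "aggregate": v.aggregate}
            for v in self.valuations
            for cid, c in v.contributions.items()
        ]
        return pd.DataFrame(rows)

    def dominant_criterion(self):
        return dominant_criterion(self.valuations)

    def plot_contributions(self, ax=None):
        """Stacked bar of per-criterion contributions, one bar per trial."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        ids = list(self.model.criteria.ids)
        bottoms = [0.0] * len(self.valuations)
        xs = range(len(self.valuations))
        for cid in ids:
            heights = [v.contributions[cid] for v in self.valuations]
            ax.bar(xs, heights, bottom=bottoms, label=cid)
            bottoms = [b + h for b, h in zip(bottoms, heights)]
        ax.set_xticks(list(xs))
        ax.set_xticklabels([v.trial_id for v in self.valuations], rotation=30, ha="right")
        ax.set_ylabel("contribution to aggregate value (0-100)")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        w = self.model.weights
        lines = [
            f"Portfolio of {len(self.valuations)} trials, "
            f"weights: {w.provenance} (n={w.n_responses}, total={w.total():.1f})",
            "",
            self.to_frame()[["rank", "aggregate"]].round(2).to_string(),
        ]
        per_trial, modal, count = self.dominant_criterion()
        lines.append("")
        lines.append(
            f"dominant criterion: {', '.join(modal)} leads in {count} of "
            f"{len(self.valuations)} trials"
        )
        return "\n".join(lines)
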