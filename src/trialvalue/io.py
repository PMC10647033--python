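"""Delimited-text and config I/O for surveys, portfolios, weights and reports.

All tables are comma-separated UTF-8 with a header row and a "." decimal
separator; criterion columns are identified by id (``rank_<id>``,
``weight_<id>``, or the id itself for portfolios), never by position.
Unanswered survey questions are empty cells.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .criteria import CriteriaSet, TrialRecord, default_criteria_set
from .utils import round_half_up
from .weights import SwingResponse, WeightVector

__all__ = [
    "responses_from_frame",
    "read_survey",
    "write_survey",
    "read_portfolio",
    "write_portfolio",
    "read_weights",
    "write_weights",
    "read_midpoints",
    "write_valuation_report",
    "write_metadata",
]

_DEMOGRAPHICS = ("background", "paid_affiliation", "trial_experience", "country")


def _cell(value):
    """Empty CSV cells (NaN after pandas parsing) become missing answers."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def responses_from_frame(df: pd.DataFrame, criteria: CriteriaSet | None = None) -> list[SwingResponse]:
    """Parse a survey table into responses, tolerating partially answered rows."""
    criteria = criteria or default_criteria_set()
    if "respondent_id" not in df.columns:
        raise ValueError("survey table needs a 'respondent_id' column")
    out: list[SwingResponse] = []
    for _, row in df.iterrows():
        ranks: dict[str, int] = {}
        weights: dict[str, float] = {}
        for cid in criteria.ids:
            r = _cell(row.get(f"rank_{cid}"))
            if r is not None:
                ranks[cid] = int(r)
            w = _cell(row.get(f"weight_{cid}"))
            if w is not None:
                weights[cid] = float(w)
        demo = {name: str(_cell(row.get(name)) or "") for name in _DEMOGRAPHICS}
        out.append(
            SwingResponse(
                respondent_id=str(row["respondent_id"]),
                ranks=ranks,
                raw_weights=weights,
                **demo,
            )
        )
    return out


def survey_to_frame(responses: Sequence[SwingResponse], criteria: CriteriaSet | None = None) -> pd.DataFrame:
    criteria = criteria or default_criteria_set()
    rows = []
    for r in responses:
        row: dict = {"respondent_id": r.respondent_id}
        for name in _DEMOGRAPHICS:
            row[name] = getattr(r, name)
        for cid in criteria.ids:
            row[f"rank_{cid}"] = r.ranks.get(cid)
            row[f"weight_{cid}"] = r.raw_weights.get(cid)
        rows.append(row)
    cols = (
        ["respondent_id", *_DEMOGRAPHICS]
        + [f"rank_{cid}" for cid in criteria.ids]
        + [f"weight_{cid}" for cid in criteria.ids]
    )
    return pd.DataFrame(rows, columns=cols)


def write_survey(responses: Sequence[SwingResponse], path, criteria: CriteriaSet | None = None) -> None:
    survey_to_frame(responses, criteria).to_csv(path, index=False)


def read_survey(path, criteria: CriteriaSet | None = None) -> list[SwingResponse]:
    return responses_from_frame(pd.read_csv(path), criteria)


def read_portfolio(path, criteria: CriteriaSet | None = None) -> list[TrialRecord]:
    """Read a trial table: ``trial_id`` plus one column per criterion id."""
    criteria = criteria or default_criteria_set()
    df = pd.read_csv(path)
    if "trial_id" not in df.columns:
        raise ValueError("trial table needs a 'trial_id' column")
    records = []
    for _, row in df.iterrows():
        raw = {}
        for cid in criteria.ids:
            if cid in df.columns:
                v = _cell(row[cid])
                if v is not None:
                    raw[cid] = v
        records.append(TrialRecord(trial_id=str(row["trial_id"]), raw_values=raw))
    return records


def write_portfolio(records: Sequence[TrialRecord], path, criteria: CriteriaSet | None = None) -> None:
    criteria = criteria or default_criteria_set()
    rows = [
        {"trial_id": r.trial_id, **{cid: r.raw_values.get(cid) for cid in criteria.ids}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["trial_id", *criteria.ids]).to_csv(path, index=False)


def write_weights(weights: WeightVector, path) -> None:
    payload = {
        "weights": {k: float(v) for k, v in weights.weights.items()},
        "provenance": weights.provenance,
        "n_responses": int(weights.n_responses),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_weights(path) -> WeightVector:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return WeightVector(
        weights={k: float(v) for k, v in payload["weights"].items()},
        provenance=payload.get("provenance", "manual"),
        n_responses=int(payload.get("n_responses", 0)),
    )


def read_midpoints(path):
    """Read bisection elicitations: criterion_id, respondent_id, midpoint columns."""
    from .pvf import MidpointElicitation

    df = pd.read_csv(path)
    needed = {"criterion_id", "midpoint"}
    if not needed.issubset(df.columns):
        raise ValueError("midpoint table needs 'criterion_id' and 'midpoint' columns")
    return [
        MidpointElicitation(
            criterion_id=str(row["criterion_id"]),
            respondent_id=str(row.get("respondent_id", "")),
            midpoint_raw=float(row["midpoint"]),
        )
        for _, row in df.iterrows()
    ]


def write_valuation_report(results, path, precision: int = 2) -> None:
    """Write the ranked valuation table, rounded half-up to ``precision``.

    A full-precision companion ``<path stem>_full<suffix>`` is always written
    alongside, so downstream checks never depend on report rounding.
    """
    import os

    df = results.to_frame().reset_index()
    stem, suffix = os.path.splitext(str(path))
    df.to_csv(stem + "_full" + suffix, index=False)
    rounded = df.copy()
    for col in rounded.columns:
        if rounded[col].dtype.kind == "f":
            rounded[col] = rounded[col].map(lambda v: round_half_up(v, precision))
    rounded.to_csv(path, index=False)


def write_metadata(params: Mapping, path) -> None:
    """Sidecar provenance file echoing every generation parameter."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: _plain(v) for k, v in dict(params).items()}, fh, sort_keys=False)


def _plain(v):
    if isinstance(v, Mapping):
        return {k: _plain(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    if hasattr(v, "item"):  # numpy scalars
        return v.item()
    return v
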