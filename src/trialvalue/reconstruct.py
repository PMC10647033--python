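"""Inverse elicitation: recover PVF parameters from known aggregate scores.

When a deployed MCDA instrument's partial value functions are lost or
unpublished but its scored outputs are available (here: the six validation
trials and their published aggregates), the bent-stick midpoints and the
ordinal level values can be estimated by least squares.  The fit minimises
the squared aggregate residuals plus a small regulariser pulling each
parameter toward its neutral default (range centre / equal spacing), which
makes the under-determined problem well-posed and the solution deterministic.

The two-segment family is not guaranteed to reproduce a published score
column exactly; the returned report carries the per-trial residuals so the
caller can judge the fit rather than trust it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .criteria import CONTINUOUS, ORDINAL, CriteriaSet, TrialRecord, default_criteria_set
from .datasets import reference_aggregates, reference_portfolio, reference_weights
from .pvf import PartialValueFunction, build_bent_stick, categorical_pvf
from .valuation import value_trial
from .weights import WeightVector

__all__ = ["PvfFitReport", "fit_pvf_midpoints", "reconstruct_reference_pvfs"]

_EDGE = 0.01  # keep midpoints off the anchors by 1% of the range


@dataclass(frozen=True)
class PvfFitReport:
    """Diagnostics of an inverse PVF fit."""

    residuals: Mapping[str, float]  # trial_id -> fitted minus target aggregate
    max_abs_error: float
    midpoints: Mapping[str, float]
    level_values: Mapping[str, tuple[float, ...]]


def _parameterisation(criteria: CriteriaSet):
    """Variable layout: one midpoint per continuous criterion, one value per
    interior level of each ordinal criterion."""
    names: list[tuple[str, object]] = []
    x0: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    for crit in criteria:
        if crit.kind == CONTINUOUS:
            lo, hi = crit.raw_interval()
            span = hi - lo
            names.append((crit.id, "mid"))
            x0.append((lo + hi) / 2.0)
            lb.append(lo + _EDGE * span)
            ub.append(hi - _EDGE * span)
        else:
            n = len(crit.levels)
            for i in range(1, n - 1):  # anchors stay at 0 and 100
                names.append((crit.id, i))
                x0.append(100.0 * i / (n - 1))
                lb.append(0.0)
                ub.append(100.0)
    return names, np.array(x0), np.array(lb), np.array(ub)


def _build_pvfs(criteria: CriteriaSet, names, x) -> dict[str, PartialValueFunction]:
    mids: dict[str, float] = {}
    levels: dict[str, list[float]] = {}
    for (cid, which), v in zip(names, x):
        if which == "mid":
            mids[cid] = float(v)
        else:
            levels.setdefault(cid, []).append(float(v))
    out: dict[str, PartialValueFunction] = {}
    for crit in criteria:
        if crit.kind == CONTINUOUS:
            out[crit.id] = build_bent_stick(crit, mids[crit.id])
        else:
            interior = sorted(levels.get(crit.id, []))  # monotone by construction
            out[crit.id] = categorical_pvf(crit, [0.0, *interior, 100.0])
    return out


def fit_pvf_midpoints(
    records: Sequence[TrialRecord],
    aggregates: Mapping[str, float],
    weights: WeightVector,
    criteria: CriteriaSet | None = None,
    regularisation: float = 0.02,
) -> tuple[dict[str, PartialValueFunction], PvfFitReport]:
    """Fit bent-stick midpoints and ordinal level values to known aggregates.

    Parameters
    ----------
    records : trial records whose aggregates are known
    aggregates : trial_id -> known aggregate value on the 0-100 scale
    weights : the weight vector the instrument used
    regularisation : pull (per unit of scaled parameter) toward neutral defaults

    Returns the fitted PVF set and a :class:`PvfFitReport` with residuals.
    """
    criteria = criteria or default_criteria_set()
    records = [r for r in records if r.trial_id in aggregates]
    if not records:
        raise ValueError("no records match the given aggregates")
    names, x0, lb, ub = _parameterisation(criteria)
    scale = ub - lb
    targets = np.array([float(aggregates[r.trial_id]) for r in records])

    def residuals(x: np.ndarray) -> np.ndarray:
        pvfs = _build_pvfs(criteria, names, x)
        agg = np.array(
            [value_trial(r, pvfs, weights, criteria).aggregate for r in records]
        )
        reg = regularisation * (x - x0) / scale
        return np.concatenate([agg - targets, reg])

    sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    pvfs = _build_pvfs(criteria, names, sol.x)
    fitted = {r.trial_id: value_trial(r, pvfs, weights, criteria).aggregate for r in records}
    resid = {tid: fitted[tid] - float(aggregates[tid]) for tid in fitted}
    mids = {p.criterion_id: p.mid_raw for p in pvfs.values() if p.kind == CONTINUOUS}
    lvls = {
        p.criterion_id: tuple(p.level_values.values())
        for p in pvfs.values()
        if p.kind == ORDINAL
    }
    report = PvfFitReport(
        residuals=resid,
        max_abs_error=float(max(abs(v) for v in resid.values())),
        midpoints=mids,
        level_values=lvls,
    )
    return pvfs, report


def reconstruct_reference_pvfs(
    renormalise_weights: bool = False,
) -> tuple[dict[str, PartialValueFunction], PvfFitReport]:
    """Fit the PVF set of the original instrument from its published validation scores."""
    weights = reference_weights()
    if renormalise_weights:
        weights = weights.renormalised()
    return fit_pvf_midpoints(
        reference_portfolio(), reference_aggregates(), weights
    )
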