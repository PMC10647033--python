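"""Bent-stick partial value functions (PVFs).

A PVF maps one criterion's raw metric onto the common 0-100 value scale.  For
continuous criteria the shape is elicited by bisection: stakeholders name the
raw value they consider exactly half as valuable a swing as worst-to-best, and
the PVF is two straight segments, worst anchor (value 0) to that midpoint
(value 50), then midpoint to best anchor (value 100).  Direction is carried by
the anchors themselves, so a cost criterion whose worst anchor is numerically
largest needs no special casing.  Ordinal criteria map each level to a fixed
value, 0 at the first level and 100 at the last.

Raw inputs outside the elicited range are clamped to the nearer anchor, so
every evaluation lands in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

from .criteria import CONTINUOUS, ORDINAL, CriteriaSet, Criterion

__all__ = [
    "MidpointElicitation",
    "PartialValueFunction",
    "average_midpoint",
    "build_bent_stick",
    "categorical_pvf",
    "default_pvf_set",
    "load_pvf_config",
    "pvf_set_to_config",
    "save_pvf_config",
]


@dataclass(frozen=True)
class MidpointElicitation:
    """One stakeholder's bisection answer: the raw value they equate with value 50."""

    criterion_id: str
    respondent_id: str
    midpoint_raw: float


@dataclass(frozen=True)
class PartialValueFunction:
    """Piecewise-linear map from a criterion's raw scale to value in [0, 100]."""

    criterion_id: str
    kind: str = CONTINUOUS
    worst_raw: float | None = None
    best_raw: float | None = None
    mid_raw: float | None = None
    level_values: Mapping[str, float] | None = None  # ordinal criteria only

    def __post_init__(self) -> None:
        if self.kind == CONTINUOUS:
            if self.worst_raw is None or self.best_raw is None or self.mid_raw is None:
                raise ValueError(f"{self.criterion_id}: continuous PVF needs worst, best and mid")
            _check_between(self.criterion_id, self.worst_raw, self.mid_raw, self.best_raw)
        elif self.kind == ORDINAL:
            if not self.level_values:
                raise ValueError(f"{self.criterion_id}: ordinal PVF needs level values")
            vals = list(self.level_values.values())
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{self.criterion_id}: level values must be non-decreasing")
            if vals[0] != 0 or vals[-1] != 100:
                raise ValueError(f"{self.criterion_id}: level values must run from 0 to 100")
        else:
            raise ValueError(f"{self.criterion_id}: unknown kind {self.kind!r}")

    def evaluate(self, x) -> float:
        """Value in [0, 100] for a raw metric value or category label."""
        if self.kind == ORDINAL:
            assert self.level_values is not None
            try:
                return float(self.level_values[x])
            except KeyError:
                raise ValueError(
                    f"{self.criterion_id}: unknown level {x!r}; "
                    f"expected one of {list(self.level_values)}"
                ) from None
        worst, best, mid = float(self.worst_raw), float(self.best_raw), float(self.mid_raw)
        x = float(x)
        lo, hi = sorted((worst, best))
        x = min(max(x, lo), hi)
        if worst < best:  # value increases with the metric
            if x <= mid:
                return (x - worst) / (mid - worst) * 50.0
            return 50.0 + (x - mid) / (best - mid) * 50.0
        # decreasing metric (cost, survival-as-unmet-need)
        if x >= mid:
            return (worst - x) / (worst - mid) * 50.0
        return 50.0 + (mid - x) / (mid - best) * 50.0


def _check_between(cid: str, worst: float, mid: float, best: float) -> None:
    lo, hi = sorted((worst, best))
    if not lo < mid < hi:
        raise ValueError(
            f"{cid}: midpoint {mid} must lie strictly between the anchors ({worst}, {best})"
        )


def average_midpoint(elicitations: Sequence[MidpointElicitation]) -> float:
    """Arithmetic mean of the elicited value-50 midpoints for one criterion."""
    if not elicitations:
        raise ValueError("degenerate input: no midpoint elicitations")
    ids = {e.criterion_id for e in elicitations}
    if len(ids) != 1:
        raise ValueError(f"elicitations mix criteria: {sorted(ids)}")
    return float(sum(e.midpoint_raw for e in elicitations)) / len(elicitations)


def build_bent_stick(criterion: Criterion, mid_raw: float) -> PartialValueFunction:
    """Two-segment PVF for a continuous criterion from its averaged midpoint."""
    if criterion.kind != CONTINUOUS:
        raise TypeError(f"{criterion.id} is categorical; give it level values instead")
    _check_between(criterion.id, criterion.worst_raw, mid_raw, criterion.best_raw)
    return PartialValueFunction(
        criterion_id=criterion.id,
        kind=CONTINUOUS,
        worst_raw=float(criterion.worst_raw),
        best_raw=float(criterion.best_raw),
        mid_raw=float(mid_raw),
    )


def categorical_pvf(criterion: Criterion, level_values: Sequence[float] | None = None) -> PartialValueFunction:
    """PVF for an ordinal criterion; defaults to equally spaced level values."""
    if criterion.kind != ORDINAL:
        raise TypeError(f"{criterion.id} is continuous; build a bent stick instead")
    n = len(criterion.levels)
    if level_values is None:
        level_values = [100.0 * i / (n - 1) for i in range(n)]
    if len(level_values) != n:
        raise ValueError(
            f"{criterion.id}: {n} levels but {len(level_values)} level values"
        )
    return PartialValueFunction(
        criterion_id=criterion.id,
        kind=ORDINAL,
        level_values=dict(zip(criterion.levels, (float(v) for v in level_values))),
    )


def default_pvf_set(
    criteria: CriteriaSet,
    midpoints: Mapping[str, float] | None = None,
    level_values: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, PartialValueFunction]:
    """A complete PVF set: elicited midpoints where given, neutral shapes elsewhere.

    A continuous criterion with no elicited midpoint gets the exact middle of
    its range, i.e. a single straight line; an ordinal criterion with no
    configured values gets equal spacing.
    """
    midpoints = midpoints or {}
    level_values = level_values or {}
    out: dict[str, PartialValueFunction] = {}
    for crit in criteria:
        if crit.kind == CONTINUOUS:
            mid = midpoints.get(crit.id, (float(crit.worst_raw) + float(crit.best_raw)) / 2.0)
            out[crit.id] = build_bent_stick(crit, mid)
        else:
            out[crit.id] = categorical_pvf(crit, level_values.get(crit.id))
    return out


def load_pvf_config(config, criteria: CriteriaSet) -> dict[str, PartialValueFunction]:
    """Build a PVF set from a config mapping (or a YAML path).

    Per criterion the config may give ``mid`` (bent stick from the criterion's
    anchors), explicit ``worst``/``best``/``mid`` overriding the anchors, or
    ``level_values`` for ordinal criteria.  Every criterion in the set must be
    covered.
    """
    if not isinstance(config, Mapping):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    out: dict[str, PartialValueFunction] = {}
    for crit in criteria:
        if crit.id not in config:
            raise ValueError(f"PVF config is missing criterion {crit.id!r}")
        entry = config[crit.id]
        try:
            if crit.kind == ORDINAL or "level_values" in entry:
                vals = entry["level_values"]
                if isinstance(vals, Mapping):
                    vals = [vals[lv] for lv in crit.levels]
                out[crit.id] = categorical_pvf(crit, vals)
            else:
                worst = float(entry.get("worst", crit.worst_raw))
                best = float(entry.get("best", crit.best_raw))
                out[crit.id] = PartialValueFunction(
                    criterion_id=crit.id,
                    kind=CONTINUOUS,
                    worst_raw=worst,
                    best_raw=best,
                    mid_raw=float(entry["mid"]),
                )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"PVF config invalid for criterion {crit.id!r}: {exc}") from exc
    return out


def pvf_set_to_config(pvfs: Mapping[str, PartialValueFunction]) -> dict:
    out: dict = {}
    for cid, p in pvfs.items():
        if p.kind == ORDINAL:
            out[cid] = {"level_values": dict(p.level_values)}
        else:
            out[cid] = {"worst": p.worst_raw, "best": p.best_raw, "mid": p.mid_raw}
    return out


def save_pvf_config(pvfs: Mapping[str, PartialValueFunction], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(pvf_set_to_config(pvfs), fh, sort_keys=False)
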