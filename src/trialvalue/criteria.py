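"""Value criteria for clinical-trial MCDA and the trial records scored against them.

A criterion maps one measurable property of a trial (five-year survival of the
target disease, overall-survival gain, total cost, ...) onto the common 0-100
value scale via a partial value function.  The direction of value is encoded
purely by the ordering of ``worst_raw`` and ``best_raw``: for total cost the
worst anchor (105 M AUD) is numerically *larger* than the best (3 M AUD), and
no separate sign flag exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Criterion",
    "CriteriaSet",
    "TrialRecord",
    "ValidationFinding",
    "CRITERION_IDS",
    "default_criteria_set",
    "validate_trial",
    "access_percent_to_level",
]

#: canonical ordering of the seven-criterion instrument
CRITERION_IDS = (
    "unmet_need",
    "population_size",
    "trial_access",
    "patient_outcomes",
    "total_cost",
    "academic_impact",
    "use_of_results",
)

CONTINUOUS = "continuous"
ORDINAL = "ordinal_categorical"


def access_percent_to_level(percent: float) -> int:
    """Map percent-of-eligible-patients access (0-100) onto the 1-5 level scale.

    Levels are 20-point bands: ``level = ceil(percent / 20)`` clamped to
    [1, 5], so 55% of eligible patients corresponds to level 3.
    """
    if not math.isfinite(percent):
        raise ValueError(f"access percent must be finite, got {percent!r}")
    return int(min(5, max(1, math.ceil(percent / 20.0))))


@dataclass(frozen=True)
class Criterion:
    """One value criterion: its measurement scale, range and value direction."""

    id: str
    label: str
    kind: str  # CONTINUOUS or ORDINAL
    worst_raw: float | None = None
    best_raw: float | None = None
    units: str = ""
    levels: tuple[str, ...] = ()
    metric_description: str = ""
    #: trial_access only: accept a percent 0-100 and band it onto levels 1-5
    percent_input: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, ORDINAL):
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")
        if self.kind == CONTINUOUS:
            if self.worst_raw is None or self.best_raw is None:
                raise ValueError(f"{self.id}: continuous criteria need worst/best anchors")
            if self.worst_raw == self.best_raw:
                raise ValueError(f"{self.id}: worst_raw equals best_raw")
        else:
            if len(self.levels) < 2:
                raise ValueError(f"{self.id}: ordinal criteria need >= 2 ordered levels")

    @property
    def increasing(self) -> bool:
        """True when value grows with the raw metric (best anchor above worst)."""
        if self.kind != CONTINUOUS:
            return True
        return self.best_raw > self.worst_raw  # type: ignore[operator]

    def raw_interval(self) -> tuple[float, float]:
        """Numeric (low, high) raw interval regardless of value direction."""
        if self.kind != CONTINUOUS:
            raise TypeError(f"{self.id} is categorical; it has no raw interval")
        lo, hi = sorted((float(self.worst_raw), float(self.best_raw)))
        return lo, hi

    def prepare_value(self, x):
        """Normalise a recorded raw entry onto the scale the PVF evaluates.

        For ``trial_access`` in percent-input mode this applies the 20-point
        band mapping; categorical labels are checked against the level list;
        everything else passes through as float.
        """
        if self.kind == ORDINAL:
            if x not in self.levels:
                raise ValueError(
                    f"{self.id}: unknown level {x!r}; expected one of {list(self.levels)}"
                )
            return x
        x = float(x)
        if self.percent_input:
            return float(access_percent_to_level(x))
        return x


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered collection of criteria; its length is the ``n`` of the instrument."""

    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def __iter__(self):
        return iter(self.criteria)

    def __getitem__(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def __contains__(self, criterion_id: str) -> bool:
        return any(c.id == criterion_id for c in self.criteria)

    def to_config(self) -> dict:
        out: dict = {}
        for c in self.criteria:
            entry: dict = {"label": c.label, "kind": c.kind, "units": c.units}
            if c.kind == CONTINUOUS:
                entry["worst"] = c.worst_raw
                entry["best"] = c.best_raw
                if c.percent_input:
                    entry["percent_input"] = True
            else:
                entry["levels"] = list(c.levels)
            out[c.id] = entry
        return out

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_config(cls, config: Mapping) -> "CriteriaSet":
        crits = []
        for cid, entry in config.items():
            kind = entry.get("kind", CONTINUOUS)
            crits.append(
                Criterion(
                    id=cid,
                    label=entry.get("label", cid),
                    kind=kind,
                    worst_raw=entry.get("worst"),
                    best_raw=entry.get("best"),
                    units=entry.get("units", ""),
                    levels=tuple(entry.get("levels", ())),
                    percent_input=bool(entry.get("percent_input", False)),
                )
            )
        return cls(tuple(crits))

    @classmethod
    def load(cls, path) -> "CriteriaSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass(frozen=True)
class TrialRecord:
    """A trial's raw metric entries, one per criterion (number or level label)."""

    trial_id: str
    raw_values: Mapping[str, object] = field(default_factory=dict)

    def value(self, criterion_id: str):
        return self.raw_values[criterion_id]


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    criterion_id: str
    message: str


def default_criteria_set() -> CriteriaSet:
    """The seven-criterion cancer clinical-trial instrument with its elicited ranges.

    Two criteria run *against* the numeric scale: unmet need is operationalised
    as five-year survival of the target disease (85% survival = well served,
    value 0; 18% = poorly served, value 100) and total cost runs from 105 M AUD
    (worst) down to 3 M AUD (best).
    """
    return CriteriaSet(
        (
            Criterion(
                id="unmet_need",
                label="Unmet need",
                kind=CONTINUOUS,
                worst_raw=85.0,
                best_raw=18.0,
                units="% 5-year survival",
                metric_description=(
                    "Five-year survival of the target cancer; poorer survival "
                    "means greater unmet need and hence greater trial value."
                ),
            ),
            Criterion(
                id="population_size",
                label="Size of target population",
                kind=CONTINUOUS,
                worst_raw=0.2,
                best_raw=1000.0,
                units="prevalence per 100,000",
                metric_description="Prevalence of the target disease.",
            ),
            Criterion(
                id="trial_access",
                label="Eligible participants can access the trial",
                kind=CONTINUOUS,
                worst_raw=1.0,
                best_raw=5.0,
                units="access level 1-5",
                percent_input=True,
                metric_description=(
                    "Share of eligible patients with geographic access, banded "
                    "onto levels 1 (<20%) to 5 (100%)."
                ),
            ),
            Criterion(
                id="patient_outcomes",
                label="Patient outcomes",
                kind=CONTINUOUS,
                worst_raw=3.0,
                best_raw=36.0,
                units="months overall-survival gain",
                metric_description="Increase in overall survival demonstrated by the trial.",
            ),
            Criterion(
                id="total_cost",
                label="Total trial cost",
                kind=CONTINUOUS,
                worst_raw=105.0,
                best_raw=3.0,
                units="million AUD",
                metric_description="Total cost of running the trial to completion.",
            ),
            Criterion(
                id="academic_impact",
                label="Academic impact",
                kind=CONTINUOUS,
                worst_raw=10.0,
                best_raw=1000.0,
                units="citations",
                metric_description="Citations received by the primary results publication.",
            ),
            Criterion(
                id="use_of_results",
                label="Use of trial results",
                kind=ORDINAL,
                levels=("unused", "informed_research", "regulatory_approval", "informed_policy"),
                metric_description=(
                    "How the results were used, in order of increasing value: "
                    "unused, informed research decisions, granted regulatory "
                    "approval, informed policy."
                ),
            ),
        )
    )


def validate_trial(record: TrialRecord, criteria: CriteriaSet) -> list[ValidationFinding]:
    """Check a trial record against a criteria set.

    Missing criteria and unknown categorical labels are errors.  Numeric
    values outside the elicited [worst, best] range are only *warnings*: real
    portfolios contain them (an overall-survival gain below the 3-month floor,
    citation counts above 1000) and evaluation clamps such values to the
    nearer anchor.
    """
    findings: list[ValidationFinding] = []
    for crit in criteria:
        if crit.id not in record.raw_values:
            findings.append(
                ValidationFinding("error", crit.id, f"{record.trial_id}: missing entry for {crit.id}")
            )
            continue
        x = record.raw_values[crit.id]
        if crit.kind == ORDINAL:
            if x not in crit.levels:
                findings.append(
                    ValidationFinding(
                        "error",
                        crit.id,
                        f"{record.trial_id}: unknown level {x!r} for {crit.id} "
                        f"(expected one of {list(crit.levels)})",
                    )
                )
            continue
        try:
            xv = float(x)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            findings.append(
                ValidationFinding("error", crit.id, f"{record.trial_id}: non-numeric value {x!r}")
            )
            continue
        if crit.percent_input:
            if not 0.0 <= xv <= 100.0:
                findings.append(
                    ValidationFinding(
                        "warning",
                        crit.id,
                        f"{record.trial_id}: access percent {xv} outside [0, 100]; "
                        "level will be clamped",
                    )
                )
            continue
        lo, hi = crit.raw_interval()
        if not lo <= xv <= hi:
            findings.append(
                ValidationFinding(
                    "warning",
                    crit.id,
                    f"{record.trial_id}: {crit.id} value {xv} outside [{lo}, {hi}] "
                    f"{crit.units}; it will be clamped to the nearer anchor",
                )
            )
    known = set(criteria.ids)
    for cid in record.raw_values:
        if cid not in known:
            findings.append(
                ValidationFinding("error", cid, f"{record.trial_id}: unknown criterion {cid!r}")
            )
    return findings
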